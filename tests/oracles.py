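"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — closed forms, exhaustive
enumeration, textbook formulas — and shares no code with the library paths
it validates.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# -- geodesy ------------------------------------------------------------

R_KM = 6371.0088


def law_of_cosines_km(lat1, lon1, lat2, lon2):
    """Spherical law of cosines great-circle distance (km)."""
    p1, l1, p2, l2 = map(math.radians, (lat1, lon1, lat2, lon2))
    c = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(l2 - l1)
    return R_KM * math.acos(min(1.0, max(-1.0, c)))


# -- alignment ----------------------------------------------------------


def brute_force_align_score(a: str, b: str, params) -> float:
    """Best global-alignment score by enumerating every monotone alignment.

    Scores each complete move string directly: a gap run of length L costs
    gap_open + L * gap_extend unless it is the first or last run of the
    alignment and end gaps are free.
    """
    best = float("-inf")
    open_, ext = params.gap_open, params.gap_extend
    free = params.free_end_gaps
    n, m = len(a), len(b)
    stack = [(0, 0, ())]  # i, j, moves (0 diag, 1 consume a, 2 consume b)
    out = []

    def score(moves) -> float:
        runs: list[list] = []
        for mv in moves:
            if runs and runs[-1][0] == mv:
                runs[-1][1] += 1
            else:
                runs.append([mv, 1])
        total = 0.0
        ai = bi = 0
        for ridx, (mv, L) in enumerate(runs):
            if mv == 0:
                for _ in range(L):
                    same = a[ai] == b[bi] and a[ai] != "N"
                    total += params.match if same else params.mismatch
                    ai += 1
                    bi += 1
            else:
                ai, bi = (ai + L, bi) if mv == 1 else (ai, bi + L)
                terminal = ridx == 0 or ridx == len(runs) - 1
                if not (free and terminal):
                    total += open_ + L * ext
        return total

    def rec(i, j, moves):
        nonlocal best
        if i == n and j == m:
            s = score(moves)
            if s > best:
                best = s
            return
        if i < n and j < m:
            rec(i + 1, j + 1, moves + (0,))
        if i < n:
            rec(i + 1, j, moves + (1,))
        if j < m:
            rec(i, j + 1, moves + (2,))

    rec(0, 0, ())
    return best


# -- matrix statistics --------------------------------------------------


def pearson_upper_triangles(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson correlation of the vectorized upper triangles."""
    iu = np.triu_indices(x.shape[0], k=1)
    vx, vy = x[iu], y[iu]
    vx = vx - vx.mean()
    vy = vy - vy.mean()
    return float((vx @ vy) / math.sqrt((vx @ vx) * (vy @ vy)))


def exhaustive_mantel_p(x: np.ndarray, y: np.ndarray, alternative="greater") -> float:
    """Exact permutation p by enumerating every joint relabeling of y."""
    n = x.shape[0]
    obs = pearson_upper_triangles(x, y)
    stats = []
    for perm in itertools.permutations(range(n)):
        p = np.asarray(perm)
        stats.append(pearson_upper_triangles(x, y[np.ix_(p, p)]))
    stats = np.asarray(stats)
    tol = 1e-12
    if alternative == "greater":
        count = np.sum(stats >= obs - tol)
    elif alternative == "less":
        count = np.sum(stats <= obs + tol)
    else:
        count = np.sum(np.abs(stats) >= abs(obs) - tol)
    return float(count) / len(stats)


# -- clustering ---------------------------------------------------------


def connected_component_partition(values: np.ndarray, labels, threshold: float):
    """Brute-force BFS connected components of the >= threshold graph."""
    n = len(labels)
    seen = set()
    groups = []
    for start in range(n):
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            i = frontier.pop()
            for j in range(n):
                if j != i and j not in comp and values[i, j] >= threshold:
                    comp.add(j)
                    frontier.append(j)
        seen |= comp
        groups.append(tuple(sorted(labels[i] for i in comp)))
    return tuple(sorted(groups, key=lambda g: g[0]))


def random_symmetric_similarity(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random similarity_percent matrix: symmetric, diagonal 100."""
    v = rng.uniform(0, 100, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 100.0)
    return v


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.uniform(0, 1000, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return v
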