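"""Matrix correlation tests for isolation-by-distance analyses.

Two statistics are implemented:

* the **standardized Mantel statistic** between two distance matrices,

  .. math:: r_M = \\frac{1}{d-1} \\sum_{i<j} \\mathrm{stand}(D_x)_{ij}\\,
            \\mathrm{stand}(D_y)_{ij}, \\qquad d = n(n-1)/2,

  which is exactly the Pearson correlation of the two vectorized upper
  triangles, with a permutation null formed by jointly relabeling the rows
  and columns of one matrix;

* the **Spearman rank correlation** between pairwise genetic similarity and
  a binary tectonic-plate sympatry matrix (average ranks for ties), with the
  same joint-relabeling permutation null.

For n <= 7 labels the full set of n! relabelings is enumerated and the
p-value is exact; otherwise a seeded Monte-Carlo sample is drawn and the
add-one convention (B+1 in the denominator, the observed statistic counted
once) keeps reported p-values in (0, 1].
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .fixtures_io import LabeledMatrix, SiteTable

EXHAUSTIVE_MAX_N = 7  # 7! = 5040 relabelings; beyond this Monte-Carlo takes over
DEFAULT_N_PERM = 9999
_TIE_TOL = 1e-12


class DegenerateMatrixError(ValueError):
    """All off-diagonal entries equal: the standardized statistic is undefined."""


class LabelMismatchError(ValueError):
    """The two matrices do not cover the same label set."""


@dataclass(frozen=True)
class MantelResult:
    r_m: float
    n: int
    d: int
    p_value: float | None
    n_perm: int
    exhaustive: bool
    alternative: str
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "statistic": "mantel_r_m",
            "r_m": self.r_m,
            "n": self.n,
            "d": self.d,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "exhaustive": self.exhaustive,
            "alternative": self.alternative,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class SpearmanResult:
    r_s: float
    n: int
    n_pairs: int
    p_value: float | None
    n_perm: int
    exhaustive: bool
    alternative: str
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "statistic": "spearman_r_s",
            "r_s": self.r_s,
            "n": self.n,
            "n_pairs": self.n_pairs,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "exhaustive": self.exhaustive,
            "alternative": self.alternative,
            "seed": self.seed,
        }


def standardize_upper_triangle(m: LabeledMatrix) -> np.ndarray:
    """Z-scores of the d off-diagonal upper-triangle entries.

    Uses the sample standard deviation (divisor d-1) so that
    (1/(d-1)) * sum(stand(x) * stand(y)) is exactly the Pearson sample
    correlation of the two vectors.
    """
    v = m.upper_triangle()
    if len(v) < 3:
        raise ValueError("need n >= 3 labels (at least 3 pairs) to standardize")
    sd = v.std(ddof=1)
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateMatrixError(
            f"all {len(v)} off-diagonal entries of the {m.kind} matrix are equal; "
            "the standardized statistic is undefined"
        )
    return (v - v.mean()) / sd


def _reconcile(x: LabeledMatrix, y: LabeledMatrix) -> LabeledMatrix:
    """Reorder y to x's label order; strict label-set equality."""
    sx, sy = set(x.labels), set(y.labels)
    if sx != sy:
        only_x = sorted(sx - sy)
        only_y = sorted(sy - sx)
        raise LabelMismatchError(
            f"label sets differ: only in first matrix {only_x}; only in second {only_y}"
        )
    return y.reorder(x.labels)


def _embed_symmetric(vec: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    return out + out.T


def _tail_count(perm_stats: np.ndarray, observed: float, alternative: str) -> int:
    if alternative == "greater":
        return int(np.sum(perm_stats >= observed - _TIE_TOL))
    if alternative == "less":
        return int(np.sum(perm_stats <= observed + _TIE_TOL))
    if alternative == "two-sided":
        return int(np.sum(np.abs(perm_stats) >= abs(observed) - _TIE_TOL))
    raise ValueError(f"unknown alternative {alternative!r}")


def _joint_permutation_test(
    zx: np.ndarray,
    zy: np.ndarray,
    n: int,
    n_perm: int,
    alternative: str,
    seed: int | None,
):
    """Permutation p for r = <zx, triu(Zy_perm)>/(d-1) under joint relabeling.

    zx, zy are the standardized (or rank-standardized) upper triangles.
    Returns (r_obs, p, n_perm_done, exhaustive).
    """
    d = n * (n - 1) // 2
    iu = np.triu_indices(n, k=1)
    Zy = _embed_symmetric(zy, n)
    r_obs = float(zx @ zy) / (d - 1)

    if n_perm <= 0:
        return r_obs, None, 0, False

    if n <= EXHAUSTIVE_MAX_N and n_perm >= math.factorial(n):
        stats = np.empty(math.factorial(n))
        for k, perm in enumerate(itertools.permutations(range(n))):
            p = np.asarray(perm)
            stats[k] = zx @ Zy[np.ix_(p, p)][iu]
        stats /= d - 1
        count = _tail_count(stats, r_obs, alternative)
        return r_obs, count / len(stats), len(stats), True

    if seed is None:
        raise ValueError("a seed is required for Monte-Carlo permutations")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_perm)
    for k in range(n_perm):
        p = rng.permutation(n)
        stats[k] = zx @ Zy[np.ix_(p, p)][iu]
    stats /= d - 1
    count = _tail_count(stats, r_obs, alternative)
    return r_obs, (count + 1) / (n_perm + 1), n_perm, False


def mantel(
    x: LabeledMatrix,
    y: LabeledMatrix,
    n_perm: int = DEFAULT_N_PERM,
    alternative: str = "greater",
    seed: int | None = None,
) -> MantelResult:
    """Standardized Mantel test between two distance matrices.

    Labels are reconciled by name (strict set equality); the permutation
    null jointly permutes rows and columns of the second matrix.  With
    n <= 7 and ``n_perm >= n!`` all relabelings are enumerated and the
    p-value is exact.  ``n_perm=0`` computes the statistic only (allowed
    from n = 3); permutation p-values need n >= 4.
    """
    y = _reconcile(x, y)
    n = len(x.labels)
    if n < 3:
        raise ValueError("Mantel statistic needs n >= 3")
    if n_perm > 0 and n < 4:
        raise ValueError("permutation p-value needs n >= 4; use n_perm=0 for the statistic")
    zx = standardize_upper_triangle(x)
    zy = standardize_upper_triangle(y)
    r, p, done, exhaustive = _joint_permutation_test(zx, zy, n, n_perm, alternative, seed)
    return MantelResult(
        r_m=r, n=n, d=n * (n - 1) // 2, p_value=p, n_perm=done,
        exhaustive=exhaustive, alternative=alternative, seed=seed,
    )


def sympatry_matrix(sites: SiteTable) -> LabeledMatrix:
    """Binary same-tectonic-plate matrix: 1 iff two sites share a plate label.

    Plates are taken verbatim from the site table — boundary sites get
    whatever label the user assigned; nothing is inferred from coordinates.
    """
    missing = [r.name for r in sites if not r.plate]
    if missing:
        raise ValueError(
            "sympatry matrix needs a plate label for every site; missing for: "
            + ", ".join(missing)
        )
    names = sites.names
    plates = [sites[n].plate for n in names]
    n = len(names)
    values = np.array(
        [[1.0 if plates[i] == plates[j] else 0.0 for j in range(n)] for i in range(n)]
    )
    return LabeledMatrix(names, values, kind="sympatry")


def spearman_sympatry(
    genetic: LabeledMatrix,
    sympatry: LabeledMatrix,
    n_perm: int = DEFAULT_N_PERM,
    alternative: str = "greater",
    seed: int | None = None,
) -> SpearmanResult:
    """Spearman rank correlation between genetic similarity and sympatry.

    The d upper-triangle genetic values and the d binary sympatry values are
    rank-transformed (average ranks for ties); r_s is the Pearson correlation
    of the rank vectors, i.e. cov of the ranks over the product of their
    standard deviations.  The permutation null is the same joint row/column
    relabeling used by :func:`mantel`, applied to the sympatry matrix.
    """
    sympatry = _reconcile(genetic, sympatry)
    n = len(genetic.labels)
    if n < 4:
        raise ValueError("Spearman sympatry test needs n >= 4")
    rank_g = rankdata(genetic.upper_triangle())
    rank_s = rankdata(sympatry.upper_triangle())
    for v, which in ((rank_g, "genetic"), (rank_s, "sympatry")):
        if v.std(ddof=1) == 0.0:
            raise DegenerateMatrixError(
                f"{which} ranks have zero variance (all pairwise values equal); "
                "the rank correlation is undefined"
            )
    zg = (rank_g - rank_g.mean()) / rank_g.std(ddof=1)
    zs = (rank_s - rank_s.mean()) / rank_s.std(ddof=1)
    r, p, done, exhaustive = _joint_permutation_test(zg, zs, n, n_perm, alternative, seed)
    return SpearmanResult(
        r_s=r, n=n, n_pairs=n * (n - 1) // 2, p_value=p, n_perm=done,
        exhaustive=exhaustive, alternative=alternative, seed=seed,
    )
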