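"""Pairwise sequence identity, similarity/distance conversion, and JC69.

Percent identity between marker sequences (16S rRNA, pmoAB2-style fragments)
is computed from a global alignment with affine gap costs and, by default,
free end gaps — the "identity over the aligned region" convention used in
the rRNA species-threshold literature.  The Jukes–Cantor correction converts
an observed fraction of differing sites into substitutions per site and is
used by the simulator's parameter-recovery harness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NEG_INF = float("-inf")
_ALPHABET = set("ACGTN")


class SequenceError(ValueError):
    """Empty sequence, bad alphabet, or duplicate name."""


class SaturationError(ValueError):
    """Observed divergence at or beyond the JC69 saturation limit p = 3/4."""


@dataclass(frozen=True)
class AlignmentParams:
    """Scores for global alignment.

    A gap of length L costs ``gap_open + L * gap_extend``.  With
    ``free_end_gaps`` (the default) gaps hanging off either end of either
    sequence are free and their columns are excluded from the identity
    denominator.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5
    free_end_gaps: bool = True

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")


DEFAULT_PARAMS = AlignmentParams()


class SequenceSet:
    """Ordered collection of named, uppercase ACGT(+N) nucleotide sequences."""

    def __init__(self, records: Iterable[tuple[str, str]]):
        self.records: list[tuple[str, str]] = []
        seen: set[str] = set()
        for name, seq in records:
            name = str(name)
            if name in seen:
                raise SequenceError(f"duplicate sequence name {name!r}")
            seen.add(name)
            self.records.append((name, _check_sequence(seq, name)))

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.records]

    def __getitem__(self, name: str) -> str:
        for n, s in self.records:
            if n == name:
                return s
        raise KeyError(name)


def _check_sequence(seq: str, name: str = "<sequence>") -> str:
    seq = str(seq).upper()
    if not seq:
        raise SequenceError(f"sequence {name!r} is empty")
    bad = set(seq) - _ALPHABET
    if bad:
        raise SequenceError(
            f"sequence {name!r} contains non-nucleotide character(s): {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | Path) -> SequenceSet:
    return SequenceSet((rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta"))


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=n, description="") for n, s in seqs),
        str(path),
        "fasta",
    )


# -- alignment ----------------------------------------------------------


def align_global(a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS):
    """Gotoh affine-gap global alignment.

    Returns ``(score, aligned_a, aligned_b)`` where the aligned strings use
    '-' for gaps.  Ties during traceback resolve diagonal > up > left so
    co-optimal alignments are reported deterministically.
    """
    a = _check_sequence(a)
    b = _check_sequence(b)
    n, m = len(a), len(b)
    open_, ext = params.gap_open, params.gap_extend
    free = params.free_end_gaps

    # states: M diagonal, Y gap in b (consume a, "up"), X gap in a (consume b, "left")
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        X[0, j] = 0.0 if free else open_ + j * ext
    for i in range(1, n + 1):
        Y[i, 0] = 0.0 if free else open_ + i * ext

    # row-wise fill with plain float lists (scalar numpy indexing is slow)
    match_s, mismatch_s = params.match, params.mismatch
    oe = open_ + ext
    prev_m, prev_x, prev_y = M[0].tolist(), X[0].tolist(), Y[0].tolist()
    for i in range(1, n + 1):
        ai = a[i - 1]
        cur_m = [NEG_INF] * (m + 1)
        cur_x = [NEG_INF] * (m + 1)
        cur_y = [float(Y[i, 0])] + [NEG_INF] * m
        for j in range(1, m + 1):
            sub = match_s if (ai == b[j - 1] and ai != "N") else mismatch_s
            pm, py, px = prev_m[j - 1], prev_y[j - 1], prev_x[j - 1]
            best_prev = pm if pm >= py else py
            if px > best_prev:
                best_prev = px
            cur_m[j] = sub + best_prev
            y1, y2, y3 = prev_m[j] + oe, prev_y[j] + ext, prev_x[j] + oe
            cur_y[j] = y1 if y1 >= y2 else y2
            if y3 > cur_y[j]:
                cur_y[j] = y3
            x1, x2, x3 = cur_m[j - 1] + oe, cur_x[j - 1] + ext, cur_y[j - 1] + oe
            cur_x[j] = x1 if x1 >= x2 else x2
            if x3 > cur_x[j]:
                cur_x[j] = x3
        M[i], X[i], Y[i] = cur_m, cur_x, cur_y
        prev_m, prev_x, prev_y = cur_m, cur_x, cur_y

    # terminal cell: with free end gaps the best score may sit anywhere on the
    # last row/column, the remaining overhang being free
    if free:
        best = (NEG_INF, n, m, "M")
        for state, grid in (("M", M), ("Y", Y), ("X", X)):
            for i in range(n + 1):
                if grid[i, m] > best[0]:
                    best = (grid[i, m], i, m, state)
            for j in range(m + 1):
                if grid[n, j] > best[0]:
                    best = (grid[n, j], n, j, state)
        score, ti, tj, state = best
    else:
        state = max(("M", "Y", "X"), key=lambda s: {"M": M, "Y": Y, "X": X}[s][n, m])
        score, ti, tj = {"M": M, "Y": Y, "X": X}[state][n, m], n, m

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    # trailing overhang (free end gaps only)
    for i in range(n, ti, -1):
        out_a.append(a[i - 1])
        out_b.append("-")
    for j in range(m, tj, -1):
        out_a.append("-")
        out_b.append(b[j - 1])

    i, j = ti, tj
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 or j == 0:
                break  # boundary: remaining is leading overhang
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            sub = params.match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else params.mismatch
            target = M[i, j] - sub
            i, j = i - 1, j - 1
            for prev in ("M", "Y", "X"):  # diagonal > up > left
                if abs({"M": M, "Y": Y, "X": X}[prev][i, j] - target) <= tol:
                    state = prev
                    break
        elif state == "Y":
            if i == 0:
                break
            out_a.append(a[i - 1])
            out_b.append("-")
            here = Y[i, j]
            i -= 1
            if abs(M[i, j] + open_ + ext - here) <= tol:
                state = "M"
            elif abs(Y[i, j] + ext - here) <= tol:
                state = "Y"
            else:
                state = "X"
        else:  # X
            if j == 0:
                break
            out_a.append("-")
            out_b.append(b[j - 1])
            here = X[i, j]
            j -= 1
            if abs(M[i, j] + open_ + ext - here) <= tol:
                state = "M"
            elif abs(X[i, j] + ext - here) <= tol:
                state = "X"
            else:
                state = "Y"
    # leading overhang
    while i > 0:
        out_a.append(a[i - 1])
        out_b.append("-")
        i -= 1
    while j > 0:
        out_a.append("-")
        out_b.append(b[j - 1])
        j -= 1

    return float(score), "".join(reversed(out_a)), "".join(reversed(out_b))


def _trim_terminal_overhangs(aligned_a: str, aligned_b: str) -> tuple[str, str]:
    """Drop leading/trailing columns where either sequence has an end gap."""
    start, end = 0, len(aligned_a)
    while start < end and (aligned_a[start] == "-" or aligned_b[start] == "-"):
        start += 1
    while end > start and (aligned_a[end - 1] == "-" or aligned_b[end - 1] == "-"):
        end -= 1
    return aligned_a[start:end], aligned_b[start:end]


def pairwise_identity(a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS) -> float:
    """Percent identity of the optimal global alignment, in [0, 100].

    Identity = 100 x matches / aligned columns; with free end gaps the
    terminal overhang columns are excluded from the denominator (internal
    gap columns still count as non-matches).  N never matches anything.
    Symmetric by construction.
    """
    # canonical orientation so identity(a, b) == identity(b, a) exactly even
    # among co-optimal alignments
    if b < a:
        a, b = b, a
    _, al_a, al_b = align_global(a, b, params)
    if params.free_end_gaps:
        al_a, al_b = _trim_terminal_overhangs(al_a, al_b)
    ncols = len(al_a)
    if ncols == 0:
        return 0.0
    matches = sum(
        1 for x, y in zip(al_a, al_b) if x == y and x != "-" and x != "N"
    )
    return 100.0 * matches / ncols


def p_distance(a: str, b: str) -> float:
    """Fraction of differing sites between equal-length ungapped sequences."""
    a = _check_sequence(a)
    b = _check_sequence(b)
    if len(a) != len(b):
        raise SequenceError(
            f"p_distance needs equal-length sequences ({len(a)} vs {len(b)})"
        )
    xa = np.frombuffer(a.encode(), dtype="S1")
    xb = np.frombuffer(b.encode(), dtype="S1")
    return float(np.mean(xa != xb))


def identity_matrix(
    seqs: SequenceSet,
    params: AlignmentParams = DEFAULT_PARAMS,
    method: str = "align",
) -> "LabeledMatrix":  # noqa: F821
    """All-pairs percent-identity matrix (similarity_percent, diagonal 100).

    method="align" runs the affine-gap aligner per pair; method="hamming"
    requires equal-length sequences and scores 100*(1 - p_distance), the
    right choice for simulator output which contains no indels.
    """
    from .fixtures_io import LabeledMatrix

    if len(seqs) < 2:
        raise SequenceError("need at least 2 sequences")
    names = seqs.names
    n = len(names)
    values = np.full((n, n), 100.0)
    recs = seqs.records
    for i in range(n):
        for j in range(i + 1, n):
            try:
                if method == "align":
                    ident = pairwise_identity(recs[i][1], recs[j][1], params)
                elif method == "hamming":
                    ident = 100.0 * (1.0 - p_distance(recs[i][1], recs[j][1]))
                else:
                    raise ValueError(f"unknown method {method!r}")
            except SequenceError as exc:
                raise SequenceError(f"pair ({names[i]}, {names[j]}): {exc}") from exc
            values[i, j] = values[j, i] = ident
    return LabeledMatrix(names, values, kind="similarity_percent")


# -- conversions --------------------------------------------------------


def similarity_to_distance(m: "LabeledMatrix") -> "LabeledMatrix":  # noqa: F821
    """Elementwise D = 100 - S; similarity_percent -> distance_percent."""
    from .fixtures_io import LabeledMatrix

    if m.kind != "similarity_percent":
        raise ValueError(f"expected a similarity_percent matrix, got {m.kind!r}")
    return LabeledMatrix(m.labels, 100.0 - m.values, kind="distance_percent")


def distance_to_similarity(m: "LabeledMatrix") -> "LabeledMatrix":  # noqa: F821
    """Inverse of :func:`similarity_to_distance`."""
    from .fixtures_io import LabeledMatrix

    if m.kind != "distance_percent":
        raise ValueError(f"expected a distance_percent matrix, got {m.kind!r}")
    return LabeledMatrix(m.labels, 100.0 - m.values, kind="similarity_percent")


def jc69_distance(p: float) -> float:
    """Jukes–Cantor corrected distance d = -(3/4) ln(1 - 4p/3), subs/site.

    Defined for observed difference fractions p in [0, 0.75); at p >= 0.75
    the model is saturated and a :class:`SaturationError` is raised.
    """
    if not 0.0 <= p < 0.75:
        raise SaturationError(f"p = {p} outside [0, 0.75): JC69 distance undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)
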