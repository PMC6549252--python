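"""Threshold-based species and geovar delimitation from similarity matrices.

Microbial taxonomy draws species boundaries with fixed similarity cut-offs:
genomic DNA-DNA hybridization (DDH) >= 70 % conventionally means "same
species", while 16S rRNA identity thresholds of 97 % (classic) or 98.7 %
(revised) flag candidate conspecifics.  Groups are formed by thresholding
the pairwise similarity matrix — single linkage (connected components of
the >=threshold graph) by default, complete linkage (every cross pair must
satisfy the threshold) optionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .fixtures_io import LabeledMatrix

DDH_SPECIES_THRESHOLD = 70.0
S16_SPECIES_THRESHOLD = 98.7
S16_CLASSIC_THRESHOLD = 97.0


@dataclass(frozen=True)
class ClusterSet:
    """A partition of the matrix labels produced by threshold clustering."""

    partition: tuple[tuple[str, ...], ...]
    threshold: float
    linkage: str
    matrix_kind: str

    @property
    def n_groups(self) -> int:
        return len(self.partition)

    def group_of(self, label: str) -> tuple[str, ...]:
        for group in self.partition:
            if label in group:
                return group
        raise KeyError(label)

    def to_dict(self) -> dict:
        return {
            "partition": [list(g) for g in self.partition],
            "n_groups": self.n_groups,
            "threshold": self.threshold,
            "linkage": self.linkage,
            "matrix_kind": self.matrix_kind,
        }


def _canonical_partition(groups: Iterable[Iterable[str]]) -> tuple[tuple[str, ...], ...]:
    """Sort members within groups and groups by first member — label-order invariant."""
    canon = [tuple(sorted(g)) for g in groups]
    return tuple(sorted(canon, key=lambda g: g[0]))


def cluster_at_threshold(
    m: LabeledMatrix, threshold: float, linkage: str = "single"
) -> ClusterSet:
    """Partition labels so grouped isolates satisfy similarity >= threshold.

    single — connected components of the graph with an edge wherever
    pairwise similarity >= threshold (one indirect chain suffices);
    complete — agglomerative merging in which two groups fuse only if
    *every* cross pair meets the threshold, best (highest minimum cross
    similarity) merge first, ties broken lexicographically.
    """
    if m.kind != "similarity_percent":
        raise ValueError(f"clustering expects a similarity_percent matrix, got {m.kind!r}")
    if not 0.0 <= threshold <= 100.0:
        raise ValueError(f"threshold {threshold} outside [0, 100]")
    labels = m.labels
    n = len(labels)
    adj = m.values >= threshold
    np.fill_diagonal(adj, False)

    if linkage == "single":
        n_comp, assignment = connected_components(csr_matrix(adj), directed=False)
        groups = [[] for _ in range(n_comp)]
        for idx, comp in enumerate(assignment):
            groups[comp].append(labels[idx])
    elif linkage == "complete":
        groups = [[lab] for lab in labels]

        def min_cross(g1: list[str], g2: list[str]) -> float:
            return min(m.loc(a, b) for a in g1 for b in g2)

        while True:
            best = None  # (neg similarity not needed: maximize similarity)
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    s = min_cross(groups[i], groups[j])
                    if s >= threshold:
                        key = (-s, min(groups[i] + groups[j]))
                        if best is None or key < best[0]:
                            best = (key, i, j)
            if best is None:
                break
            _, i, j = best
            groups[i] = groups[i] + groups[j]
            del groups[j]
    else:
        raise ValueError(f"unknown linkage {linkage!r} (expected 'single' or 'complete')")

    return ClusterSet(
        partition=_canonical_partition(groups),
        threshold=threshold,
        linkage=linkage,
        matrix_kind=m.kind,
    )


def group_extreme(
    m: LabeledMatrix,
    members: Iterable[str],
    others: Iterable[str] | None = None,
    mode: str = "min",
) -> tuple[float, tuple[str, str]]:
    """Extreme pairwise value within a group or across two disjoint groups.

    With ``others=None`` the extreme is over all unordered member pairs
    (|members| >= 2 required); otherwise over the members x others cross
    pairs.  Returns ``(value, (a, b))`` with the achieving pair, the
    lexicographically first pair on ties.
    """
    if mode not in ("min", "max"):
        raise ValueError(f"mode must be 'min' or 'max', got {mode!r}")
    members = sorted(set(members))
    unknown = [x for x in members if x not in m.labels]
    if unknown:
        raise ValueError(f"unknown member label(s): {', '.join(unknown)}")
    if others is None:
        if len(members) < 2:
            raise ValueError("within-group extreme needs at least 2 members")
        pairs = [(a, b) for i, a in enumerate(members) for b in members[i + 1:]]
    else:
        others = sorted(set(others))
        overlap = sorted(set(members) & set(others))
        if overlap:
            raise ValueError(f"members and others overlap: {', '.join(overlap)}")
        unknown = [x for x in others if x not in m.labels]
        if unknown:
            raise ValueError(f"unknown other label(s): {', '.join(unknown)}")
        pairs = [tuple(sorted((a, b))) for a in members for b in others]
    pairs = sorted(set(pairs))
    values = [m.loc(a, b) for a, b in pairs]
    pick = min if mode == "min" else max
    extreme = pick(values)
    for (a, b), v in zip(pairs, values):
        if v == extreme:
            return extreme, (a, b)
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class DelimitationThresholds:
    """Cut-offs (%) for the pairwise decision table."""

    ddh_species: float = DDH_SPECIES_THRESHOLD
    s16_species: float = S16_SPECIES_THRESHOLD
    s16_classic: float = S16_CLASSIC_THRESHOLD


@dataclass(frozen=True)
class RelationshipCall:
    label: str
    flags: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict:
        return {"label": self.label, "flags": list(self.flags)}


def classify_relationship(
    s16: float,
    ddh: float,
    thresholds: DelimitationThresholds = DelimitationThresholds(),
    distinct_sites: bool = False,
) -> RelationshipCall:
    """Classify a pair of isolates from its 16S identity and DDH values.

    Decision table (all comparisons inclusive, >=):

    * ddh >= ddh_species and s16 >= s16_classic -> ``same_species``
      (``same_geovar_candidate`` instead when the caller asserts the two
      isolates come from distinct sampling sites — the classic geovar
      situation of conspecifics separated in space);
    * ddh >= ddh_species but s16 < s16_classic -> ``ambiguous``
      (markers conflict);
    * ddh < ddh_species -> ``distinct_species``; if nevertheless
      s16 >= s16_species the ``ambiguous_16s`` flag is raised — 16S alone
      would have lumped the pair.
    """
    for name, v in (("s16", s16), ("ddh", ddh)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} value {v} outside [0, 100]")
    flags: list[str] = []
    if ddh >= thresholds.ddh_species:
        if s16 >= thresholds.s16_classic:
            label = "same_geovar_candidate" if distinct_sites else "same_species"
        else:
            label = "ambiguous"
            flags.append("conflicting_markers")
    else:
        label = "distinct_species"
        if s16 >= thresholds.s16_species:
            flags.append("ambiguous_16s")
    return RelationshipCall(label=label, flags=tuple(flags))


def write_cluster_tsv(clusters: ClusterSet, path) -> None:
    """Flat two-column (label, group index) TSV of a partition."""
    lines = ["label\tgroup"]
    for g_idx, group in enumerate(clusters.partition):
        for label in group:
            lines.append(f"{label}\t{g_idx}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
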