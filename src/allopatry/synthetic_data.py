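"""Synthetic allopatric-divergence datasets for end-to-end testing.

The generator emulates the study design of globally scattered geothermal
sampling sites whose microbial residents diverge with geographic
separation: sites are placed on the sphere (uniformly, or in clusters that
stand in for volcanic regions sharing a tectonic plate), a stepping-stone
colonization tree connects each new site to its nearest already-colonized
neighbour, and sequences evolve along the tree under Jukes–Cantor
substitution with the expected number of substitutions per site
proportional to the great-circle length of each colonization step
(``mu`` substitutions/site per 1000 km).  Because JC transition matrices
compose along a path, the expected corrected divergence between two sites
is exactly ``mu``  x  (tree-path distance)/1000 — which is what
:func:`recover_mu` estimates back, closing the parameter-recovery loop.

All stages draw from child seeds spawned deterministically from one root
seed, so every output is bit-identical across runs with the same seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fixtures_io import LabeledMatrix, SiteRecord, SiteTable
from .gendist import SaturationError, SequenceSet, jc69_distance, p_distance
from .geodesy import GeoPoint, great_circle_km

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class IBDParams:
    """Parameters of the isolation-by-distance generator.

    mu is the expected number of substitutions per site accumulated over
    1000 km of colonization path — the human-scale knob for how fast
    identity decays with distance at the study's 10^3–10^4 km span.
    """

    n_sites: int = 10
    placement: str = "uniform_sphere"  # or "clustered"
    n_clusters: int = 3
    cluster_spread_deg: float = 1.0
    seq_length: int = 10_000
    mu: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 3:
            raise ValueError("n_sites must be >= 3")
        if self.seq_length < 100:
            raise ValueError("seq_length must be >= 100")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.placement not in ("uniform_sphere", "clustered"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.placement == "clustered" and self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")


@dataclass(frozen=True)
class ColonizationTree:
    """Spanning tree of colonization steps; edge lengths in great-circle km."""

    root: str
    parent: dict = field(default_factory=dict)   # name -> parent name (root -> None)
    edge_km: dict = field(default_factory=dict)  # name -> length of edge to parent

    def __post_init__(self) -> None:
        if self.parent.get(self.root) is not None:
            raise ValueError("root must have no parent")
        for name, length in self.edge_km.items():
            if length < 0:
                raise ValueError(f"negative edge length at {name!r}")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.parent)

    def _path_to_root(self, name: str) -> list[str]:
        path = [name]
        seen = {name}
        while self.parent[path[-1]] is not None:
            nxt = self.parent[path[-1]]
            if nxt in seen:
                raise ValueError("cycle in colonization tree")
            path.append(nxt)
            seen.add(nxt)
        return path

    def path_km(self, a: str, b: str) -> float:
        """Tree-path distance between two sites (sum of edge lengths)."""
        pa = self._path_to_root(a)
        pb = self._path_to_root(b)
        in_a = set(pa)
        lca = next(x for x in pb if x in in_a)
        dist = 0.0
        for x in pa:
            if x == lca:
                break
            dist += self.edge_km[x]
        for x in pb:
            if x == lca:
                break
            dist += self.edge_km[x]
        return dist

    def total_length_km(self) -> float:
        return float(sum(self.edge_km[x] for x in self.parent if self.parent[x] is not None))

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "parent": dict(sorted(self.parent.items())),
            "edge_km": {k: self.edge_km[k] for k in sorted(self.edge_km)},
        }


def _child_seeds(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_sites(params: IBDParams) -> SiteTable:
    """Place n_sites on the sphere.

    uniform_sphere: lon ~ U(-180, 180], lat = arcsin(U(-1, 1)) — area-uniform.
    clustered: n_clusters centers drawn area-uniformly, sites dealt to
    centers round-robin and jittered by a Gaussian of cluster_spread_deg
    degrees; the plate label records cluster membership (uniform placement
    puts every site on one nominal plate).
    """
    rng = _child_seeds(params.seed, 3)[0]
    width = len(str(params.n_sites - 1))
    names = [f"S{i:0{width}d}" for i in range(params.n_sites)]

    def draw_point() -> tuple[float, float]:
        lat = float(np.degrees(np.arcsin(rng.uniform(-1.0, 1.0))))
        lon = float(rng.uniform(-180.0, 180.0))
        return lat, lon

    records = []
    if params.placement == "uniform_sphere":
        for name in names:
            lat, lon = draw_point()
            records.append(SiteRecord(name=name, lat=lat, lon=lon, plate="P0"))
    else:
        centers = [draw_point() for _ in range(params.n_clusters)]
        for i, name in enumerate(names):
            c = i % params.n_clusters
            clat, clon = centers[c]
            lat = float(np.clip(clat + rng.normal(0.0, params.cluster_spread_deg), -90.0, 90.0))
            lon = clon + rng.normal(0.0, params.cluster_spread_deg)
            point = GeoPoint(lat, lon)  # normalizes longitude
            records.append(
                SiteRecord(name=name, lat=point.lat, lon=point.lon, plate=f"P{c}")
            )
    return SiteTable(records)


def build_colonization_tree(sites: SiteTable, seed: int) -> ColonizationTree:
    """Stepping-stone colonization: random root, random arrival order, each
    new site attaching to the nearest already-colonized site.

    Distance ties attach to the lexicographically smaller candidate name, so
    the tree is a pure function of (sites, seed).
    """
    records = [r for r in sites]
    if len(records) < 2:
        raise ValueError("need at least 2 sites")
    missing = [r.name for r in records if not r.has_coordinates]
    if missing:
        raise ValueError("sites lacking coordinates: " + ", ".join(missing))
    rng = np.random.default_rng(seed)
    order = [records[i] for i in rng.permutation(len(records))]
    root = order[0]
    parent: dict = {root.name: None}
    edge_km: dict = {}
    colonized = [root]
    points = {r.name: GeoPoint(r.lat, r.lon) for r in records}
    for rec in order[1:]:
        best_name, best_d = None, np.inf
        for cand in sorted(colonized, key=lambda r: r.name):
            d = great_circle_km(points[rec.name], points[cand.name])
            if d < best_d:  # strict: earlier (lexicographically smaller) wins ties
                best_name, best_d = cand.name, d
        parent[rec.name] = best_name
        edge_km[rec.name] = best_d
        colonized.append(rec)
    return ColonizationTree(root=root.name, parent=parent, edge_km=edge_km)


def _edge_mutation_probability(mu: float, g_km: float) -> float:
    """JC probability a site differs after mu*g/1000 expected substitutions."""
    return 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * mu * g_km / 1000.0))


def evolve_sequences(
    tree: ColonizationTree, seq_length: int, mu: float, seed: int
) -> SequenceSet:
    """Jukes–Cantor evolution along the colonization tree.

    The root sequence is uniform over ACGT; along each edge of length g km
    every site independently mutates with probability
    p(g) = (3/4)(1 - exp(-(4/3) mu g / 1000)) to one of the three other
    bases, uniformly.  Edge processes compose to JC of the summed path, so
    expected pairwise divergence is linear in tree-path distance.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=seq_length)
    seqs = {tree.root: root_seq}
    # children in deterministic order
    children: dict = {}
    for name, par in tree.parent.items():
        if par is not None:
            children.setdefault(par, []).append(name)
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for child in sorted(children.get(node, []), reverse=True):
            p = _edge_mutation_probability(mu, tree.edge_km[child])
            seq = seqs[node].copy()
            mask = rng.random(seq_length) < p
            n_mut = int(mask.sum())
            if n_mut:
                seq[mask] = (seq[mask] + rng.integers(1, 4, size=n_mut)) % 4
            seqs[child] = seq
            stack.append(child)
    return SequenceSet(
        (name, _BASES[seqs[name]].tobytes().decode()) for name in sorted(seqs)
    )


def jc_distance_matrix(seqs: SequenceSet) -> LabeledMatrix:
    """Pairwise JC-corrected distances (subs/site) for equal-length sequences."""
    names = seqs.names
    n = len(names)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = jc69_distance(p_distance(seqs.records[i][1], seqs.records[j][1]))
            values[i, j] = values[j, i] = d
    return LabeledMatrix(names, values, kind="distance_subs")


def recover_mu(seqs: SequenceSet, tree: ColonizationTree) -> float:
    """Estimate mu from sequences evolved on a known colonization tree.

    For every pair, the JC-corrected divergence is regressed through the
    origin on tree-path distance; the slope x 1000 estimates mu.  Saturated
    pairs (observed difference fraction >= 3/4) are excluded with a warning;
    if every pair is saturated the estimate is undefined.
    """
    names = seqs.names
    d_vals: list[float] = []
    g_vals: list[float] = []
    n_saturated = 0
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = p_distance(seqs.records[i][1], seqs.records[j][1])
            try:
                d = jc69_distance(p)
            except SaturationError:
                n_saturated += 1
                continue
            d_vals.append(d)
            g_vals.append(tree.path_km(names[i], names[j]))
    if n_saturated:
        warnings.warn(
            f"{n_saturated} saturated pair(s) excluded from mu recovery",
            stacklevel=2,
        )
    if not d_vals:
        raise SaturationError("all pairs saturated; mu cannot be recovered")
    g = np.asarray(g_vals)
    d = np.asarray(d_vals)
    denom = float(g @ g)
    if denom == 0.0:
        return 0.0  # all sites co-located; only mu = 0 is consistent
    return float(d @ g) / denom * 1000.0


@dataclass(frozen=True)
class SyntheticDataset:
    """A complete simulated study: sites, colonization tree, sequences, truth."""

    params: IBDParams
    sites: SiteTable
    tree: ColonizationTree
    sequences: SequenceSet

    def ground_truth(self) -> dict:
        return {
            "mu": self.params.mu,
            "seed": self.params.seed,
            "seq_length": self.params.seq_length,
            "placement": self.params.placement,
            "tree": self.tree.to_dict(),
        }

    def write_ground_truth(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.ground_truth(), indent=2) + "\n")


def simulate_dataset(params: IBDParams) -> SyntheticDataset:
    """Run the three generator stages under child seeds of ``params.seed``."""
    seed_seq = np.random.SeedSequence(params.seed).spawn(3)
    sites = simulate_sites(params)
    tree = build_colonization_tree(sites, seed=int(seed_seq[1].generate_state(1)[0] % (2**31)))
    seqs = evolve_sequences(
        tree,
        params.seq_length,
        params.mu,
        seed=int(seed_seq[2].generate_state(1)[0] % (2**31)),
    )
    return SyntheticDataset(params=params, sites=sites, tree=tree, sequences=seqs)
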