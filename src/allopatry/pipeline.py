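"""End-to-end isolation-by-distance pipeline.

Runs the stages in method order — geographic distance matrix from the site
table, genetic similarity matrices from FASTA and/or precomputed tables,
Mantel test of every genetic distance matrix against geography, Spearman
rank correlation against tectonic-plate sympatry, and threshold species
delimitation — and collects everything into one machine-readable report.

Conventions enforced end to end: correlation stages run on *distances*
(similarity matrices are converted via D = 100 - S first and the report
records this); strains without coordinates are excluded from geographic
analyses with a prominent warning but retained for delimitation; degenerate
matrices abort only the affected statistic, never the whole run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from . import __version__
from .delimitation import (
    DelimitationThresholds,
    classify_relationship,
    cluster_at_threshold,
    write_cluster_tsv,
)
from .fixtures_io import (
    LabeledMatrix,
    SiteTable,
    read_matrix,
    read_site_table,
    write_matrix,
)
from .gendist import identity_matrix, read_fasta, similarity_to_distance
from .geodesy import geographic_distance_matrix
from .matrix_stats import (
    DegenerateMatrixError,
    mantel,
    spearman_sympatry,
    sympatry_matrix,
)

logger = logging.getLogger("allopatry")


class PipelineError(ValueError):
    """Configuration or input problem that prevents the run from starting."""


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and settings for one pipeline run.

    At least one genetic input (FASTA or a precomputed similarity matrix)
    is required; a seed is required whenever Monte-Carlo permutations will
    run (n <= 7 label sets are enumerated exhaustively and need none).
    """

    site_table: Path
    fasta: tuple[Path, ...] = ()
    ddh_matrix: Path | None = None
    s16_matrix: Path | None = None
    extra_matrices: tuple[tuple[str, Path], ...] = ()
    n_perm: int = 9999
    alternative: str = "greater"
    seed: int | None = None
    thresholds: DelimitationThresholds = field(default_factory=DelimitationThresholds)
    outdir: Path | None = None

    def __post_init__(self) -> None:
        if not (self.fasta or self.ddh_matrix or self.s16_matrix or self.extra_matrices):
            raise PipelineError(
                "at least one genetic input (FASTA or similarity matrix) is required"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _matrix_summary(m: LabeledMatrix) -> dict:
    return {"labels": list(m.labels), "kind": m.kind, "n": len(m.labels)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the report dict (also written to disk
    when ``config.outdir`` is set)."""
    warnings_list: list[str] = []

    def warn(msg: str) -> None:
        logger.warning(msg)
        warnings_list.append(msg)

    inputs: dict[str, str] = {}

    logger.info("reading site table %s", config.site_table)
    sites = read_site_table(config.site_table)
    inputs[str(config.site_table)] = _sha256(config.site_table)

    # -- genetic matrices ------------------------------------------------
    genetic: dict[str, LabeledMatrix] = {}
    if config.ddh_matrix:
        genetic["ddh"] = read_matrix(config.ddh_matrix, kind="similarity_percent")
        inputs[str(config.ddh_matrix)] = _sha256(config.ddh_matrix)
    if config.s16_matrix:
        genetic["s16"] = read_matrix(config.s16_matrix, kind="similarity_percent")
        inputs[str(config.s16_matrix)] = _sha256(config.s16_matrix)
    for name, path in config.extra_matrices:
        genetic[name] = read_matrix(path, kind="similarity_percent")
        inputs[str(path)] = _sha256(path)
    for path in config.fasta:
        name = f"fasta:{Path(path).stem}"
        logger.info("computing identity matrix for %s", path)
        genetic[name] = identity_matrix(read_fasta(path))
        inputs[str(path)] = _sha256(path)

    # -- geography -------------------------------------------------------
    with_coords = [r.name for r in sites if r.has_coordinates]
    without_coords = [r.name for r in sites if not r.has_coordinates]
    if without_coords:
        warn(
            "sites without coordinates excluded from geographic analyses: "
            + ", ".join(without_coords)
        )

    geo = None
    if len(with_coords) >= 2:
        geo = geographic_distance_matrix(sites.subset(with_coords))

    # -- Mantel per genetic matrix --------------------------------------
    mantel_results: dict[str, dict] = {}
    for name, sim in genetic.items():
        if geo is None:
            mantel_results[name] = {"error": "fewer than 2 sites with coordinates"}
            continue
        common = [lab for lab in sim.labels if lab in geo.labels]
        dropped = sorted(set(sim.labels) - set(common))
        if dropped:
            warn(
                f"matrix {name!r}: labels without coordinates dropped from the "
                f"Mantel test: {', '.join(dropped)}"
            )
        if len(common) < 4:
            mantel_results[name] = {
                "error": f"only {len(common)} labels shared with the geographic matrix"
            }
            continue
        gen_dist = similarity_to_distance(sim.reorder(common))
        try:
            res = mantel(
                gen_dist,
                geo.reorder(common),
                n_perm=config.n_perm,
                alternative=config.alternative,
                seed=config.seed,
            )
            mantel_results[name] = res.to_dict()
            logger.info(
                "Mantel %s: r_m=%.4f p=%s (n=%d, %s)",
                name, res.r_m, res.p_value, res.n,
                "exhaustive" if res.exhaustive else f"{res.n_perm} permutations",
            )
        except DegenerateMatrixError as exc:
            warn(f"Mantel {name!r} skipped: {exc}")
            mantel_results[name] = {"error": str(exc)}

    # -- Spearman vs tectonic sympatry ----------------------------------
    spearman_results: dict[str, dict] = {}
    with_plates = [r.name for r in sites if r.plate]
    plates = {r.name: r.plate for r in sites if r.plate}
    if with_plates:
        for name, sim in genetic.items():
            common = [lab for lab in sim.labels if lab in plates]
            dropped = sorted(set(sim.labels) - set(common))
            if dropped:
                warn(
                    f"matrix {name!r}: labels without a plate assignment dropped "
                    f"from the sympatry test: {', '.join(dropped)}"
                )
            if len(common) < 4:
                spearman_results[name] = {
                    "error": f"only {len(common)} labels carry plate assignments"
                }
                continue
            symp = sympatry_matrix(sites.subset(common))
            try:
                res = spearman_sympatry(
                    sim.reorder(common),
                    symp,
                    n_perm=config.n_perm,
                    alternative=config.alternative,
                    seed=config.seed,
                )
                spearman_results[name] = res.to_dict()
                logger.info("Spearman %s: r_s=%.4f p=%s", name, res.r_s, res.p_value)
            except DegenerateMatrixError as exc:
                warn(f"Spearman {name!r} skipped: {exc}")
                spearman_results[name] = {"error": str(exc)}

    # -- delimitation (all strains, coordinates not required) -----------
    th = config.thresholds
    cluster_plan = {
        "ddh": [th.ddh_species],
        "s16": [th.s16_classic, th.s16_species],
    }
    clusters: dict[str, dict] = {}
    for name, sim in genetic.items():
        for threshold in cluster_plan.get(name, [th.ddh_species]):
            cs = cluster_at_threshold(sim, threshold)
            clusters.setdefault(name, {})[f"{threshold:g}"] = cs.to_dict()
            logger.info(
                "delimitation %s @ %.1f%%: %d group(s)", name, threshold, cs.n_groups
            )

    classification: list[dict] = []
    if "ddh" in genetic and "s16" in genetic:
        ddh_m, s16_m = genetic["ddh"], genetic["s16"]
        common = [lab for lab in ddh_m.labels if lab in s16_m.labels]
        for i, a in enumerate(common):
            for b in common[i + 1:]:
                call = classify_relationship(
                    s16_m.loc(a, b), ddh_m.loc(a, b), thresholds=th,
                    distinct_sites=(a in sites and b in sites and a != b),
                )
                classification.append(
                    {"pair": [a, b], "s16": s16_m.loc(a, b), "ddh": ddh_m.loc(a, b),
                     **call.to_dict()}
                )

    report = {
        "tool": {"name": "allopatry", "version": __version__},
        "seed": config.seed,
        "n_perm": config.n_perm,
        "alternative": config.alternative,
        "inputs": inputs,
        "sites": {
            "n": len(sites),
            "with_coordinates": with_coords,
            "without_coordinates": without_coords,
            "plates": plates,
        },
        "matrices": {
            **{name: _matrix_summary(m) for name, m in genetic.items()},
            **({"geographic_km": _matrix_summary(geo)} if geo is not None else {}),
        },
        "mantel": mantel_results,
        "spearman": spearman_results,
        "clusters": clusters,
        "classification": classification,
        "conventions": {
            "correlation_input": "distance (similarities converted via 100 - S)",
            "thresholds": {
                "ddh_species": th.ddh_species,
                "s16_species": th.s16_species,
                "s16_classic": th.s16_classic,
            },
            "linkage": "single",
        },
        "warnings": warnings_list,
    }

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
        if geo is not None:
            write_matrix(geo, outdir / "geographic_km.tsv")
        for name, sim in genetic.items():
            safe = name.replace(":", "_")
            write_matrix(sim, outdir / f"{safe}_similarity.tsv")
        for name, by_threshold in clusters.items():
            for t_str in by_threshold:
                cs = cluster_at_threshold(
                    genetic[name], float(t_str)
                )
                write_cluster_tsv(
                    cs, outdir / f"{name.replace(':', '_')}_clusters_{t_str}.tsv"
                )
        logger.info("report written to %s", outdir / "report.json")

    return report


# -- report schema ------------------------------------------------------


def report_schema() -> dict:
    """The shipped structural schema for pipeline reports."""
    schema_text = (resources.files(__package__) / "data" / "report.schema.json").read_text()
    return json.loads(schema_text)


_JSON_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "null": type(None),
}


def validate_report(report: dict) -> None:
    """Structural validation of a report against the shipped schema.

    Checks required keys and JSON types at the top level and one level into
    required sub-objects; raises ValueError on the first violation.
    """
    schema = report_schema()
    if not isinstance(report, dict):
        raise ValueError("report must be a JSON object")
    for key in schema["required"]:
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    for key, spec in schema.get("properties", {}).items():
        if key not in report:
            continue
        types = spec.get("type")
        if types is None:
            continue
        if isinstance(types, str):
            types = [types]
        pytypes = tuple(_JSON_TYPES[t] for t in types)
        value = report[key]
        if not isinstance(value, pytypes) or (
            isinstance(value, bool) and int not in pytypes
        ):
            raise ValueError(
                f"report key {key!r} has type {type(value).__name__}, expected {types}"
            )
        for subkey in spec.get("required", []):
            if subkey not in value:
                raise ValueError(f"report key {key!r} missing sub-key {subkey!r}")
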