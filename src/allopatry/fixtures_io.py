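"""File formats and packaged study fixtures.

Two tabular formats carry everything in the pipeline:

* **site tables** — TSV with columns ``name`` and either ``coordinate``
  (degree/decimal-minute string) or ``lat`` + ``lon`` (decimal degrees),
  plus optional ``plate``, ``temperature``, ``ph``;
* **labeled matrices** — square TSV whose first row and first column are
  strain labels; the upper triangle may be left blank (mirrored on load),
  matching how pairwise similarity tables are printed in the literature.

The module also ships, as machine-readable fixtures, the study data for the
nine thermoacidophilic Verrucomicrobia methanotroph isolates: a six-site
sampling table (strains Fur, Rib, Fdl, Yel, Ice, Phi with coordinates and
tectonic-plate labels) and two nine-strain similarity matrices (in-silico
DNA-DNA hybridization %, and 16S rRNA identity %; strains SolV, V4 and Kam1
appear in the matrices but have no published coordinates).
"""

from __future__ import annotations

import re
import shutil
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .geodesy import parse_coordinate

SYMMETRY_TOL = 1e-9  # hand-entered percentages: anything beyond this is a data error

#: Expected diagonal value for each matrix kind.
DIAGONAL_CONVENTION: Mapping[str, float] = {
    "similarity_percent": 100.0,
    "distance_km": 0.0,
    "distance_percent": 0.0,
    "distance_subs": 0.0,  # substitutions per site (model-corrected)
    "sympatry": 1.0,
}

#: Tectonic-plate assignment for all nine fixture strains (boundary sites kept
#: as explicit user-level labels; plates are never inferred from coordinates).
NINE_STRAIN_PLATES: Mapping[str, str] = {
    "SolV": "Eurasian",
    "Fur": "Eurasian",
    "Rib": "Eurasian",
    "Fdl": "Eurasian",
    "Ice": "Eurasian",
    "Yel": "North American",
    "Phi": "Philippine-boundary",
    "V4": "Australian-Pacific",
    "Kam1": "Okhotsk",
}


class SiteTableError(ValueError):
    """Malformed site table (duplicate names, unparseable rows, ...)."""


class MatrixFormatError(ValueError):
    """Malformed labeled matrix (asymmetry, bad diagonal, non-square, ...)."""


_RANGE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*[–—-]\s*(\d+(?:\.\d+)?)\s*$")


def _parse_scalar_or_range(text: str | None) -> float | None:
    """Parse '55' -> 55.0 and a printed range '62–64' -> its midpoint 63.0."""
    if text is None or str(text).strip() in ("", "nan"):
        return None
    s = str(text).strip()
    m = _RANGE_RE.match(s)
    if m:
        return (float(m.group(1)) + float(m.group(2))) / 2.0
    try:
        return float(s)
    except ValueError:
        return None


@dataclass(frozen=True)
class SiteRecord:
    """One sampling site / isolate.

    Coordinates may be absent (lat/lon None) for strains whose sampling
    location was never published; such records can still enter sympatry and
    delimitation analyses but are rejected by geographic ones.
    """

    name: str
    lat: float | None = None
    lon: float | None = None
    plate: str | None = None
    coordinate_text: str | None = None
    temperature_text: str | None = None
    ph_text: str | None = None

    @property
    def has_coordinates(self) -> bool:
        return self.lat is not None and self.lon is not None

    @property
    def temperature_c(self) -> float | None:
        """Parsed temperature; midpoint when the source prints a range."""
        return _parse_scalar_or_range(self.temperature_text)

    @property
    def ph(self) -> float | None:
        return _parse_scalar_or_range(self.ph_text)


class SiteTable:
    """Ordered, name-unique collection of :class:`SiteRecord`."""

    def __init__(self, records: Iterable[SiteRecord]):
        self.records = list(records)
        names = [r.name for r in self.records]
        dupes = sorted({n for n in names if names.count(n) > 1})
        if dupes:
            raise SiteTableError(f"duplicate site name(s): {', '.join(dupes)}")
        self._index = {r.name: r for r in self.records}

    def __iter__(self) -> Iterator[SiteRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, name: str) -> SiteRecord:
        return self._index[name]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def subset(self, names: Iterable[str]) -> "SiteTable":
        names = list(names)
        missing = [n for n in names if n not in self._index]
        if missing:
            raise SiteTableError(f"unknown site name(s): {', '.join(missing)}")
        return SiteTable(self._index[n] for n in names)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "lat": [r.lat for r in self.records],
                "lon": [r.lon for r in self.records],
                "plate": [r.plate for r in self.records],
                "temperature": [r.temperature_text for r in self.records],
                "ph": [r.ph_text for r in self.records],
            }
        )


class LabeledMatrix:
    """Square, symmetric, label-indexed matrix of similarities or distances.

    kind is one of ``similarity_percent`` (diag 100, values in [0, 100]),
    ``distance_km`` / ``distance_percent`` (diag 0, values >= 0) or
    ``sympatry`` (binary, diag 1).
    """

    def __init__(self, labels: Iterable[str], values: np.ndarray, kind: str):
        self.labels = [str(x) for x in labels]
        self.values = np.asarray(values, dtype=float)
        self.kind = kind
        self.validate()

    @property
    def diagonal_convention(self) -> float:
        return DIAGONAL_CONVENTION[self.kind]

    def validate(self) -> None:
        if self.kind not in DIAGONAL_CONVENTION:
            raise MatrixFormatError(
                f"unknown matrix kind {self.kind!r}; expected one of "
                f"{sorted(DIAGONAL_CONVENTION)}"
            )
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise MatrixFormatError("duplicate labels in matrix")
        if self.values.shape != (n, n):
            raise MatrixFormatError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise MatrixFormatError("matrix contains non-finite values")
        asym = np.abs(self.values - self.values.T).max(initial=0.0)
        if asym > SYMMETRY_TOL:
            i, j = np.unravel_index(
                np.abs(self.values - self.values.T).argmax(), self.values.shape
            )
            raise MatrixFormatError(
                f"matrix asymmetric at ({self.labels[i]}, {self.labels[j]}): "
                f"{self.values[i, j]} vs {self.values[j, i]}"
            )
        diag = np.diag(self.values)
        if np.abs(diag - self.diagonal_convention).max(initial=0.0) > SYMMETRY_TOL:
            bad = self.labels[int(np.abs(diag - self.diagonal_convention).argmax())]
            raise MatrixFormatError(
                f"diagonal of {self.kind} matrix must be {self.diagonal_convention}; "
                f"violated at {bad!r}"
            )
        if self.kind == "similarity_percent":
            if self.values.min() < -SYMMETRY_TOL or self.values.max() > 100 + SYMMETRY_TOL:
                raise MatrixFormatError("similarity_percent values must lie in [0, 100]")
        elif self.kind == "sympatry":
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise MatrixFormatError("sympatry matrix must be binary")
        else:
            if self.values.min() < -SYMMETRY_TOL:
                raise MatrixFormatError("distances must be non-negative")

    # -- access ---------------------------------------------------------

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def reorder(self, labels: Iterable[str]) -> "LabeledMatrix":
        """Submatrix/reordering by label; raises on unknown labels."""
        labels = list(labels)
        missing = [x for x in labels if x not in self.labels]
        if missing:
            raise MatrixFormatError(f"unknown label(s): {', '.join(missing)}")
        idx = [self.labels.index(x) for x in labels]
        return LabeledMatrix(labels, self.values[np.ix_(idx, idx)], self.kind)

    def upper_triangle(self) -> np.ndarray:
        """The d = n(n-1)/2 off-diagonal entries, row-major upper triangle."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, LabeledMatrix)
            and self.labels == other.labels
            and self.kind == other.kind
            and np.array_equal(self.values, other.values)
        )


# -- site-table I/O -----------------------------------------------------


def read_site_table(path: str | Path) -> SiteTable:
    """Read a TSV site table.

    Requires a ``name`` column and either a ``coordinate`` column
    (degree/decimal-minute strings) or numeric ``lat``/``lon`` columns.
    Rows may omit coordinates entirely (blank cells).  Duplicate names and
    unparseable coordinates are rejected with the offending row named.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    if "name" not in df.columns:
        raise SiteTableError(f"{path}: missing required column 'name'")
    has_coord = "coordinate" in df.columns
    has_latlon = "lat" in df.columns and "lon" in df.columns
    if not (has_coord or has_latlon):
        raise SiteTableError(f"{path}: need a 'coordinate' column or 'lat'+'lon' columns")

    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        name = row["name"].strip()
        if not name:
            raise SiteTableError(f"{path} row {row_no}: empty site name")
        lat = lon = None
        coord_text = None
        if has_coord and row.get("coordinate", "").strip():
            coord_text = row["coordinate"].strip()
            try:
                point = parse_coordinate(coord_text)
            except ValueError as exc:
                raise SiteTableError(f"{path} row {row_no} ({name!r}): {exc}") from exc
            lat, lon = point.lat, point.lon
        elif has_latlon and row.get("lat", "").strip() and row.get("lon", "").strip():
            try:
                lat, lon = float(row["lat"]), float(row["lon"])
            except ValueError as exc:
                raise SiteTableError(
                    f"{path} row {row_no} ({name!r}): bad lat/lon "
                    f"{row['lat']!r}/{row['lon']!r}"
                ) from exc
        plate = row.get("plate", "").strip() or None
        temp = row.get("temperature", row.get("temperature_c", "")).strip() or None
        ph = row.get("ph", "").strip() or None
        records.append(
            SiteRecord(
                name=name, lat=lat, lon=lon, plate=plate,
                coordinate_text=coord_text, temperature_text=temp, ph_text=ph,
            )
        )
    return SiteTable(records)


def write_site_table(table: SiteTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index=False)


# -- matrix I/O ---------------------------------------------------------


def read_matrix(path: str | Path, kind: str) -> LabeledMatrix:
    """Read a labeled square matrix TSV.

    First row and first column are labels.  A blank upper triangle is filled
    by mirroring the lower one (similarity tables are conventionally printed
    lower-triangular); when both triangles are present they must agree to
    1e-9 absolute.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    row_labels = [str(x).strip() for x in df.index]
    col_labels = [str(x).strip() for x in df.columns]
    if row_labels != col_labels:
        raise MatrixFormatError(
            f"{path}: row labels {row_labels} != column labels {col_labels} (matrix must be square)"
        )
    n = len(row_labels)
    values = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            cell = str(df.iat[i, j]).strip()
            if cell:
                try:
                    values[i, j] = float(cell)
                except ValueError as exc:
                    raise MatrixFormatError(
                        f"{path}: non-numeric cell {cell!r} at "
                        f"({row_labels[i]}, {col_labels[j]})"
                    ) from exc
    # mirror blanks
    for i in range(n):
        for j in range(n):
            if np.isnan(values[i, j]):
                if np.isnan(values[j, i]):
                    raise MatrixFormatError(
                        f"{path}: cell ({row_labels[i]}, {col_labels[j]}) blank on both triangles"
                    )
                values[i, j] = values[j, i]
    return LabeledMatrix(row_labels, values, kind=kind)


def _fmt_cell(v: float, digits: int | None) -> str:
    if digits is not None:
        return format(float(v), f".{digits}g")
    r = repr(float(v))  # shortest string that round-trips exactly
    return r[:-2] if r.endswith(".0") else r


def write_matrix(matrix: LabeledMatrix, path: str | Path, digits: int | None = None) -> None:
    """Write a labeled matrix TSV; read_matrix(write_matrix(m)) == m.

    By default cells are written with the shortest decimal representation
    that round-trips the float exactly (so hand-entered ``88.4`` stays
    ``88.4``); pass ``digits`` to truncate computed matrices for display.
    """
    lines = ["\t".join(["label", *matrix.labels])]
    for i, lab in enumerate(matrix.labels):
        cells = [_fmt_cell(matrix.values[i, j], digits) for j in range(len(matrix.labels))]
        lines.append("\t".join([lab, *cells]))
    Path(path).write_text("\n".join(lines) + "\n")


# -- packaged fixtures --------------------------------------------------

_DATA = resources.files(__package__) / "data"


def packaged_fixtures() -> dict:
    """The study's printed tables as in-memory objects.

    Returns ``{"site_table": SiteTable, "ddh_matrix": LabeledMatrix,
    "s16_matrix": LabeledMatrix}`` — six coordinate-bearing sites and two
    nine-strain similarity matrices.  Strains SolV, V4 and Kam1 occur only
    in the matrices (their coordinates were never published).
    """
    with resources.as_file(_DATA / "study_sites.tsv") as p:
        site_table = read_site_table(p)
    with resources.as_file(_DATA / "study_ddh.tsv") as p:
        ddh = read_matrix(p, kind="similarity_percent")
    with resources.as_file(_DATA / "study_16s.tsv") as p:
        s16 = read_matrix(p, kind="similarity_percent")
    return {"site_table": site_table, "ddh_matrix": ddh, "s16_matrix": s16}


def dump_fixtures(outdir: str | Path) -> list[Path]:
    """Copy the packaged fixture TSVs into *outdir*; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for fname in ("study_sites.tsv", "study_ddh.tsv", "study_16s.tsv"):
        with resources.as_file(_DATA / fname) as src:
            dest = outdir / fname
            shutil.copyfile(src, dest)
            written.append(dest)
    return written
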