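"""Domain types, configuration, and readers/writers.

The package analyses phenotyped cell tables exported from a cell-detection
tool (one row per detected cell, centroid coordinates in micrometres, a
phenotype label from a closed vocabulary), tumor-field polygon annotations
(GeoJSON, coordinates in µm), specimen metadata, and NPX protein-by-sample
matrices from a proximity-extension assay (log2 scale, with plate labels
and a missingness mask).

Coordinates live in a planar slide frame with y increasing downward, the
convention of common cell-detection exports.  Only distances and areas are
ever used, so the orientation is immaterial.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import MultiPolygon, Polygon, mapping as geom_mapping, shape as geom_shape
from shapely.validation import explain_validity, make_valid

log = logging.getLogger("timetopo.io")

# ---------------------------------------------------------------------------
# Vocabulary and errors
# ---------------------------------------------------------------------------

#: Closed phenotype vocabulary of the seven-color panel.
PHENOTYPES: tuple[str, ...] = (
    "tumor",
    "macrophage_cd163",
    "b_cell",
    "t_cd8",
    "t_cd4_helper",
    "treg",
    "other",
)

#: The five immune phenotypes that enter neighborhood and density analyses.
IMMUNE_PHENOTYPES: tuple[str, ...] = (
    "macrophage_cd163",
    "b_cell",
    "t_cd8",
    "t_cd4_helper",
    "treg",
)

#: Optional marker flags (five-color tumor-resident workflow; meaningful on t_cd8).
MARKER_FLAGS: tuple[str, ...] = ("cd103", "ki67")

SPECIMEN_KINDS = ("resection", "biopsy")
SITES = ("oral_cavity", "hypopharynx", "larynx", "oropharynx")
HPV_STATUSES = ("positive", "negative", "unknown")


class TimetopoError(Exception):
    """Base class for package errors."""


class FormatError(TimetopoError):
    """Malformed input table or matrix."""


class GeometryError(TimetopoError):
    """Invalid or irreparable polygon geometry."""


class ZoningError(TimetopoError):
    """Tissue-zone construction impossible for this specimen."""


class ClassificationError(TimetopoError):
    """Immunotype call refused (missing density or biopsy specimen)."""


class NeighborhoodError(TimetopoError):
    """Neighborhood clustering impossible (e.g. fewer immune cells than k)."""


class StatsError(TimetopoError):
    """Statistical test refused (degenerate or insufficient data)."""


class ValidationError(TimetopoError):
    """Invalid parameter value."""


# ---------------------------------------------------------------------------
# Randomness: named substreams
# ---------------------------------------------------------------------------

def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for a named substream of the pipeline seed.

    Every source of randomness in the package draws from one of these, so a
    single integer seed makes the whole pipeline reproducible while modules
    stay statistically independent.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# Cells
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cell:
    """One detected cell: centroid in µm, phenotype, optional marker flags."""

    cell_id: str
    x: float
    y: float
    phenotype: str
    flags: frozenset[str] = frozenset()
    specimen_id: str | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValidationError(f"cell {self.cell_id}: non-finite coordinates")
        if self.phenotype not in PHENOTYPES:
            raise ValidationError(
                f"cell {self.cell_id}: phenotype {self.phenotype!r} outside vocabulary"
            )
        bad = set(self.flags) - set(MARKER_FLAGS)
        if bad:
            raise ValidationError(f"cell {self.cell_id}: unknown flags {sorted(bad)}")


_CELL_COLUMNS = ["cell_id", "x", "y", "phenotype", "cd103", "ki67"]


def cells_to_frame(cells: Iterable[Cell]) -> pd.DataFrame:
    """Tabulate Cell records into the canonical cell frame."""
    rows = [
        (c.cell_id, c.x, c.y, c.phenotype, "cd103" in c.flags, "ki67" in c.flags)
        for c in cells
    ]
    df = pd.DataFrame(rows, columns=_CELL_COLUMNS)
    df["cell_id"] = df["cell_id"].astype(str)
    return df


def frame_to_cells(frame: pd.DataFrame, specimen_id: str | None = None) -> list[Cell]:
    out = []
    for row in frame.itertuples(index=False):
        flags = set()
        if getattr(row, "cd103", False):
            flags.add("cd103")
        if getattr(row, "ki67", False):
            flags.add("ki67")
        out.append(
            Cell(str(row.cell_id), float(row.x), float(row.y), row.phenotype,
                 frozenset(flags), specimen_id)
        )
    return out


class CellTable:
    """Frame-backed collection of cells with a parse summary.

    Iterating yields :class:`Cell`; ``.frame`` exposes the underlying
    DataFrame (columns cell_id, x, y, phenotype, cd103, ki67) that the
    analysis modules consume.
    """

    def __init__(self, frame: pd.DataFrame, summary: dict | None = None):
        missing = [c for c in ("cell_id", "x", "y", "phenotype") if c not in frame.columns]
        if missing:
            raise FormatError(f"cell frame missing required columns: {missing}")
        frame = frame.copy()
        for flag in MARKER_FLAGS:
            if flag not in frame.columns:
                frame[flag] = False
            frame[flag] = frame[flag].astype(bool)
        bad = set(frame["phenotype"]) - set(PHENOTYPES)
        if bad:
            raise ValidationError(f"phenotypes outside vocabulary: {sorted(bad)}")
        self.frame = frame[_CELL_COLUMNS].reset_index(drop=True)
        self.summary = summary or {"n_rows": len(frame), "n_unknown_phenotype": 0}

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[Cell]:
        return iter(frame_to_cells(self.frame))


def as_cell_frame(cells) -> pd.DataFrame:
    """Coerce a CellTable, DataFrame or iterable of Cell to the cell frame."""
    if isinstance(cells, CellTable):
        return cells.frame
    if isinstance(cells, pd.DataFrame):
        return cells
    return cells_to_frame(cells)


# ---------------------------------------------------------------------------
# Specimen and configuration
# ---------------------------------------------------------------------------

@dataclass
class Specimen:
    """A stained slide: cells plus tumor-field annotations and metadata.

    Diagnostic biopsies sample the tumor center only and carry no invasive
    margin; resections include the margin and are the specimens eligible for
    immunotyping.
    """

    specimen_id: str
    kind: str = "resection"
    site: str = "oral_cavity"
    hpv_status: str = "negative"
    cells: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_CELL_COLUMNS))
    tumor_fields: list[Polygon] = field(default_factory=list)
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in SPECIMEN_KINDS:
            raise ValidationError(f"unknown specimen kind {self.kind!r}")
        if self.site not in SITES:
            raise ValidationError(f"unknown site {self.site!r}")
        if self.hpv_status not in HPV_STATUSES:
            raise ValidationError(f"unknown hpv status {self.hpv_status!r}")
        self.cells = as_cell_frame(self.cells)


#: Default mapping from common marker-combination labels to the vocabulary.
DEFAULT_PHENOTYPE_ALIASES: dict[str, str] = {
    "CD44v6": "tumor",
    "panCK": "tumor",
    "CD163": "macrophage_cd163",
    "CD19": "b_cell",
    "CD8": "t_cd8",
    "CD3+CD8-FoxP3-": "t_cd4_helper",
    "FoxP3": "treg",
}


@dataclass
class PipelineConfig:
    """All numeric constants of the pipeline, with the published defaults.

    Lengths are µm, densities cells/mm².  ``tumor_area_buffer`` is the
    stromal collar beyond the outer tumor cells; ``margin_halfwidth`` the
    half-width of the invasive-margin band (250 µm inward + 250 µm outward =
    a 500 µm band).  The immunotype thresholds are 100 cells/mm² (tumor
    center), 82.8 cells/mm² (tumor fields; a cohort median, recomputable via
    ``tf_cd8_threshold_mode='cohort_median'``) and 200 cells/mm² (invasive
    margin), compared strictly (">").
    """

    tumor_area_buffer: float = 250.0
    margin_halfwidth: float = 250.0
    tc_cd8_threshold: float = 100.0
    im_cd8_threshold: float = 200.0
    tf_cd8_threshold_mode: str = "fixed"  # fixed | cohort_median
    tf_cd8_threshold_fixed: float = 82.8
    radius_fraction_r: float = 10.0
    neighborhood_radius: float = 50.0
    neighborhood_k: int = 4
    dominance_fraction: float = 0.40
    protein_presence_min: float = 0.85
    random_seed: int = 0
    # geometry details
    margin_mode: str = "contour"  # contour | area_boundary
    buffer_quad_segs: int = 16
    repair_geometries: bool = True
    # analysis switches
    scale_neighborhood_features: bool = False
    include_index_cell_feature: bool = False
    chi2_continuity_correction: bool = False
    linkage_method: str = "ward"
    linkage_metric: str = "euclidean"
    phenotype_aliases: dict = field(default_factory=lambda: dict(DEFAULT_PHENOTYPE_ALIASES))

    def __post_init__(self) -> None:
        for name in ("tumor_area_buffer", "margin_halfwidth", "radius_fraction_r",
                     "neighborhood_radius"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("tc_cd8_threshold", "im_cd8_threshold", "tf_cd8_threshold_fixed"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0 < self.protein_presence_min <= 1):
            raise ValidationError("protein_presence_min must be in (0, 1]")
        if self.neighborhood_k < 2:
            raise ValidationError("neighborhood_k must be >= 2")
        if self.tf_cd8_threshold_mode not in ("fixed", "cohort_median"):
            raise ValidationError("tf_cd8_threshold_mode must be fixed|cohort_median")
        if self.margin_mode not in ("contour", "area_boundary"):
            raise ValidationError("margin_mode must be contour|area_boundary")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# NPX matrices
# ---------------------------------------------------------------------------

@dataclass
class NPXMatrix:
    """Protein × sample matrix of normalized protein expression (log2 scale).

    ``values`` is proteins × samples; ``plate`` maps sample → plate label;
    ``missing`` marks below-LOD/absent entries (same shape as values, and the
    corresponding values are NaN).
    """

    values: pd.DataFrame
    plate: pd.Series
    missing: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != self.missing.shape:
            raise ValidationError("missing mask shape differs from values")
        if not self.values.columns.equals(self.missing.columns) or not self.values.index.equals(
            self.missing.index
        ):
            raise ValidationError("missing mask labels differ from values")
        if not self.values.columns.equals(self.plate.index):
            raise ValidationError("plate labels do not match sample columns")
        if self.values.index.duplicated().any():
            raise FormatError("duplicate protein names")

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# Cell-table I/O
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    header = path.read_text().splitlines()[0] if path.read_text() else ""
    return "\t" if "\t" in header else ","


def read_cell_table(path: str | Path, aliases: Mapping[str, str] | None = None) -> CellTable:
    """Read a delimited cell table (CSV or TSV, auto-detected from the header).

    Required columns: ``cell_id``, ``x_um``, ``y_um``, ``phenotype`` (plain
    ``x``/``y`` also accepted); optional boolean columns ``cd103``/``ki67``.
    Phenotype strings are passed through ``aliases`` first; anything still
    outside the vocabulary maps to ``other`` with a logged warning.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"cell_id": str}, float_precision="round_trip")
    df = df.rename(columns={"x_um": "x", "y_um": "y"})
    for col in ("cell_id", "x", "y", "phenotype"):
        if col not in df.columns:
            raise FormatError(f"cell table {path.name}: missing required column {col!r}")
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            line = int(np.flatnonzero(coerced.isna())[0]) + 2  # header is line 1
            raise FormatError(f"cell table {path.name}: non-numeric {col} at line {line}")
        df[col] = coerced.astype(float)

    alias_map = dict(DEFAULT_PHENOTYPE_ALIASES)
    if aliases:
        alias_map.update(aliases)
    phen = df["phenotype"].astype(str).map(lambda p: alias_map.get(p, p))
    unknown = ~phen.isin(PHENOTYPES)
    n_unknown = int(unknown.sum())
    if n_unknown:
        log.warning(
            "cell table %s: %d rows with unknown phenotype %s mapped to 'other'",
            path.name, n_unknown, sorted(set(phen[unknown]))[:5],
        )
        phen = phen.where(~unknown, "other")
    df["phenotype"] = phen
    for flag in MARKER_FLAGS:
        if flag in df.columns:
            df[flag] = df[flag].fillna(False).astype(bool)
        else:
            df[flag] = False
    summary = {"n_rows": len(df), "n_unknown_phenotype": n_unknown}
    return CellTable(df[_CELL_COLUMNS], summary)


def write_cell_table(cells, path: str | Path) -> None:
    frame = as_cell_frame(cells).rename(columns={"x": "x_um", "y": "y_um"})
    frame.to_csv(path, index=False, float_format="%.17g")  # exact round-trip


# ---------------------------------------------------------------------------
# Polygon annotation I/O (GeoJSON, RFC 7946; coordinates in µm)
# ---------------------------------------------------------------------------

def _as_polygons(geom) -> list[Polygon]:
    if isinstance(geom, Polygon):
        return [geom]
    if isinstance(geom, MultiPolygon):
        return list(geom.geoms)
    if geom.is_empty:
        return []
    raise GeometryError(f"unsupported geometry type {geom.geom_type}")


def read_annotations(path: str | Path, repair: bool = True) -> list[Polygon]:
    """Read tumor-field polygons from a GeoJSON FeatureCollection.

    Invalid rings are repaired with ``make_valid`` when ``repair`` is true,
    otherwise rejected with a :class:`GeometryError`.
    """
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise FormatError("annotations must be a GeoJSON FeatureCollection")
    polygons: list[Polygon] = []
    for i, feature in enumerate(data.get("features", [])):
        geom = geom_shape(feature["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise GeometryError(f"feature {i}: unsupported type {geom.geom_type}")
        if not geom.is_valid:
            if not repair:
                raise GeometryError(f"feature {i}: {explain_validity(geom)}")
            geom = make_valid(geom)
            log.warning("annotations %s: repaired invalid feature %d", Path(path).name, i)
        for poly in _as_polygons(geom):
            if not poly.is_empty:
                polygons.append(poly)
    return polygons


def write_annotations(polygons: Sequence[Polygon], path: str | Path,
                      properties: Sequence[dict] | None = None) -> None:
    features = []
    for i, poly in enumerate(polygons):
        props = properties[i] if properties else {}
        features.append({"type": "Feature", "properties": props,
                         "geometry": geom_mapping(poly)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# Metadata I/O
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the specimen metadata table (CSV; one row per specimen)."""
    df = pd.read_csv(path, dtype={"specimen_id": str})
    if "specimen_id" not in df.columns:
        raise FormatError("metadata: missing required column 'specimen_id'")
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# NPX I/O
# ---------------------------------------------------------------------------

def read_npx(path: str | Path, proteins_in: str = "columns") -> NPXMatrix:
    """Read an NPX matrix from CSV.

    With ``proteins_in='columns'`` (default) rows are samples with a
    ``sample_id`` and a ``plate`` column and one column per protein; with
    ``proteins_in='rows'`` rows are proteins (first column ``protein``),
    columns are samples, and a special first row labelled ``_plate`` carries
    the plate labels.  Empty cells become missing.
    """
    if proteins_in == "columns":
        header = Path(path).read_text().splitlines()[0].split(",")
        dupes = sorted({h for h in header if header.count(h) > 1})
        if dupes:
            raise FormatError(f"duplicate protein names: {dupes}")
        df = pd.read_csv(path, dtype={"sample_id": str, "plate": str})
        for col in ("sample_id", "plate"):
            if col not in df.columns:
                raise FormatError(f"NPX table: missing required column {col!r}")
        df = df.set_index("sample_id")
        plate = df.pop("plate")
        values = df.T.astype(float)
    elif proteins_in == "rows":
        df = pd.read_csv(path, dtype={"protein": str})
        if "protein" not in df.columns:
            raise FormatError("NPX table: missing required column 'protein'")
        df = df.set_index("protein")
        if "_plate" not in df.index:
            raise FormatError("NPX table: missing '_plate' row")
        plate = df.loc["_plate"].astype(str)
        values = df.drop(index="_plate").astype(float)
    else:
        raise ValidationError("proteins_in must be 'columns' or 'rows'")
    if values.index.duplicated().any():
        dupes = sorted(set(values.index[values.index.duplicated()]))
        raise FormatError(f"duplicate protein names: {dupes}")
    missing = values.isna()
    plate.index.name = None
    values.index.name = None
    values.columns.name = None
    return NPXMatrix(values=values, plate=plate, missing=missing)


def write_npx(npx: NPXMatrix, path: str | Path) -> None:
    """Write an NPX matrix as CSV (samples as rows, plate column)."""
    out = npx.values.mask(npx.missing).T
    out.insert(0, "plate", npx.plate)
    out.index.name = "sample_id"
    out.to_csv(path)
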