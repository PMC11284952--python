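"""Synthetic specimen and NPX generation.

Generates fully specified synthetic specimens — perturbed-circle tumor-field
landscapes populated with phenotyped cells — plus NPX protein matrices with
plate shifts and missingness, so every downstream stage of the pipeline is
testable without patient material.

Cells follow a homogeneous Poisson point process per tissue zone at
configurable densities per phenotype; B cells can additionally be laid down
as a Thomas-type parent–offspring cluster process, emulating the B-cell
aggregates seen in tissue.  Four archetype parameter sets target the four
CD8-based immunotypes (fully infiltrated, stroma-restricted,
immune-excluded, immune-desert) with a wide safety margin to each decision
threshold, so the intended label is recovered essentially always.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .io_model import (
    IMMUNE_PHENOTYPES,
    NPXMatrix,
    PipelineConfig,
    Specimen,
    ValidationError,
    substream,
)
from .zoning import ZoneSet, build_zones

log = logging.getLogger("timetopo.synthetic")

IMMUNOTYPES = ("fully_infiltrated", "stroma_restricted", "immune_excluded", "immune_desert")


@dataclass
class FieldGeometry:
    """Tumor-field landscape: ``n_blobs`` perturbed circles of radius
    ``blob_radius`` placed on a ring of radius ``ring_radius`` with positional
    jitter, so the tumor center retains both field and stroma compartments."""

    n_blobs: int = 6
    blob_radius: float = 350.0  # µm
    ring_radius: float = 900.0  # µm
    jitter: float = 80.0  # µm
    roughness: float = 0.10  # relative boundary perturbation
    n_vertices: int = 64


@dataclass
class AggregateParams:
    """Thomas cluster process for B-cell aggregates: Poisson parents at
    ``parent_intensity`` per mm², Poisson(mean_offspring) offspring scattered
    isotropically with Gaussian ``dispersion`` (µm), clipped to the zone."""

    parent_intensity: float = 1.5
    mean_offspring: float = 25.0
    dispersion: float = 30.0


@dataclass
class ArchetypeSpec:
    """Densities (cells/mm²) per (region, compartment) and phenotype, plus the
    aggregate and field-geometry parameters, for one immunotype archetype."""

    immunotype: str
    zone_densities: dict  # (region, compartment) -> {phenotype: cells/mm²}
    aggregate_params: AggregateParams | None = None
    field_geometry: FieldGeometry = field(default_factory=FieldGeometry)

    def __post_init__(self) -> None:
        if self.immunotype not in IMMUNOTYPES:
            raise ValidationError(f"unknown immunotype {self.immunotype!r}")
        for key, dens in self.zone_densities.items():
            for phen, d in dens.items():
                if d < 0:
                    raise ValidationError(f"negative density for {key}/{phen}")


# CD8 densities per archetype, chosen ≥2× above / ≤0.5× below every decision
# threshold they must clear or miss (thresholds: TC 100, TF 82.8, IM 200).
_CD8 = {
    "fully_infiltrated": {("center", "field"): 300, ("center", "stroma"): 500,
                          ("margin", "field"): 300, ("margin", "stroma"): 600},
    "stroma_restricted": {("center", "field"): 25, ("center", "stroma"): 900,
                          ("margin", "field"): 25, ("margin", "stroma"): 800},
    "immune_excluded": {("center", "field"): 5, ("center", "stroma"): 30,
                        ("margin", "field"): 300, ("margin", "stroma"): 600},
    "immune_desert": {("center", "field"): 2, ("center", "stroma"): 8,
                      ("margin", "field"): 10, ("margin", "stroma"): 30},
}

# Background densities shared across archetypes (cells/mm²): tumor cells fill
# the fields; myeloid and T-helper/Treg infiltrates concentrate in stroma and
# the margin, matching the qualitative density structure of resections.
_BACKGROUND = {
    ("center", "field"): {"tumor": 800, "macrophage_cd163": 80, "t_cd4_helper": 120,
                          "treg": 60, "b_cell": 5, "other": 100},
    ("center", "stroma"): {"macrophage_cd163": 150, "t_cd4_helper": 300,
                           "treg": 150, "b_cell": 15, "other": 100},
    ("margin", "field"): {"tumor": 800, "macrophage_cd163": 100, "t_cd4_helper": 150,
                          "treg": 70, "b_cell": 10, "other": 100},
    ("margin", "stroma"): {"macrophage_cd163": 200, "t_cd4_helper": 400,
                           "treg": 180, "b_cell": 25, "other": 100},
}


def default_archetype(immunotype: str) -> ArchetypeSpec:
    """The default archetype parameter set for one of the four immunotypes."""
    if immunotype not in IMMUNOTYPES:
        raise ValidationError(f"unknown immunotype {immunotype!r}")
    dens = {}
    for key, base in _BACKGROUND.items():
        dens[key] = dict(base)
        dens[key]["t_cd8"] = _CD8[immunotype][key]
    return ArchetypeSpec(immunotype=immunotype, zone_densities=dens,
                         aggregate_params=AggregateParams())


# ---------------------------------------------------------------------------
# Geometry generation
# ---------------------------------------------------------------------------

def _blob(center: np.ndarray, radius: float, roughness: float, n_vertices: int,
          rng: np.random.Generator) -> Polygon:
    """A perturbed circle: radius modulated by low-order Fourier harmonics so
    the ring stays simple (no self-intersection) at moderate roughness."""
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.full(n_vertices, radius)
    if roughness > 0:
        for m in range(2, 6):
            amp = roughness * radius * rng.normal() / m
            phase = rng.uniform(0, 2 * np.pi)
            r = r + amp * np.cos(m * theta + phase)
    r = np.clip(r, 0.2 * radius, None)
    xy = np.column_stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)])
    return Polygon(xy)


def generate_tumor_fields(spec: ArchetypeSpec, seed: int) -> list[Polygon]:
    """Generate the tumor-field polygons for an archetype landscape.

    Overlapping blobs are merged; all returned polygons are simple and valid.
    """
    geom = spec.field_geometry
    if geom.blob_radius < 100:
        raise ValidationError("blob radius must be >= 100 µm")
    rng = substream(seed, "tumor_fields")
    blobs = []
    for i in range(geom.n_blobs):
        angle = 2 * np.pi * i / geom.n_blobs
        center = geom.ring_radius * np.array([np.cos(angle), np.sin(angle)])
        center = center + rng.uniform(-geom.jitter, geom.jitter, size=2)
        blobs.append(_blob(center, geom.blob_radius, geom.roughness,
                           geom.n_vertices, rng))
    merged = unary_union(blobs)
    polys = list(merged.geoms) if merged.geom_type == "MultiPolygon" else [merged]
    polys = [p for p in polys if not p.is_empty and p.area > 0]
    if not polys:
        raise ValidationError("field-geometry parameters yielded empty geometry")
    for p in polys:
        if not p.is_valid:
            raise ValidationError("generated tumor field is invalid")
    return polys


# ---------------------------------------------------------------------------
# Point processes
# ---------------------------------------------------------------------------

def _uniform_in_polygon(polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample n points uniformly inside a polygon."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = polygon.bounds
    shapely.prepare(polygon)
    out: list[np.ndarray] = []
    need = n
    while need > 0:
        m = max(32, int(need / max(polygon.area / ((maxx - minx) * (maxy - miny)), 1e-6)) + 16)
        pts = np.column_stack([rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)])
        keep = shapely.covers(polygon, shapely.points(pts[:, 0], pts[:, 1]))
        got = pts[keep][:need]
        out.append(got)
        need -= len(got)
    return np.concatenate(out)


def populate_cells(zones: ZoneSet, zone_densities: dict, seed: int,
                   id_prefix: str = "c") -> pd.DataFrame:
    """Poisson-populate every zone with cells at the given densities.

    ``zone_densities`` maps (region, compartment) → {phenotype: cells/mm²};
    per zone and phenotype the count is Poisson(density × area) and positions
    are uniform within the zone polygon.
    """
    rng = substream(seed, "populate_cells")
    rows = []
    counter = 0
    for key in sorted(zone_densities):
        dens = zone_densities[key]
        polygon = zones.zones[key]
        area = zones.areas[key]
        if polygon.is_empty or area == 0:
            continue
        for phen in sorted(dens):
            d = dens[phen]
            if d < 0:
                raise ValidationError(f"negative density for {key}/{phen}")
            n = int(rng.poisson(d * area))
            pts = _uniform_in_polygon(polygon, n, rng)
            for x, y in pts:
                rows.append((f"{id_prefix}{counter}", x, y, phen))
                counter += 1
    df = pd.DataFrame(rows, columns=["cell_id", "x", "y", "phenotype"])
    df["cd103"] = False
    df["ki67"] = False
    return df


def generate_b_cell_aggregates(zone, params: AggregateParams, seed: int,
                               id_prefix: str = "b",
                               parents: np.ndarray | None = None) -> pd.DataFrame:
    """Thomas-process B-cell aggregates clipped to a zone polygon.

    ``parents`` overrides the Poisson parent process with fixed parent
    locations (n × 2 array, µm), useful for calibration checks.
    """
    if params.dispersion <= 0:
        raise ValidationError("dispersion must be > 0")
    if params.parent_intensity < 0 or params.mean_offspring < 0:
        raise ValidationError("aggregate intensities must be >= 0")
    rng = substream(seed, "b_cell_aggregates")
    rows = []
    if zone.is_empty or zone.area == 0:
        return pd.DataFrame(columns=["cell_id", "x", "y", "phenotype", "cd103", "ki67"])
    if parents is None:
        area = zone.area / 1e6
        n_parents = int(rng.poisson(params.parent_intensity * area))
        parents = _uniform_in_polygon(zone, n_parents, rng)
    else:
        parents = np.asarray(parents, dtype=float).reshape(-1, 2)
    shapely.prepare(zone)
    counter = 0
    for px, py in parents:
        n_off = int(rng.poisson(params.mean_offspring))
        if n_off == 0:
            continue
        offsets = rng.normal(0.0, params.dispersion, size=(n_off, 2))
        pts = np.array([px, py]) + offsets
        keep = shapely.covers(zone, shapely.points(pts[:, 0], pts[:, 1]))
        for x, y in pts[keep]:
            rows.append((f"{id_prefix}{counter}", x, y, "b_cell", False, False))
            counter += 1
    return pd.DataFrame(rows, columns=["cell_id", "x", "y", "phenotype", "cd103", "ki67"])


# ---------------------------------------------------------------------------
# Archetype specimens
# ---------------------------------------------------------------------------

def generate_archetype(immunotype: str, seed: int,
                       config: PipelineConfig | None = None,
                       spec: ArchetypeSpec | None = None,
                       specimen_id: str | None = None) -> Specimen:
    """Generate a full synthetic resection specimen of one immunotype.

    Returns a Specimen whose covariates record the intended label under
    ``intended_immunotype``.  Identical (immunotype, seed, config) give
    bit-identical output.
    """
    config = config or PipelineConfig()
    spec = spec or default_archetype(immunotype)
    fields = generate_tumor_fields(spec, seed)
    zones = build_zones(fields, config)
    cells = populate_cells(zones, spec.zone_densities, seed)
    if spec.aggregate_params is not None:
        agg = generate_b_cell_aggregates(
            zones.zones[("margin", "stroma")].union(zones.zones[("center", "stroma")]),
            spec.aggregate_params, seed)
        cells = pd.concat([cells, agg], ignore_index=True)
    rng = substream(seed, "specimen_meta")
    site = ("oral_cavity", "hypopharynx", "larynx")[int(rng.integers(3))]
    return Specimen(
        specimen_id=specimen_id or f"{immunotype}_s{seed}",
        kind="resection",
        site=site,
        hpv_status="negative",
        cells=cells,
        tumor_fields=fields,
        covariates={"intended_immunotype": immunotype},
    )


# ---------------------------------------------------------------------------
# NPX matrices
# ---------------------------------------------------------------------------

def generate_npx(n_proteins: int = 92, n_samples: int = 11,
                 plate_assignment=None, plate_shifts=None,
                 missing_rate: float = 0.05, noise_sd: float = 0.3,
                 seed: int = 0) -> NPXMatrix:
    """Synthetic NPX matrix: protein baseline + sample effect + plate shift +
    Gaussian noise, with i.i.d. missingness at ``missing_rate``.

    ``plate_assignment`` maps each sample index to a plate label (default:
    two plates A/B split evenly); ``plate_shifts`` maps plate label to an
    additive NPX shift (default 0).
    """
    if not (0 <= missing_rate <= 1):
        raise ValidationError("missing_rate must be in [0, 1]")
    rng = substream(seed, "npx")
    proteins = [f"protein_{i:03d}" for i in range(n_proteins)]
    samples = [f"sample_{j:02d}" for j in range(n_samples)]
    if plate_assignment is None:
        plate_assignment = ["A" if j < n_samples // 2 else "B" for j in range(n_samples)]
    plate = pd.Series(list(plate_assignment), index=samples)
    shifts = dict(plate_shifts or {})

    baseline = rng.normal(5.0, 2.0, size=n_proteins)
    sample_effect = rng.normal(0.0, 0.5, size=n_samples)
    noise = rng.normal(0.0, noise_sd, size=(n_proteins, n_samples))
    values = baseline[:, None] + sample_effect[None, :] + noise
    values = values + np.array([shifts.get(p, 0.0) for p in plate])[None, :]
    missing = rng.random(size=values.shape) < missing_rate
    vdf = pd.DataFrame(values, index=proteins, columns=samples)
    mdf = pd.DataFrame(missing, index=proteins, columns=samples)
    vdf = vdf.mask(mdf)
    return NPXMatrix(values=vdf, plate=plate, missing=mdf)
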