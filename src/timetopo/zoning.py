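"""Tissue-zone construction from tumor-field polygons.

The tumor area is the union of tumor fields, with enclosed stroma filled
in, plus a stromal collar extending 250 µm beyond the outer tumor cells.
The invasive margin is the 500 µm band straddling the outer tumor-field
contour (250 µm inward + 250 µm outward, clipped to the tumor area); the
tumor center is the remaining tumor area.  Within every zone, tumor fields
and tumor stroma are distinguished, giving four (region × compartment)
bins plus an "outside" label for cells beyond the tumor area.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .io_model import PipelineConfig, ZoningError, as_cell_frame

log = logging.getLogger("timetopo.zoning")

UM2_PER_MM2 = 1e6

REGIONS = ("center", "margin")
COMPARTMENTS = ("field", "stroma")


def area_mm2(geom: BaseGeometry) -> float:
    """Polygon area in mm² (coordinates are µm)."""
    return geom.area / UM2_PER_MM2


def fill_holes(geom: BaseGeometry) -> BaseGeometry:
    """Drop interior rings: stroma fully enclosed by tumor belongs to the
    tumor area and must not spawn margin bands."""
    if geom.is_empty:
        return geom
    if isinstance(geom, Polygon):
        return Polygon(geom.exterior)
    if isinstance(geom, MultiPolygon):
        return unary_union([Polygon(p.exterior) for p in geom.geoms])
    raise ZoningError(f"cannot fill holes of {geom.geom_type}")


def build_tumor_area(tumor_fields, buffer: float, quad_segs: int = 16) -> BaseGeometry:
    """Outward-buffer the union of tumor fields by ``buffer`` µm, holes filled.

    Fields farther apart than twice the buffer yield a multipolygon.
    """
    if buffer <= 0:
        raise ZoningError("buffer must be > 0")
    fields = list(tumor_fields)
    if not fields:
        raise ZoningError("specimen has no delineated tumor fields")
    union = unary_union(fields)
    if union.is_empty:
        raise ZoningError("tumor-field union is empty")
    return fill_holes(fill_holes(union).buffer(buffer, quad_segs=quad_segs))


def build_invasive_margin(tumor_fields, tumor_area: BaseGeometry, halfwidth: float,
                          mode: str = "contour", quad_segs: int = 16) -> BaseGeometry:
    """The margin band of total width ``2 × halfwidth`` (500 µm at default).

    ``mode='contour'`` (default) takes all points within ``halfwidth`` of the
    outer tumor-field contour, clipped to the tumor area — the constructive
    reading of a band drawn 250 µm to each side of the outlined tumor front.
    ``mode='area_boundary'`` instead peels the outer ``2 × halfwidth`` layer
    off the tumor area itself.
    """
    if halfwidth <= 0:
        raise ZoningError("halfwidth must be > 0")
    if mode == "contour":
        outer = fill_holes(unary_union(list(tumor_fields)))
        band = outer.boundary.buffer(halfwidth, quad_segs=quad_segs)
        margin = band.intersection(tumor_area)
    elif mode == "area_boundary":
        eroded = tumor_area.buffer(-2 * halfwidth, quad_segs=quad_segs)
        margin = tumor_area.difference(eroded)
    else:
        raise ZoningError(f"unknown margin mode {mode!r}")
    center = tumor_area.difference(margin)
    if center.is_empty or center.area == 0:
        log.warning("margin band consumes the whole tumor area; tumor center is empty")
        return tumor_area
    return margin


def build_tumor_center(tumor_area: BaseGeometry, invasive_margin: BaseGeometry) -> BaseGeometry:
    """Tumor center = tumor area minus the invasive margin."""
    if invasive_margin.is_empty:
        return tumor_area
    return tumor_area.difference(invasive_margin)


def split_field_stroma(zone: BaseGeometry, tumor_fields) -> tuple[BaseGeometry, BaseGeometry]:
    """Split a zone into its tumor-field and tumor-stroma parts."""
    fields = unary_union(list(tumor_fields))
    field_part = zone.intersection(fields)
    stroma_part = zone.difference(field_part)
    return field_part, stroma_part


@dataclass
class ZoneSet:
    """All tissue zones of one specimen, with areas in mm².

    ``zones`` maps (region, compartment) — e.g. ("center", "stroma") — to a
    polygon; ``areas`` carries those plus the marginals "tumor_area",
    "center", "margin", "field", "stroma".
    """

    tumor_fields: BaseGeometry
    tumor_area: BaseGeometry
    invasive_margin: BaseGeometry
    tumor_center: BaseGeometry
    zones: dict = field(default_factory=dict)
    areas: dict = field(default_factory=dict)

    def validate(self, rel_tol: float = 1e-6) -> None:
        """Check the additivity invariants (margin + center = tumor area, and
        field + stroma = each region) to relative tolerance."""
        total = self.tumor_area.area
        if total == 0:
            raise ZoningError("tumor area has zero area")
        if abs(self.invasive_margin.area + self.tumor_center.area - total) > rel_tol * total:
            raise ZoningError("margin + center areas do not sum to tumor area")
        for region, region_geom in (("center", self.tumor_center),
                                    ("margin", self.invasive_margin)):
            parts = sum(self.zones[(region, c)].area for c in COMPARTMENTS)
            if abs(parts - region_geom.area) > rel_tol * max(total, 1.0):
                raise ZoningError(f"field + stroma areas do not sum to {region} area")


def build_zones(tumor_fields, config: PipelineConfig | None = None) -> ZoneSet:
    """Construct the full ZoneSet from tumor-field polygons."""
    config = config or PipelineConfig()
    qs = config.buffer_quad_segs
    fields_union = unary_union(list(tumor_fields))
    tumor_area = build_tumor_area(tumor_fields, config.tumor_area_buffer, qs)
    margin = build_invasive_margin(tumor_fields, tumor_area, config.margin_halfwidth,
                                   config.margin_mode, qs)
    center = build_tumor_center(tumor_area, margin)

    zones: dict = {}
    for region, geom in (("center", center), ("margin", margin)):
        f, s = split_field_stroma(geom, [fields_union])
        zones[(region, "field")] = f
        zones[(region, "stroma")] = s

    areas = {key: area_mm2(geom) for key, geom in zones.items()}
    areas["tumor_area"] = area_mm2(tumor_area)
    areas["center"] = area_mm2(center)
    areas["margin"] = area_mm2(margin)
    areas["field"] = areas[("center", "field")] + areas[("margin", "field")]
    areas["stroma"] = areas[("center", "stroma")] + areas[("margin", "stroma")]

    zs = ZoneSet(tumor_fields=fields_union, tumor_area=tumor_area,
                 invasive_margin=margin, tumor_center=center, zones=zones, areas=areas)
    zs.validate()
    return zs


def assign_cells_to_zones(cells, zones: ZoneSet) -> pd.DataFrame:
    """Label every cell with (region, compartment) or "outside".

    Point-in-polygon includes the boundary.  Measure-zero ties resolve by a
    deterministic precedence: margin over center, field over stroma.
    """
    frame = as_cell_frame(cells)
    if len(frame) == 0:
        return pd.DataFrame(columns=["cell_id", "region", "compartment"])
    points = shapely.points(frame["x"].to_numpy(dtype=float),
                            frame["y"].to_numpy(dtype=float))

    def covered(geom) -> np.ndarray:
        if geom.is_empty:
            return np.zeros(len(points), dtype=bool)
        shapely.prepare(geom)
        return shapely.covers(geom, points)

    in_area = covered(zones.tumor_area)
    in_margin = covered(zones.invasive_margin) & in_area
    in_field = covered(zones.tumor_fields) & in_area

    region = np.where(~in_area, "outside", np.where(in_margin, "margin", "center"))
    compartment = np.where(~in_area, "", np.where(in_field, "field", "stroma"))
    return pd.DataFrame({
        "cell_id": frame["cell_id"].to_numpy(),
        "region": region,
        "compartment": compartment,
    })


def zoneset_to_features(zones: ZoneSet) -> tuple[list, list]:
    """Flatten a ZoneSet to (polygons, properties) for GeoJSON export."""
    polys, props = [], []
    named = [("tumor_area", zones.tumor_area), ("invasive_margin", zones.invasive_margin),
             ("tumor_center", zones.tumor_center), ("tumor_fields", zones.tumor_fields)]
    named += [(f"{r}_{c}", zones.zones[(r, c)]) for r in REGIONS for c in COMPARTMENTS]
    for name, geom in named:
        polys.append(geom)
        props.append({"zone": name, "area_mm2": area_mm2(geom)})
    return polys, props
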