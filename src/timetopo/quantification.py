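"""Zone-wise densities, fractions, ratios, and the immunotype decision tree.

The four-way immunotype is a function of three CD8+ T-cell densities: the
tumor center (TC), tumor fields (TF) and invasive margin (IM).  A specimen
with TC density above 100 cells/mm² is infiltrated — fully infiltrated when
the TF density also exceeds the cohort median of 82.8 cells/mm², otherwise
stroma-restricted.  Below the TC threshold, an IM density above
200 cells/mm² marks an immune-excluded tumor, otherwise immune-desert.
All comparisons are strict ("more than"); equality falls to the lower
branch.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import (
    IMMUNE_PHENOTYPES,
    PHENOTYPES,
    ClassificationError,
    PipelineConfig,
    Specimen,
    StatsError,
    as_cell_frame,
)
from .zoning import COMPARTMENTS, REGIONS, ZoneSet, assign_cells_to_zones

log = logging.getLogger("timetopo.quantification")

IMMUNOTYPE_LABELS = ("fully_infiltrated", "stroma_restricted",
                     "immune_excluded", "immune_desert")


def compute_densities(specimen_or_cells, zones: ZoneSet,
                      labels: pd.DataFrame | None = None,
                      specimen_id: str | None = None) -> pd.DataFrame:
    """Per-(region, compartment, phenotype) counts, areas and densities.

    One row per base bin plus marginal rows: region "tumor_area" aggregates
    the whole tumor area; compartment "all" aggregates field + stroma.  A
    phenotype "all_immune" row aggregates the five immune phenotypes.  Cells
    labelled outside the tumor area are excluded.  Densities are cells/mm²,
    NaN when a zone has zero area.
    """
    if isinstance(specimen_or_cells, Specimen):
        cells = specimen_or_cells.cells
        specimen_id = specimen_id or specimen_or_cells.specimen_id
    else:
        cells = as_cell_frame(specimen_or_cells)
    if labels is None:
        labels = assign_cells_to_zones(cells, zones)
    merged = cells.reset_index(drop=True).assign(
        region=labels["region"].to_numpy(), compartment=labels["compartment"].to_numpy())
    inside = merged[merged["region"] != "outside"]

    bins: list[tuple[str, str]] = [(r, c) for r in REGIONS for c in COMPARTMENTS]
    bins += [(r, "all") for r in REGIONS]
    bins += [("tumor_area", c) for c in COMPARTMENTS] + [("tumor_area", "all")]

    def bin_area(region: str, compartment: str) -> float:
        if region == "tumor_area":
            if compartment == "all":
                return zones.areas["tumor_area"]
            return zones.areas[compartment]
        if compartment == "all":
            return zones.areas[region]
        return zones.areas[(region, compartment)]

    def bin_mask(region: str, compartment: str) -> pd.Series:
        m = pd.Series(True, index=inside.index)
        if region != "tumor_area":
            m &= inside["region"] == region
        if compartment != "all":
            m &= inside["compartment"] == compartment
        return m

    rows = []
    phen_groups = [(p, (p,)) for p in PHENOTYPES] + [("all_immune", IMMUNE_PHENOTYPES)]
    for region, compartment in bins:
        sub = inside[bin_mask(region, compartment)]
        area = bin_area(region, compartment)
        for name, members in phen_groups:
            count = int(sub["phenotype"].isin(members).sum())
            if area > 0:
                density = count / area
            else:
                density = np.nan
                log.warning("zone (%s, %s) has zero area; density missing",
                            region, compartment)
            rows.append((specimen_id, region, compartment, name, count, area, density))
    return pd.DataFrame(rows, columns=["specimen_id", "region", "compartment",
                                       "phenotype", "count", "area_mm2", "density"])


def get_density(table: pd.DataFrame, region: str, compartment: str,
                phenotype: str, specimen_id: str | None = None) -> float:
    """Look up one density from a density table (NaN if absent)."""
    m = ((table["region"] == region) & (table["compartment"] == compartment)
         & (table["phenotype"] == phenotype))
    if specimen_id is not None:
        m &= table["specimen_id"] == specimen_id
    sub = table[m]
    return float(sub["density"].iloc[0]) if len(sub) else float("nan")


def density_ratio(density_a: float, density_b: float) -> float:
    """a / b, NaN when b is zero or either input missing."""
    if density_b == 0 or not np.isfinite(density_a) or not np.isfinite(density_b):
        return float("nan")
    return density_a / density_b


def cohort_tf_threshold(density_tables: pd.DataFrame) -> float:
    """Median CD8 density in tumor fields across the cohort's resections.

    Input is a concatenated density table; uses the (tumor_area, field,
    t_cd8) rows, one per specimen.
    """
    m = ((density_tables["region"] == "tumor_area")
         & (density_tables["compartment"] == "field")
         & (density_tables["phenotype"] == "t_cd8"))
    vals = density_tables.loc[m, "density"].dropna()
    if vals.empty:
        raise StatsError("no tumor-field CD8 densities in cohort")
    return float(vals.median())


@dataclass
class ImmunotypeCall:
    """Result of the decision tree, with the branch record for auditing."""

    specimen_id: str | None
    label: str
    tc_cd8: float
    tf_cd8: float | None
    im_cd8: float | None
    thresholds: dict = field(default_factory=dict)
    decision_path: list = field(default_factory=list)


def call_immunotype(tc_cd8: float, tf_cd8: float | None, im_cd8: float | None,
                    tc_threshold: float = 100.0, tf_threshold: float = 82.8,
                    im_threshold: float = 200.0,
                    specimen_id: str | None = None) -> ImmunotypeCall:
    """Apply the four-way CD8 decision tree (strict inequalities).

    The TF density is only required on the infiltrated branch and the IM
    density only on the non-infiltrated branch; a missing density on the
    branch actually taken raises :class:`ClassificationError`.
    """
    if tc_cd8 is None or not np.isfinite(tc_cd8):
        raise ClassificationError("missing tumor-center CD8 density")
    thresholds = {"tc": tc_threshold, "tf": tf_threshold, "im": im_threshold}
    path = []
    if tc_cd8 > tc_threshold:
        path.append(f"tc_cd8 {tc_cd8:.1f} > {tc_threshold:g}")
        if tf_cd8 is None or not np.isfinite(tf_cd8):
            raise ClassificationError("missing tumor-field CD8 density")
        if tf_cd8 > tf_threshold:
            path.append(f"tf_cd8 {tf_cd8:.1f} > {tf_threshold:g}")
            label = "fully_infiltrated"
        else:
            path.append(f"tf_cd8 {tf_cd8:.1f} <= {tf_threshold:g}")
            label = "stroma_restricted"
    else:
        path.append(f"tc_cd8 {tc_cd8:.1f} <= {tc_threshold:g}")
        if im_cd8 is None or not np.isfinite(im_cd8):
            raise ClassificationError("missing invasive-margin CD8 density")
        if im_cd8 > im_threshold:
            path.append(f"im_cd8 {im_cd8:.1f} > {im_threshold:g}")
            label = "immune_excluded"
        else:
            path.append(f"im_cd8 {im_cd8:.1f} <= {im_threshold:g}")
            label = "immune_desert"
    return ImmunotypeCall(specimen_id=specimen_id, label=label, tc_cd8=tc_cd8,
                          tf_cd8=tf_cd8, im_cd8=im_cd8, thresholds=thresholds,
                          decision_path=path)


def immunotype_specimen(specimen: Specimen, density_table: pd.DataFrame,
                        config: PipelineConfig | None = None,
                        tf_threshold: float | None = None) -> ImmunotypeCall:
    """Immunotype one resection specimen from its density table.

    Biopsies sample only the tumor center and carry no invasive margin, so
    classification is refused for them.
    """
    config = config or PipelineConfig()
    if specimen.kind != "resection":
        raise ClassificationError(
            f"specimen {specimen.specimen_id}: immunotyping requires a resection "
            f"(got {specimen.kind})")
    if tf_threshold is None:
        tf_threshold = config.tf_cd8_threshold_fixed
    sid = specimen.specimen_id
    return call_immunotype(
        tc_cd8=get_density(density_table, "center", "all", "t_cd8", sid),
        tf_cd8=get_density(density_table, "tumor_area", "field", "t_cd8", sid),
        im_cd8=get_density(density_table, "margin", "all", "t_cd8", sid),
        tc_threshold=config.tc_cd8_threshold,
        tf_threshold=tf_threshold,
        im_threshold=config.im_cd8_threshold,
        specimen_id=sid,
    )


def phenotype_fractions(cells, labels: pd.DataFrame, group_by="phenotype",
                        subset: pd.Series | None = None) -> pd.DataFrame:
    """Per-zone fractions of a grouping over a cell subset.

    ``group_by`` is a column name or list of column names (e.g. "phenotype",
    or ["cd103"] / ["cd103", "ki67"] for the tumor-resident five-color
    workflow); ``subset`` an optional boolean mask selecting the denominator
    population (e.g. CD8 cells only).  Fractions sum to 1 within each
    non-empty (region, compartment) bin; empty bins yield no rows.
    """
    frame = as_cell_frame(cells).reset_index(drop=True)
    frame = frame.assign(region=labels["region"].to_numpy(),
                         compartment=labels["compartment"].to_numpy())
    frame = frame[frame["region"] != "outside"]
    if subset is not None:
        frame = frame[np.asarray(subset)[frame.index]]
    cols = [group_by] if isinstance(group_by, str) else list(group_by)
    counts = (frame.groupby(["region", "compartment"] + cols, observed=True)
              .size().rename("count").reset_index())
    totals = counts.groupby(["region", "compartment"], observed=True)["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    return counts
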