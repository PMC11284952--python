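"""NPX secretome processing.

Proteins measured by proximity-extension assay arrive as NPX values (log2
scale).  Processing follows the assay's published conventions: proteins
present in less than 85% of samples are discarded; intensity normalization
(V2) shifts each protein on each plate so its per-plate median equals the
overall median, removing plate effects; samples and proteins are then
hierarchically clustered, and protein levels are correlated against immune
densities with Spearman's rank correlation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import spearmanr

from .io_model import NPXMatrix, StatsError, ValidationError

log = logging.getLogger("timetopo.secretome")


def filter_proteins(npx: NPXMatrix, min_presence: float = 0.85
                    ) -> tuple[NPXMatrix, list[str]]:
    """Retain proteins non-missing in at least ``min_presence`` of samples.

    The rule is "discard when present in less than min_presence": a protein
    present in exactly that fraction is retained.  Returns the filtered
    matrix and the list of discarded protein names.
    """
    if not (0 < min_presence <= 1):
        raise ValidationError("min_presence must be in (0, 1]")
    presence = 1.0 - npx.missing.mean(axis=1)
    keep = presence >= min_presence
    discarded = list(npx.values.index[~keep])
    if discarded:
        log.info("discarded %d/%d proteins below %.0f%% presence",
                 len(discarded), len(keep), 100 * min_presence)
    filtered = NPXMatrix(values=npx.values.loc[keep].copy(),
                         plate=npx.plate.copy(),
                         missing=npx.missing.loc[keep].copy())
    return filtered, discarded


@dataclass
class NormalizationReport:
    """Shifts applied per protein × plate (NPX units), with the per-plate
    medians before/after and the overall (pre-normalization) medians."""

    shifts: pd.DataFrame  # proteins × plates
    pre_plate_medians: pd.DataFrame
    post_plate_medians: pd.DataFrame
    overall_medians: pd.Series


def intensity_normalize(npx: NPXMatrix) -> tuple[NPXMatrix, NormalizationReport]:
    """Intensity normalization: per protein and plate, shift values by
    (overall median − plate median) so every per-plate median equals the
    overall pre-normalization median.

    The missing mask is untouched.  A plate with no non-missing value for a
    protein has an undefined shift; those entries stay unshifted, with a
    warning.
    """
    values = npx.values.copy()
    plates = sorted(npx.plate.unique())
    overall = values.median(axis=1, skipna=True)
    shifts = pd.DataFrame(0.0, index=values.index, columns=plates)
    pre = pd.DataFrame(np.nan, index=values.index, columns=plates)
    post = pd.DataFrame(np.nan, index=values.index, columns=plates)
    for plate in plates:
        cols = npx.plate.index[npx.plate == plate]
        plate_median = values[cols].median(axis=1, skipna=True)
        pre[plate] = plate_median
        undefined = plate_median.isna()
        if undefined.any():
            log.warning("plate %s: %d proteins all-missing; left unshifted",
                        plate, int(undefined.sum()))
        shift = (overall - plate_median).fillna(0.0)
        shifts[plate] = shift
        values[cols] = values[cols].add(shift, axis=0)
        post[plate] = values[cols].median(axis=1, skipna=True)
    normalized = NPXMatrix(values=values, plate=npx.plate.copy(),
                           missing=npx.missing.copy())
    report = NormalizationReport(shifts=shifts, pre_plate_medians=pre,
                                 post_plate_medians=post, overall_medians=overall)
    return normalized, report


@dataclass
class ClusteringResult:
    sample_linkage: np.ndarray | None
    protein_linkage: np.ndarray | None
    sample_order: list[str]
    protein_order: list[str]


def hierarchical_cluster(npx: NPXMatrix, method: str = "ward",
                         metric: str = "euclidean") -> ClusteringResult:
    """Agglomerative clustering of samples and proteins.

    Missing entries are filled with the per-protein median for the distance
    computation only (the matrix itself is not modified).  Degenerate inputs
    (fewer than two samples or proteins) yield a single-leaf ordering with no
    merge tree on that axis.
    """
    filled = npx.values.apply(lambda row: row.fillna(row.median()), axis=1)
    filled = filled.fillna(0.0)  # proteins missing everywhere

    def _cluster(matrix: np.ndarray, names: list[str]):
        if len(names) < 2:
            return None, list(names)
        lk = linkage(matrix, method=method, metric=metric)
        order = [names[i] for i in leaves_list(lk)]
        return lk, order

    sample_lk, sample_order = _cluster(filled.T.to_numpy(), list(filled.columns))
    protein_lk, protein_order = _cluster(filled.to_numpy(), list(filled.index))
    return ClusteringResult(sample_linkage=sample_lk, protein_linkage=protein_lk,
                            sample_order=sample_order, protein_order=protein_order)


def correlate_densities(npx: NPXMatrix, density_table: pd.DataFrame,
                        phenotype: str, region: str = "tumor_area",
                        compartment: str = "all", min_pairs: int = 4) -> pd.DataFrame:
    """Spearman correlation of each protein's NPX level with an immune
    density across matched specimens.

    NPX sample identifiers must match the density table's specimen_id.
    Observations are pairwise complete; proteins (or inputs) with fewer than
    ``min_pairs`` complete pairs are refused.
    """
    m = ((density_table["region"] == region)
         & (density_table["compartment"] == compartment)
         & (density_table["phenotype"] == phenotype))
    dens = density_table[m].set_index("specimen_id")["density"]
    common = [s for s in npx.samples if s in dens.index]
    if len(common) < min_pairs:
        raise StatsError(
            f"only {len(common)} matched specimens; need at least {min_pairs}")
    y = dens.loc[common].to_numpy(dtype=float)
    rows = []
    for protein in npx.proteins:
        x = npx.values.loc[protein, common].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        if n < min_pairs:
            rho, p = float("nan"), float("nan")
        else:
            rho, p = spearmanr(x[ok], y[ok])
        rows.append((protein, rho, p, n))
    return pd.DataFrame(rows, columns=["protein", "rho", "p_value", "n"])
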