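"""Inter-cell distance statistics: average minimum distance and radius fractions.

The average minimum distance (AMD) from a reference phenotype to a target
phenotype is the mean, over reference cells, of the Euclidean distance from
each reference centroid to its nearest target centroid.  AMD is asymmetric:
amd(A, B) generally differs from amd(B, A).  When reference and target sets
coincide, each cell's nearest neighbour excludes itself.  The radius
fraction is the share of a counted population having at least one probe
cell within a fixed radius (inclusive boundary), 10 µm by default.

Distances are centroid-to-centroid and no edge correction is applied; by
default metrics are computed over cells inside the tumor area.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io_model import PHENOTYPES, ValidationError, as_cell_frame


@dataclass
class AMDResult:
    reference_phenotype: str
    target_phenotype: str
    amd: float  # µm; NaN when either set empty
    n_reference: int
    per_cell_min_distances: np.ndarray | None = None


@dataclass
class RadiusFractionResult:
    counted_phenotype: str
    probe_phenotype: str
    radius: float  # µm
    fraction: float  # NaN when counted set empty; 0 when probe set empty
    n_counted: int


def min_distance_to_nearest(reference_xy: np.ndarray, target_xy: np.ndarray,
                            exclude_self: bool = False) -> np.ndarray | None:
    """Distance from each reference point to its nearest target point (µm).

    With ``exclude_self`` the reference and target arrays are taken to be the
    same point set and each point's own entry is skipped.  Returns None when
    the target set is empty (a missing result, not infinity).
    """
    reference_xy = np.asarray(reference_xy, dtype=float)
    target_xy = np.asarray(target_xy, dtype=float)
    if len(reference_xy) == 0:
        return np.empty(0)
    if len(target_xy) == 0 or (exclude_self and len(target_xy) < 2):
        return None
    tree = cKDTree(target_xy)
    if exclude_self:
        d, _ = tree.query(reference_xy, k=2)
        return d[:, 1]
    d, _ = tree.query(reference_xy, k=1)
    return d


def _phenotype_xy(frame: pd.DataFrame, phenotype: str) -> np.ndarray:
    sub = frame[frame["phenotype"] == phenotype]
    return sub[["x", "y"]].to_numpy(dtype=float)


def amd(cells, reference_phenotype: str, target_phenotype: str,
        keep_distances: bool = False) -> AMDResult:
    """Average minimum distance from a reference to a target phenotype."""
    frame = as_cell_frame(cells)
    ref = _phenotype_xy(frame, reference_phenotype)
    tgt = _phenotype_xy(frame, target_phenotype)
    dists = min_distance_to_nearest(ref, tgt,
                                    exclude_self=reference_phenotype == target_phenotype)
    if dists is None or len(ref) == 0:
        return AMDResult(reference_phenotype, target_phenotype, float("nan"), len(ref))
    return AMDResult(reference_phenotype, target_phenotype, float(np.mean(dists)),
                     len(ref), dists if keep_distances else None)


def amd_matrix(cells, phenotypes=None) -> pd.DataFrame:
    """Reference × target matrix of AMD values (µm); NaN where a phenotype is
    absent.  The diagonal uses the self-exclusion rule."""
    frame = as_cell_frame(cells)
    phenotypes = list(phenotypes) if phenotypes is not None else list(PHENOTYPES)
    mat = pd.DataFrame(np.nan, index=phenotypes, columns=phenotypes, dtype=float)
    xy = {p: _phenotype_xy(frame, p) for p in phenotypes}
    trees = {p: cKDTree(a) for p, a in xy.items() if len(a)}
    for ref in phenotypes:
        if len(xy[ref]) == 0:
            continue
        for tgt in phenotypes:
            if tgt not in trees:
                continue
            if ref == tgt:
                if len(xy[tgt]) < 2:
                    continue
                d, _ = trees[tgt].query(xy[ref], k=2)
                mat.loc[ref, tgt] = float(np.mean(d[:, 1]))
            else:
                d, _ = trees[tgt].query(xy[ref], k=1)
                mat.loc[ref, tgt] = float(np.mean(d))
    return mat


def fraction_within_radius(counted_xy: np.ndarray, probe_xy: np.ndarray,
                           radius: float, exclude_self: bool = False) -> float:
    """Fraction of counted points with ≥1 probe point at distance ≤ radius."""
    if radius <= 0:
        raise ValidationError("radius must be > 0")
    counted_xy = np.asarray(counted_xy, dtype=float)
    probe_xy = np.asarray(probe_xy, dtype=float)
    if len(counted_xy) == 0:
        return float("nan")
    if len(probe_xy) == 0 or (exclude_self and len(probe_xy) < 2):
        return 0.0
    tree = cKDTree(probe_xy)
    counts = tree.query_ball_point(counted_xy, r=radius, return_length=True)
    counts = np.asarray(counts)
    if exclude_self:
        counts = counts - 1  # each point finds itself at distance 0
    return float(np.mean(counts > 0))


def radius_fraction(cells, counted_phenotype: str, probe_phenotype: str,
                    radius: float = 10.0) -> RadiusFractionResult:
    """Fraction of counted-phenotype cells with a probe-phenotype cell within
    ``radius`` µm (boundary inclusive)."""
    frame = as_cell_frame(cells)
    counted = _phenotype_xy(frame, counted_phenotype)
    probe = _phenotype_xy(frame, probe_phenotype)
    frac = fraction_within_radius(counted, probe, radius,
                                  exclude_self=counted_phenotype == probe_phenotype)
    return RadiusFractionResult(counted_phenotype, probe_phenotype, radius,
                                frac, len(counted))
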