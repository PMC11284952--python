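"""Immune cellular neighborhoods.

For every immune cell (CD163+ macrophage, B cell, CD8+ T cell, CD4+ T
helper, Treg) the neighbours within 50 µm are counted per immune phenotype;
k-means on those count vectors (k = 4 per specimen) partitions the immune
cells into cellular neighborhoods.  Tumor and "other" cells never enter the
count vectors.  A phenotype making up ≥ 40% of a cluster dominates it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .io_model import IMMUNE_PHENOTYPES, NeighborhoodError, ValidationError, as_cell_frame

log = logging.getLogger("timetopo.neighborhoods")


def count_neighbors(cells, radius: float = 50.0) -> pd.DataFrame:
    """Per-immune-cell neighbour counts within ``radius`` µm, by phenotype.

    Rows are the immune cells (indexed by cell_id, in input order), columns
    the five immune phenotypes; the index cell itself is excluded from its
    own counts.
    """
    if radius <= 0:
        raise ValidationError("radius must be > 0")
    frame = as_cell_frame(cells)
    immune = frame[frame["phenotype"].isin(IMMUNE_PHENOTYPES)].reset_index(drop=True)
    xy = immune[["x", "y"]].to_numpy(dtype=float)
    counts = pd.DataFrame(0, index=immune["cell_id"], columns=list(IMMUNE_PHENOTYPES))
    if len(immune) == 0:
        return counts
    for phen in IMMUNE_PHENOTYPES:
        mask = (immune["phenotype"] == phen).to_numpy()
        if not mask.any():
            continue
        tree = cKDTree(xy[mask])
        c = np.asarray(tree.query_ball_point(xy, r=radius, return_length=True))
        c = c - mask.astype(int)  # self-exclusion: a cell always finds itself
        counts[phen] = c
    counts["phenotype"] = immune["phenotype"].to_numpy()
    return counts


def cluster_neighborhoods(count_matrix: pd.DataFrame, k: int = 4, seed: int = 0,
                          scale: bool = False, n_init: int = 10) -> np.ndarray:
    """K-means labels (1..k, canonical order = descending cluster size).

    Features are the raw neighbour counts by default; ``scale`` standardizes
    them first.  k-means++ initialization with ``n_init`` restarts and a
    fixed seed makes labels deterministic.  When there are fewer distinct
    count vectors than k, the distinct vectors define the effective clusters
    and the remaining labels stay empty.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    features = count_matrix[list(IMMUNE_PHENOTYPES)].to_numpy(dtype=float)
    n = len(features)
    if n < k:
        raise NeighborhoodError(
            f"only {n} immune cells but k={k}; specimen skipped")
    if scale:
        features = StandardScaler().fit_transform(features)
    n_unique = len(np.unique(features, axis=0))
    eff_k = min(k, n_unique)
    if eff_k < k:
        log.warning("only %d distinct count vectors; using %d effective clusters",
                    n_unique, eff_k)
    km = KMeans(n_clusters=eff_k, init="k-means++", n_init=n_init,
                random_state=int(seed) & 0x7FFFFFFF)
    raw = km.fit_predict(features)
    # canonicalize: label 1 = largest cluster, ties broken by raw label
    sizes = np.bincount(raw, minlength=eff_k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(eff_k, dtype=int)
    remap[order] = np.arange(1, eff_k + 1)
    return remap[raw]


def neighborhood_composition(labels: np.ndarray, phenotypes, k: int = 4,
                             dominance_fraction: float = 0.40) -> pd.DataFrame:
    """Per-cluster totals, per-phenotype counts/fractions and dominance flags.

    Clusters 1..k all appear; empty clusters have total 0 and NaN fractions.
    A phenotype with fraction ≥ ``dominance_fraction`` is flagged dominant.
    """
    phenotypes = np.asarray(phenotypes)
    labels = np.asarray(labels)
    rows = []
    for cluster in range(1, k + 1):
        mask = labels == cluster
        total = int(mask.sum())
        row: dict = {"cluster": cluster, "total": total}
        for phen in IMMUNE_PHENOTYPES:
            cnt = int((phenotypes[mask] == phen).sum())
            frac = cnt / total if total else float("nan")
            row[f"count_{phen}"] = cnt
            row[f"fraction_{phen}"] = frac
            row[f"dominant_{phen}"] = bool(total and frac >= dominance_fraction)
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


def neighborhood_map(cells_or_counts, labels: np.ndarray,
                     path=None) -> pd.DataFrame:
    """Per-cell (x, y, cluster) table, optionally rendered to an image file.

    ``cells_or_counts`` must carry the immune cells in the same order the
    count matrix was built (the output of :func:`count_neighbors` aligns).
    """
    frame = as_cell_frame(cells_or_counts)
    immune = frame[frame["phenotype"].isin(IMMUNE_PHENOTYPES)].reset_index(drop=True)
    if len(immune) != len(labels):
        raise ValidationError("labels length does not match immune-cell count")
    table = immune[["cell_id", "x", "y"]].copy()
    table["cluster"] = np.asarray(labels)
    if path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        for cluster in sorted(table["cluster"].unique()):
            sub = table[table["cluster"] == cluster]
            ax.scatter(sub["x"], sub["y"], s=4, label=f"neighborhood {cluster}")
        ax.set_aspect("equal")
        ax.invert_yaxis()  # slide frame: y increases downward
        ax.set_xlabel("x (µm)")
        ax.set_ylabel("y (µm)")
        ax.legend(markerscale=3, fontsize=8)
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return table
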