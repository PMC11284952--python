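"""Cellular neighborhoods: counts, clustering, composition, determinism."""
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from timetopo import (
    Cell,
    cluster_neighborhoods,
    count_neighbors,
    neighborhood_composition,
    neighborhood_map,
)
from timetopo.io_model import IMMUNE_PHENOTYPES, NeighborhoodError, cells_to_frame


def _cells(spec):
    return cells_to_frame(
        [Cell(f"c{i}", float(x), float(y), p) for i, (x, y, p) in enumerate(spec)])


def _disc(rng, center, n, radius=20.0):
    theta = rng.uniform(0, 2 * np.pi, n)
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    return np.column_stack([center[0] + r * np.cos(theta),
                            center[1] + r * np.sin(theta)])


def _two_blobs(seed=0, n=60, sep=2000.0):
    """Two well-separated compact blobs (diameter < 50 µm, so every cell sees
    its whole blob): all-B-cell vs all-CD8."""
    rng = np.random.default_rng(seed)
    left = _disc(rng, (0.0, 0.0), n)
    right = _disc(rng, (sep, 0.0), n)
    spec = [(x, y, "b_cell") for x, y in left] + [(x, y, "t_cd8") for x, y in right]
    truth = np.array([0] * n + [1] * n)
    return _cells(spec), truth


class TestCounts:
    def test_single_immune_cell_zero_vector(self):
        counts = count_neighbors(_cells([(0, 0, "t_cd8"), (5, 5, "tumor")]), 50)
        assert len(counts) == 1  # tumor cell is not a center
        assert counts[list(IMMUNE_PHENOTYPES)].to_numpy().sum() == 0

    def test_line_of_three(self):
        cells = _cells([(0, 0, "t_cd8"), (40, 0, "t_cd8"), (80, 0, "t_cd8")])
        counts = count_neighbors(cells, 50)
        assert list(counts["t_cd8"]) == [1, 2, 1]

    def test_tumor_and_other_excluded(self):
        cells = _cells([(0, 0, "t_cd8"), (10, 0, "tumor"), (20, 0, "other"),
                        (30, 0, "treg")])
        counts = count_neighbors(cells, 50)
        assert len(counts) == 2  # only the immune cells are centers
        assert counts[list(IMMUNE_PHENOTYPES)].sum().sum() == 2  # cd8↔treg only

    def test_matches_brute_force(self, rng):
        n = 2000
        xy = rng.uniform(0, 1500, size=(n, 2))
        phen = rng.choice(list(IMMUNE_PHENOTYPES) + ["tumor"], n)
        cells = cells_to_frame([Cell(f"c{i}", x, y, p)
                                for i, ((x, y), p) in enumerate(zip(xy, phen))])
        counts = count_neighbors(cells, 50.0)
        imm = cells[cells["phenotype"].isin(IMMUNE_PHENOTYPES)].reset_index(drop=True)
        ixy = imm[["x", "y"]].to_numpy()
        d = np.sqrt(((ixy[:, None, :] - ixy[None, :, :]) ** 2).sum(-1))
        within = (d <= 50.0)
        np.fill_diagonal(within, False)
        for phen_name in IMMUNE_PHENOTYPES:
            mask = (imm["phenotype"] == phen_name).to_numpy()
            brute = within[:, mask].sum(axis=1)
            np.testing.assert_array_equal(counts[phen_name].to_numpy(), brute)


class TestClustering:
    def test_planted_blobs_recovered(self):
        cells, truth = _two_blobs()
        counts = count_neighbors(cells, 50)
        labels = cluster_neighborhoods(counts, k=2, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_fewer_cells_than_k_rejected(self):
        counts = count_neighbors(_cells([(0, 0, "t_cd8"), (10, 0, "treg")]), 50)
        with pytest.raises(NeighborhoodError):
            cluster_neighborhoods(counts, k=4, seed=0)

    def test_identical_vectors_one_effective_cluster(self):
        # isolated cells all have zero count vectors
        cells = _cells([(i * 1000.0, 0, "t_cd8") for i in range(8)])
        counts = count_neighbors(cells, 50)
        labels = cluster_neighborhoods(counts, k=4, seed=0)
        assert set(labels) == {1}
        comp = neighborhood_composition(labels, counts["phenotype"].to_numpy(), k=4)
        assert comp.loc[1, "total"] == 8
        assert (comp.loc[2:, "total"] == 0).all()
        assert comp.loc[2:, "fraction_t_cd8"].isna().all()

    def test_determinism(self):
        cells, _ = _two_blobs(seed=4)
        counts = count_neighbors(cells, 50)
        a = cluster_neighborhoods(counts, k=4, seed=9)
        b = cluster_neighborhoods(counts, k=4, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_permutation_invariance_up_to_renaming(self, rng):
        cells, _ = _two_blobs(seed=2, n=40)
        counts = count_neighbors(cells, 50)
        labels = cluster_neighborhoods(counts, k=2, seed=1)
        perm = rng.permutation(len(counts))
        labels_perm = cluster_neighborhoods(counts.iloc[perm], k=2, seed=1)
        assert adjusted_rand_score(labels[perm], labels_perm) == 1.0

    def test_canonical_order_by_size(self):
        cells, truth = _two_blobs(n=50)
        # drop some cells from the right blob so sizes differ
        counts = count_neighbors(cells.iloc[:80], 50)
        labels = cluster_neighborhoods(counts, k=2, seed=0)
        sizes = np.bincount(labels)[1:]
        assert sizes[0] >= sizes[1]


class TestCompositionAndMap:
    def test_dominance_at_exact_threshold(self):
        phen = np.array(["t_cd4_helper"] * 4 + ["t_cd8"] * 6)
        labels = np.ones(10, dtype=int)
        comp = neighborhood_composition(labels, phen, k=2, dominance_fraction=0.40)
        assert comp.loc[1, "fraction_t_cd4_helper"] == pytest.approx(0.40)
        assert comp.loc[1, "dominant_t_cd4_helper"]  # ≥ 40% dominates
        assert not comp.loc[1, "dominant_b_cell"]

    def test_counts_conserved(self):
        cells, _ = _two_blobs(seed=6)
        counts = count_neighbors(cells, 50)
        labels = cluster_neighborhoods(counts, k=4, seed=0)
        comp = neighborhood_composition(labels, counts["phenotype"].to_numpy(), k=4)
        assert comp["total"].sum() == len(counts)
        for phen in IMMUNE_PHENOTYPES:
            assert comp[f"count_{phen}"].sum() == (counts["phenotype"] == phen).sum()

    def test_map_round_trip_and_plot(self, tmp_path):
        cells, _ = _two_blobs(seed=8, n=30)
        counts = count_neighbors(cells, 50)
        labels = cluster_neighborhoods(counts, k=2, seed=0)
        path = tmp_path / "map.png"
        table = neighborhood_map(cells, labels, path=path)
        np.testing.assert_array_equal(table["cluster"].to_numpy(), labels)
        assert path.exists() and path.stat().st_size > 0

    def test_planted_regions_spatially_contiguous(self):
        cells, _ = _two_blobs(seed=3)
        counts = count_neighbors(cells, 50)
        labels = cluster_neighborhoods(counts, k=2, seed=0)
        table = neighborhood_map(cells, labels)
        xy = table[["x", "y"]].to_numpy()
        from timetopo import min_distance_to_nearest
        same, cross = [], []
        for lab in (1, 2):
            a, b = xy[table["cluster"] == lab], xy[table["cluster"] != lab]
            same.append(np.mean(min_distance_to_nearest(a, a, exclude_self=True)))
            cross.append(np.mean(min_distance_to_nearest(a, b)))
        assert max(same) < min(cross)
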