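"""Synthetic generator: determinism, containment, sampling distributions."""
import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Point, Polygon

from timetopo import generate_archetype, generate_npx
from timetopo.io_model import ValidationError
from timetopo.spatial import min_distance_to_nearest
from timetopo.synthetic import (
    AggregateParams,
    ArchetypeSpec,
    FieldGeometry,
    default_archetype,
    generate_b_cell_aggregates,
    generate_tumor_fields,
    populate_cells,
)
from timetopo.zoning import build_zones


def _spec(**geom_kw):
    spec = default_archetype("fully_infiltrated")
    spec.field_geometry = FieldGeometry(**geom_kw)
    return spec


class TestTumorFields:
    def test_zero_roughness_circle_area(self):
        spec = _spec(n_blobs=1, blob_radius=400, ring_radius=0, jitter=0, roughness=0)
        polys = generate_tumor_fields(spec, seed=0)
        assert len(polys) == 1
        assert polys[0].area == pytest.approx(np.pi * 400**2, rel=0.01)

    def test_seed_determinism(self):
        spec = _spec(n_blobs=3)
        a = generate_tumor_fields(spec, seed=5)
        b = generate_tumor_fields(spec, seed=5)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            assert pa.equals_exact(pb, 0)

    def test_validity_sweep(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            spec = _spec(n_blobs=int(rng.integers(1, 7)),
                         blob_radius=float(rng.uniform(150, 500)),
                         ring_radius=float(rng.uniform(0, 1200)),
                         jitter=float(rng.uniform(0, 150)),
                         roughness=float(rng.uniform(0, 0.25)))
            for poly in generate_tumor_fields(spec, seed=seed):
                assert poly.is_valid and poly.area > 0

    def test_small_radius_rejected(self):
        with pytest.raises(ValidationError):
            generate_tumor_fields(_spec(blob_radius=50), seed=0)


@pytest.fixture(scope="module")
def square_zones():
    # 1 mm² square field with standard buffers
    field = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
    return build_zones([field])


class TestPopulate:
    def test_zero_density_no_cells(self, square_zones):
        dens = {key: {"t_cd8": 0.0} for key in square_zones.zones}
        cells = populate_cells(square_zones, dens, seed=0)
        assert len(cells) == 0

    def test_negative_density_rejected(self, square_zones):
        with pytest.raises(ValidationError):
            populate_cells(square_zones, {("center", "field"): {"t_cd8": -1}}, seed=0)

    def test_poisson_mean(self, square_zones):
        # one zone at density 100: mean count over 500 seeds within ±3σ of
        # Poisson(100 × area)
        key = ("center", "field")
        area = square_zones.areas[key]
        expected = 100.0 * area
        counts = [len(populate_cells(square_zones, {key: {"t_cd8": 100.0}}, seed=s))
                  for s in range(500)]
        tol = 3 * np.sqrt(expected / 500)
        assert np.mean(counts) == pytest.approx(expected, abs=tol)

    def test_containment(self, square_zones):
        dens = {key: {"t_cd8": 150.0} for key in square_zones.zones}
        cells = populate_cells(square_zones, dens, seed=7)
        pts = shapely.points(cells["x"].to_numpy(), cells["y"].to_numpy())
        # every cell lies inside the union of its zones (tumor area)
        assert shapely.covers(square_zones.tumor_area, pts).all()


class TestAggregates:
    ZONE = Point(0, 0).buffer(2000)

    def test_zero_parents_empty(self):
        params = AggregateParams(parent_intensity=0.0, mean_offspring=10, dispersion=20)
        assert len(generate_b_cell_aggregates(self.ZONE, params, seed=0)) == 0

    def test_bad_dispersion_rejected(self):
        with pytest.raises(ValidationError):
            generate_b_cell_aggregates(
                self.ZONE, AggregateParams(dispersion=0), seed=0)

    def test_halfnormal_mean_offspring_distance(self):
        # 2-D isotropic Gaussian offsets: E|r| = σ√(π/2)
        sigma = 20.0
        params = AggregateParams(mean_offspring=200, dispersion=sigma)
        dists = []
        for seed in range(30):
            cells = generate_b_cell_aggregates(self.ZONE, params, seed=seed,
                                               parents=np.array([[0.0, 0.0]]))
            r = np.hypot(cells["x"], cells["y"])
            dists.append(r.mean())
        expected = sigma * np.sqrt(np.pi / 2)
        assert np.mean(dists) == pytest.approx(expected, rel=0.05)

    def test_clustering_shrinks_nearest_neighbor_distance(self):
        # aggregated B cells are closer together than a Poisson pattern of
        # equal intensity, in the large majority of seeds
        wins = 0
        zone = self.ZONE
        params = AggregateParams(parent_intensity=2.0, mean_offspring=30, dispersion=30)
        from timetopo.zoning import build_zones
        for seed in range(30):
            agg = generate_b_cell_aggregates(zone, params, seed=seed)
            if len(agg) < 10:
                continue
            rng = np.random.default_rng(seed)
            n = len(agg)
            theta = rng.uniform(0, 2 * np.pi, n)
            rad = 2000 * np.sqrt(rng.uniform(0, 1, n))
            poisson_xy = np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])
            agg_xy = agg[["x", "y"]].to_numpy()
            nnd_agg = np.median(min_distance_to_nearest(agg_xy, agg_xy, exclude_self=True))
            nnd_poi = np.median(min_distance_to_nearest(poisson_xy, poisson_xy,
                                                        exclude_self=True))
            wins += nnd_agg < nnd_poi
        assert wins >= 27  # ≥90% of informative seeds


class TestArchetypes:
    def test_determinism(self):
        a = generate_archetype("stroma_restricted", seed=3)
        b = generate_archetype("stroma_restricted", seed=3)
        pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_intended_label_recorded(self, infiltrated_specimen):
        assert infiltrated_specimen.covariates["intended_immunotype"] == "fully_infiltrated"
        assert infiltrated_specimen.kind == "resection"

    def test_stroma_restricted_construction(self):
        spec = default_archetype("stroma_restricted")
        for key in spec.zone_densities:
            assert spec.zone_densities[key]["t_cd8"] <= 41.4 or key[1] == "stroma"

    def test_unknown_immunotype_rejected(self):
        with pytest.raises(ValidationError):
            default_archetype("lukewarm")


class TestNPX:
    def test_no_shift_no_noise_plates_aligned(self):
        npx = generate_npx(n_proteins=5, n_samples=8, noise_sd=0.0,
                           missing_rate=0.0, seed=0)
        overall = npx.values.median(axis=1)
        for plate in npx.plate.unique():
            cols = npx.plate.index[npx.plate == plate]
            # sample effects still differ, so medians agree only loosely;
            # with zero plate shift the deviation is pure sample effect
            diff = (npx.values[cols].median(axis=1) - overall).abs()
            assert (diff < 1.0).all()

    def test_missing_rate_binomial(self):
        # 85%-presence filter retention under missing_rate 0.2, 92 proteins:
        # per protein P(retained) = P(Binom(n, 0.2) ≤ floor(0.15 n))
        from scipy.stats import binom
        n_samples, rate = 20, 0.2
        p_keep = binom.cdf(int(np.floor(0.15 * n_samples)), n_samples, rate)
        expected = 92 * p_keep
        sd = np.sqrt(92 * p_keep * (1 - p_keep))
        kept = []
        from timetopo.secretome import filter_proteins
        for seed in range(200):
            npx = generate_npx(n_proteins=92, n_samples=n_samples,
                               missing_rate=rate, seed=seed)
            filtered, _ = filter_proteins(npx, 0.85)
            kept.append(len(filtered.proteins))
        tol = 3 * sd / np.sqrt(200)
        assert np.mean(kept) == pytest.approx(expected, abs=tol)

    def test_invalid_missing_rate(self):
        with pytest.raises(ValidationError):
            generate_npx(missing_rate=1.5, seed=0)
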