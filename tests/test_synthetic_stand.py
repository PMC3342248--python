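"""Statistical and geometric properties of the synthetic stand generator."""

import math

import numpy as np
import pytest
from shapely.geometry import LineString

import standforge as sf
from standforge.stand_model import PlotGeometry, write_stand
from standforge.synthetic_stand import (
    NegativeExponentialDBH,
    _segment_crossings,
    apply_segregation,
    sample_dbh,
    sample_hardcore,
    sample_thomas,
)

WIN = PlotGeometry(200.0, 200.0, 20.0)


class TestThomas:
    def test_no_offspring_gives_empty_pattern(self, rng):
        pts = sample_thomas(0.01, 0.0, 3.0, WIN, rng)
        assert pts.shape == (0, 2)

    def test_zero_parent_intensity_gives_empty_pattern(self, rng):
        assert sample_thomas(0.0, 5.0, 3.0, WIN, rng).shape == (0, 2)

    def test_mean_count_matches_intensity(self):
        # E[n] = κ·μ·|A|; Monte-Carlo over 200 seeded realizations
        kappa, mu = 0.002, 8.0
        counts = [
            len(sample_thomas(kappa, mu, 4.0, WIN, np.random.default_rng(s)))
            for s in range(200)
        ]
        expected = kappa * mu * WIN.area_m2
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_determinism_given_seed(self):
        a = sample_thomas(0.005, 6.0, 3.0, WIN, np.random.default_rng(3))
        b = sample_thomas(0.005, 6.0, 3.0, WIN, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)


class TestHardCore:
    def test_zero_core_reduces_to_poisson_counts(self):
        lam = 0.003
        counts = [
            len(sample_hardcore(lam, 0.0, WIN, np.random.default_rng(s)))
            for s in range(200)
        ]
        expected = lam * WIN.area_m2
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_minimum_spacing_holds_for_any_seed(self, seed):
        h = 4.0
        pts = sample_hardcore(0.004, h, WIN, np.random.default_rng(seed))
        assert len(pts) > 2
        d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= h

    def test_conflicting_proposals_leave_exactly_one_survivor(self):
        # a 1×1 window with a core radius beyond its diagonal: any
        # multi-point proposal set collapses to a single accepted point
        tiny = PlotGeometry(1.0, 1.0, 1.0)
        for seed in range(30):
            rng = np.random.default_rng(seed)
            pts = sample_hardcore(5.0, 2.0, tiny, rng)
            assert len(pts) <= 1


class TestSegregation:
    def test_zero_probability_is_identity(self, rng):
        small = rng.uniform(0, 200, (50, 2))
        large = rng.uniform(0, 200, (5, 2))
        out = apply_segregation(small, large, 10.0, 0.0, rng)
        np.testing.assert_array_equal(out, small)

    def test_certain_thinning_clears_the_neighborhood(self, rng):
        small = rng.uniform(0, 200, (400, 2))
        large = rng.uniform(0, 200, (8, 2))
        out = apply_segregation(small, large, 10.0, 1.0, rng)
        d = np.hypot(out[:, None, 0] - large[None, :, 0],
                     out[:, None, 1] - large[None, :, 1])
        assert d.min() >= 10.0


class TestDbhModels:
    def test_empty_draw(self, rng):
        assert len(sample_dbh(0, NegativeExponentialDBH(0.1), rng)) == 0

    def test_all_values_above_census_threshold(self, rng):
        for model in (NegativeExponentialDBH(0.1),
                      sf.synthetic_stand.RotatedSigmoidDBH()):
            vals = sample_dbh(5000, model, rng)
            assert vals.min() >= 1.0

    def test_mle_recovers_the_exponential_rate(self, rng):
        # shifted-exponential MLE: b̂ = 1/mean(x − 1)
        b = 0.08
        vals = sample_dbh(10_000, NegativeExponentialDBH(b), rng)
        b_hat = 1.0 / np.mean(vals - 1.0)
        assert abs(b_hat - b) / b < 0.05

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            NegativeExponentialDBH(-0.1)


class TestGenerateStand:
    def test_same_seed_gives_byte_identical_layers(self, tmp_path):
        cfg = sf.StandConfig(width_m=120.0, height_m=120.0, rng_seed=77,
                             n_transects=10)
        for sub in ("a", "b"):
            write_stand(sf.generate_stand(cfg), tmp_path / sub)
        for name in ("geometry.json", "stems.csv", "snags.csv",
                     "demography.csv", "transects.csv", "shrub_patches.geojson"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes(), name

    def test_snag_frequency_is_binomial_around_target(self, small_stand):
        f = sf.StandConfig().snag_fraction
        n_ref = sum(1 for s in small_stand.live_stems if s.dbh_cm >= 10.0)
        ratio = len(small_stand.snags) / n_ref
        sigma = math.sqrt(f * (1 - f) / n_ref)
        assert abs(ratio - f) < 3 * sigma

    def test_shrub_cover_hits_target(self, small_stand):
        target = sf.StandConfig().shrub_cover
        assert abs(small_stand.shrub_cover_fraction() - target) <= 0.02

    def test_snag_invariants(self, small_stand):
        for s in small_stand.snags:
            assert s.dbh_cm >= 10.0
            assert s.height_m >= 1.8
            assert 1 <= s.decay_class <= 5
            assert s.top_diameter_cm <= s.dbh_cm

    def test_small_trees_cluster_and_large_trees_space_out(self, small_stand):
        from standforge import ppa
        geom = small_stand.geometry
        parts = sf.classify_diameter(small_stand.live_stems)
        small = ppa.PointPattern.from_stems(parts["small"], geom)
        grid = np.arange(0.0, 15.01, 0.25)
        env = ppa.envelope(small, "csr", 39, np.random.default_rng(1), r_grid=grid)
        lo, hi = ppa.envelope_bounds(env)
        i10 = int(np.argmin(np.abs(grid - 10.0)))
        assert env.observed.l_hat[i10] > hi[i10]          # aggregation
        large = np.array([[s.x_m, s.y_m] for s in parts["large"]])
        d = np.hypot(*(large[:, None, :] - large[None, :, :]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= sf.StandConfig().hard_core_m    # hard core


class TestTransectGeometry:
    def test_crossing_detector_agrees_with_shapely(self, rng):
        t0 = np.array([50.0, 50.0])
        t1 = np.array([70.0, 50.0])
        a = rng.uniform(30, 90, (300, 2))
        ang = rng.uniform(0, math.pi, 300)
        ln = rng.uniform(1, 15, 300)
        b = a + np.column_stack([np.cos(ang), np.sin(ang)]) * ln[:, None]
        ours = _segment_crossings(t0, t1, a, b)
        line = LineString([t0, t1])
        theirs = np.array([
            line.crosses(LineString([p, q])) for p, q in zip(a, b)
        ])
        np.testing.assert_array_equal(ours, theirs)

    def test_intercept_diameters_are_piece_diameters(self, small_stand):
        # coarse intercepts inherit the crossing piece's (constant) diameter,
        # so every recorded intercept is ≥ the 10 cm recording threshold
        diams = [ci.diameter_cm for tr in small_stand.transects
                 for ci in tr.coarse_intercepts]
        assert diams and min(diams) >= 10.0

    def test_infeasible_cover_target_rejected(self):
        cfg = sf.StandConfig(width_m=120.0, height_m=120.0, shrub_cover=1.0)
        with pytest.raises(ValueError):
            sf.generate_stand(cfg)
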