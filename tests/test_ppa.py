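"""Point-pattern estimators, null models, envelopes, GoF, correlogram."""

import math

import numpy as np
import pytest

import standforge as sf
from standforge import ppa
from standforge.stand_model import PlotGeometry

WIN = PlotGeometry(100.0, 100.0, 20.0)


def toroidal_k(points: np.ndarray, window: PlotGeometry, r_grid: np.ndarray
               ) -> np.ndarray:
    """Brute-force K on the torus (no edge correction needed)."""
    w, h = window.width_m, window.height_m
    n = len(points)
    dx = np.abs(points[:, None, 0] - points[None, :, 0])
    dy = np.abs(points[:, None, 1] - points[None, :, 1])
    dx = np.minimum(dx, w - dx)
    dy = np.minimum(dy, h - dy)
    d = np.hypot(dx, dy)
    iu = np.triu_indices(n, k=1)
    pair_d = d[iu]
    return np.array([
        window.area_m2 / (n * (n - 1)) * 2.0 * np.sum(pair_d <= r)
        for r in r_grid
    ])


class TestKHat:
    def test_no_neighbors_below_pair_distance(self):
        pat = ppa.PointPattern(np.array([[40.0, 50.0], [60.0, 50.0]]), WIN)
        k = ppa.k_hat_isotropic(pat, np.array([0.0, 5.0, 19.0]))
        assert np.all(k == 0.0)
        k2 = ppa.k_hat_isotropic(pat, np.array([0.0, 21.0]))
        assert k2[-1] > 0.0

    def test_interior_pair_needs_no_correction(self):
        # both circles fully inside: weight 1 → K = A/(n(n−1))·2
        pat = ppa.PointPattern(np.array([[48.0, 50.0], [52.0, 50.0]]), WIN)
        k = ppa.k_hat_isotropic(pat, np.array([0.0, 5.0]))
        assert k[-1] == pytest.approx(WIN.area_m2 / 2.0 * 2.0, rel=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            ppa.k_hat_isotropic(ppa.PointPattern(np.array([[1.0, 1.0]]), WIN),
                                np.array([0.0, 1.0]))

    def test_large_r_warns_without_override(self, rng):
        pat = ppa.simulate_csr(30, WIN, rng)
        with pytest.warns(UserWarning, match="quarter"):
            ppa.k_hat_isotropic(pat, np.arange(0.0, 30.1, 1.0))


class TestLHat:
    def test_csr_mean_is_near_zero(self):
        # below r = 1 m the expected pair count for n = 100 on 10⁴ m² is
        # near zero, so K̂ = 0 and L − r ≈ −r·P(no pair): an inherent bias
        # of the square-root transform, not of the estimator.  The
        # near-zero check therefore starts at 1 m.
        rng = np.random.default_rng(7)
        grid = np.arange(0.0, 25.01, 0.25)
        curves = [ppa.l_hat(ppa.simulate_csr(100, WIN, rng), grid).l_hat
                  for _ in range(500)]
        bias = np.abs(np.mean(curves, axis=0))
        assert bias[grid >= 1.0].max() < 0.15
        # at sub-meter radii the bias is bounded by the analytic envelope
        small = grid < 1.0
        assert np.all(bias[small] <= grid[small] + 1e-9)

    def test_thomas_pattern_is_detected_as_clustered(self):
        big = PlotGeometry(320.0, 320.0, 20.0)
        pts = sf.sample_thomas(0.002, 8.0, 4.0, big, np.random.default_rng(3))
        res = ppa.l_hat(ppa.PointPattern(pts, big), np.array([0.0, 10.0]))
        assert res.l_hat[-1] > 0.0

    def test_centering_convention(self, rng):
        pat = ppa.simulate_csr(50, WIN, rng)
        grid = np.arange(0.0, 10.1, 0.5)
        centered = ppa.l_hat(pat, grid).l_hat
        raw = ppa.l_hat(pat, grid, centered=False).l_hat
        np.testing.assert_allclose(raw - grid, centered, rtol=0, atol=1e-12)
        assert centered[0] == 0.0


class TestBivariate:
    def test_empty_pattern_rejected(self, rng):
        p1 = ppa.simulate_csr(10, WIN, rng)
        p2 = ppa.PointPattern(np.empty((0, 2)), WIN)
        with pytest.raises(ValueError):
            ppa.k12_hat_isotropic(p1, p2, np.array([0.0, 5.0]))

    def test_mismatched_windows_rejected(self, rng):
        p1 = ppa.simulate_csr(10, WIN, rng)
        p2 = ppa.simulate_csr(10, PlotGeometry(200.0, 200.0, 20.0), rng)
        with pytest.raises(ValueError):
            ppa.k12_hat_isotropic(p1, p2, np.array([0.0, 5.0]))

    def test_type_centric_symmetry_is_exact(self, rng):
        p1 = ppa.simulate_csr(35, WIN, rng)
        p2 = ppa.simulate_csr(55, WIN, rng)
        grid = np.arange(0.0, 20.1, 0.5)
        k12 = ppa.k12_hat_isotropic(p1, p2, grid)
        k21 = ppa.k12_hat_isotropic(p2, p1, grid)
        np.testing.assert_allclose(k12, k21, rtol=0, atol=1e-10)

    def test_segregated_stand_shows_repulsion(self):
        rng = np.random.default_rng(21)
        small = rng.uniform(0, 100, (600, 2))
        large = rng.uniform(0, 100, (15, 2))
        thinned = sf.apply_segregation(small, large, 10.0, 1.0, rng)
        p1 = ppa.PointPattern(large, WIN)
        p2 = ppa.PointPattern(thinned, WIN)
        grid = np.arange(0.0, 9.01, 0.25)
        env = ppa.envelope((p1, p2), "population_independence", 99, rng,
                           r_grid=grid)
        lo, _ = ppa.envelope_bounds(env)
        i5 = int(np.argmin(np.abs(grid - 5.0)))
        assert env.observed.l_hat[i5] < lo[i5]


class TestNullModels:
    def test_csr_empty_and_seeded(self):
        assert ppa.simulate_csr(0, WIN, np.random.default_rng(0)).n == 0
        a = ppa.simulate_csr(20, WIN, np.random.default_rng(5)).points
        b = ppa.simulate_csr(20, WIN, np.random.default_rng(5)).points
        np.testing.assert_array_equal(a, b)

    def test_csr_is_uniform_on_the_window(self):
        rng = np.random.default_rng(17)
        means = np.array([ppa.simulate_csr(40, WIN, rng).points.mean(axis=0)
                          for _ in range(1000)])
        grand = means.mean(axis=0)
        se = means.std(axis=0, ddof=1) / math.sqrt(len(means))
        assert np.all(np.abs(grand - [50.0, 50.0]) < 3 * se)

    def test_toroidal_shift_identities(self, rng):
        pat = ppa.simulate_csr(25, WIN, rng)
        same = ppa.toroidal_shift(pat, (0.0, 0.0))
        np.testing.assert_allclose(same.points, pat.points)
        wrapped = ppa.toroidal_shift(pat, (WIN.width_m, WIN.height_m))
        np.testing.assert_allclose(wrapped.points, pat.points, atol=1e-9)

    def test_toroidal_distances_preserved_under_random_shifts(self):
        rng = np.random.default_rng(9)
        pat = ppa.simulate_csr(20, WIN, rng)
        grid = np.arange(0.0, 20.1, 1.0)
        ref = toroidal_k(pat.points, WIN, grid)
        for _ in range(100):
            shifted = ppa.toroidal_shift(
                pat, (rng.uniform(0, 100), rng.uniform(0, 100)))
            np.testing.assert_allclose(toroidal_k(shifted.points, WIN, grid),
                                       ref, rtol=0, atol=1e-8)


class TestEnvelope:
    def test_single_simulation_allowed(self, rng):
        env = ppa.envelope(ppa.simulate_csr(30, WIN, rng), "csr", 1, rng,
                           r_grid=np.arange(0.0, 5.1, 0.5))
        assert env.simulated.shape[0] == 1

    def test_unknown_null_model_rejected(self, rng):
        with pytest.raises(ValueError):
            ppa.envelope(ppa.simulate_csr(10, WIN, rng), "matern", 5, rng)

    def test_population_independence_preserves_internal_structure(self, rng):
        # each subpattern is rigid on the torus: its toroidal-metric K is
        # invariant under the null's random shifts
        p1 = ppa.simulate_csr(20, WIN, rng)
        grid = np.arange(0.0, 15.1, 0.5)
        ref = toroidal_k(p1.points, WIN, grid)
        for _ in range(20):
            shifted = ppa.toroidal_shift(
                p1, (rng.uniform(0, 100), rng.uniform(0, 100)))
            np.testing.assert_allclose(toroidal_k(shifted.points, WIN, grid),
                                       ref, atol=1e-8)


class TestGoF:
    def _env_from_curves(self, curves):
        grid = np.arange(0.0, 9.01, 0.25)
        obs = ppa.LResult(r_grid=grid, l_hat=curves[0])
        return ppa.EnvelopeResult(observed=obs, simulated=np.array(curves[1:]),
                                  null_model="csr")

    def test_all_identical_curves_tie_to_p_one(self):
        grid = np.arange(0.0, 9.01, 0.25)
        flat = np.zeros(len(grid))
        env = self._env_from_curves([flat] * 100)
        gof = ppa.gof_loosmore_ford(env)
        assert gof.p_value == 1.0

    def test_extreme_observation_attains_minimal_p(self, rng):
        big = PlotGeometry(320.0, 320.0, 20.0)
        pts = sf.sample_thomas(0.002, 8.0, 4.0, big, np.random.default_rng(3))
        pat = ppa.PointPattern(pts, big)
        env = ppa.envelope(pat, "csr", 99, rng, r_grid=np.arange(0.0, 9.01, 0.25))
        gof = ppa.gof_loosmore_ford(env)
        assert gof.p_value == pytest.approx(0.01)

    def test_bounds_must_lie_inside_grid(self, rng):
        env = ppa.envelope(ppa.simulate_csr(20, WIN, rng), "csr", 5, rng,
                           r_grid=np.arange(0.0, 9.01, 0.25))
        with pytest.raises(ValueError):
            ppa.gof_loosmore_ford(env, r_min=0.0, r_max=50.0)


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [
        (0.05, 12, 0.004),
        (0.05, 1, 0.05),
        (0.06, 2, 0.03),
    ])
    def test_threshold_values(self, alpha, m, expected):
        assert ppa.bonferroni(alpha, m) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ppa.bonferroni(0.0, 3)
        with pytest.raises(ValueError):
            ppa.bonferroni(0.05, 0)


class TestCorrelogram:
    def test_zero_variance_flagged_not_estimable(self, rng):
        mids = [(float(i * 20), 0.0) for i in range(10)]
        out = ppa.transect_correlogram([5.0] * 10, mids, [0.0, 50.0, 100.0],
                                       rng=rng, n_perm=49)
        assert not out["estimable"].any()

    def test_eastward_gradient_is_detected_at_short_range(self, rng):
        mids = [(float(x), float(y)) for x in range(0, 200, 20)
                for y in range(0, 200, 20)]
        vals = [m[0] + 0.01 * m[1] for m in mids]
        out = ppa.transect_correlogram(vals, mids, [0.0, 40.0], rng=rng,
                                       n_perm=199)
        row = out.iloc[0]
        assert row.estimable and row.correlation > 0.5
        assert row.p_value <= 0.01

    def test_rejection_rate_under_spatial_noise_is_near_alpha(self):
        rng = np.random.default_rng(31)
        mids = [(float(x), float(y)) for x in range(0, 100, 20)
                for y in range(0, 100, 20)]
        classes = [0.0, 40.0, 80.0]
        rejections = np.zeros(2)
        n_rep = 200
        for _ in range(n_rep):
            vals = rng.normal(size=len(mids))
            out = ppa.transect_correlogram(vals, mids, classes, rng=rng,
                                           n_perm=99)
            rejections += (out["p_value"].to_numpy() <= 0.05)
        rates = rejections / n_rep
        assert np.all(rates >= 0.01) and np.all(rates <= 0.09)
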