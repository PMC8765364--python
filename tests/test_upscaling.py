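import numpy as np
import pytest
from scipy import integrate

from mangrove_nbudget.upscaling import (
    GridSpec,
    IdwSurface,
    SiteValueDistribution,
    _density,
    aboveground_n_stock,
    areal_from_total,
    draw_site_values,
    draw_skew_normal,
    estuary_estimate,
    estuary_iteration,
    idw_interpolate,
    skew_from_sample,
    soil_share,
    truncation_bias,
)


def square_grid(n, cell_size=10.0, origin=(0.0, 0.0)):
    offsets = (np.arange(n) + 0.5) * cell_size
    xx, yy = np.meshgrid(origin[0] + offsets, origin[1] + offsets)
    return GridSpec(cell_size=cell_size,
                    mask=np.column_stack([xx.ravel(), yy.ravel()]))


class TestGridSpec:
    def test_area_accounting(self):
        grid = square_grid(3, cell_size=2.0)
        assert grid.n_cells == 9
        assert grid.total_area_ha == pytest.approx(9 * 4 / 1e4)

    def test_ascii_mask(self):
        grid = GridSpec.from_ascii("101\n010\n", cell_size=1.0)
        assert grid.n_cells == 3

    def test_mask_csv_round_trip(self, tmp_path):
        grid = square_grid(4, cell_size=5.0)
        grid.to_mask_csv(tmp_path / "m.csv")
        back = GridSpec.from_mask_csv(tmp_path / "m.csv", cell_size=5.0)
        assert np.array_equal(back.mask, grid.mask)


class TestIdw:
    def test_single_point_constant_field(self):
        assert idw_interpolate([(0, 0, 7.0)], (123.0, -45.0)) == 7.0

    def test_equidistant_symmetry(self):
        known = [(0.0, 0.0, 2.0), (10.0, 0.0, 4.0)]
        assert idw_interpolate(known, (5.0, 0.0)) == pytest.approx(3.0)

    def test_exact_at_known_point(self):
        known = [(0.0, 0.0, 2.0), (10.0, 0.0, 4.0)]
        assert idw_interpolate(known, (10.0, 0.0)) == 4.0

    def test_convex_combination(self):
        rng = np.random.default_rng(1)
        known = [(x, y, v) for x, y, v in
                 zip(rng.uniform(0, 100, 6), rng.uniform(0, 100, 6),
                     rng.uniform(2, 9, 6))]
        vals = [v for _, _, v in known]
        for q in rng.uniform(-50, 150, size=(20, 2)):
            out = idw_interpolate(known, tuple(q))
            assert min(vals) - 1e-12 <= out <= max(vals) + 1e-12

    def test_no_points_rejected(self):
        with pytest.raises(ValueError):
            idw_interpolate([], (0, 0))


class TestSkewNormal:
    def test_degenerate_sd_zero(self):
        dist = SiteValueDistribution("s", 5.0, 0.0, 1.0)
        assert draw_skew_normal(dist, 0) == 5.0

    def test_symmetric_clt_check(self):
        dist = SiteValueDistribution("s", 3.0, 1.5, 1.0)
        draws = draw_skew_normal(dist, 11, size=10**5)
        assert abs(draws.mean() - 3.0) < 3 * 1.5 / np.sqrt(10**5)

    def test_skewed_moments_match_density_integral(self):
        # oracle: numeric integration of the skewed density
        dist = SiteValueDistribution("s", 10.0, 2.0, 2.0)
        m0, _ = integrate.quad(lambda x: _density(dist, x), -50, 80)
        m1, _ = integrate.quad(lambda x: x * _density(dist, x), -50, 80)
        m2, _ = integrate.quad(lambda x: x**2 * _density(dist, x), -50, 80)
        assert m0 == pytest.approx(1.0, abs=1e-8)
        assert m1 == pytest.approx(10.0, abs=1e-6)
        assert np.sqrt(m2 - m1**2) == pytest.approx(2.0, abs=1e-6)

        draws = draw_skew_normal(dist, 7, size=2 * 10**5)
        assert draws.mean() == pytest.approx(10.0, abs=0.03)
        assert draws.std() == pytest.approx(2.0, abs=0.03)
        from scipy.stats import skew
        assert skew(draws) > 0.2

    def test_skew_estimator_round_trip(self):
        dist = SiteValueDistribution("s", 0.0, 1.0, 2.0)
        draws = draw_skew_normal(dist, 3, size=2 * 10**5)
        assert skew_from_sample(draws) == pytest.approx(2.0, abs=0.15)

    def test_skew_estimator_small_sample_fallback(self):
        assert skew_from_sample([1.0, 2.0], default=1.5) == 1.5

    def test_truncation_bias_negligible_far_from_zero(self):
        dist = SiteValueDistribution("s", 100.0, 1.0, 1.5)
        assert truncation_bias(dist) == pytest.approx(0.0, abs=1e-12)

    def test_truncation_recentring_near_zero(self, caplog):
        dist = SiteValueDistribution("s", 0.5, 1.0, 1.0)
        bias = truncation_bias(dist)
        assert bias > 0.005  # clipping shifts the mean noticeably
        rng = np.random.default_rng(0)
        with caplog.at_level("WARNING"):
            values = draw_site_values(dist, rng, size=10**5)
        assert "re-centring" in caplog.text
        assert values.min() >= 0.0


class TestEstuaryIteration:
    def test_constant_field_conservation(self):
        grid = square_grid(5, cell_size=20.0)
        sites = {"a": (0.0, 0.0), "b": (100.0, 100.0)}
        dists = {s: SiteValueDistribution(s, 4.0, 0.0) for s in sites}
        total = estuary_iteration(dists, sites, grid, seed=0)
        assert total == pytest.approx(4.0 * grid.total_area_ha)

    def test_single_site_constant(self):
        grid = square_grid(4, cell_size=10.0)
        total = estuary_iteration(
            {"a": SiteValueDistribution("a", 2.5, 0.0)},
            {"a": (0.0, 0.0)}, grid, seed=0)
        assert total == pytest.approx(2.5 * grid.total_area_ha)

    def test_enumeration_oracle_on_3x3_mask(self):
        # brute force: hand IDW at each of the 9 cells
        grid = square_grid(3, cell_size=10.0)
        sites = {"a": (0.0, 0.0), "b": (30.0, 30.0)}
        values = {"a": 2.0, "b": 8.0}
        power = 2.0
        expected = 0.0
        for cx, cy in grid.mask:
            wsum = vsum = 0.0
            for s, (sx, sy) in sites.items():
                d2 = (cx - sx) ** 2 + (cy - sy) ** 2
                w = d2 ** (-power / 2)
                wsum += w
                vsum += w * values[s]
            expected += (vsum / wsum) * grid.cell_area_ha
        dists = {s: SiteValueDistribution(s, values[s], 0.0) for s in sites}
        got = estuary_iteration(dists, sites, grid, power=power, seed=1)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_missing_location_is_error(self):
        grid = square_grid(2)
        with pytest.raises(KeyError, match="nowhere"):
            estuary_iteration(
                {"nowhere": SiteValueDistribution("nowhere", 1.0, 0.0)},
                {}, grid, seed=0)


class TestEstuaryEstimate:
    def test_zero_variance_equals_deterministic(self):
        grid = square_grid(4, cell_size=25.0)
        sites = {"a": (0.0, 0.0), "b": (80.0, 80.0)}
        dists = {"a": SiteValueDistribution("a", 3.0, 0.0),
                 "b": SiteValueDistribution("b", 6.0, 0.0)}
        est = estuary_estimate(dists, sites, grid, n_iterations=10, seed=0)
        det = estuary_iteration(dists, sites, grid, seed=99)
        assert est.total_se == pytest.approx(0.0, abs=1e-12)
        assert est.total_mean == pytest.approx(det)
        assert est.areal_mean == pytest.approx(det / grid.total_area_ha)

    def test_reproducible_with_seed(self):
        grid = square_grid(4)
        sites = {"a": (0.0, 0.0), "b": (15.0, 35.0)}
        dists = {s: SiteValueDistribution(s, 5.0, 1.0, 1.8) for s in sites}
        a = estuary_estimate(dists, sites, grid, n_iterations=20, seed=3)
        b = estuary_estimate(dists, sites, grid, n_iterations=20, seed=3)
        assert a == b

    def test_se_scaling_law(self):
        grid = square_grid(4)
        sites = {"a": (0.0, 0.0), "b": (15.0, 35.0)}
        dists = {s: SiteValueDistribution(s, 5.0, 1.0, 1.5) for s in sites}
        small = estuary_estimate(dists, sites, grid, n_iterations=100, seed=5)
        large = estuary_estimate(dists, sites, grid, n_iterations=400, seed=5)
        assert small.total_se / large.total_se == pytest.approx(2.0, rel=0.3)

    def test_rejects_single_iteration(self):
        grid = square_grid(2)
        with pytest.raises(ValueError):
            estuary_estimate({"a": SiteValueDistribution("a", 1.0, 0.0)},
                             {"a": (0.0, 0.0)}, grid, n_iterations=1)

    def test_grid_refinement_consistency(self):
        # halving the cell size changes a zero-variance areal mean < 0.5%
        sites = {"a": (25.0, 25.0), "b": (75.0, 75.0)}
        dists = {"a": SiteValueDistribution("a", 2.0, 0.0),
                 "b": SiteValueDistribution("b", 8.0, 0.0)}
        coarse = square_grid(10, cell_size=10.0)
        fine = square_grid(20, cell_size=5.0)
        t_coarse = estuary_iteration(dists, sites, coarse, seed=0) \
            / coarse.total_area_ha
        t_fine = estuary_iteration(dists, sites, fine, seed=0) \
            / fine.total_area_ha
        assert abs(t_fine - t_coarse) / t_coarse < 0.005


class TestAboveground:
    def test_monospecific_stand(self):
        assert aboveground_n_stock({"Avicennia germinans": 1.0}, 100.0) \
            == pytest.approx(0.26)

    def test_weighted_mixture(self):
        comp = {"Avicennia germinans": 0.5, "Laguncularia racemosa": 0.5}
        assert aboveground_n_stock(comp, 100.0) == pytest.approx(0.2085)

    def test_zero_biomass(self):
        assert aboveground_n_stock({"Rhizophora mangle": 1.0}, 0.0) == 0.0

    def test_bad_composition_rejected(self):
        with pytest.raises(ValueError):
            aboveground_n_stock({"Rhizophora mangle": 0.7}, 10.0)


class TestTableArithmetic:
    def test_areal_from_total(self):
        assert areal_from_total(16340.0, 2313.0) == pytest.approx(7.1,
                                                                  abs=0.05)

    def test_soil_share(self):
        assert soil_share(9.0, 1.0) == pytest.approx(0.9)
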