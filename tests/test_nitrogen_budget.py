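import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mangrove_nbudget.core_model import HISTORIC, RECENT, SedimentCore
from mangrove_nbudget.nitrogen_budget import (
    NonDecayingProfileWarning,
    StockResult,
    core_period_stock,
    extrapolate_depth_profile,
    molar_cn,
    n_accumulation_rate,
    normalize_stock_rate,
    slice_n_stock,
)
from conftest import make_slice


class TestSliceStock:
    @pytest.mark.parametrize("bd,thick,fn,expected", [
        (0.5, 28, 0.005, 7.0),
        (0.5, 28, 0.0, 0.0),
        (0.2, 18, 0.0124, 4.464),
    ])
    def test_formula(self, bd, thick, fn, expected):
        sl = make_slice(0, thick, 2000, bd=bd, fn=fn)
        assert slice_n_stock(sl) == pytest.approx(expected)


class TestCorePeriodStock:
    def test_additivity_over_slices(self, simple_core):
        total = core_period_stock(simple_core, RECENT).value
        parts = [slice_n_stock(s) for s in simple_core.slices[:2]]
        assert total == pytest.approx(sum(parts))

    def test_empty_period_gives_zero(self):
        core = SedimentCore("c", "s", [make_slice(0, 1, 1900)])
        res = core_period_stock(core, RECENT)
        assert res.value == 0.0 and res.depth_range is None

    def test_column_sum_oracle(self):
        # independent oracle: tabulate per-slice stocks by hand formula
        rows = [(0, 2, 2010, 0.3, 0.012), (2, 4, 2000, 0.4, 0.010),
                (4, 6, 1990, 0.5, 0.008), (6, 8, 1960, 0.6, 0.006)]
        expected_recent = sum(bd * (b - t) * fn * 100
                              for t, b, d, bd, fn in rows if 1970 <= d < 2016)
        core = SedimentCore("c", "s", [
            make_slice(t, b, d, bd=bd, fn=fn) for t, b, d, bd, fn in rows
        ])
        res = core_period_stock(core, RECENT)
        assert res.value == pytest.approx(expected_recent)
        assert res.depth_range == (0, 6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(
        st.floats(0.1, 1.0), st.floats(0.001, 0.02)), min_size=1, max_size=8))
    def test_partition_invariance(self, params):
        # stock of a core equals the sum over any slice partition
        slices = [make_slice(2 * i, 2 * i + 2, 2010 - i, bd=bd, fn=fn)
                  for i, (bd, fn) in enumerate(params)]
        core = SedimentCore("c", "s", slices)
        total = core_period_stock(core, RECENT).value
        assert total == pytest.approx(
            sum(slice_n_stock(s) for s in slices), rel=1e-12)


class TestAccumulation:
    @pytest.mark.parametrize("sar,bd,fn,expected", [
        (5.5, 0.35, 0.012, 23.1),
        (0.0, 0.35, 0.012, 0.0),
        (2.0, 0.5, 0.01, 10.0),
    ])
    def test_formula(self, sar, bd, fn, expected):
        assert n_accumulation_rate(sar, bd, fn) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            n_accumulation_rate(-1, 0.5, 0.01)

    def test_unit_coherence_with_stock_arithmetic(self):
        # a 1-year slice of thickness sar/10 cm holds the annual deposit
        sar, bd, fn = 3.7, 0.44, 0.0087
        one_year = make_slice(0, sar / 10.0, 2015, bd=bd, fn=fn)
        assert n_accumulation_rate(sar, bd, fn) / 100.0 == pytest.approx(
            slice_n_stock(one_year), abs=1e-9)


class TestMolarCN:
    def test_published_cell(self):
        assert molar_cn(0.312, 0.0097) == pytest.approx(37.6, abs=0.1)

    def test_equal_molar_identity(self):
        assert molar_cn(0.12011, 0.14007) == pytest.approx(1.0)

    def test_hand_value(self):
        assert molar_cn(0.10, 0.01) == pytest.approx(11.66, abs=0.01)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            molar_cn(0.1, 0.0)


class TestNormalize:
    @pytest.mark.parametrize("value,period,expected", [
        (7.1, RECENT, 7.1 / 46),
        (2.3, HISTORIC, 2.3 / 40),
        (0.0, RECENT, 0.0),
    ])
    def test_division_by_duration(self, value, period, expected):
        res = StockResult(value, period, None)
        assert normalize_stock_rate(res) == pytest.approx(expected)


class TestExtrapolation:
    def test_constant_profile_doubles(self):
        import warnings

        profile = [(d, 0.3) for d in (10.0, 20.0, 30.0, 40.0, 50.0)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NonDecayingProfileWarning)
            s50 = extrapolate_depth_profile(profile, 50)
            s100 = extrapolate_depth_profile(profile, 100)
        assert s100 == pytest.approx(2 * s50)

    def test_growing_density_warns(self):
        profile = [(d, np.exp(0.02 * d)) for d in (5.0, 15.0, 25.0)]
        with pytest.warns(NonDecayingProfileWarning):
            extrapolate_depth_profile(profile, 50)

    def test_matches_analytic_exponential_integral(self):
        a, b = 1.0, -0.02
        depths = np.arange(2.0, 30.0, 2.0)
        profile = [(d, float(np.exp(a + b * d))) for d in depths]
        deepest = depths[-1]
        target = 100.0
        observed = extrapolate_depth_profile(profile, deepest)
        expected_tail = np.exp(a) / b * (np.exp(b * target)
                                         - np.exp(b * deepest))
        got = extrapolate_depth_profile(profile, target)
        assert got - observed == pytest.approx(expected_tail, abs=1e-6)

    def test_target_at_deepest_is_identity(self):
        profile = [(d, np.exp(-0.05 * d)) for d in (5.0, 15.0, 25.0)]
        assert extrapolate_depth_profile(profile, 25.0) \
            == extrapolate_depth_profile(profile, 25.0 + 1e-13)

    def test_monotone_in_target_depth(self):
        profile = [(d, np.exp(1 - 0.03 * d)) for d in (5.0, 15.0, 25.0)]
        stocks = [extrapolate_depth_profile(profile, t)
                  for t in (25, 40, 60, 100, 200)]
        assert all(b >= a for a, b in zip(stocks, stocks[1:]))

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_depth_profile([(5, 1.0), (10, 0.0), (15, 1.0)], 20)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_depth_profile([(5, 1.0), (10, 0.5)], 20)
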