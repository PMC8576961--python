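"""Population-share weights, HEPE fields, contribution decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hepe.exceedance import ExceedanceField
from hepe.grid import GridSpec, PopulationRaster
from hepe.indicators import (
    HepeField,
    compute_hepe,
    contribution,
    contribution_summary,
    daily_accumulate,
    find_peak_hours,
    normalize_population,
    temporal_profile,
)


def pop_raster(grid, values, tag="sm", hour=10):
    return PopulationRaster(grid=grid, values=values, source_tag=tag, hour=hour)


def ep_field(grid, values, hour=10):
    return ExceedanceField(grid=grid, ep=np.asarray(values, float), hour=hour)


@pytest.fixture
def grid3() -> GridSpec:
    return GridSpec(0, 100, 100, 1, 3)


class TestNormalization:
    def test_min_max_then_sum(self, grid3):
        shares = normalize_population(pop_raster(grid3, [[0.0, 5.0, 10.0]]))
        np.testing.assert_allclose(shares, [[0.0, 1 / 3, 2 / 3]], atol=1e-12)

    def test_positive_scale_invariance(self, grid3):
        a = normalize_population(pop_raster(grid3, [[0.0, 5.0, 10.0]]))
        b = normalize_population(pop_raster(grid3, [[0.0, 50.0, 100.0]]))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_constant_raster_gets_equal_shares(self):
        grid = GridSpec(0, 100, 100, 1, 4)
        shares = normalize_population(pop_raster(grid, [[7.0, 7.0, 7.0, 7.0]]))
        np.testing.assert_allclose(shares, 0.25, atol=1e-12)

    def test_all_zero_raster_rejected(self, grid3):
        with pytest.raises(ValueError, match="all zero"):
            normalize_population(pop_raster(grid3, [[0.0, 0.0, 0.0]]))

    @given(st.lists(st.floats(0, 1e6), min_size=4, max_size=16).filter(lambda v: max(v) > 0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_shares_always_sum_to_one(self, values):
        n = len(values)
        grid = GridSpec(0, 100, 100, 1, n)
        shares = normalize_population(pop_raster(grid, np.array(values).reshape(1, n)))
        assert abs(shares.sum() - 1.0) < 1e-9
        assert np.all(shares >= 0)


class TestHepe:
    def test_share_times_exceedance(self, grid3):
        shares = np.array([[0.0, 1 / 3, 2 / 3]])
        f = compute_hepe(shares, ep_field(grid3, [[3.0, 3.0, 3.0]]), "sm")
        np.testing.assert_allclose(f.values, [[0.0, 1.0, 2.0]], atol=1e-12)

    def test_zero_exceedance_annihilates(self, grid3, rng):
        v = rng.random((1, 3))
        shares = v / v.sum()
        f = compute_hepe(shares, ep_field(grid3, [[0.0, 0.0, 0.0]]), "sm")
        assert (f.values == 0).all()

    def test_concentrated_weight(self, grid3):
        shares = np.array([[1.0, 0.0, 0.0]])
        f = compute_hepe(shares, ep_field(grid3, [[10.0, 10.0, 10.0]]), "psd")
        np.testing.assert_allclose(f.values, [[10.0, 0.0, 0.0]], atol=1e-12)

    def test_grid_mismatch_rejected(self, grid3):
        other = GridSpec(0, 100, 100, 1, 4)
        with pytest.raises(ValueError):
            compute_hepe(np.full((1, 4), 0.25), ep_field(grid3, [[1.0, 1.0, 1.0]]), "sm")

    def test_scale_invariance_of_hepe(self, grid3):
        """Rescaling the population raster leaves the HEPE field unchanged."""
        ep = ep_field(grid3, [[2.0, 0.0, 8.0]])
        v = np.array([[10.0, 30.0, 60.0]])
        f1 = compute_hepe(normalize_population(pop_raster(grid3, v)), ep, "sm")
        f2 = compute_hepe(normalize_population(pop_raster(grid3, 37.5 * v)), ep, "sm")
        np.testing.assert_allclose(f1.values, f2.values, atol=1e-15)

    def test_total_hepe_is_weighted_mean_exceedance(self, small_grid, rng):
        v = rng.random(small_grid.shape)
        ep_vals = rng.random(small_grid.shape) * 10
        shares = normalize_population(pop_raster(small_grid, v))
        f = compute_hepe(shares, ep_field(small_grid, ep_vals), "sm")
        assert f.total == pytest.approx(float((shares * ep_vals).sum()), rel=1e-12)


class TestAccumulation:
    def _field(self, grid, values, hour=10, tag="sm"):
        return HepeField(grid=grid, values=values, source_tag=tag, hour=hour)

    def test_single_field_identity(self, grid3):
        f = self._field(grid3, np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_array_equal(daily_accumulate([f]).values, f.values)

    def test_two_equal_fields_double(self, grid3):
        f = self._field(grid3, np.array([[1.0, 2.0, 3.0]]))
        g = self._field(grid3, f.values.copy(), hour=11)
        np.testing.assert_allclose(daily_accumulate([f, g]).values, 2 * f.values)

    def test_many_random_fields_match_direct_sum(self, small_grid, rng):
        fields = [self._field(small_grid, rng.random(small_grid.shape), hour=10 + i)
                  for i in range(14)]
        acc = daily_accumulate(fields)
        direct = np.zeros(small_grid.shape)
        for f in fields:
            direct = direct + f.values
        np.testing.assert_allclose(acc.values, direct, rtol=1e-12)
        assert acc.values.min() >= max(f.values.min() for f in fields)

    def test_mixed_sources_rejected(self, grid3):
        f = self._field(grid3, np.ones((1, 3)), tag="sm")
        g = self._field(grid3, np.ones((1, 3)), hour=11, tag="psd")
        with pytest.raises(ValueError, match="mixed"):
            daily_accumulate([f, g])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            daily_accumulate([])


class TestProfilePeaks:
    def test_interior_local_maximum(self):
        assert find_peak_hours([10, 11, 12], [1.0, 3.0, 2.0]) == [11]

    def test_monotone_series_peaks_at_endpoint(self):
        assert find_peak_hours([10, 11, 12], [1.0, 2.0, 3.0]) == [12]

    def test_temporal_profile_reports_mean_and_peak(self, grid3):
        fields = [
            HepeField(grid=grid3, values=np.full((1, 3), m), source_tag="sm", hour=10 + i)
            for i, m in enumerate([1.0, 3.0, 2.0])
        ]
        df = temporal_profile(fields)
        assert df["mean"].tolist() == [1.0, 3.0, 2.0]
        assert df.attrs["peak_hours"] == [11]


class TestContribution:
    def _pair(self, grid, psd_vals, sm_vals, hour=10):
        return (
            HepeField(grid=grid, values=np.asarray(psd_vals, float), source_tag="psd", hour=hour),
            HepeField(grid=grid, values=np.asarray(sm_vals, float), source_tag="sm", hour=hour),
        )

    def test_three_to_one_is_75_percent(self, grid3):
        psd, sm = self._pair(grid3, [[3.0, 0.0, 2.0]], [[1.0, 2.0, 0.0]])
        c = contribution(psd, sm)
        np.testing.assert_allclose(c.pct, [[75.0, 0.0, 100.0]])

    def test_undefined_where_both_zero(self, grid3):
        psd, sm = self._pair(grid3, [[0.0, 1.0, 0.0]], [[0.0, 1.0, 2.0]])
        c = contribution(psd, sm)
        assert np.isnan(c.pct[0, 0])
        assert c.defined_mask.sum() == 2

    def test_complementary_fields_sum_to_100(self, small_grid, rng):
        psd, sm = self._pair(small_grid, rng.random(small_grid.shape) * (rng.random(small_grid.shape) > 0.3),
                             rng.random(small_grid.shape) * (rng.random(small_grid.shape) > 0.3))
        c_psd = contribution(psd, sm)
        c_sm = contribution(sm, psd)
        both = c_psd.defined_mask
        np.testing.assert_allclose(c_psd.pct[both] + c_sm.pct[both], 100.0, atol=1e-9)

    def test_hour_mismatch_rejected(self, grid3):
        psd, _ = self._pair(grid3, [[1.0, 1.0, 1.0]], [[1.0, 1.0, 1.0]])
        _, sm = self._pair(grid3, [[1.0, 1.0, 1.0]], [[1.0, 1.0, 1.0]], hour=11)
        with pytest.raises(ValueError, match="hour"):
            contribution(psd, sm)


class TestContributionSummary:
    def test_uniform_field(self, grid3):
        psd = HepeField(grid=grid3, values=np.full((1, 3), 3.0), source_tag="psd", hour=10)
        sm = HepeField(grid=grid3, values=np.full((1, 3), 1.0), source_tag="sm", hour=10)
        df = contribution_summary([contribution(psd, sm)])
        row = df.iloc[0]
        assert row["mean"] == 75.0 and row["sd"] == 0.0

    def test_half_zero_half_hundred(self):
        grid = GridSpec(0, 100, 100, 1, 4)
        psd = HepeField(grid=grid, values=np.array([[1.0, 1.0, 0.0, 0.0]]), source_tag="psd", hour=10)
        sm = HepeField(grid=grid, values=np.array([[0.0, 0.0, 1.0, 1.0]]), source_tag="sm", hour=10)
        row = contribution_summary([contribution(psd, sm)]).iloc[0]
        assert (row["mean"], row["min"], row["max"]) == (50.0, 0.0, 100.0)

    def test_matches_bruteforce_masked_statistics(self, small_grid, rng):
        fields = []
        for h in range(10, 14):
            psd = HepeField(grid=small_grid, values=rng.random(small_grid.shape) * (rng.random(small_grid.shape) > 0.5),
                            source_tag="psd", hour=h)
            sm = HepeField(grid=small_grid, values=rng.random(small_grid.shape) * (rng.random(small_grid.shape) > 0.5),
                           source_tag="sm", hour=h)
            fields.append(contribution(psd, sm))
        df = contribution_summary(fields).set_index("hour")
        for f in fields:
            vals = f.pct[np.isfinite(f.pct)]
            row = df.loc[f.hour]
            assert row["mean"] == pytest.approx(vals.mean(), abs=1e-12)
            assert row["sd"] == pytest.approx(vals.std(), abs=1e-12)
            assert row["min"] == vals.min() and row["max"] == vals.max()

    def test_hour_with_no_defined_cells_flagged(self, grid3):
        c = contribution(
            HepeField(grid=grid3, values=np.zeros((1, 3)), source_tag="psd", hour=10),
            HepeField(grid=grid3, values=np.zeros((1, 3)), source_tag="sm", hour=10),
        )
        row = contribution_summary([c]).iloc[0]
        assert row["n_defined"] == 0 and np.isnan(row["mean"])
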