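"""Elevation bins, density-tail groups and the v^2 ~ 1/rho regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermalsoar.altitude_analysis import (
    compare_groups,
    contrast_percentages,
    density_tail_groups,
    equal_count_bins,
    fit_speed_density_model,
    radius_altitude_trend,
    theoretical_speed_density_slope,
)
from thermalsoar.errors import DomainError, FitError
from thermalsoar.flight_mechanics import G, bank_angle


def _kin_frame(rho, v, radius=None, altitude=None):
    rho = np.asarray(rho, float)
    v = np.asarray(v, float)
    radius = np.full_like(rho, 30.0) if radius is None else np.asarray(radius)
    altitude = np.linspace(500, 6000, len(rho)) if altitude is None \
        else np.asarray(altitude)
    return pd.DataFrame(
        {
            "rho": rho,
            "v": v,
            "radius": radius,
            "altitude": altitude,
            "bank": [bank_angle(vi, ri) for vi, ri in zip(v, radius)],
            "lift_coeff": 2.0 * G * 10.54 / (rho * v**2),
        }
    )


class TestEqualCountBins:
    @pytest.mark.parametrize("n, k, sizes", [(150, 15, {10}), (8595, 15, {573})])
    def test_exact_partitions(self, n, k, sizes):
        rng = np.random.default_rng(0)
        bins = equal_count_bins(rng.uniform(0, 6500, n), k=k)
        counts = np.bincount(bins)[1:]
        assert set(counts) == sizes and counts.sum() == n

    def test_too_few_values(self):
        with pytest.raises(DomainError):
            equal_count_bins(np.arange(7), k=15)

    @settings(max_examples=30, deadline=None)
    @given(n=st.integers(16, 400), seed=st.integers(0, 1000))
    def test_partition_invariants(self, n, seed):
        values = np.random.default_rng(seed).normal(size=n)
        bins = equal_count_bins(values, k=15)
        counts = np.bincount(bins, minlength=16)[1:]
        assert counts.sum() == n
        assert counts.max() - counts.min() <= 1
        # bins are ordered by value: every value in bin b <= min of bin b+2
        order = np.argsort(values, kind="stable")
        assert np.all(np.diff(bins[order]) >= 0)


class TestDensityTailGroups:
    @pytest.mark.parametrize("n, expected", [(8595, 430), (100, 5), (30, 2)])
    def test_group_sizes_round_half_up(self, n, expected):
        rng = np.random.default_rng(1)
        df = _kin_frame(rng.uniform(0.65, 1.1, n), rng.uniform(9, 14, n))
        low, high = density_tail_groups(df, fraction=0.05)
        assert len(low) == len(high) == expected
        assert low["rho"].min() >= high["rho"].max()
        assert not set(low.index) & set(high.index)

    def test_overlapping_groups_rejected(self):
        df = _kin_frame([1.0, 0.9, 0.8], [10, 11, 12])
        with pytest.raises(DomainError):
            density_tail_groups(df, fraction=0.5)


class TestCompareGroups:
    def test_identical_groups_give_zero_contrasts(self):
        df = _kin_frame([1.0] * 5, [10.0] * 5)
        c = compare_groups(df, df.copy())
        assert c.density_excess_pct == 0.0
        assert c.radius_increase_pct == 0.0
        assert c.airspeed_increase_pct == 0.0
        assert c.C_L_diff_pct == 0.0

    def test_field_scale_contrasts_from_group_means(self):
        # densities 1.099 vs 0.646 kg/m3, radii 28.3 vs 44.3 m, C_L 1.83/1.74
        pct = contrast_percentages(1.099, 0.646, 28.3, 44.3, 1.83, 1.74)
        assert pct["density_excess_pct"] == pytest.approx(70.12, abs=0.01)
        assert pct["radius_increase_pct"] == pytest.approx(56.54, abs=0.01)
        assert pct["C_L_diff_pct"] == pytest.approx(4.918, abs=0.001)

    def test_scale_invariance_of_density_excess(self):
        a = contrast_percentages(1.099, 0.646, 28.3, 44.3, 1.83, 1.74)
        b = contrast_percentages(2.198, 1.292, 28.3, 44.3, 1.83, 1.74)
        assert a["density_excess_pct"] == pytest.approx(b["density_excess_pct"],
                                                        rel=1e-12)


class TestSpeedDensityModel:
    def test_constant_cl_recovers_theoretical_slope(self):
        rho = np.linspace(1.099, 0.646, 40)
        slope_true = theoretical_speed_density_slope(10.54, 1.787)
        v = np.sqrt(slope_true / rho)
        fit = fit_speed_density_model(_kin_frame(rho, v))
        assert slope_true == pytest.approx(115.73, abs=0.01)
        assert fit.slope == pytest.approx(slope_true, rel=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_density_is_degenerate(self):
        with pytest.raises(FitError):
            fit_speed_density_model(_kin_frame([1.0] * 10, np.linspace(9, 14, 10)))

    def test_noisy_constant_cl_slope_within_10pct(self):
        rng = np.random.default_rng(3)
        rho = rng.uniform(0.646, 1.099, 400)
        slope_true = theoretical_speed_density_slope(10.54, 1.787)
        v = np.sqrt(slope_true / rho) + rng.normal(0.0, 1.0, 400)
        fit = fit_speed_density_model(_kin_frame(rho, v))
        assert fit.slope == pytest.approx(slope_true, rel=0.10)
        assert 0.0 < fit.r_squared < 1.0
        assert fit.p_value < 1e-4


class TestRadiusTrend:
    def test_exact_exponential_growth(self):
        h = np.linspace(500, 6000, 50)
        r = 28.3 * 1.125 ** (h / 1000.0)
        trend, fit = radius_altitude_trend(
            _kin_frame(np.ones(50), np.full(50, 10.5), radius=r, altitude=h))
        assert trend == pytest.approx(12.5, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("factor, expected", [(1.0, 0.0), (2.0, 100.0)])
    def test_limits(self, factor, expected):
        h = np.linspace(0, 3000, 30)
        r = 30.0 * factor ** (h / 1000.0)
        trend, _ = radius_altitude_trend(
            _kin_frame(np.ones(30), np.full(30, 10.5), radius=r, altitude=h))
        assert trend == pytest.approx(expected, abs=1e-9)

    def test_insufficient_span(self):
        h = np.linspace(1000, 1500, 20)
        with pytest.raises(FitError):
            radius_altitude_trend(
                _kin_frame(np.ones(20), np.full(20, 10.5), altitude=h))
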