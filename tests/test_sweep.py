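import numpy as np
import pandas as pd
import pytest

import hemospin as hs
from hemospin.sweep import SweepSpec

# coarse-but-resolved settings shared by the sweep tests: 100 cells and a
# 100 g acceleration step keep each sweep under a second
COARSE = dict(n_cells=100, acceleration_grid=np.arange(100.0, 1501.0, 100.0))


@pytest.fixture(scope="module")
def curve_10min():
    spec = SweepSpec(include_wbc=False, **COARSE)
    return hs.recovery_curve(spec, 600.0)


class TestRecoveryCurve:
    def test_rise_peak_decay_shape(self, curve_10min):
        """At 10 minutes the averaged platelet recovery rises to a single
        interior maximum and then decays."""
        y = curve_10min["E_PLT_mean"].to_numpy()
        i = int(np.argmax(y))
        assert 0 < i < y.size - 1
        assert np.all(np.diff(y[: i + 1]) > 0)
        assert y[-1] < y[i] - 0.02

    def test_two_minutes_never_peaks_in_range(self):
        """A 2-minute spin cannot separate the plasma fast enough: the
        recovery keeps rising through 1500 g."""
        spec = SweepSpec(include_wbc=False, **COARSE)
        curve = hs.recovery_curve(spec, 120.0)
        y = curve["E_PLT_mean"].to_numpy()
        assert np.argmax(y) == y.size - 1
        crit = hs.critical_acceleration(curve)
        assert crit.at_edge

    def test_empty_grid_gives_empty_table(self):
        spec = SweepSpec(acceleration_grid=np.array([]), include_wbc=False)
        assert len(hs.recovery_curve(spec, 600.0)) == 0

    def test_plasma_recovery_monotone_in_acceleration_and_time(
        self, curve_10min
    ):
        for he in (0.37, 0.45, 0.52):
            col = curve_10min[f"E_plas_He{he:g}"].to_numpy()
            assert np.all(np.diff(col) >= 0)
        spec = SweepSpec(include_wbc=False, **COARSE)
        shorter = hs.recovery_curve(spec, 300.0)
        assert np.all(
            shorter["E_plas_mean"].to_numpy()
            <= curve_10min["E_plas_mean"].to_numpy() + 1e-12
        )

    def test_plasma_recovery_bounded_by_fully_settled_state(self, curve_10min):
        for he in (0.37, 0.45, 0.52):
            bound = hs.fully_settled_plasma_bound(he, 0.8)
            assert curve_10min[f"E_plas_He{he:g}"].max() <= bound + 1e-9

    def test_maximum_recovery_falls_with_hematocrit(self, curve_10min):
        """Denser initial packing means less recoverable plasma: the peak
        E_PLT decreases from He 0.37 to 0.52 while its critical
        acceleration grows."""
        peaks, crits = [], []
        for he in (0.37, 0.45, 0.52):
            crit = hs.critical_acceleration(curve_10min, f"E_PLT_He{he:g}")
            peaks.append(crit.e_max)
            crits.append(crit.acceleration_g)
        assert peaks[0] > peaks[1] > peaks[2]
        assert crits[0] < crits[2]

    def test_maximum_recovery_grows_with_blood_volume(self):
        peaks, crits = [], []
        for v_ml in (3.5, 7.5, 9.0):
            spec = SweepSpec(
                whole_blood_volume=v_ml * 1e-6, include_wbc=False, **COARSE
            )
            crit = hs.critical_acceleration(hs.recovery_curve(spec, 600.0))
            peaks.append(crit.e_max)
            crits.append(crit.acceleration_g)
        assert peaks[0] < peaks[1] < peaks[2]
        assert crits[0] < crits[2]


class TestCriticalAcceleration:
    def test_exact_on_synthetic_parabola(self):
        a = np.arange(100.0, 1501.0, 100.0)
        y = -((a - 640.0) ** 2)
        curve = pd.DataFrame({"a_c_g": a, "E_PLT_mean": y})
        crit = hs.critical_acceleration(curve)
        assert crit.acceleration_g == pytest.approx(640.0, abs=1e-9)
        assert not crit.tie and not crit.at_edge

    def test_flat_curve_returns_leftmost_with_tie_flag(self):
        a = np.arange(100.0, 601.0, 100.0)
        curve = pd.DataFrame({"a_c_g": a, "E_PLT_mean": np.ones_like(a)})
        crit = hs.critical_acceleration(curve)
        assert crit.acceleration_g == 100.0
        assert crit.tie

    def test_too_few_points_rejected(self):
        curve = pd.DataFrame({"a_c_g": [1.0, 2.0], "E_PLT_mean": [0.1, 0.2]})
        with pytest.raises(Exception):
            hs.critical_acceleration(curve)


class TestPolarCurve:
    def test_pairs_collapse_across_spin_times(self):
        """(E_plas, E_PLT) pairs from different spin times fall on one
        curve: both quantities depend on the protocol only through the
        product of time and acceleration."""
        spec = SweepSpec(include_wbc=False, **COARSE)
        table = hs.polar_curve(spec, [120.0, 900.0])
        short = table[table.t_c_min == 2.0].sort_values("E_plas_mean")
        long = table[table.t_c_min == 15.0].sort_values("E_plas_mean")
        lo = max(short.E_plas_mean.min(), long.E_plas_mean.min())
        hi = min(short.E_plas_mean.max(), long.E_plas_mean.max())
        xs = np.linspace(lo, hi, 30)
        y_short = np.interp(xs, short.E_plas_mean, short.E_PLT_mean)
        y_long = np.interp(xs, long.E_plas_mean, long.E_PLT_mean)
        assert np.max(np.abs(y_short - y_long)) < 0.02

    def test_initial_rise_is_near_linear(self):
        """Away from the peak itself, E_PLT grows almost linearly with
        E_plas on the rising branch."""
        spec = SweepSpec(
            include_wbc=False, n_cells=100,
            acceleration_grid=np.arange(100.0, 1501.0, 20.0),
        )
        curve = hs.recovery_curve(spec, 600.0)
        y = curve["E_PLT_mean"].to_numpy()
        x = curve["E_plas_mean"].to_numpy()
        i = int(np.argmax(y))
        rising = y[: i + 1] <= 0.85 * y[i]
        r = np.corrcoef(x[: i + 1][rising], y[: i + 1][rising])[0, 1]
        assert r > 0.99

    def test_single_protocol_single_point(self):
        spec = SweepSpec(
            include_wbc=False, n_cells=100,
            acceleration_grid=np.array([500.0]),
        )
        table = hs.polar_curve(spec, [600.0])
        assert len(table) == 1


class TestSensitivityBudget:
    def test_gain_minus_loss_matches_product_rule(self):
        """d(ratio * E_plas)/da_c must equal gain - loss numerically."""
        spec = SweepSpec(include_wbc=False, **COARSE)
        budget = hs.sensitivity_budget(spec, 600.0, 0.52)
        t = budget.table
        unclipped = t["ratio"] * t["E_plas"]
        direct = np.gradient(unclipped.to_numpy(), t["a_c_g"].to_numpy())
        combined = (t["gain_term"] - t["loss_term"]).to_numpy()
        # the tolerance reflects the central-difference error on the
        # cell-quantised E_plas curve; the terms themselves are ~2e-3
        np.testing.assert_allclose(direct, combined, atol=1.5e-4)

    def test_balance_point_sits_at_the_recovery_peak(self):
        spec = SweepSpec(
            include_wbc=False, n_cells=100,
            acceleration_grid=np.arange(100.0, 1501.0, 50.0),
        )
        budget = hs.sensitivity_budget(spec, 600.0, 0.52)
        assert budget.balance_ac is not None
        t = budget.table
        unclipped = (t["ratio"] * t["E_plas"]).to_numpy()
        a_peak = t["a_c_g"].to_numpy()[np.argmax(unclipped)]
        assert abs(budget.balance_ac - a_peak) <= 50.0 + 1e-9

    def test_zero_slope_means_no_loss_and_no_balance(self):
        spec = SweepSpec(
            include_wbc=False,
            coefficients=hs.CorrelationCoefficients(c1=0.0, c2=0.5128),
            **COARSE,
        )
        budget = hs.sensitivity_budget(spec, 600.0, 0.45)
        assert np.all(budget.table["loss_term"] == 0.0)
        assert budget.balance_ac is None


class TestGeometryCrossing:
    def test_identical_curves_have_no_crossing(self, curve_10min):
        assert hs.geometry_crossing(curve_10min, curve_10min) is None

    def test_flat_beats_conical_before_the_crossing(self):
        spec_f = SweepSpec(hematocrit_set=(0.52,), include_wbc=False, **COARSE)
        spec_c = SweepSpec(
            geometry=hs.TubeGeometry.conical(), hematocrit_set=(0.52,),
            include_wbc=False, **COARSE,
        )
        flat = hs.recovery_curve(spec_f, 600.0)
        con = hs.recovery_curve(spec_c, 600.0)
        cross = hs.geometry_crossing(flat, con, "E_PLT_He0.52")
        assert cross is not None
        before = flat["a_c_g"] < cross - 100.0
        assert np.all(
            flat.loc[before, "E_PLT_He0.52"].to_numpy()
            >= con.loc[before, "E_PLT_He0.52"].to_numpy()
        )


class TestOptimizationMap:
    def test_single_cell_map(self):
        spec = SweepSpec(
            include_wbc=False, n_cells=100, time_grid_min=(10,),
            acceleration_grid=np.array([500.0]),
        )
        omap = hs.optimization_map(spec)
        assert omap.e_plt.shape == (1, 1)

    def test_map_grid_matches_direct_curve(self):
        spec = SweepSpec(include_wbc=False, time_grid_min=(5, 10), **COARSE)
        omap = hs.optimization_map(spec)
        curve = hs.recovery_curve(spec, 600.0)
        np.testing.assert_allclose(
            omap.e_plt[1], curve["E_PLT_mean"].to_numpy(), atol=1e-12
        )
        q = omap.query(600.0, 500.0)
        assert q["E_PLT"] == pytest.approx(
            float(curve.loc[curve.a_c_g == 500.0, "E_PLT_mean"].iloc[0])
        )

    def test_operating_points_are_feasible_grid_points(self):
        spec = SweepSpec(time_grid_min=(2, 10, 15), **COARSE)
        omap = hs.optimization_map(spec)
        pts = omap.operating_points(target_e_plt=0.75)
        assert set(pts) == {"time_efficient", "integrity_preserving", "trade_off"}
        for p in pts.values():
            assert p["E_PLT"] >= 0.75


class TestWbcVersusPlatelet:
    def test_wbc_peaks_at_lower_acceleration_than_platelets(self):
        """White cells settle on a slower velocity scale, so their
        recovery peaks earlier in acceleration."""
        spec = SweepSpec(hematocrit_set=(0.45,), c_w_set=(5e-3,), **COARSE)
        curve = hs.recovery_curve(spec, 600.0)
        crit_plt = hs.critical_acceleration(curve, "E_PLT_He0.45")
        crit_wbc = hs.critical_acceleration(curve, "E_WBC_He0.45")
        assert crit_wbc.acceleration_g < crit_plt.acceleration_g

    def test_wbc_recovery_scale_is_tens_of_percent_at_most(self):
        spec = SweepSpec(**COARSE)
        curve = hs.recovery_curve(spec, 600.0)
        assert 0.0 < curve["E_WBC_mean"].max() < 0.5
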