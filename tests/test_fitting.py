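"""Estimation: noiseless self-consistency, identifiability guards,
bootstrap contracts and model comparison."""

import numpy as np
import pytest

import ribokin as rk
from ribokin.data import BindingDataset, InhibitionDataset, VelocitySeries
from ribokin.errors import DomainError, IdentifiabilityError
from ribokin.models import fraction_bound, percent_activity


def _binding_data(kd, grid=(0.3, 0.6, 1.2, 2.4, 4.8, 9.6)):
    p = np.asarray(grid, dtype=float)
    return BindingDataset(p, fraction_bound(p, rk.BindingParams(kd_app=kd)))


def _inhibition_data(ic50, grid=None):
    i = np.geomspace(1e-3, 10, 10) if grid is None else np.asarray(grid, dtype=float)
    return InhibitionDataset(i, percent_activity(i, rk.InhibitionCurveParams(ic50=ic50)))


class TestBindingFit:
    @pytest.mark.parametrize("kd", [1.39, 3.0])
    def test_noiseless_recovery(self, kd):
        res = rk.fit_binding_isotherm(_binding_data(kd))
        assert res.converged
        assert res.params["kd_app"] == pytest.approx(kd, rel=1e-6)

    def test_two_points_exact_interpolation(self):
        res = rk.fit_binding_isotherm(_binding_data(2.0, grid=(1.0, 4.0)))
        assert res.params["kd_app"] == pytest.approx(2.0, rel=1e-8)
        assert res.rss == pytest.approx(0.0, abs=1e-12)

    def test_zero_signal_rejected(self):
        with pytest.raises(IdentifiabilityError):
            rk.fit_binding_isotherm(BindingDataset([1, 2, 4], [0, 0, 0]))

    def test_saturated_titration_rejected(self):
        with pytest.raises(IdentifiabilityError):
            rk.fit_binding_isotherm(BindingDataset([4, 8, 16], [99.0, 99.5, 99.8]))


class TestInhibitionFit:
    @pytest.mark.parametrize("ic50", [0.033, 4.0])
    def test_noiseless_recovery(self, ic50):
        res = rk.fit_inhibition_curve(_inhibition_data(ic50))
        assert res.converged
        assert res.params["ic50"] == pytest.approx(ic50, rel=1e-6)

    def test_fitted_curve_starts_at_full_activity(self):
        res = rk.fit_inhibition_curve(_inhibition_data(0.033))
        ic50 = res.params["ic50"]
        assert 100.0 * ic50 / (0.0 + ic50) == pytest.approx(100.0)

    def test_flat_data_rejected(self):
        with pytest.raises(IdentifiabilityError):
            rk.fit_inhibition_curve(InhibitionDataset([0.01, 0.1, 1], [100, 100, 100]))


class TestSaturationFit:
    def test_noiseless_michaelis_menten_exact(self):
        s = np.geomspace(5, 500, 8)
        ser = VelocitySeries(0.0, s, 1.0 * s / (50.0 + s))
        res = rk.fit_saturation(ser, model="michaelis_menten")
        assert res.params["vmax"] == pytest.approx(1.0, rel=1e-6)
        assert res.params["km"] == pytest.approx(50.0, rel=1e-6)

    def test_noiseless_substrate_inhibition_recovery(self, truth_params, noiseless_grid_series):
        base = noiseless_grid_series[0]
        res = rk.fit_saturation(base, model="eq3")
        for name, true in (("vmax", 1.0), ("km", 50.0), ("ki_thf", 200.0)):
            assert res.params[name] == pytest.approx(true, rel=1e-4)

    def test_plain_mm_fit_underestimates_vmax_on_inhibited_data(self, noiseless_grid_series):
        base = noiseless_grid_series[0]
        res = rk.fit_saturation(base, model="michaelis_menten")
        assert res.params["vmax"] < 1.0  # the declining tail drags Vmax down

    def test_design_without_postoptimum_points_warns(self, truth_params):
        s = np.array([5.0, 10.0, 20.0, 40.0, 80.0])  # optimum at 100
        v = rk.velocity_substrate_inhibition(s, truth_params)
        res = rk.fit_saturation(VelocitySeries(0.0, s, v), model="eq3")
        assert any("optimum" in w for w in res.warnings)


class TestGlobalFit:
    def test_noiseless_recovery_of_all_five_parameters(self, noiseless_grid_series):
        res = rk.fit_global(noiseless_grid_series, model="eq4")
        assert res.converged
        truth = {"vmax": 1.0, "km": 50.0, "ki_thf": 200.0, "ki": 0.031, "alpha": 18.8}
        for name, val in truth.items():
            assert res.params[name] == pytest.approx(val, rel=1e-3), name

    def test_multistart_lands_on_same_optimum(self, noisy_grid_series):
        single = rk.fit_global(noisy_grid_series, model="eq4")
        multi = rk.fit_global(noisy_grid_series, model="eq4", multistart=True)
        assert multi.rss == pytest.approx(single.rss, rel=1e-6)
        assert multi.params["ki"] == pytest.approx(single.params["ki"], rel=1e-4)

    def test_alpha_fixed_to_one_degenerates_and_flags_ki(self, noiseless_grid_series):
        res = rk.fit_global(noiseless_grid_series, model="eq4", fixed={"alpha": 1.0})
        # with alpha = 1 the inhibitor drops out of the rate law entirely
        assert any("ki" in w and "unidentifiable" in w for w in res.warnings)

    def test_too_few_inhibitor_levels_rejected(self, noiseless_grid_series):
        with pytest.raises(IdentifiabilityError):
            rk.fit_global(noiseless_grid_series[:2], model="eq4")

    def test_unit_rescaling_invariance(self, noisy_grid_series):
        """Expressing every concentration in mM instead of uM rescales the
        concentration-valued estimates by exactly 1e-3."""
        res_um = rk.fit_global(noisy_grid_series, model="eq4")
        scaled = [VelocitySeries(s.inhibitor_conc / 1e3, s.substrate_conc / 1e3,
                                 s.velocity, s.replicate) for s in noisy_grid_series]
        res_mm = rk.fit_global(scaled, model="eq4")
        for name in ("km", "ki_thf", "ki"):
            assert res_mm.params[name] * 1e3 == pytest.approx(res_um.params[name], rel=1e-4)
        for name in ("vmax", "alpha"):
            assert res_mm.params[name] == pytest.approx(res_um.params[name], rel=1e-4)


class TestBootstrap:
    def test_same_seed_identical_intervals(self, truth_params):
        design = rk.builtin_design("protein-titration")
        data = rk.generate_binding_dataset(design, rk.BindingParams(kd_app=1.39), seed=5)
        fit = rk.fit_binding_isotherm(data)
        a = rk.bootstrap_ci(fit, data, n_resamples=150, seed=9)
        b = rk.bootstrap_ci(fit, data, n_resamples=150, seed=9)
        assert a.ci == b.ci

    def test_noiseless_data_degenerate_intervals(self):
        data = _binding_data(1.39)
        fit = rk.fit_binding_isotherm(data)
        res = rk.bootstrap_ci(fit, data, n_resamples=120, seed=1)
        lo, hi = res.ci["kd_app"]
        assert hi - lo == pytest.approx(0.0, abs=1e-6)

    def test_small_resample_count_warns(self):
        data = _binding_data(1.39)
        fit = rk.fit_binding_isotherm(data)
        res = rk.bootstrap_ci(fit, data, n_resamples=50, seed=2)
        assert any("unreliable" in w for w in res.warnings)

    def test_more_data_shrinks_intervals(self, truth_params):
        """Median interval width decreases when the design is replicated."""
        widths = []
        for reps in (2, 8):
            design = rk.builtin_design("protein-titration", replicates=reps, cv=0.05)
            ws = []
            for seed in range(8):
                data = rk.generate_binding_dataset(design, rk.BindingParams(kd_app=1.39), seed=seed)
                fit = rk.fit_binding_isotherm(data)
                res = rk.bootstrap_ci(fit, data, n_resamples=150, seed=seed)
                lo, hi = res.ci["kd_app"]
                ws.append(hi - lo)
            widths.append(np.median(ws))
        assert widths[1] < widths[0]


class TestModelComparison:
    def test_identical_fits_tie(self, noiseless_grid_series):
        a = rk.fit_global(noiseless_grid_series, model="eq4")
        b = rk.fit_global(noiseless_grid_series, model="eq4")
        cmp = rk.compare_models([a, b])
        assert cmp.preferred == "tie"

    def test_mismatched_data_rejected(self, noiseless_grid_series, noisy_grid_series):
        a = rk.fit_global(noiseless_grid_series, model="eq4")
        b = rk.fit_global(noisy_grid_series, model="eq4")
        with pytest.raises(DomainError):
            rk.compare_models([a, b])

    def test_hyperbolic_truth_prefers_full_model(self, noisy_grid_series):
        full = rk.fit_global(noisy_grid_series, model="eq4")
        reduced = rk.fit_global(noisy_grid_series, model="pure_competitive")
        cmp = rk.compare_models([full, reduced])
        assert cmp.preferred == "eq4"
        assert reduced.rss >= full.rss  # nested-model RSS ordering
        ft = [t for t in cmp.f_tests if t["full"] == "eq4"][0]
        assert ft["p"] < 0.01

    def test_competitive_truth_never_overfits(self, truth_params):
        """Simulated pure-competitive data: the hyperbolic model is never
        preferred; the verdict is the reduced model or a boundary tie."""
        design = rk.builtin_design("thf-inhibitor-grid")
        eq4_wins = 0
        for seed in range(20):
            series = rk.generate_velocity_matrix(design, truth_params, seed=seed,
                                                 variant="pure_competitive")
            cmp = rk.compare_models([rk.fit_global(series, model="eq4"),
                                     rk.fit_global(series, model="pure_competitive")])
            eq4_wins += (cmp.preferred == "eq4")
        assert eq4_wins <= 1
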