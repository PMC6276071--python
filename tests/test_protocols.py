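"""Protocol drivers, Michaelis-Menten fitting, Haldane ratios,
counterflow and carrier calibration."""

import numpy as np
import pytest

from portersim import (
    CarrierParams,
    ConfigurationError,
    FluxCurve,
    MultisiteParams,
    Protocol,
    build_asymmetric_carrier,
    build_multisite_chain,
    build_symmetric_carrier,
    calibrate_carrier,
    carrier_observables,
    fit_michaelis_menten,
    haldane_ratio,
    random_balanced_carrier,
    run_counterflow,
    run_equilibrium_exchange,
    run_zero_trans,
)

from conftest import SMALL_GRID, oracle_net_influx, rapid_equilibrium_forms


class TestProtocolValidation:
    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            Protocol("zero_trans_influx", (1.0, 1.0, 2.0))

    def test_grid_must_be_positive(self):
        with pytest.raises(ValueError):
            Protocol("zero_trans_influx", (-1.0, 2.0))

    def test_unknown_type(self):
        with pytest.raises(ValueError):
            Protocol("infinite_cis")


class TestZeroTrans:
    def test_matches_independent_oracle(self):
        """Zero-trans curve values equal a hand-built rate-matrix
        solve of the same carrier."""
        p = CarrierParams(kd_out=3.0, kd_in=30.0, b_out_in=1.0, b_in_out=None,
                          f_out_in=10.0, f_in_out=10.0, auto_close=True)
        curve = run_zero_trans(build_asymmetric_carrier(p), "influx", SMALL_GRID)
        expected = [oracle_net_influx(p, c, 0.0) for c in SMALL_GRID]
        assert curve.fluxes == pytest.approx(expected, rel=1e-10)

    def test_monotone_saturation(self):
        for model in (build_symmetric_carrier(), build_asymmetric_carrier(),
                      build_multisite_chain()):
            curve = run_zero_trans(model, "influx", SMALL_GRID)
            assert curve.fluxes[0] < curve.fluxes[-1]
            assert np.all(np.diff(curve.fluxes) > 0)

    def test_flux_vanishes_at_zero_concentration(self, asym_model):
        grid = (1e-6, 1e-4, 1e-2, 1.0, 100.0)
        curve = run_zero_trans(asym_model, "influx", grid)
        assert curve.fluxes[0] < 1e-5
        assert np.all(curve.fluxes >= 0)


class TestMichaelisMentenFit:
    def test_exact_data_recovered(self):
        grid = np.geomspace(0.05, 500.0, 12)
        curve = FluxCurve(Protocol("zero_trans_influx", tuple(grid)),
                          grid, 2.0 * grid / (5.0 + grid))
        fit = fit_michaelis_menten(curve)
        assert fit.converged
        assert fit.km == pytest.approx(5.0, rel=1e-10)
        assert fit.vmax == pytest.approx(2.0, rel=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_requires_five_points(self):
        grid = (0.1, 1.0, 10.0, 100.0)
        curve = FluxCurve(Protocol("zero_trans_influx", grid),
                          np.array(grid), np.ones(4))
        with pytest.raises(ValueError, match="at least 5"):
            fit_michaelis_menten(curve)

    def test_requires_wide_range(self):
        grid = tuple(np.linspace(1.0, 10.0, 8))
        curve = FluxCurve(Protocol("zero_trans_influx", grid),
                          np.array(grid), np.ones(8))
        with pytest.raises(ValueError, match="100-fold"):
            fit_michaelis_menten(curve)

    def test_rapid_equilibrium_km_closed_form(self):
        """With fast binding, the fitted influx Km matches the
        algebraic rapid-equilibrium expression within 1%."""
        p = CarrierParams(kd_out=3.0, kd_in=30.0, b_out_in=1.0, b_in_out=None,
                          f_out_in=10.0, f_in_out=10.0, k_on=1e5, auto_close=True)
        summary = carrier_observables(build_asymmetric_carrier(p))
        forms = rapid_equilibrium_forms(p)
        assert summary.influx.km == pytest.approx(forms["km_influx"], rel=0.01)
        assert summary.influx.vmax == pytest.approx(forms["vm_influx"], rel=0.01)
        assert summary.efflux.vmax == pytest.approx(forms["vm_efflux"], rel=0.01)


class TestEquilibriumExchange:
    def test_exchange_symmetry_on_balanced_model(self, asym_model):
        ee_in = run_equilibrium_exchange(asym_model, "influx", SMALL_GRID)
        ee_out = run_equilibrium_exchange(asym_model, "efflux", SMALL_GRID)
        assert ee_in.fluxes == pytest.approx(ee_out.fluxes, rel=1e-8)

    @pytest.mark.parametrize("f,b", [(10.0, 1.0), (0.5, 1.0), (2.0, 2.0)])
    def test_accelerated_exchange_iff_loaded_transit_faster(self, f, b):
        """Exchange Vmax exceeds net-flux Vmax exactly when liganded
        transit outpaces the empty-carrier return, with the ratio
        matching the rapid-equilibrium closed form (b+f)/(2b)."""
        p = CarrierParams(kd_out=3.0, kd_in=3.0, b_out_in=b, b_in_out=b,
                          f_out_in=f, f_in_out=f, k_on=1e5)
        s = carrier_observables(build_symmetric_carrier(p))
        ratio = s.exchange_influx.vmax / s.influx.vmax
        assert ratio == pytest.approx((b + f) / (2 * b), rel=0.01)
        assert (ratio > 1) == (f > b)


class TestHaldane:
    def test_balanced_carrier_haldane_is_one(self, asym_model):
        s = carrier_observables(asym_model)
        assert haldane_ratio(s.influx, s.efflux) == pytest.approx(1.0, abs=1e-6)

    def test_random_balanced_carriers(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            _, model = random_balanced_carrier(rng)
            s = carrier_observables(model)
            assert haldane_ratio(s.influx, s.efflux) == pytest.approx(1.0, abs=1e-4)

    def test_rejects_failed_fits(self):
        from portersim import SaturationFit
        good = SaturationFit(1.0, 1.0, 0.0, 0.0, 0.0, True, 10)
        bad = SaturationFit(np.nan, np.nan, np.nan, np.nan, np.nan, False, 10)
        with pytest.raises(ValueError):
            haldane_ratio(good, bad)


class TestCounterflow:
    def test_carrier_overshoot(self, sym_model):
        """Preloaded unlabelled ligand inside drives the inside label
        concentration transiently above the outside level."""
        res = run_counterflow(sym_model, inside_load=100.0, tracer_outside=1.0,
                              t_grid=np.linspace(0.0, 300.0, 300),
                              inside_capacity=1.0)
        assert res.overshoot > 1.5
        assert res.label_ratio[-1] < res.overshoot  # decays after the peak

    def test_exchange_site_chain_overshoot(self):
        model = build_multisite_chain(MultisiteParams(exchange_site=True))
        res = run_counterflow(model, inside_load=100.0, tracer_outside=1.0,
                              t_grid=np.linspace(0.0, 60.0, 300),
                              inside_capacity=1.0)
        assert res.overshoot > 1.05

    def test_plain_chain_has_no_overshoot(self):
        res = run_counterflow(build_multisite_chain(), inside_load=100.0,
                              tracer_outside=1.0,
                              t_grid=np.linspace(0.0, 60.0, 200),
                              inside_capacity=1.0)
        assert res.overshoot <= 1.0 + 1e-6

    def test_no_preload_no_overshoot(self, sym_model):
        res = run_counterflow(sym_model, inside_load=0.0, tracer_outside=1.0,
                              t_grid=np.linspace(0.0, 100.0, 200),
                              inside_capacity=1.0)
        assert res.overshoot <= 1.0 + 1e-9
        assert np.all(np.diff(res.label_ratio) >= -1e-9)

    def test_clamped_inside_rejected(self, sym_model):
        with pytest.raises(ConfigurationError, match="finite inside"):
            run_counterflow(sym_model, t_grid=np.linspace(0.0, 1.0, 5))


class TestCalibration:
    def test_self_consistency(self):
        """Observables generated from a known carrier are recovered by
        the calibration with negligible residual."""
        truth = CarrierParams(kd_out=2.0, kd_in=24.0, b_out_in=1.0, b_in_out=None,
                              f_out_in=6.0, f_in_out=11.0, k_on=800.0,
                              auto_close=True)
        obs = carrier_observables(build_asymmetric_carrier(truth),
                                  SMALL_GRID).observables()
        targets = {k: obs[k] for k in
                   ("km_net_influx", "km_exchange_influx",
                    "vm_net_efflux_over_influx")}
        cal = calibrate_carrier(targets, n_starts=4, seed=3, grid=SMALL_GRID,
                                pin_kd_ratio=12.0)
        assert cal.success
        for key in targets:
            assert abs(cal.residuals[key]) < 1e-6

    def test_reference_calibration_hits_independent_targets(self, reference_calibration):
        cal = reference_calibration
        obs = cal.regenerated()
        assert obs["km_net_influx"] == pytest.approx(1.0, rel=1e-4)
        assert obs["km_exchange_influx"] == pytest.approx(5.0, rel=1e-4)
        assert obs["vm_net_efflux_over_influx"] == pytest.approx(3.9, rel=1e-4)

    def test_reference_model_shows_glut1_asymmetry_signature(self, reference_calibration):
        """The calibrated carrier reproduces the characteristic
        asymmetry pattern: Km and Vm for net influx below those for net
        efflux, exchange Vm and Km above net influx."""
        s = reference_calibration.summary
        assert s.influx.km < s.efflux.km
        assert s.influx.vmax < s.efflux.vmax
        assert s.exchange_influx.vmax > s.influx.vmax
        assert s.exchange_influx.km > s.influx.km

    def test_vm_km_slope_identity(self, reference_calibration):
        """The structural identity behind the calibration design: one
        shared Vmax/Km slope across zero-trans influx, efflux and
        equilibrium exchange."""
        s = reference_calibration.summary
        slopes = [s.influx.specificity, s.efflux.specificity,
                  s.exchange_influx.specificity]
        assert slopes[1] == pytest.approx(slopes[0], rel=1e-6)
        assert slopes[2] == pytest.approx(slopes[0], rel=1e-4)

    def test_unknown_fit_key_rejected(self):
        with pytest.raises(ValueError, match="fit_keys"):
            calibrate_carrier({"km_net_influx": 1.0}, fit_keys=("bogus",))
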