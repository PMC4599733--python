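"""Estimation procedures: Arrhenius NLS, shape WLS, maintenance conversion,
threshold/coupler calibration, covariation recovery, field food level."""

import numpy as np
import pandas as pd
import pytest

import debstar as d
from debstar.calibration import (DEFAULT_ANCHORS, ObservationSet,
                                 calibrate_stage_thresholds,
                                 calibrate_wet_coupler, covariation_fit,
                                 estimate_field_f, fit_arrhenius,
                                 fit_shape_coefficient, mean_relative_error,
                                 pm_from_starved_respiration,
                                 predict_zero_variate)
from debstar.lifecycle import EstimationError
from debstar.params import ParameterError
from debstar.validate import packaged_observations, validate_targets


# ---------------------------------------------------------------------------
# Arrhenius fit
# ---------------------------------------------------------------------------

def arrhenius_series(arr, n=12):
    T = np.linspace(arr.TL - 2.0, arr.TH + 3.0, n)
    r = d.temperature_correction(T, arr)
    return T, r / r.max()


def test_arrhenius_fit_recovers_slope(params_arr):
    """Noise-free series from the packaged response: TA back within 1%."""
    _, arr = params_arr
    T, r = arrhenius_series(arr)
    fitted, res = fit_arrhenius(T, r)
    assert fitted.TA == pytest.approx(arr.TA, rel=0.01)
    assert res.mre < 1e-6  # exact model class, no noise


def test_arrhenius_fitted_curve_peaks_near_upper_boundary(params_arr):
    _, arr = params_arr
    T, r = arrhenius_series(arr)
    fitted, _ = fit_arrhenius(T, r)
    grid = np.linspace(T.min(), T.max(), 400)
    curve = d.temperature_correction(grid, fitted)
    T_peak = grid[np.argmax(curve)]
    assert fitted.TH - 5.0 < T_peak <= fitted.TH + 0.5
    assert curve[-1] < curve.max()


def test_arrhenius_fit_needs_enough_points(params_arr):
    _, arr = params_arr
    T, r = arrhenius_series(arr, n=5)
    with pytest.raises(ParameterError, match="at least 6"):
        fit_arrhenius(T, r)


# ---------------------------------------------------------------------------
# shape coefficient
# ---------------------------------------------------------------------------

def test_shape_fit_exact_on_cube_law(params_arr):
    L = np.linspace(0.5, 7.0, 9)
    delta, sd = fit_shape_coefficient(L, (0.57 * L) ** 3)
    assert delta == pytest.approx(0.57, abs=1e-12)
    assert sd == pytest.approx(0.0, abs=1e-9)


def test_shape_fit_single_pair_closed_form():
    delta, _ = fit_shape_coefficient([4.0], [12.0])
    assert delta == pytest.approx(12.0 ** (1 / 3) / 4.0, rel=1e-12)


def test_shape_fit_monte_carlo_band():
    """10% multiplicative noise around delta = 0.63: recovery within 0.07."""
    rng = np.random.default_rng(11)
    L = np.linspace(1.0, 7.0, 15)
    clean = (0.63 * L) ** 3
    deltas = [fit_shape_coefficient(L, clean * rng.lognormal(0, 0.1, len(L)))[0]
              for _ in range(100)]
    assert abs(np.mean(deltas) - 0.63) < 0.02
    assert np.percentile(np.abs(np.array(deltas) - 0.63), 95) < 0.07


def test_shape_fit_rejects_degenerate_weights():
    with pytest.raises(ParameterError, match="weights"):
        fit_shape_coefficient([1.0, 2.0], [0.2, 1.5], weights=[0.0, 0.0])


# ---------------------------------------------------------------------------
# maintenance from starved respiration
# ---------------------------------------------------------------------------

def test_starved_respiration_conversion_matches_published_pair():
    assert pm_from_starved_respiration(558.0) == pytest.approx(7.564, abs=1e-9)


def test_starved_respiration_is_linear_and_guarded():
    assert pm_from_starved_respiration(0.0) == 0.0
    assert (pm_from_starved_respiration(200.0)
            == pytest.approx(2 * pm_from_starved_respiration(100.0)))
    with pytest.raises(ParameterError):
        pm_from_starved_respiration(-1.0)


# ---------------------------------------------------------------------------
# stage thresholds, acceleration, wet coupler
# ---------------------------------------------------------------------------

def test_threshold_calibration_fixed_point(calibrated, env_lab):
    """Re-simulating with the calibrated thresholds returns the anchors."""
    p, arr = calibrated
    pred = predict_zero_variate(p, arr, ["L_b", "L_j", "L_p"])
    assert pred["L_b"] == pytest.approx(DEFAULT_ANCHORS["L_b"], rel=0.01)
    assert pred["L_p"] == pytest.approx(DEFAULT_ANCHORS["L_p"], rel=0.01)
    # L_j anchor is derived from the maximum length through the closed form
    s_M_expected = (p.delta_M * DEFAULT_ANCHORS["L_i"]
                    / (p.kappa * p.pAm / p.pM_vol))
    assert p.s_M == pytest.approx(s_M_expected, rel=1e-9)
    assert pred["L_j"] == pytest.approx(s_M_expected * DEFAULT_ANCHORS["L_b"],
                                        rel=0.01)


def test_acceleration_factor_near_published_ratio(calibrated):
    p, _ = calibrated
    assert p.s_M == pytest.approx(5.08, abs=0.05)


def test_higher_puberty_anchor_raises_threshold(params_arr):
    p, arr = params_arr
    lo = calibrate_stage_thresholds(p.evolve(d_dw=0.1), arr, {"L_p": 2.0})
    hi = calibrate_stage_thresholds(p.evolve(d_dw=0.1), arr, {"L_p": 3.0})
    assert hi.EHp > lo.EHp


def test_unreachable_anchor_reported(params_arr):
    p, arr = params_arr
    with pytest.raises(EstimationError, match="not reachable"):
        calibrate_stage_thresholds(p.evolve(d_dw=0.1), arr, {"L_p": 9.0})


def test_wet_coupler_solves_anchor_and_field_value(params_arr):
    p, _ = params_arr
    d_dw = calibrate_wet_coupler(p, anchor_PI=0.30)
    assert d_dw == pytest.approx(0.10, abs=0.005)
    # equilibrium PI at field food with the coupler from the f=1 anchor
    x = (p.rho_E / d_dw) * 0.8 * p.Em
    assert x / (1.0 + x) == pytest.approx(0.25, abs=0.01)
    # vanishing anchor sends the coupler to infinity
    assert calibrate_wet_coupler(p, anchor_PI=1e-9) > 1e6
    with pytest.raises(ParameterError):
        calibrate_wet_coupler(p, anchor_PI=1.2)


def test_thresholds_independent_of_calibration_temperature(params_arr):
    """A thermal correction rescales time, not the state-space path."""
    p, arr = params_arr
    p271 = calibrate_stage_thresholds(p.evolve(d_dw=0.1), arr, T=271.5)
    p285 = calibrate_stage_thresholds(p.evolve(d_dw=0.1), arr, T=285.0)
    assert p285.EHb == pytest.approx(p271.EHb, rel=1e-4)
    assert p285.EHp == pytest.approx(p271.EHp, rel=1e-4)


# ---------------------------------------------------------------------------
# covariation fit and MRE scoring
# ---------------------------------------------------------------------------

def _self_consistent_obs(p, arr, names):
    pred = predict_zero_variate(p, arr, names)
    return ObservationSet(zero_variate=pd.DataFrame({
        "name": names, "value": [pred[n] for n in names],
        "unit": "x", "temp_K": 271.5, "weight": 1.0}))


def test_covariation_recovers_perturbed_parameters(calibrated):
    """Self-consistency: obs from known parameters, start off by ~10%."""
    p, arr = calibrated
    names = ["L_i", "W_i", "PI", "Wd_0"]
    obs = _self_consistent_obs(p, arr, names)
    start = p.evolve(pAm=p.pAm * 1.08, pM_vol=p.pM_vol * 0.93,
                     kappa=min(p.kappa * 1.05, 0.99))
    fitted, res = covariation_fit(obs, start, arr,
                                  free=["pAm", "pM_vol", "kappa"])
    for name in ("pAm", "pM_vol", "kappa"):
        assert res.estimates[name] == pytest.approx(getattr(p, name), rel=0.02)
    assert res.mre < 0.01


def test_covariation_start_at_optimum_keeps_zero_loss(calibrated):
    p, arr = calibrated
    obs = _self_consistent_obs(p, arr, ["L_i", "PI"])
    fitted, res = covariation_fit(obs, p, arr, free=["pAm"], maxiter=200)
    assert res.mre < 1e-6
    assert res.estimates["pAm"] == pytest.approx(p.pAm, rel=1e-4)


def test_zero_weight_equivalent_to_removal(calibrated):
    """A zero-weight observation has no influence on the estimates."""
    p, arr = calibrated
    names = ["L_i", "PI", "Wd_0"]
    obs_full = _self_consistent_obs(p, arr, names)
    obs_zero = _self_consistent_obs(p, arr, names)
    obs_zero.zero_variate.loc[obs_zero.zero_variate.name == "Wd_0",
                              ["value", "weight"]] = [99.0, 0.0]
    obs_drop = _self_consistent_obs(p, arr, ["L_i", "PI"])
    start = p.evolve(pAm=p.pAm * 1.05)
    est_zero = covariation_fit(obs_zero, start, arr, free=["pAm"])[1].estimates
    est_drop = covariation_fit(obs_drop, start, arr, free=["pAm"])[1].estimates
    assert est_zero["pAm"] == pytest.approx(est_drop["pAm"], rel=1e-6)


def test_unknown_observable_rejected(calibrated):
    p, arr = calibrated
    obs = ObservationSet(zero_variate=pd.DataFrame({
        "name": ["no_such_thing"], "value": [1.0], "unit": "x",
        "temp_K": [271.5], "weight": [1.0]}))
    with pytest.raises(ParameterError, match="no forward prediction"):
        covariation_fit(obs, p, arr, free=["pAm"])


def test_mean_relative_error_definition():
    assert mean_relative_error([2.0, 4.0], [1.0, 5.0]) == pytest.approx(
        (0.5 + 0.25) / 2)


def test_packaged_observation_errors_close_to_reference_fit(calibrated):
    """Forward predictions score near the reference goodness of fit.

    Per-row relative errors against the packaged single-point observations
    should sit close to the residuals of the original covariation estimate
    for most rows (wet-weight convention differences allowed on a few)."""
    p, arr = calibrated
    report = validate_targets(p, arr)
    reference = {"a_b": 0.19, "a_j": 0.02, "L_b": 0.24, "L_j": 0.17,
                 "L_p": 0.08, "L_i": 0.01, "L_i_f": 0.05, "Wd_0": 0.07,
                 "W_p": 0.04, "W_i": 0.05, "W_i_f": 0.01, "GSI": 0.16,
                 "PI": 0.00}
    close = sum(abs(row.rel_error - reference[row.name_]) <= 0.05
                for row in report.rename(columns={"name": "name_"}).itertuples())
    assert close >= 10


# ---------------------------------------------------------------------------
# field functional response
# ---------------------------------------------------------------------------

def test_field_f_recovered_from_field_maximum_size(calibrated):
    p, arr = calibrated
    L_lab, _ = d.ultimate_size(p, arr, f=1.0)
    assert estimate_field_f(0.80 * L_lab, p) == pytest.approx(0.80, abs=0.02)
    assert estimate_field_f(L_lab, p) == pytest.approx(1.0, abs=0.01)


def test_field_f_linear_in_size_ratio(calibrated):
    p, arr = calibrated
    L_lab, _ = d.ultimate_size(p, arr, f=1.0)
    f1 = estimate_field_f(0.5 * L_lab, p)
    f2 = estimate_field_f(0.25 * L_lab, p)
    assert f1 == pytest.approx(2 * f2, rel=0.01)
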