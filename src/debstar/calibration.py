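"""Parameter-estimation procedures.

Covers the directly estimated parameters (Arrhenius temperature response by
nonlinear least squares, post-metamorphic shape coefficient by weighted
least squares, volume-specific maintenance from starved respiration), the
derived quantities that anchor the life cycle to observed stage sizes
(maturity thresholds, acceleration factor, wet-mass coupler), and a
simplified covariation estimation: a single Nelder-Mead minimisation of a
weighted squared-relative-error loss over zero-variate observations plus
optional pseudo-data penalties, scored by the mean absolute relative error
(MRE).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .core import OXYCALORIC_J_PER_MG_O2, temperature_correction
from .lifecycle import (EstimationError, V0_EMBRYO, _run_segment,
                        equilibrium_pR, initial_reserve, ultimate_size)
from .core import Stage
from .params import ArrheniusParams, DEBParams, Environment, ParameterError
from .reproduction import stationary_peak_gsi

__all__ = [
    "ObservationSet",
    "FitResult",
    "fit_arrhenius",
    "fit_shape_coefficient",
    "pm_from_starved_respiration",
    "calibrate_stage_thresholds",
    "calibrate_wet_coupler",
    "calibrate",
    "covariation_fit",
    "estimate_field_f",
    "predict_zero_variate",
    "mean_relative_error",
    "DEFAULT_ANCHORS",
]

#: stage-size anchors (physical cm at f = 1) used to place the maturity
#: thresholds: arm length at birth and puberty as published, and the length at
#: metamorphosis derived from the maximum length so that the closed-form
#: ultimate size is honoured (see docs/methods.md)
DEFAULT_ANCHORS = {"L_b": 0.03, "L_j": None, "L_p": 2.15, "L_i": 7.10}

PI_ANCHOR = 0.30  # equilibrium pyloric index of ad-libitum-fed animals


@dataclass
class ObservationSet:
    """Zero-variate points and uni-variate series with weights.

    ``zero_variate`` rows: (name, value, unit, temp_K, weight).
    ``uni_variate``: mapping series_id -> DataFrame(x, y, temp_K, f, weight).
    """

    zero_variate: pd.DataFrame
    uni_variate: dict[str, pd.DataFrame] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        req = {"name", "value", "unit", "temp_K", "weight"}
        if not req.issubset(self.zero_variate.columns):
            raise ParameterError(f"zero-variate table needs columns {sorted(req)}")
        if (self.zero_variate.weight < 0).any():
            raise ParameterError("weights must be >= 0")

    @classmethod
    def from_csv(cls, zero_variate_path: str | Path,
                 uni_variate_path: str | Path | None = None) -> "ObservationSet":
        zv = pd.read_csv(zero_variate_path)
        uv: dict[str, pd.DataFrame] = {}
        if uni_variate_path is not None:
            table = pd.read_csv(uni_variate_path)
            uv = {sid: g.drop(columns="series_id").reset_index(drop=True)
                  for sid, g in table.groupby("series_id")}
        return cls(zero_variate=zv, uni_variate=uv)


@dataclass
class FitResult:
    """Point estimates with uncertainties and goodness of fit."""

    estimates: dict[str, float]
    sds: dict[str, float]
    mre: float
    per_dataset_mre: dict[str, float] = dc_field(default_factory=dict)
    converged: bool = True
    n_iter: int = 0
    message: str = ""

    def __post_init__(self) -> None:
        if self.mre < 0:
            raise ParameterError("MRE cannot be negative")


def mean_relative_error(observed, predicted, weights=None) -> float:
    """Arithmetic mean of |pred - obs| / |obs| over all points.

    Zero-weight points are excluded (weights only select; the MRE itself is
    unweighted, matching its use as a goodness-of-fit score)."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    keep = np.ones_like(obs, bool) if weights is None else np.asarray(weights, float) > 0
    return float(np.mean(np.abs(pred[keep] - obs[keep]) / np.abs(obs[keep])))


# ---------------------------------------------------------------------------
# direct estimations
# ---------------------------------------------------------------------------

def _arrhenius_scaled(T, TA, TL, TH, TAL, TAH, T1):
    """Thermal response normalised to 1 at the reference temperature T1."""
    arr = ArrheniusParams(TA=TA, TL=TL, TH=TH, TAL=TAL, TAH=TAH, Tref=T1)
    return temperature_correction(np.asarray(T, float), arr)


def fit_arrhenius(
    temps_K: np.ndarray,
    scaled_rates: np.ndarray,
    start_TAL: float = 5.0e4,
    start_TAH: float = 5.0e4,
) -> tuple[ArrheniusParams, FitResult]:
    """Nonlinear least squares for the five-parameter thermal response.

    Expects rates scaled to a maximum of 1.  Start values: the Arrhenius
    slope from a log-linear regression of the scaled rate on 1/T over the
    rising branch (observations at or below the temperature of the maximum
    rate), the observed extreme temperatures for the tolerance boundaries,
    and generic boundary slopes for TAL/TAH; the reference temperature is
    free with the temperature of the maximum as its start.
    """
    T = np.asarray(temps_K, float)
    r = np.asarray(scaled_rates, float)
    if len(T) < 6:
        raise ParameterError("need at least 6 temperature points")
    if np.any(r <= 0):
        raise ParameterError("scaled rates must be positive")

    T_at_max = T[np.argmax(r)]
    rising = T <= T_at_max
    if rising.sum() >= 2:
        slope = np.polyfit(1.0 / T[rising], np.log(r[rising]), 1)[0]
        TA0 = max(-slope, 100.0)
    else:  # pragma: no cover - degenerate layout
        TA0 = 5000.0
    x0 = np.array([TA0, T.min(), T.max(), start_TAL, start_TAH, T_at_max])

    def residuals(x):
        try:
            return _arrhenius_scaled(T, *x) - r
        except ParameterError:
            return np.full_like(r, 1e6)

    lb = [100.0, T.min() - 30.0, T_at_max, 1e3, 1e3, T.min()]
    ub = [5e4, T_at_max, T.max() + 30.0, 1e7, 1e6, T.max()]
    res = optimize.least_squares(residuals, x0, bounds=(lb, ub),
                                 xtol=1e-12, ftol=1e-12, gtol=1e-12)
    if not res.success or not np.all(np.isfinite(res.x)):
        raise EstimationError(
            f"Arrhenius fit failed ({res.message}); start values were {x0}")
    names = ["TA", "TL", "TH", "TAL", "TAH", "Tref"]
    # linearised covariance; singular directions (inactive boundary terms)
    # are reported as inf rather than failing the fit
    J = res.jac
    dof = max(len(r) - len(names), 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.pinv(J.T @ J)
        sds = {n: float(math.sqrt(max(cov[i, i], 0.0))) for i, n in enumerate(names)}
    except np.linalg.LinAlgError:  # pragma: no cover
        sds = {n: math.inf for n in names}
    est = dict(zip(names, map(float, res.x)))
    fitted = _arrhenius_scaled(T, *res.x)
    out = ArrheniusParams(**est)
    return out, FitResult(estimates=est, sds=sds,
                          mre=mean_relative_error(r, fitted),
                          converged=True, n_iter=int(res.nfev), message=res.message)


def fit_shape_coefficient(
    lengths_cm: np.ndarray,
    wet_weights_g: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[float, float]:
    """Weighted least squares for the cube-law W = (delta * L)^3.

    Linear in u = delta^3, so the WLS solution is closed-form; the standard
    deviation of delta follows by the delta method.  Returns (delta, sd).
    """
    L = np.asarray(lengths_cm, float)
    W = np.asarray(wet_weights_g, float)
    if len(L) < 1 or np.any(L <= 0) or np.any(W <= 0):
        raise ParameterError("need positive length-weight pairs")
    w = np.ones_like(L) if weights is None else np.asarray(weights, float)
    if np.all(w == 0):
        raise ParameterError("all weights are zero")
    X = L ** 3
    u = float(np.sum(w * X * W) / np.sum(w * X * X))
    delta = u ** (1.0 / 3.0)
    dof = max(int(np.sum(w > 0)) - 1, 1)
    resid = W - u * X
    s2 = float(np.sum(w * resid ** 2) / dof)
    var_u = s2 / float(np.sum(w * X * X))
    sd = math.sqrt(var_u) / (3.0 * delta ** 2) if delta > 0 else math.inf
    return delta, sd


def pm_from_starved_respiration(o2_rate_ug_d_cm3: float) -> float:
    """Volume-specific maintenance (J d-1 cm-3) from the oxygen consumption
    of starved individuals (ug O2 d-1 cm-3), via the oxycaloric coefficient."""
    if o2_rate_ug_d_cm3 < 0:
        raise ParameterError("oxygen consumption rate must be >= 0")
    return o2_rate_ug_d_cm3 * 1e-3 * OXYCALORIC_J_PER_MG_O2


# ---------------------------------------------------------------------------
# life-cycle anchoring (thresholds, acceleration, wet coupler)
# ---------------------------------------------------------------------------

def calibrate_stage_thresholds(
    p: DEBParams,
    arr: ArrheniusParams,
    anchors: dict | None = None,
    T: float = 271.5,
    rtol: float = 1e-8,
) -> DEBParams:
    """Place the maturity thresholds by forward integration at f = 1.

    ``anchors`` maps physical lengths (cm): L_b at birth, L_j at
    metamorphosis, L_p at puberty; if L_j is None it is derived from the
    maximum-length anchor L_i through the closed-form ultimate size, which
    fixes the acceleration factor s_M = Lj/Lb (structural).  The egg energy
    is solved jointly so that reserve density at birth equals [Em]; the
    maturity accumulated at each anchor length becomes the threshold.
    Thresholds are temperature-independent (a thermal correction rescales
    time, not the state-space path).
    """
    anchors = {**DEFAULT_ANCHORS, **(anchors or {})}
    L_b, L_j, L_p = anchors["L_b"], anchors["L_j"], anchors["L_p"]
    if L_j is None:
        L_inf_struct = p.kappa * p.pAm / p.pM_vol  # f = 1, s_M = 1
        s_M = p.delta_M * anchors["L_i"] / L_inf_struct
        L_j = s_M * L_b
    else:
        s_M = L_j / L_b
    if not (0 < L_b < L_j and L_b < L_p):
        raise ParameterError("anchors must be positive with L_b < L_j and L_b < L_p")
    if s_M < 1:
        raise ParameterError("anchors imply an acceleration factor below 1")

    env = Environment(T=T, f=1.0)
    Lb_struct = p.delta_M_lrv * L_b
    Lj_struct = p.delta_M_lrv * L_j
    Lp_struct = p.delta_M * L_p
    if Lp_struct >= s_M * p.kappa * p.pAm / p.pM_vol:
        raise EstimationError(
            f"puberty anchor {L_p} cm is not reachable: it exceeds the "
            "ultimate structural length implied by the parameters")

    # embryo: shoot for the egg energy putting reserve density at [Em] when
    # structural length reaches the birth anchor
    E0, a_b, y_b = initial_reserve(p, arr, env, stop_kind="L",
                                   stop_value=Lb_struct, rtol=rtol)
    EHb = float(y_b[2])
    p1 = p.evolve(EHb=EHb, EHj=None, EHp=None, s_M=float(s_M), Lb_struct=Lb_struct)

    # larva with acceleration L/Lb until the metamorphosis anchor
    def hit_Lj(t, y):
        return max(y[1], 0.0) ** (1.0 / 3.0) - Lj_struct

    sol = _run_segment(tuple(y_b), Stage.LARVA, env, p1, arr, Lb_struct,
                       a_b, a_b + 5000.0, stop_event=hit_Lj, rtol=rtol)
    if not len(sol.t_events[0]):
        raise EstimationError("larva never reached the metamorphosis anchor")
    a_j = float(sol.t_events[0][0])
    y_j = sol.y_events[0][0]
    EHj = float(y_j[2])

    # juvenile at fixed s_M until the puberty anchor
    p2 = p1.evolve(EHj=EHj)

    def hit_Lp(t, y):
        return max(y[1], 0.0) ** (1.0 / 3.0) - Lp_struct

    sol = _run_segment(tuple(y_j), Stage.JUVENILE, env, p2, arr, None,
                       a_j, a_j + 200000.0, stop_event=hit_Lp, rtol=rtol)
    if not len(sol.t_events[0]):
        raise EstimationError("juvenile never reached the puberty anchor")
    EHp = float(sol.y_events[0][0][2])
    return p2.evolve(EHp=EHp)


def calibrate_wet_coupler(p: DEBParams, anchor_PI: float = PI_ANCHOR) -> float:
    """Dry-to-wet ratio d_dw reconciling the dry reserve coupler with wet
    weights.

    Solves (rho_E/d_dw)[Em] / (dV + (rho_E/d_dw)[Em]) = anchor_PI, the
    equilibrium pyloric index of an ad-libitum-fed animal (f = 1, gonad
    excluded)."""
    if not (0.0 < anchor_PI < 1.0):
        raise ParameterError("anchor PI must lie in (0, 1)")
    x = anchor_PI / (1.0 - anchor_PI)  # reserve wet mass per unit structure mass
    return p.rho_E * p.Em / (x * p.dV)


def calibrate(
    p: DEBParams,
    arr: ArrheniusParams,
    anchors: dict | None = None,
    anchor_PI: float = PI_ANCHOR,
    T: float = 271.5,
) -> DEBParams:
    """Full calibration: wet coupler, maturity thresholds and acceleration."""
    p = p.evolve(d_dw=calibrate_wet_coupler(p, anchor_PI))
    return calibrate_stage_thresholds(p, arr, anchors, T=T)


# ---------------------------------------------------------------------------
# forward predictions of the zero-variate observables
# ---------------------------------------------------------------------------

def predict_zero_variate(
    p: DEBParams,
    arr: ArrheniusParams,
    names: list[str] | None = None,
    T: float = 271.5,
) -> dict[str, float]:
    """Forward-model predictions of the classic zero-variate observables.

    Supported names: a_b, a_j, L_b, L_j, L_p, L_i, L_i_f, Wd_0, W_p, W_i,
    W_i_f, GSI, PI (ages d, lengths physical cm, weights wet g, egg weight
    ug dry).  Stage lengths/ages come from forward integration against the
    calibrated maturity thresholds, asymptotic sizes from the closed form,
    and GSI from the stationary reproductive cycle at the maximum size.
    """
    all_names = ["a_b", "a_j", "L_b", "L_j", "L_p", "L_i", "L_i_f", "Wd_0",
                 "W_p", "W_i", "W_i_f", "GSI", "PI"]
    names = all_names if names is None else names
    unknown = set(names) - set(all_names)
    if unknown:
        raise ParameterError(f"no forward prediction for observables {sorted(unknown)}")
    p.require_calibrated()
    env = Environment(T=T, f=1.0)
    out: dict[str, float] = {}
    coupler = p.rho_E / p.d_dw

    need_embryo = {"a_b", "L_b", "Wd_0"} & set(names)
    need_larva = {"a_j", "L_j"} & set(names)
    need_juv = {"L_p", "W_p"} & set(names)
    if need_embryo or need_larva or need_juv:
        E0, a_b, y_b = initial_reserve(p, arr, env)
        out["a_b"] = a_b
        out["L_b"] = y_b[1] ** (1 / 3) / p.delta_M_lrv
        out["Wd_0"] = E0 * p.rho_E * 1e6
    if need_larva or need_juv:
        def hit_EHj(t, y):
            return y[2] - p.EHj

        sol = _run_segment(tuple(y_b), Stage.LARVA, env, p, arr, p.Lb_struct,
                           a_b, a_b + 5000.0, stop_event=hit_EHj)
        a_j = float(sol.t_events[0][0])
        y_j = sol.y_events[0][0]
        out["a_j"] = a_j
        out["L_j"] = y_j[1] ** (1 / 3) / p.delta_M_lrv
    if need_juv:
        def hit_EHp(t, y):
            return y[2] - p.EHp

        sol = _run_segment(tuple(y_j), Stage.JUVENILE, env, p, arr, None,
                           a_j, a_j + 200000.0, stop_event=hit_EHp)
        y_p = sol.y_events[0][0]
        out["L_p"] = y_p[1] ** (1 / 3) / p.delta_M
        out["W_p"] = p.dV * y_p[1] + coupler * (y_p[0] + y_p[3])
    if {"L_i", "W_i", "GSI"} & set(names):
        L_i, W_i = ultimate_size(p, arr, f=1.0, T=T)
        out["L_i"], out["W_i"] = L_i, W_i
    if {"L_i_f", "W_i_f"} & set(names):
        out["L_i_f"], out["W_i_f"] = ultimate_size(p, arr, f=p.f_f, T=T)
    if "GSI" in names:
        V = (L_i * p.delta_M) ** 3
        pR = equilibrium_pR(p, arr, env, L_i)
        out["GSI"] = stationary_peak_gsi(pR, p, V, p.Em * V)
    if "PI" in names:
        x = coupler * p.Em
        out["PI"] = x / (p.dV + x)
    return {k: out[k] for k in names}


# ---------------------------------------------------------------------------
# simplified covariation estimation
# ---------------------------------------------------------------------------

def covariation_fit(
    obs: ObservationSet,
    start: DEBParams,
    arr: ArrheniusParams,
    free: list[str],
    pseudo: list[tuple[str, float, float]] | None = None,
    T: float = 271.5,
    maxiter: int = 5000,
    xtol: float = 1e-6,
) -> tuple[DEBParams, FitResult]:
    """Nelder-Mead minimisation of weighted squared relative errors.

    ``free`` lists the DEBParams fields to estimate; every other parameter
    (including the calibrated thresholds, which are anchored to data rather
    than to the free parameters) is held at its ``start`` value.  ``pseudo``
    adds penalty terms w*((theta - value)/value)^2 keeping weakly determined
    parameters near canonical values.  Observation names must be supported
    by :func:`predict_zero_variate`.  Returns the estimated parameter set
    and a :class:`FitResult` whose MRE covers all positive-weight points.
    """
    start.require_calibrated()
    zv = obs.zero_variate
    names = list(zv.name)
    values = zv.value.to_numpy(float)
    wts = zv.weight.to_numpy(float)
    pseudo = pseudo or []
    x0 = np.array([getattr(start, f) for f in free], float)
    if not np.all(np.isfinite(x0)):
        raise ParameterError("start values for free parameters must be finite")

    def build(x) -> DEBParams:
        return start.evolve(**dict(zip(free, x)))

    def loss(x) -> float:
        if np.any(x <= 0):
            return 1e12
        try:
            trial = build(x)
            pred = predict_zero_variate(trial, arr, names, T=T)
        except (ParameterError, EstimationError, OverflowError):
            return 1e12
        arr_pred = np.array([pred[n] for n in names])
        sq = wts * ((arr_pred - values) / values) ** 2
        pen = sum(w * ((getattr(trial, nm) - val) / val) ** 2
                  for nm, val, w in pseudo)
        return float(np.sum(sq) + pen)

    res = optimize.minimize(loss, x0, method="Nelder-Mead",
                            options={"maxiter": maxiter, "xatol": xtol,
                                     "fatol": xtol ** 2, "adaptive": True})
    fitted = build(res.x)
    pred = predict_zero_variate(fitted, arr, names, T=T)
    arr_pred = np.array([pred[n] for n in names])
    per_ds = {n: float(abs(pv - ov) / abs(ov))
              for n, pv, ov in zip(names, arr_pred, values)}
    result = FitResult(
        estimates=dict(zip(free, map(float, res.x))),
        sds={f: math.nan for f in free},
        mre=mean_relative_error(values, arr_pred, wts),
        per_dataset_mre=per_ds,
        converged=bool(res.success),
        n_iter=int(res.nit),
        message=res.message,
    )
    return fitted, result


def estimate_field_f(
    field_max_length_cm: float,
    p: DEBParams,
    lab_max_length_cm: float | None = None,
) -> float:
    """Scaled functional response of a field population from its maximum size.

    The asymptotic length is proportional to f, so the field f is the ratio
    of field to laboratory (f = 1) maximum length; implemented as a bounded
    1-D minimisation of the squared relative error of the predicted maximum
    length for robustness to future extensions.
    """
    p.require_calibrated()
    if lab_max_length_cm is None:
        lab_max_length_cm = p.s_M * p.kappa * p.pAm / p.pM_vol / p.delta_M
    if field_max_length_cm <= 0:
        raise ParameterError("field maximum length must be positive")

    def err(f):
        return ((f * lab_max_length_cm - field_max_length_cm)
                / field_max_length_cm) ** 2

    res = optimize.minimize_scalar(err, bounds=(1e-3, 1.0), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x)
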