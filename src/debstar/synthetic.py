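"""Synthetic-data generators with known ground truth.

The original observations behind the calibration procedures (a two-year
ad-libitum feeding experiment, respiration-versus-temperature series and
oocyte-cohort growth curves) are unpublished or available only as figures,
so every estimation routine in the package is exercised against generated
data: cube-law length-weight pairs with multiplicative noise, the
five-parameter thermal response sampled across the tolerance window with
additive noise, lifecycle growth series, power-law cohort mass
trajectories, and full zero-variate record sets.  Each generator returns
the data table together with a ground-truth record; tests must read truth
from the record, never from the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .core import temperature_correction
from .params import ArrheniusParams, DEBParams, Environment, ParameterError
from .reproduction import cohort_mass_curve

__all__ = ["GeneratorSpec", "generate", "KINDS"]

KINDS = ("length_weight", "o2_temperature", "growth_series",
         "cohort_series", "zero_variate_set")

#: default noise levels: multiplicative lognormal for masses/weights
#: (strictly positive), additive gaussian (fraction of the maximum) for
#: scaled rates
DEFAULT_NOISE_SD = {"multiplicative": 0.1, "additive": 0.05}


@dataclass
class GeneratorSpec:
    """What to generate: kind, ground truth, size, noise model and seed."""

    kind: str
    true_params: dict[str, Any] = field(default_factory=dict)
    n: int = 20
    noise: str = "none"          # none | multiplicative | additive
    noise_sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ParameterError(f"unknown generator kind {self.kind!r}; choose from {KINDS}")
        if self.noise not in ("none", "multiplicative", "additive"):
            raise ParameterError(f"unknown noise model {self.noise!r}")
        if self.n < 3:
            raise ParameterError("need n >= 3 points")
        if self.noise_sd is None:
            self.noise_sd = 0.0 if self.noise == "none" else DEFAULT_NOISE_SD[self.noise]
        if self.noise_sd < 0:
            raise ParameterError("noise sd must be >= 0")


def _apply_noise(values: np.ndarray, spec: GeneratorSpec,
                 rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    if spec.noise == "none" or spec.noise_sd == 0:
        return values
    if spec.noise == "multiplicative":
        return values * rng.lognormal(mean=0.0, sigma=spec.noise_sd, size=len(values))
    return np.maximum(values + rng.normal(0.0, spec.noise_sd * scale, size=len(values)),
                      1e-9)


def generate(
    spec: GeneratorSpec,
    p: DEBParams | None = None,
    arr: ArrheniusParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Produce a CSV-ready table plus the ground-truth record.

    Model components (``p``, ``arr``) default to the packaged parameter set;
    ``growth_series`` and ``zero_variate_set`` require calibrated
    parameters.  ``spec.true_params`` overrides the generating values (e.g.
    ``delta``, ``a``, ``b``, ``pR_ref``, ``f``, ``T``, Arrhenius fields).
    """
    from .params import default_params

    if p is None or arr is None:
        dp, da = default_params()
        p = p or dp
        arr = arr or da
    rng = np.random.default_rng(spec.seed)
    tp = dict(spec.true_params)

    if spec.kind == "length_weight":
        delta = tp.pop("delta", p.delta_M)
        L = np.linspace(tp.pop("L_min", 0.5), tp.pop("L_max", 7.0), spec.n)
        W = (delta * L) ** 3
        W = _apply_noise(W, spec, rng)
        return (pd.DataFrame({"length_cm": L, "wet_weight_g": W}),
                {"delta": delta, "noise": spec.noise, "noise_sd": spec.noise_sd,
                 "seed": spec.seed})

    if spec.kind == "o2_temperature":
        fields = {k: tp.pop(k, getattr(arr, k))
                  for k in ("TA", "TL", "TH", "TAL", "TAH", "Tref")}
        gen_arr = ArrheniusParams(**fields)
        T = np.linspace(gen_arr.TL - 2.0, gen_arr.TH + 3.0, spec.n)
        rate = temperature_correction(T, gen_arr)
        rate = rate / rate.max()
        rate = _apply_noise(rate, spec, rng, scale=1.0)
        rate = rate / rate.max()
        return (pd.DataFrame({"temp_K": T, "scaled_rate": rate}),
                {**fields, "noise": spec.noise, "noise_sd": spec.noise_sd,
                 "seed": spec.seed})

    if spec.kind == "cohort_series":
        a = tp.pop("a", 1.201)
        b = tp.pop("b", 1.157)
        pR_ref = tp.pop("pR_ref", 50.0)
        age = np.linspace(730.0 / spec.n, 730.0, spec.n)
        Y = cohort_mass_curve(age, pR_ref, p, a=a, b=b)
        Y = _apply_noise(Y, spec, rng)
        return (pd.DataFrame({"age_d": age, "mass_g": Y}),
                {"a": a, "b": b, "pR_ref": pR_ref, "noise": spec.noise,
                 "noise_sd": spec.noise_sd, "seed": spec.seed})

    if spec.kind == "growth_series":
        from .lifecycle import simulate_lifecycle

        f = tp.pop("f", 1.0)
        T = tp.pop("T", 271.5)
        t_end = tp.pop("t_end", 2000.0)
        env = Environment(T=T, f=f)
        traj, _ = simulate_lifecycle(p, arr, env, t_end=t_end,
                                     record_interval=max(t_end / spec.n, 1.0))
        idx = np.linspace(0, len(traj) - 1, min(spec.n, len(traj))).astype(int)
        sub = traj.iloc[idx][["age_d", "length_cm", "wetweight_g"]].copy()
        sub["wetweight_g"] = _apply_noise(sub.wetweight_g.to_numpy(), spec, rng)
        return (sub.reset_index(drop=True),
                {"f": f, "T": T, "noise": spec.noise, "noise_sd": spec.noise_sd,
                 "seed": spec.seed})

    # zero_variate_set
    from .calibration import predict_zero_variate

    T = tp.pop("T", 271.5)
    pred = predict_zero_variate(p, arr, T=T)
    units = {"a_b": "d", "a_j": "d", "L_b": "cm", "L_j": "cm", "L_p": "cm",
             "L_i": "cm", "L_i_f": "cm", "Wd_0": "ug", "W_p": "g", "W_i": "g",
             "W_i_f": "g", "GSI": "-", "PI": "-"}
    values = _apply_noise(np.array(list(pred.values())), spec, rng)
    table = pd.DataFrame({
        "name": list(pred), "value": values,
        "unit": [units[k] for k in pred], "temp_K": T, "weight": 1.0,
    })
    return table, {"T": T, **pred, "noise": spec.noise,
                   "noise_sd": spec.noise_sd, "seed": spec.seed}
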