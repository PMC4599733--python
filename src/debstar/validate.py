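"""Recompute the classic zero-variate predictions and compare to observations.

The packaged observation table carries the single-point observations
(ages, stage lengths, asymptotic sizes, egg dry weight, organ indices, all
at 271.5 K) that anchor the parameter set; ``validate_targets`` reruns the
forward pipeline for each and reports relative errors.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .calibration import ObservationSet, predict_zero_variate
from .params import ArrheniusParams, DEBParams, load_params

__all__ = ["packaged_observations", "validate_targets"]

OBS_RESOURCE = "zero_variate_obs.csv"


def packaged_observations() -> ObservationSet:
    """The packaged zero-variate observation table."""
    ref = resources.files("debstar.data").joinpath(OBS_RESOURCE)
    with resources.as_file(ref) as path:
        return ObservationSet.from_csv(path)


def validate_targets(
    params: DEBParams | str | Path,
    arr: ArrheniusParams | None = None,
    obs: ObservationSet | None = None,
) -> pd.DataFrame:
    """Forward-predict every packaged observable and tabulate relative errors.

    ``params`` may be a calibrated :class:`DEBParams` (with ``arr``) or the
    path of a calibrated parameter file.  Returns a table with columns
    name, observed, predicted, unit, rel_error.
    """
    if not isinstance(params, DEBParams):
        params, arr = load_params(params)
    if arr is None:
        raise ValueError("ArrheniusParams required alongside a DEBParams instance")
    params.require_calibrated()
    obs = obs or packaged_observations()
    zv = obs.zero_variate
    pred = predict_zero_variate(params, arr, list(zv.name))
    out = zv[["name", "value", "unit"]].rename(columns={"value": "observed"}).copy()
    out["predicted"] = [pred[n] for n in zv.name]
    out["rel_error"] = (out.predicted - out.observed).abs() / out.observed.abs()
    return out
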