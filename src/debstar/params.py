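"""Parameter containers and configuration I/O.

All rate and cost parameters are stored at the reference temperature
``ArrheniusParams.Tref`` and must be multiplied by the Arrhenius correction
factor (:func:`debstar.core.temperature_correction`) before use at any other
temperature.  Units throughout the package: energy J, length cm, volume cm3,
mass g, time d, temperature K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace, asdict
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "DEBParams",
    "ArrheniusParams",
    "Environment",
    "load_params",
    "save_params",
    "default_params",
    "DEFAULT_PARAMS_RESOURCE",
]


class ParameterError(ValueError):
    """Raised when a parameter container violates its invariants."""


@dataclass(frozen=True)
class ArrheniusParams:
    """Five-parameter Arrhenius description of thermal sensitivity.

    The response combines an Arrhenius factor with slope ``TA`` and two
    boundary terms that suppress rates outside the tolerance window
    ``[TL, TH]`` with boundary slopes ``TAL`` and ``TAH``.  ``Tref`` is the
    temperature at which the rate parameters of the energy budget are stated.
    """

    TA: float = 5303.0       # Arrhenius temperature, K
    TL: float = 269.5        # lower boundary of the tolerance range, K
    TH: float = 288.0        # upper boundary of the tolerance range, K
    TAL: float = 120200.0    # Arrhenius temperature at the lower boundary, K
    TAH: float = 68360.0     # Arrhenius temperature at the upper boundary, K
    Tref: float = 285.0      # reference temperature, K

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ParameterError(f"ArrheniusParams.{f.name} must be a positive finite number, got {v!r}")
        if not (self.TL < self.Tref <= self.TH):
            raise ParameterError(
                f"tolerance window must contain the reference temperature: "
                f"TL={self.TL} < Tref={self.Tref} <= TH={self.TH} fails"
            )


@dataclass(frozen=True)
class Environment:
    """Ambient conditions: temperature (K) and scaled functional response f.

    ``f`` is feeding level relative to ad-libitum conditions, in [0, 1]; the
    underlying prey density is not modelled.
    """

    T: float = 271.5
    f: float = 1.0

    def __post_init__(self) -> None:
        if not (self.T > 0 and math.isfinite(self.T)):
            raise ParameterError(f"temperature must be positive, got {self.T!r}")
        if not (0.0 <= self.f <= 1.0):
            raise ParameterError(f"scaled functional response must be in [0, 1], got {self.f!r}")


@dataclass(frozen=True)
class DEBParams:
    """Full parameter set of the energy budget (stated at ``Tref``).

    The first block holds the primary parameters of the standard model with
    metabolic acceleration between birth and metamorphosis; the second block
    holds conversion couplers; the last block holds quantities derived by
    calibration (maturity thresholds, acceleration factor, dry-to-wet ratio)
    which are ``None`` until :func:`debstar.calibration.calibrate` has run.
    """

    pAm: float = 6.82        # {pAm}: max surface-specific assimilation, J d-1 cm-2
    pM_vol: float = 6.93     # [pM]: volume-specific maintenance, J d-1 cm-3
    EG: float = 2579.0       # [EG]: volume-specific cost of structure, J cm-3
    kappa: float = 0.81      # fraction of mobilised energy to soma
    v_dot: float = 0.007     # energy conductance, cm d-1
    kJ_dot: float = 0.001    # maturity maintenance rate coefficient, d-1
    delta_M: float = 0.57    # post-metamorphic shape coefficient
    delta_M_lrv: float = 0.59  # pre-metamorphic (larval) shape coefficient
    kappa_R: float = 0.95    # reproduction efficiency
    f_f: float = 0.80        # scaled functional response in the field (McMurdo)
    # conversion couplers
    dV: float = 1.0          # density of structure, g cm-3
    rho_E: float = 4.35e-5   # dry mass per unit reserve energy, g J-1
    wE: float = 23.9         # molecular weight of reserves, g mol-1
    mu_E: float = 550.0      # chemical potential of reserves, kJ mol-1
    # calibrated / derived quantities
    d_dw: float | None = None   # dry-to-wet mass ratio of reserve-like tissue
    EHb: float | None = None    # maturity at birth, J
    EHj: float | None = None    # maturity at metamorphosis, J
    EHp: float | None = None    # maturity at puberty, J
    s_M: float | None = None    # acceleration factor acquired by metamorphosis
    Lb_struct: float | None = None  # structural length at birth, cm

    def __post_init__(self) -> None:
        positive = ("pAm", "pM_vol", "EG", "v_dot", "kJ_dot", "delta_M",
                    "delta_M_lrv", "dV", "rho_E", "wE", "mu_E")
        for name in positive:
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ParameterError(f"DEBParams.{name} must be positive, got {v!r}")
        if not (0.0 < self.kappa < 1.0):
            raise ParameterError(f"kappa must be in (0, 1), got {self.kappa!r}")
        if not (0.0 < self.kappa_R <= 1.0):
            raise ParameterError(f"kappa_R must be in (0, 1], got {self.kappa_R!r}")
        if not (0.0 < self.f_f <= 1.0):
            raise ParameterError(f"f_f must be in (0, 1], got {self.f_f!r}")
        # reserve dry mass per Joule must agree with wE / mu_E to 1%
        implied = self.wE / (self.mu_E * 1e3)
        if abs(implied - self.rho_E) > 0.01 * self.rho_E:
            raise ParameterError(
                f"rho_E={self.rho_E} inconsistent with wE/mu_E={implied:.4g} g J-1"
            )
        thresholds = (self.EHb, self.EHj, self.EHp)
        if all(t is not None for t in thresholds):
            if not (0 < self.EHb < self.EHj < self.EHp):
                raise ParameterError(
                    f"maturity thresholds must satisfy 0 < EHb < EHj < EHp, got {thresholds}"
                )
        if self.s_M is not None and self.s_M < 1.0:
            raise ParameterError(f"acceleration factor s_M must be >= 1, got {self.s_M!r}")
        if self.d_dw is not None and not (0 < self.d_dw <= 1):
            raise ParameterError(f"d_dw must be in (0, 1], got {self.d_dw!r}")

    # -- derived compound quantities -------------------------------------
    @property
    def Em(self) -> float:
        """[Em]: maximum reserve density {pAm}/v, J cm-3."""
        return self.pAm / self.v_dot

    @property
    def g_energy(self) -> float:
        """Energy investment ratio g = [EG] / (kappa [Em])."""
        return self.EG / (self.kappa * self.Em)

    @property
    def is_calibrated(self) -> bool:
        return None not in (self.d_dw, self.EHb, self.EHj, self.EHp,
                            self.s_M, self.Lb_struct)

    def require_calibrated(self) -> None:
        if not self.is_calibrated:
            missing = [n for n in ("d_dw", "EHb", "EHj", "EHp", "s_M", "Lb_struct")
                       if getattr(self, n) is None]
            raise ParameterError(
                "parameter set lacks calibrated fields "
                f"{missing}; run debstar.calibration.calibrate() or load a "
                "calibrated parameter file"
            )

    def evolve(self, **changes) -> "DEBParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# flat key-value configuration files
# ---------------------------------------------------------------------------

DEFAULT_PARAMS_RESOURCE = "odontaster_validus.yaml"

_ARR_KEYS = {f.name for f in fields(ArrheniusParams)}
_DEB_KEYS = {f.name for f in fields(DEBParams)}


def load_params(path: str | Path) -> tuple[DEBParams, ArrheniusParams]:
    """Read a flat key/value YAML parameter file.

    Keys are field names of :class:`DEBParams` and :class:`ArrheniusParams`;
    unknown keys raise. Calibrated fields may be absent or null.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ParameterError(f"parameter file {path} is not a flat mapping")
    deb_kwargs, arr_kwargs = {}, {}
    for key, value in raw.items():
        if key in _ARR_KEYS:
            arr_kwargs[key] = value
        elif key in _DEB_KEYS:
            if value is not None:
                deb_kwargs[key] = value
        else:
            raise ParameterError(f"unknown parameter key {key!r} in {path}")
    return DEBParams(**deb_kwargs), ArrheniusParams(**arr_kwargs)


def save_params(path: str | Path, p: DEBParams, arr: ArrheniusParams) -> None:
    """Write a flat key/value YAML parameter file (inverse of load_params)."""
    record: dict[str, float | None] = {}
    record.update(asdict(arr))
    record.update(asdict(p))
    Path(path).write_text(yaml.safe_dump(record, sort_keys=False))


def default_params() -> tuple[DEBParams, ArrheniusParams]:
    """The packaged *Odontaster validus* parameter set (uncalibrated fields null)."""
    ref = resources.files("debstar.data").joinpath(DEFAULT_PARAMS_RESOURCE)
    with resources.as_file(ref) as path:
        return load_params(path)
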