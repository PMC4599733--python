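"""State variables, temperature correction, energy fluxes and observables.

The model follows the standard energy-budget partition: assimilated energy
enters a reserve pool E; mobilised energy pC is split by the kappa-rule into
a somatic branch (maintenance pM, then growth pG) and a developmental branch
(maturity maintenance pJ, then maturation or reproduction pR).  Surface-linked
rates (assimilation, conductance) are multiplied by a stage-dependent
acceleration: 1 for the embryo, L/Lb during the exponentially growing larval
stage, and frozen at s_M = Lj/Lb after metamorphosis.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .params import ArrheniusParams, DEBParams, Environment, ParameterError

__all__ = [
    "Stage",
    "OrganismState",
    "FluxSet",
    "Observables",
    "temperature_correction",
    "acceleration_multiplier",
    "compute_fluxes",
    "compute_observables",
    "OXYCALORIC_J_PER_MG_O2",
]

# Oxycaloric conversion linking dissipated metabolic power to oxygen
# consumption, back-derived from the calibrated pair
# 558 ug O2 d-1 cm-3  <->  7.564 J d-1 cm-3.
OXYCALORIC_J_PER_MG_O2 = 7.564 / 0.558  # ~13.56 J per mg O2


class Stage(enum.Enum):
    """Life-history stage, set by maturity relative to the thresholds."""

    EMBRYO = "embryo"        # EH < EHb: no feeding
    LARVA = "larva"          # EHb <= EH < EHj: feeding, accelerating
    JUVENILE = "juvenile"    # EHj <= EH < EHp: post-metamorphic, immature
    ADULT = "adult"          # EH >= EHp: allocation to reproduction buffer


@dataclass
class OrganismState:
    """Instantaneous state of one individual.

    ``cohorts`` holds the developing/spawning oocyte cohorts of adults (see
    :mod:`debstar.reproduction`); it stays empty for immature stages.
    """

    E: float                 # reserve energy, J
    V: float                 # structural volume, cm3
    EH: float = 0.0          # cumulative maturity, J
    ER: float = 0.0          # reproduction buffer, J
    age: float = 0.0         # days since fertilisation
    stage: Stage = Stage.EMBRYO
    cohorts: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("E", "V", "EH", "ER"):
            if getattr(self, name) < 0:
                raise ParameterError(f"OrganismState.{name} must be >= 0")

    @property
    def L(self) -> float:
        """Structural length V^(1/3), cm."""
        return self.V ** (1.0 / 3.0)

    @property
    def reserve_density(self) -> float:
        """[E] = E/V, J cm-3."""
        return self.E / self.V

    def stage_from_maturity(self, p: DEBParams) -> Stage:
        p.require_calibrated()
        if self.EH < p.EHb:
            return Stage.EMBRYO
        if self.EH < p.EHj:
            return Stage.LARVA
        if self.EH < p.EHp:
            return Stage.JUVENILE
        return Stage.ADULT


@dataclass(frozen=True)
class FluxSet:
    """Instantaneous powers (J d-1) of the kappa-rule partition.

    ``starved`` flags states where the somatic branch kappa*pC cannot cover
    maintenance; ``pG`` is then reported as 0 and the deficit is drawn from
    reserve by the integrator (no structure shrinkage).
    """

    pA: float
    pC: float
    pM: float
    pJ: float
    pG: float
    pR: float
    starved: bool = False


@dataclass(frozen=True)
class Observables:
    """Measurement model applied to a state (all masses wet unless noted)."""

    physical_length: float   # cm, arm length from mouth to arm tip
    wet_weight: float        # g, structure + reserve + buffer + gonad
    dry_egg_equivalent: float  # ug dry mass the reserve+buffer could provision
    GSI: float               # gonad wet weight / total wet weight
    PI: float                # reserve wet weight / (total - gonad)
    O2_rate: float           # mg O2 d-1 from dissipated power


def temperature_correction(T: float, arr: ArrheniusParams) -> float:
    """Multiplicative thermal correction c(T) applied to every rate parameter.

    c(T) = exp(TA/Tref - TA/T) * s(Tref)/s(T)  with
    s(T) = 1 + exp(TAL/T - TAL/TL) + exp(TAH/TH - TAH/T),
    so that c(Tref) = 1 exactly and rates are suppressed outside [TL, TH].
    Accepts scalars or numpy arrays.
    """
    T = np.asarray(T, dtype=float)
    if np.any(~np.isfinite(T)) or np.any(T <= 0):
        raise ParameterError(f"temperature must be positive and finite, got {T!r}")
    core = np.exp(arr.TA / arr.Tref - arr.TA / T)

    def boundary(temp):
        return 1.0 + np.exp(arr.TAL / temp - arr.TAL / arr.TL) + np.exp(arr.TAH / arr.TH - arr.TAH / temp)

    out = core * boundary(arr.Tref) / boundary(T)
    return float(out) if out.ndim == 0 else out


def acceleration_multiplier(state: OrganismState, p: DEBParams) -> float:
    """Stage-dependent multiplier of surface-linked rates.

    1 before birth; L/Lb from birth to metamorphosis (exponential larval
    growth); frozen at the calibrated s_M afterwards.
    """
    if state.stage is Stage.EMBRYO:
        return 1.0
    p.require_calibrated()
    if state.stage is Stage.LARVA:
        return max(1.0, min(state.L / p.Lb_struct, p.s_M))
    return p.s_M


def _accel(L: float, stage: Stage, p: DEBParams, Lb_struct: float | None = None) -> float:
    """Internal acceleration by structural length (used by integrators)."""
    if stage is Stage.EMBRYO:
        return 1.0
    if stage is Stage.LARVA:
        if Lb_struct is None:
            raise ParameterError("larval acceleration needs the structural length at birth")
        return max(1.0, min(L / Lb_struct, p.s_M if p.s_M else math.inf))
    if p.s_M is None:
        raise ParameterError("post-metamorphic fluxes need the calibrated s_M")
    return p.s_M


def compute_fluxes(
    state: OrganismState,
    env: Environment,
    p: DEBParams,
    arr: ArrheniusParams,
    Lb_struct: float | None = None,
) -> FluxSet:
    """Evaluate all powers of the kappa-rule partition at one instant.

    ``Lb_struct`` (structural length at birth, cm) is required for larval
    states; for post-metamorphic states the calibrated ``p.s_M`` is used.
    Embryos do not assimilate (birth is the onset of feeding).
    """
    c = temperature_correction(env.T, arr)
    L = state.L
    s = _accel(L, state.stage, p, Lb_struct)
    E_dens = state.E / state.V

    pA = 0.0 if state.stage is Stage.EMBRYO else env.f * p.pAm * s * c * state.V ** (2.0 / 3.0)
    v_T = p.v_dot * s * c
    pM = p.pM_vol * c * state.V
    # standard reserve mobilisation under the kappa-rule growth closure
    pC = state.V * E_dens * (p.EG * v_T / L + p.pM_vol * c) / (p.EG + p.kappa * E_dens)
    EH_eff = state.EH if p.EHp is None else min(state.EH, p.EHp)
    pJ = p.kJ_dot * c * EH_eff
    pG = p.kappa * pC - pM
    pR = (1.0 - p.kappa) * pC - pJ
    starved = pG < 0.0
    if starved:
        pG = 0.0
    return FluxSet(pA=pA, pC=pC, pM=pM, pJ=pJ, pG=pG, pR=pR, starved=starved)


def gonad_energy(state: OrganismState) -> float:
    """Summed energy of all oocyte cohorts, J (0 for immature stages)."""
    return float(sum(c.energy for c in state.cohorts))


def compute_observables(
    state: OrganismState,
    p: DEBParams,
    arr: ArrheniusParams | None = None,
    env: Environment | None = None,
) -> Observables:
    """Map a state onto measurable quantities.

    Wet mass composition: structure contributes dV*V; reserve, reproduction
    buffer and gonad contribute energy * rho_E/d_dw (reserve-like tissue with
    a common dry-to-wet ratio d_dw).  Physical length uses the larval shape
    coefficient before metamorphosis and the post-metamorphic one after.
    The O2 rate (needs ``arr`` and ``env``) converts dissipated power --
    total mobilised power not fixed into new biomass -- with the oxycaloric
    coefficient.
    """
    if p.d_dw is None:
        raise ParameterError(
            "d_dw is unset: run debstar.calibration.calibrate_wet_coupler "
            "(or calibration.calibrate) before computing wet observables"
        )
    delta = p.delta_M_lrv if state.stage in (Stage.EMBRYO, Stage.LARVA) else p.delta_M
    length = state.L / delta

    coupler = p.rho_E / p.d_dw  # g wet per J
    gonadE = gonad_energy(state)
    reserve_wet = coupler * state.E
    buffer_wet = coupler * state.ER
    gonad_wet = coupler * gonadE
    structure_wet = p.dV * state.V
    total = structure_wet + reserve_wet + buffer_wet + gonad_wet

    gsi = gonad_wet / total if total > 0 else 0.0
    soma = total - gonad_wet
    pi = reserve_wet / soma if soma > 0 else 0.0

    o2 = math.nan
    if arr is not None and env is not None:
        fx = compute_fluxes(state, env, p, arr, Lb_struct=p.Lb_struct)
        # dissipated power: mobilised energy not fixed as biomass.  Maturation
        # (immature pR) is fully dissipated; adult pR loses only the (1-kR)
        # transformation overhead; the synthesis overhead of growth is not
        # separable with a single-compound reserve and is left out.
        pR_pos = max(fx.pR, 0.0)
        if state.stage is Stage.ADULT:
            dissipated = fx.pM + fx.pJ + (1.0 - p.kappa_R) * pR_pos
        else:
            dissipated = fx.pM + fx.pJ + pR_pos
        o2 = dissipated / OXYCALORIC_J_PER_MG_O2
    return Observables(
        physical_length=length,
        wet_weight=total,
        dry_egg_equivalent=(state.E + state.ER) * p.rho_E * 1e6,
        GSI=gsi,
        PI=pi,
        O2_rate=o2,
    )
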