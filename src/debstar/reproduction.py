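"""Reproduction-buffer handling: two-cohort oogenesis and spawning.

Adults allocate reproductive income pR to a buffer ER that is continuously
transformed into gonad.  Two oocyte cohorts develop simultaneously, their
onsets one year apart, each for exactly two years; the energy drawn for a
cohort of age t grows as a power law a*t^b of its age.  A normalisation
constant makes the two-cohort drain balance the pR income over a stationary
annual cycle, so the buffer is conservative.  The mature cohort is held
until the spawning season opens, then its mass declines linearly to zero
over the spawning window.

Calendar defaults follow the McMurdo population: cohort onset 1 June,
spawning 1 July - 1 October.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .params import ArrheniusParams, DEBParams, Environment, ParameterError

__all__ = [
    "OocyteCohort",
    "CohortAllocationParams",
    "SpawningSchedule",
    "allocation_norm",
    "allocate_to_cohorts",
    "cohort_mass_curve",
    "simulate_gonad_cycle",
    "stationary_cycle",
    "stationary_standing_energy",
    "stationary_peak_gsi",
    "fit_cohort_params",
]

#: fitted allocation coefficient and exponent (cohort age in years)
DEFAULT_A = 1.201
DEFAULT_B = 1.157

DEVELOPMENT_DAYS = 730.0


@dataclass
class OocyteCohort:
    """One year-class of developing oocytes (aggregate energy, not counts)."""

    onset_day: float           # simulation day the cohort began developing
    age_t: float = 0.0         # days since onset
    energy: float = 0.0        # accumulated energy after the kappa_R overhead, J
    mass_Y: float = 0.0        # accumulated wet mass, g
    spawning: bool = False
    energy_at_spawn_start: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.age_t <= DEVELOPMENT_DAYS):
            raise ParameterError("cohort age must lie in [0, 730] d")


def allocation_norm(a: float, b: float) -> float:
    """Normalisation making the two-cohort power-law drain conservative.

    With cohort ages t and t+1 (years) and constant pR, the annual integral
    of norm*a*(t^b + (t+1)^b) must equal 1, giving
    norm = (b+1) / (a * 2^(b+1)).
    """
    if a <= 0 or b <= 0:
        raise ParameterError("allocation parameters a, b must be positive")
    return (b + 1.0) / (a * 2.0 ** (b + 1.0))


@dataclass(frozen=True)
class CohortAllocationParams:
    """Power-law allocation a*t^b (t = cohort age in years) plus its
    conservation normalisation."""

    a: float = DEFAULT_A
    b: float = DEFAULT_B
    norm: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ParameterError("allocation parameters a, b must be positive")
        if self.norm is None:
            object.__setattr__(self, "norm", allocation_norm(self.a, self.b))

    def weight(self, age_days):
        """Fraction of pR drawn by a cohort of the given age."""
        t = np.asarray(age_days, dtype=float) / 365.0
        return self.norm * self.a * np.power(t, self.b)


@dataclass(frozen=True)
class SpawningSchedule:
    """Calendar of cohort onset and spawning (days of year)."""

    cohort_onset_doy: float = 152.0    # 1 June
    spawn_start_doy: float = 182.0     # 1 July
    spawn_end_doy: float = 274.0       # 1 October
    development_days: float = DEVELOPMENT_DAYS

    def __post_init__(self) -> None:
        if not (self.cohort_onset_doy < self.spawn_start_doy < self.spawn_end_doy):
            raise ParameterError("spawning window must follow cohort onset within the year")
        if self.development_days <= 0:
            raise ParameterError("development duration must be positive")

    @property
    def spawn_window(self) -> float:
        return self.spawn_end_doy - self.spawn_start_doy


def allocate_to_cohorts(
    pR: float,
    cohorts: list[OocyteCohort],
    alloc: CohortAllocationParams,
    p: DEBParams,
    ER_available: float = math.inf,
) -> tuple[np.ndarray, float, bool]:
    """Per-cohort energy inflow (J d-1) for developing cohorts.

    Inflows are pR * norm * a * t^b for each developing (non-spawning)
    cohort; the total drawn from the buffer is clipped at ``ER_available``
    (per day) and scaled down proportionally when clipping occurs.  Returns
    ``(inflows, total_drawdown, clipped)``.  Negative pR (starvation) yields
    zero allocation with a warning.
    """
    dev = [c for c in cohorts if not c.spawning and c.age_t < DEVELOPMENT_DAYS]
    if len(dev) > 2:
        raise ParameterError("at most two cohorts may be developing simultaneously")
    inflows = np.zeros(len(cohorts))
    if pR < 0:
        warnings.warn("negative reproductive allocation (starvation): no cohort inflow")
        return inflows, 0.0, False
    for i, c in enumerate(cohorts):
        if not c.spawning and c.age_t < DEVELOPMENT_DAYS:
            inflows[i] = pR * float(alloc.weight(c.age_t))
    total = float(inflows.sum())
    clipped = False
    if total > ER_available and total > 0:
        inflows *= ER_available / total
        total = ER_available
        clipped = True
    return inflows, total, clipped


def cohort_mass_curve(age_days, pR_ref: float, p: DEBParams,
                      a: float = DEFAULT_A, b: float = DEFAULT_B):
    """Accumulated dry mass (g) of one cohort under constant income pR_ref.

    Integral of the un-normalised power-law rule: energy drawn at age t is
    pR * a * (t/365yr)^b per day, converted with the reproduction efficiency
    and the reserve dry-mass coupler:
    Y(t) = rho_E * kappa_R * pR * 365 * a * t_yr^(b+1) / (b+1).
    """
    t_yr = np.asarray(age_days, dtype=float) / 365.0
    return p.rho_E * p.kappa_R * pR_ref * 365.0 * a * np.power(t_yr, b + 1.0) / (b + 1.0)


def simulate_gonad_cycle(
    p: DEBParams,
    arr: ArrheniusParams,
    env: Environment,
    length_cm: float,
    years: int = 5,
    alloc: CohortAllocationParams | None = None,
    schedule: SpawningSchedule | None = None,
    dt: float = 0.25,
    egg_cost_E0: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Gonad dynamics of a fixed-size adult at reserve equilibrium.

    Steps the buffer/cohort bookkeeping on a regular grid: income pR flows
    into the buffer, developing cohorts drain it following the power-law
    weights, a new cohort starts every 1 June, and the matured cohort is
    released linearly over the spawning window.  Needs ``years >= 3`` to
    reach the stationary annual cycle.  Returns a time series (day,
    per-cohort masses, gonad mass, GSI, buffer) and a summary dict with the
    stationary-cycle peak GSI, annual egg output and conservation
    diagnostics.
    """
    from .lifecycle import equilibrium_pR, initial_reserve

    if years < 3:
        raise ParameterError("need years >= 3 to reach the stationary cycle")
    p.require_calibrated()
    alloc = alloc or CohortAllocationParams()
    sch = schedule or SpawningSchedule()

    pR = equilibrium_pR(p, arr, env, length_cm)
    if pR <= 0:
        raise ParameterError("no positive reproductive allocation for this size/food level")
    V = (length_cm * p.delta_M) ** 3
    E = env.f * p.Em * V
    coupler = p.rho_E / p.d_dw

    n = int(round(years * 365.0 / dt))
    ER = 0.0
    # warm start at the stationary configuration (t = 0 is a 1 June): a
    # cohort just maturing with one year's income, one mid-development, one
    # fresh; the buffer is empty at cohort onset in the stationary cycle
    A = 365.0 * pR
    mature = OocyteCohort(onset_day=-DEVELOPMENT_DAYS, age_t=DEVELOPMENT_DAYS,
                          energy=p.kappa_R * A)
    mid = OocyteCohort(onset_day=-365.0, age_t=365.0,
                       energy=p.kappa_R * A * 0.5 ** (alloc.b + 1.0))
    cohorts: list[OocyteCohort] = [mature, mid, OocyteCohort(onset_day=0.0)]
    spawned_energy = 0.0
    clip_events = 0
    next_onset = 365.0
    rows = []
    for i in range(n):
        t = i * dt
        if t >= next_onset - 1e-9:
            cohorts.append(OocyteCohort(onset_day=next_onset))
            next_onset += 365.0
        for c in cohorts:
            c.age_t = min(t - c.onset_day, DEVELOPMENT_DAYS)
        ER += pR * dt
        inflows, drawn, clipped = allocate_to_cohorts(
            pR, cohorts, alloc, p, ER_available=ER / dt)
        clip_events += clipped
        ER -= drawn * dt
        for c, q in zip(cohorts, inflows):
            c.energy += p.kappa_R * q * dt
        # maturation and spawning
        doy = (t + sch.cohort_onset_doy) % 365.0
        for c in cohorts:
            if c.spawning:
                rate = c.energy_at_spawn_start / sch.spawn_window
                release = min(rate * dt, c.energy)
                c.energy -= release
                spawned_energy += release
            elif c.age_t >= sch.development_days:
                if sch.spawn_start_doy <= doy < sch.spawn_end_doy:
                    c.spawning = True
                    c.energy_at_spawn_start = c.energy
        cohorts = [c for c in cohorts if not (c.spawning and c.energy <= 1e-12)]
        for c in cohorts:
            c.mass_Y = coupler * c.energy

        gonadE = sum(c.energy for c in cohorts)
        total_wet = p.dV * V + coupler * (E + ER + gonadE)
        rows.append({
            "t_d": t,
            "calendar_doy": doy,
            "year": int(t // 365),
            "ER_J": ER,
            "gonad_J": gonadE,
            "gonad_g": coupler * gonadE,
            "GSI": coupler * gonadE / total_wet,
            "n_cohorts": len(cohorts),
            "youngest_age_d": min((c.age_t for c in cohorts), default=np.nan),
            "oldest_mass_g": max((c.mass_Y for c in cohorts), default=0.0),
        })

    ts = pd.DataFrame(rows)
    last = ts[ts.t_d >= (years - 1) * 365.0]
    if egg_cost_E0 is None:
        egg_cost_E0, _, _ = initial_reserve(p, arr, env)
    annual_income = 365.0 * pR
    summary = {
        "pR": pR,
        "annual_income_J": annual_income,
        "peak_GSI": float(last.GSI.max()),
        "mean_standing_J": float(last.ER_J.mean() + last.gonad_J.mean()),
        "spawned_energy_J": spawned_energy,
        "eggs_per_year": p.kappa_R * annual_income / egg_cost_E0,
        "clip_steps": clip_events,
    }
    return ts, summary


def stationary_cycle(pR: float, p: DEBParams,
                     alloc: CohortAllocationParams | None = None,
                     schedule: SpawningSchedule | None = None,
                     n: int = 2000) -> pd.DataFrame:
    """Closed-form stationary annual cycle under constant income pR.

    Cohort energy at age t (years) is kappa_R * A * (t/2)^(b+1) with A the
    annual income (the conservation norm makes each cohort's lifetime
    allocation exactly one year's income); the mature cohort holds its
    energy until the spawning season opens, then declines linearly; the
    buffer carries the running imbalance between income and the two-cohort
    drain (zero at each cohort onset).  Time runs one year from cohort
    onset (1 June).
    """
    alloc = alloc or CohortAllocationParams()
    sch = schedule or SpawningSchedule()
    A = 365.0 * pR
    b1 = alloc.b + 1.0
    t = (np.arange(n) + 0.5) / n  # cycle time in years from cohort onset
    young = (t / 2.0) ** b1
    old = ((t + 1.0) / 2.0) ** b1
    # spawning cohort: full until the season opens, linear decline to zero
    t_open = (sch.spawn_start_doy - sch.cohort_onset_doy) / 365.0
    t_close = (sch.spawn_end_doy - sch.cohort_onset_doy) / 365.0
    spawning = np.where(
        t < t_open, 1.0,
        np.where(t < t_close, 1.0 - (t - t_open) / (t_close - t_open), 0.0),
    )
    gonad_J = p.kappa_R * A * (young + old + spawning)
    w = alloc.norm * alloc.a * (t ** alloc.b + (t + 1.0) ** alloc.b)
    ER_J = A * np.cumsum(1.0 - w) / n
    return pd.DataFrame({"t_yr": t, "gonad_J": gonad_J, "ER_J": ER_J,
                         "alloc_weight": w})


def stationary_standing_energy(pR: float, p: DEBParams,
                               alloc: CohortAllocationParams | None = None,
                               schedule: SpawningSchedule | None = None,
                               n: int = 2000) -> float:
    """Annual-mean standing reproductive energy (gonad + buffer), J."""
    cyc = stationary_cycle(pR, p, alloc, schedule, n)
    return float((cyc.gonad_J + cyc.ER_J).mean())


def stationary_peak_gsi(pR: float, p: DEBParams, V: float, E: float,
                        alloc: CohortAllocationParams | None = None,
                        schedule: SpawningSchedule | None = None,
                        n: int = 2000) -> float:
    """Stationary-cycle maximum GSI for an adult of structure V holding
    reserve E (J)."""
    cyc = stationary_cycle(pR, p, alloc, schedule, n)
    coupler = p.rho_E / p.d_dw
    gonad_wet = coupler * cyc.gonad_J
    total = p.dV * V + coupler * (E + cyc.ER_J) + gonad_wet
    return float((gonad_wet / total).max())


def fit_cohort_params(
    age_days: np.ndarray,
    mass_g: np.ndarray,
    pR_ref: float,
    p: DEBParams,
    p0: tuple[float, float] = (1.0, 1.0),
) -> tuple[CohortAllocationParams, dict]:
    """Nonlinear least squares for the allocation law (a, b).

    Fits the integrated cohort-growth curve :func:`cohort_mass_curve` to an
    observed cohort mass-at-age series.  Returns the fitted parameters (with
    the conservation norm recomputed) and a diagnostics dict with standard
    deviations and the residual norm.
    """
    age_days = np.asarray(age_days, float)
    mass_g = np.asarray(mass_g, float)
    if len(age_days) < 5:
        raise ParameterError("need at least 5 points to fit the cohort law")
    if age_days.max() > DEVELOPMENT_DAYS or age_days.min() <= 0:
        raise ParameterError("cohort ages must lie in (0, 730] d")

    def model(t, a, b):
        return cohort_mass_curve(t, pR_ref, p, a=a, b=b)

    try:
        popt, pcov = curve_fit(model, age_days, mass_g, p0=p0,
                               bounds=([1e-6, 1e-6], [1e3, 10.0]), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"cohort-law fit did not converge: {exc}") from exc
    resid = mass_g - model(age_days, *popt)
    sds = np.sqrt(np.diag(pcov))
    diag = {
        "a_sd": float(sds[0]),
        "b_sd": float(sds[1]),
        "rss": float(resid @ resid),
        "n": len(age_days),
    }
    return CohortAllocationParams(a=float(popt[0]), b=float(popt[1])), diag
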