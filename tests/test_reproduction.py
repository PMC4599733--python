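"""Oocyte-cohort allocation rules, the stationary gonad cycle, and the
cohort-growth fit."""

import numpy as np
import pytest

import debstar as d
from debstar.params import ParameterError
from debstar.reproduction import (CohortAllocationParams, OocyteCohort,
                                  SpawningSchedule, allocate_to_cohorts,
                                  allocation_norm, cohort_mass_curve,
                                  fit_cohort_params, stationary_cycle,
                                  stationary_standing_energy)


def test_allocation_ratio_follows_power_of_age(calibrated):
    """A two-year-old cohort draws 2^b times the flux of a one-year-old."""
    p, _ = calibrated
    alloc = CohortAllocationParams()
    old = OocyteCohort(onset_day=0.0, age_t=729.999)
    young = OocyteCohort(onset_day=365.0, age_t=365.0)
    inflows, _, _ = allocate_to_cohorts(10.0, [old, young], alloc, p)
    assert inflows[0] / inflows[1] == pytest.approx(2.0 ** alloc.b, rel=1e-3)
    assert 2.0 ** alloc.b == pytest.approx(2.23, abs=0.01)


def test_new_cohort_draws_nothing(calibrated):
    p, _ = calibrated
    inflows, total, _ = allocate_to_cohorts(
        10.0, [OocyteCohort(onset_day=0.0, age_t=0.0)],
        CohortAllocationParams(), p)
    assert inflows[0] == 0.0 and total == 0.0


def test_negative_income_gives_zero_allocation(calibrated):
    p, _ = calibrated
    with pytest.warns(UserWarning, match="starvation"):
        inflows, total, _ = allocate_to_cohorts(
            -5.0, [OocyteCohort(onset_day=0.0, age_t=100.0)],
            CohortAllocationParams(), p)
    assert total == 0.0


def test_allocation_clipped_at_available_buffer(calibrated):
    p, _ = calibrated
    cohorts = [OocyteCohort(onset_day=0.0, age_t=700.0)]
    inflows, total, clipped = allocate_to_cohorts(
        100.0, cohorts, CohortAllocationParams(), p, ER_available=1.0)
    assert clipped and total == pytest.approx(1.0)


def test_three_developing_cohorts_rejected(calibrated):
    p, _ = calibrated
    cohorts = [OocyteCohort(onset_day=-730.0 + i * 365, age_t=700.0 - i * 300)
               for i in range(3)]
    with pytest.raises(ParameterError, match="two cohorts"):
        allocate_to_cohorts(10.0, cohorts, CohortAllocationParams(), p)


def test_conservation_norm_balances_two_cohort_drain():
    """Integral of norm a (t^b + (t+1)^b) over a cohort year equals 1."""
    a, b = 1.201, 1.157
    norm = allocation_norm(a, b)
    t = np.linspace(0, 1, 200001)
    integral = np.trapezoid(norm * a * (t ** b + (t + 1) ** b), t)
    assert integral == pytest.approx(1.0, rel=1e-6)


def test_stationary_cycle_buffer_stays_nonnegative(calibrated):
    p, _ = calibrated
    cyc = stationary_cycle(40.0, p)
    assert cyc.ER_J.min() > -1e-6 * cyc.ER_J.max()


# ---------------------------------------------------------------------------
# full gonad-cycle simulation
# ---------------------------------------------------------------------------

def test_gonad_cycle_energy_conservation(gonad_cycle_run, calibrated):
    """Spawned energy per stationary year equals kappa_R x annual income."""
    p, _ = calibrated
    ts, summary = gonad_cycle_run
    years = ts.t_d.max() / 365.0
    per_year = summary["spawned_energy_J"] / years
    assert per_year == pytest.approx(p.kappa_R * summary["annual_income_J"],
                                     rel=0.01)


def test_gonad_cycle_is_periodic(gonad_cycle_run):
    """After spin-up the GSI repeats with period one year (< 1% deviation)."""
    ts, _ = gonad_cycle_run
    y3 = ts[(ts.t_d >= 3 * 365) & (ts.t_d < 4 * 365)].GSI.to_numpy()
    y4 = ts[ts.t_d >= 4 * 365].GSI.to_numpy()
    n = min(len(y3), len(y4))
    assert np.max(np.abs(y3[:n] - y4[:n])) < 0.01 * y4.max()


def test_simulation_matches_closed_form_stationary_cycle(gonad_cycle_run,
                                                         calibrated):
    p, _ = calibrated
    ts, summary = gonad_cycle_run
    assert summary["mean_standing_J"] == pytest.approx(
        stationary_standing_energy(summary["pR"], p), rel=0.01)


def test_reproductive_stock_never_fully_spent(gonad_cycle_run):
    """A sizeable fraction of the reproductive stock is always standing:
    the cycle minimum stays within a broad band around one third of the
    cycle maximum."""
    ts, _ = gonad_cycle_run
    last = ts[ts.t_d >= 4 * 365]
    standing = (last.ER_J + last.gonad_J).to_numpy()
    frac = standing.min() / standing.max()
    assert 0.15 <= frac <= 0.45


def test_oogenesis_peaks_just_before_spawning(calibrated):
    """Total allocation rate is maximal in the 60 d before the season."""
    p, _ = calibrated
    cyc = stationary_cycle(40.0, p)
    sch = SpawningSchedule()
    peak_doy = (sch.cohort_onset_doy + 365.0 * cyc.t_yr[cyc.alloc_weight.idxmax()]) % 365
    assert sch.spawn_start_doy - 60.0 <= peak_doy <= sch.spawn_start_doy


def test_cohort_mass_grows_as_power_of_age(calibrated):
    """Under constant income the integrated cohort mass follows t^(b+1)."""
    p, _ = calibrated
    t = np.array([100.0, 200.0, 400.0])
    y = cohort_mass_curve(t, 50.0, p)
    b1 = 1.157 + 1.0
    assert y[1] / y[0] == pytest.approx(2.0 ** b1, rel=1e-9)
    assert y[2] / y[1] == pytest.approx(2.0 ** b1, rel=1e-9)


def test_linear_gonad_growth_for_constant_allocation(calibrated):
    """With b -> 0 a single cohort's mass is linear in age."""
    p, _ = calibrated
    t = np.linspace(50, 700, 14)
    y = cohort_mass_curve(t, 50.0, p, a=1.0, b=1e-9)
    slopes = np.diff(y) / np.diff(t)
    assert np.allclose(slopes, slopes[0], rtol=1e-6)


# ---------------------------------------------------------------------------
# nonlinear least squares for (a, b)
# ---------------------------------------------------------------------------

def test_cohort_fit_recovers_generating_values(calibrated):
    p, _ = calibrated
    t = np.linspace(30.0, 730.0, 25)
    y = cohort_mass_curve(t, 50.0, p, a=1.201, b=1.157)
    alloc, diag = fit_cohort_params(t, y, 50.0, p)
    assert alloc.a == pytest.approx(1.201, abs=5e-4)
    assert alloc.b == pytest.approx(1.157, abs=5e-4)
    assert diag["rss"] < 1e-12


def test_cohort_fit_exact_for_linear_member(calibrated):
    p, _ = calibrated
    t = np.linspace(30.0, 730.0, 25)
    y = cohort_mass_curve(t, 50.0, p, a=0.9, b=1.0)
    alloc, _ = fit_cohort_params(t, y, 50.0, p)
    assert alloc.b == pytest.approx(1.0, abs=1e-6)


def test_cohort_fit_unbiased_under_noise(calibrated):
    """Monte-Carlo: mean recovered b within one SD of truth at 5% noise."""
    p, _ = calibrated
    rng = np.random.default_rng(7)
    t = np.linspace(30.0, 730.0, 25)
    clean = cohort_mass_curve(t, 50.0, p, a=1.201, b=1.157)
    bs, sds = [], []
    for _ in range(100):
        noisy = clean * rng.lognormal(0.0, 0.05, size=len(t))
        alloc, diag = fit_cohort_params(t, noisy, 50.0, p)
        bs.append(alloc.b)
        sds.append(diag["b_sd"])
    assert abs(np.mean(bs) - 1.157) < np.mean(sds)


def test_cohort_fit_input_validation(calibrated):
    p, _ = calibrated
    with pytest.raises(ParameterError, match="at least 5"):
        fit_cohort_params([100, 200, 300], [1, 2, 3], 50.0, p)
    with pytest.raises(ParameterError, match="730"):
        fit_cohort_params([100, 200, 300, 800, 900], [1, 2, 3, 4, 5], 50.0, p)


def test_schedule_and_cohort_invariants():
    with pytest.raises(ParameterError):
        SpawningSchedule(spawn_start_doy=100.0)  # before cohort onset
    with pytest.raises(ParameterError):
        OocyteCohort(onset_day=0.0, age_t=800.0)
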