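# Methods

## Model structure

The energy budget follows the standard reserve-structure formulation. With
reserve density [E] = E/V, structural length L = V^(1/3), and thermal
correction c(T), the mobilised flux under the κ-rule growth closure is

    pC = V [E] ( [EG] v s c / L + [pM] c ) / ( [EG] + κ [E] )

with assimilation `pA = f {pAm} s c V^(2/3)` (zero before birth — birth is
defined as the onset of feeding), somatic maintenance `[pM] c V`, maturity
maintenance `k_J c min(E_H, E_H^p)` (capped so adult maturity maintenance is
constant), growth `pG = κ pC − pM` and the developmental flux
`pR = (1−κ) pC − pJ`, which accrues to maturity before puberty and to the
reproduction buffer after. The state (E, V, E_H, E_R) is integrated with
LSODA, relative tolerance 1e-8, per-component absolute tolerances scaled to
the initial state (floored at 1e-4 of the largest component, which matters
when a component starts at zero), and terminal root-finding events at the
three maturity thresholds. Tightening the tolerance tenfold moves every
stage age and length by well under 0.1%.

**Acceleration.** Surface-linked rates (assimilation and conductance) carry
a stage multiplier s: 1 for the embryo, L/L_b for the larva (producing
exponential larval growth, since v·s/L is then constant), frozen at
s_M = L_j/L_b after metamorphosis. The embryo is seeded at V₀ = 1e-14 cm³ to
avoid the V = 0 singularity; because early embryonic length grows linearly
at rate v·c/3, the seed must be negligible on the egg length scale — a
tenfold change of V₀ moves the age at birth by < 0.1 d at this value.

**Starvation.** When κ·pC < pM the deficit is paid directly from reserve,
structure does not shrink, and no gonad is resorbed (nothing is documented
for this species); the individual is flagged dead when the reserve is
exhausted. Fluxes report `starved=True` rather than raising.

**Temperature.** c(T) = exp(T_A/T_ref − T_A/T) · s(T_ref)/s(T) with
s(T) = 1 + exp(T_AL/T − T_AL/T_L) + exp(T_AH/T_H − T_AH/T). c(T_ref) = 1
exactly. With the packaged values (T_AH = 68360 K, T_H = 288 K) the response
peaks near 285.4 K and rolls off *before* the upper boundary — it is
monotone only up to the reference temperature, which is where the maximum
oxygen consumption was observed. At 271.5 K, c = 0.414, taking the
volume-specific maintenance from 6.93 to ≈ 2.87 J d⁻¹ cm⁻³.

## Calibration

Three quantities are not published and are derived once:

* **Maturity thresholds and s_M.** Forward integration at f = 1 against
  physical-length anchors: arm length 0.03 cm at birth and 2.15 cm at
  puberty. The metamorphosis anchor is derived from the 7.10 cm maximum
  length through the closed form L∞ = f s_M κ {pAm}/[pM] (giving
  s_M = 5.077, L_j = 0.152 cm — consistent with the published two-decimal
  stage lengths, and the choice that keeps the precisely published maximum
  length exact rather than the one-significant-figure larval lengths). The
  egg energy E₀ is solved jointly by a shooting iteration (bracketed Brent
  on log E₀) so that reserve density at birth equals f·[Em]. Thresholds are
  temperature-independent: a thermal correction rescales time, not the
  state-space path (verified numerically).
* **Wet coupler d_dw.** The reserve coupler ρ_E = w_E/μ_E is a dry-mass
  coupler (it reproduces the egg dry weight), while body weights and organ
  indices are wet. A single dry-to-wet ratio for reserve-like tissue
  (reserve, buffer, gonad — assumed of similar composition) is solved from
  the f = 1 pyloric-index anchor: (ρ_E/d_dw)[Em] / (1 + (ρ_E/d_dw)[Em]) =
  0.30, giving d_dw ≈ 0.099. Nothing else is tuned: the field-food PI
  (0.255), the reserve share of body weight (≈ 27%) and the maximum weights
  then follow.
* **Oxycaloric coefficient.** 13.556 J per mg O₂, the exact ratio of the
  published starved-respiration pair (558 µg O₂ d⁻¹ cm⁻³ ↔ 7.564 J d⁻¹
  cm⁻³).

## Reproduction

Allocation to a developing cohort of age t (years) is
`pYn = pR · norm · a · t^b` with a = 1.201, b = 1.157 and
`norm = (b+1)/(a·2^(b+1))` ≈ 0.403, chosen so that the drain of two cohorts
(ages t and t+1) integrates to exactly one year's pR income — without it the
published constants would overdraw the buffer by a factor ≈ 2.5. A convenient
identity follows: each cohort's lifetime allocation equals one annual
income, so the mature cohort holds κ_R × (annual pR) when spawning opens.
The buffer E_R carries the running imbalance (minimum zero at each cohort
onset); κ_R = 0.95 is paid when buffer energy becomes gonad, and gonad wet
mass uses the same ρ_E/d_dw coupler as reserve.

Calendar (configurable): cohort onset 1 June, development exactly 730 d,
spawning 1 July – 1 October with the mature cohort's mass declining
linearly. `simulate_gonad_cycle` steps this bookkeeping at Δt = 0.25 d from
a warm start at the stationary configuration; a closed-form stationary
cycle (`stationary_cycle`) provides an independent cross-check, and the two
agree on the mean standing energy to < 1%. The cycle minimum of the
standing stock (gonad + buffer) is ≈ 43% of its maximum: a large fraction
of the reproductive investment is always present in the body.

In `fit_cohort_params` the normalisation is *not* applied — under the
normalised law the coefficient a cancels from a single-cohort trajectory
and only b would be identifiable. The fitted model is the integrated
un-normalised law Y(t) = ρ_E κ_R pR · 365 · a · t^(b+1)/(b+1), which makes
(a, b) jointly identifiable; generate-and-refit round trips on clean data
return both to better than 0.1%.

The whole-life simulation keeps a single aggregate reproductive pool with
one spawning event per year (removing the maturing cohort's two-year mean
income); the two-cohort detail is resolved by the fixed-size gonad-cycle
simulation. The ultimate wet weight reported by `ultimate_size` includes
the annual-mean standing gonad + buffer of the stationary cycle.

## Estimation procedures

* **Arrhenius fit:** `least_squares` over (T_A, T_L, T_H, T_AL, T_AH,
  T_ref) on rates scaled to max 1. Start values: T_A from a log-linear
  regression of log rate on 1/T over the rising branch; T_L/T_H from the
  observed extremes; generic 5e4 K boundary slopes; T_ref free, starting at
  the temperature of the maximum. On data from inside the tolerance window
  the lower-boundary term is O(1e-11), so T_AL is unidentifiable (its SD is
  reported accordingly via a pseudo-inverse covariance); T_A recovers to
  well under 1%.
* **Shape coefficient:** the cube law W = (δL)³ is linear in δ³, so the
  weighted least-squares solution is closed-form; SD via the delta method.
* **Covariation (simplified):** a single Nelder-Mead run minimising the
  weighted sum of squared relative errors over zero-variate observations
  plus optional pseudo-data penalties, scored by the mean absolute relative
  error (arithmetic mean of |pred−obs|/|obs|). Maturity thresholds are held
  at their data-anchored values while parameters vary. Convergence
  tolerance 1e-6, max 5000 iterations. Self-consistency recovery (exact
  observations, start perturbed ±10%, free = {pAm}, [pM], κ) returns all
  three to < 2%.
* **Field functional response:** asymptotic length is linear in f, so the
  field f is fitted as a bounded 1-D minimisation of the relative error of
  the predicted maximum length.

## Synthetic data

Generators emulate the unpublished observation sets with known truth:
cube-law length–weight pairs, the thermal response sampled on
[T_L−2, T_H+3] K scaled to max 1, lifecycle growth series, cohort
mass-at-age trajectories, and full zero-variate records. Noise defaults:
multiplicative lognormal (sd 0.1) for masses (strictly positive), additive
gaussian (sd 0.05 of the maximum) for scaled rates; a single integer seed
drives all draws and fixed seeds reproduce tables bit-for-bit. The
generators share the package's own forward model for growth and
zero-variate kinds, so round-trip tests demonstrate estimator correctness
(self-consistency), not correctness against independent laboratory data;
the cube-law and power-law kinds are closed forms independent of the ODE
machinery. Real data would add digitisation error, individual variability
and seasonal forcing that the generators deliberately omit.

## Problem sizes and known limitations

The shipped analyses use desk-scale runs: 40–50 year trajectories for
asymptotic checks, 12 years for field-food puberty, 5-year gonad cycles,
24-point cohort series, 12-point thermal series and 100-replicate
Monte-Carlo recovery studies. Known limitations: no seasonal food or
temperature forcing (published runs use constants); no spermatogenesis; no
oocyte size/count structure within a cohort; no body-wall or gonad
resorption under starvation; prey density is never modelled, only the
scaled functional response f; and the wet-mass convention rests on the
single calibrated d_dw, whose value is a reconstruction rather than a
measured quantity.
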