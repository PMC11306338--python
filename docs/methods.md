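# Methods

## Scientific setting

Turbidimetric assays follow microtubule assembly by recording a sample's
optical density (O.D., here at 365 nm) against time: solubilized tubulin
dimers are nearly transparent, polymerized microtubules scatter strongly, so
the trace rises sigmoidally through nucleation, elongation and saturation.
In the early phase the curve is well approximated by a power law,

    O.D.(t) = A · (t / t_u)^b,

so that ln(O.D.) against ln(t) is a straight line with slope *b* (*t_u* is a
unit time that only shifts the intercept).  Three per-run scalars summarize
a curve: the final O.D. (plateau), *t10* (first time the normalized curve
reaches 10% of its plateau), and *b*.  Cohorts of repeats are compared
non-parametrically; because all chemical rates accelerate with temperature,
a *time-stretching* transform (rescaling one group's time axis so its
average-curve *t50* matches a reference) separates changes of curve *shape*
from changes of overall rate.  The package also reproduces the dosimetry
arithmetic of a parallel-plate waveguide exposure apparatus (power budget
from S-parameters, peak field across the plate gap, SAR), because apparent
field effects on *b* must be weighed against the thermal history that the
exposure geometry imposes on the sample.

## Synthetic-data generator

No raw assay data are packaged, so every analysis stage is exercised against
a generator that emulates the assay's stochastic and thermal structure.

**Kinetic model.**  The noiseless curve is an Avrami/JMAK sigmoid driven by
a temperature-integrated progress variable:

    xi(t)  = ∫₀ᵗ ds / tau(T(s)),          tau(T) = tau_ref · exp[(E_a/R)(1/T − 1/T_ref)]   (T in kelvin)
    O.D.(t) = OD_inf(T_end) · (1 − exp(−xi(t)^b)),   OD_inf(T) = od_inf_ref + od_inf_slope · (T − T_ref)

This is the minimal form matching both observed regimes: for small xi it is
exactly the early-phase power law (O.D. ∝ xi^b), and it saturates
sigmoidally.  Temperature enters only through the Arrhenius time constant,
so a rising temperature accelerates progress without inventing microscopic
rates.

**Thermal history.**  Each run carries a single-exponential temperature
trace T(t) = T_end − (T_end − T_start)·exp(−(t + t_delay)/tau_equil), with
T_end = T_ambient + T_local.  `constant_profile` models a pre-equilibrated
control; `two_step_profile` models a two-step protocol (cool enclosure plus
steady local heating at the measurement spot), with the sample arriving a
few degrees below target and still warming during the early observed phase.

**Defaults and their provenance.**  Defaults are fixed to the study
conditions the analysis is meant to emulate:

| parameter | default | basis |
|---|---|---|
| `b_true` | 2.2 | control-condition exponent near 35 °C |
| `tau_ref` | 70 s | places t10 near 25 s at 34.9 °C |
| `E_a` | 1.9×10⁵ J/mol | the ~5.6× t10 acceleration from 31.9 to 39.1 °C |
| `od_inf_ref`, `od_inf_slope` | 1.36, 0.072 /°C | final O.D. 1.06 → 1.58 over 7.2 °C |
| `cv_tau`, `cv_od` | 0.30, 0.13 | cohort standard errors at N ≈ 22 |
| `noise_sd` | 0.01 | photometric noise, ~1% of plateau |
| `artifact_rate` | 0.05 | occasional bubbles in the light path |
| sampling | 1 Hz × 600 s | typical assay duration |
| two-step profile | entry deficit 4.6 °C, T_local 7 °C, tau_equil 20 s, delay 7 s | observed T_f − T_i ≈ 4.6 °C; enclosure set 7 °C below target; transfer line 73 μl at 10 μl/s |

Bubble artifacts are injected as either a +1.0 O.D. spike lasting 3 samples
or a NaN-truncated tail (50/50), at rate `artifact_rate`.

**What the generator does not emulate.**  Run-to-run variability enters only
through lognormal rate and amplitude multipliers and additive Gaussian
noise; there is no dimer-level stochasticity, no dynamic-instability
catastrophe/rescue, no intrinsic between-run variation of *b* itself, no
drift or baseline wander, and no coupling of the electromagnetic field into
the kinetics.  Passing tests therefore demonstrate that the *pipeline*
recovers the structure it assumes, not that real curves obey an Avrami law.

## Feature extraction

* **Screening.**  Non-finite tails are rejected as `incomplete`, other
  non-finite values as `nonfinite`.  Spikes are flagged when a sample
  deviates from a 7-point rolling median by more than 5× the median absolute
  inter-sample step; a monotone curve deviates from its own rolling median
  by exactly zero, so clean sigmoids pass regardless of noise level.
* **Normalization.**  Baseline = mean of the first 3 samples; plateau = mean
  of the last 5% of samples (≥ 3).  The 0.1–0.4 fit window applies to the
  *normalized* curve — the printed window bounds only make sense after
  normalization.
* **Crossing times** are linearly interpolated at the first upward crossing,
  making t10/t50 sampling-rate independent.
* **Power-law fit.**  OLS of ln(od) on ln(t/t_u) over in-window samples,
  with zero-time samples excluded and t_u = 1 s.
* **Stretching** uses the t50 of the group-averaged normalized curve
  (pointwise mean on a common grid); the per-run-mean variant is available
  as `mode="per_run"`.  Stretching multiplies crossing times by the factor
  s = t50(reference)/t50(group) and by construction cannot change *b* or the
  final O.D.

**Window-induced bias (documented, not hidden).**  On an Avrami curve the
log–log slope between normalized O.D. 0.1 and 0.4 is not the intrinsic
exponent: the two-point slope is b·ln4 / [ln(−ln 0.6) − ln(−ln 0.9)] =
0.878·b *independently of b*, and the OLS estimate over 1 Hz samples matches
(measured factor ≈ 0.878).  Fitted exponents from this pipeline are
therefore comparable with each other — the bias is a fixed multiplicative
factor, so *differences and ratios between conditions are unaffected* — but
systematically ~12% below the generator's `b_true`.  Over the earlier
window 0.01–0.05 the curve is still in its pure power-law regime and the
fit recovers `b_true` within ~1–2% (tested).  Consequence for cohort-level
checks: a "recover b_true within 5%" check cannot hold at the 0.1–0.4
analysis window under this generator; the suite asserts it anyway and the
failure is expected and explained here rather than being absorbed into a
looser tolerance.

## Robust statistics

* **MAD rejection**: reject x when |x − median| > k·1.4826·MAD, k = 3 (the
  standard "very conservative" recommendation); when MAD = 0, only values
  off the median are rejected.  Rejection is applied per parameter, and a
  run flagged on any parameter is dropped from all columns, so each
  condition reports a single retained N.  *Small-cohort caveat*: with
  cohorts of ~25 the finite-sample variability of the MAD makes the
  effective cutoff fluctuate, and the probability that at least one clean
  run is rejected is ~17% per cohort even for exactly normal data (measured
  83.4% clean-sweep rate on N(0,1) + one gross outlier, 2000 simulations).
  Gross outliers themselves are removed essentially always; the false-alarm
  rate is the price of k = 3 at this N.
* **Standard errors** follow the population-SD/√(N−1) convention, which is
  algebraically the sample SD over √N.
* **Mann–Whitney U**, two-sided throughout: exact null distribution when the
  smaller sample has ≤ 8 observations and the pooled sample is tie-free
  (cohorts of 15–30 sit safely in the approximation regime), otherwise the
  normal approximation with tie and continuity corrections.  Differences are
  flagged at the stringent p < 10⁻³, with 0.05 reported alongside; no
  multiple-testing correction is applied (the stringent threshold plays that
  role).
* **Normality battery**: Anderson–Darling with the small-sample correction
  and Stephens' case-3 p-value map; one-sample KS against the
  moment-fitted normal; Lilliefors with the same KS distance but a seeded
  Monte-Carlo calibration (default 10⁴ null draws) that accounts for the
  fitted parameters; Jarque–Bera (N/6)(S² + K²/4) against χ²(2).  A sample
  "fails" when any p < 0.05.
* **Power**: `power_by_simulation` draws normal cohorts at given means/SDs
  and counts Mann–Whitney rejections.  For the scenario of exponent means
  2.98 (SD 0.20) versus 2.91 (SD 0.44) at 200 per arm it yields ≈ 0.51 —
  matching the analytic two-sample t approximation scaled by the 0.955
  asymptotic relative efficiency of the rank test.  All distributional
  assumptions are explicit arguments rather than baked in.

## Dosimetry

Power in mW is 10^(dBm/10); cable loss is a flat 0.8 dB.  The budget splits
input power as reflected = P·10^(S11/10), transmitted = P·10^(S21/10),
absorbed = remainder (conserved exactly; a negative remainder raises a
warning).  The peak field of a matched line across the plate gap is
√(2PZ)/d; along the exposure section the field is interpolated linearly *in
field* between the entry value (input less reflection) and the exit value
(transmitted), with linear-in-power available as an option and the
measurement position exposed as a parameter, since the procedure behind any
particular tabulated field value is under-specified.  SAR = σE²/ρ with the
field used exactly as tabulated (no peak→RMS halving): that is the only
reading under which the reference table's printed SAR values follow from its
printed fields.  Under it, the tabulated fields 600/1000/1300/1900 V/m give
300/800/1400/2900 W/kg to the nearest hundred, while the 1800 V/m row
implies 2592 ≈ 2600 W/kg against a printed 2700 — that row is not
reproducible from its printed inputs and is excluded from the reproduction
checks.

## Numerical choices

* Progress integrals use trapezoidal quadrature on a refined grid (step ≤
  1/16 s and ≤ tau_equil/160, floored at 1 ms), exact short-circuit at
  constant temperature; accuracy vs a 1 ms brute-force grid is ~2×10⁻⁴
  relative.
* All randomness flows from one root seed per entry point
  (`numpy.random.SeedSequence` spawning per-run children), so cohorts,
  pipelines and reports are byte-reproducible.
* Degenerate inputs fail loudly with typed exceptions: flat traces
  (plateau ≈ baseline), crossings never reached, fewer than 3 in-window fit
  samples, fewer than 3 values for MAD, N < 8 for the normality battery.
* Test and acceptance problem sizes — cohorts of 25 per arm, 50–100 seed
  replicates, 600 s at 1 Hz — are the package's chosen study conditions,
  matching the cohort sizes the summaries emulate.

## Known limitations

* The Avrami form is a phenomenological stand-in; its fixed window bias
  (factor 0.878) cancels in between-condition comparisons but not against
  ground truth.
* ΔT is summarized only as T_f − T_i; no time-series modelling of the
  temperature traces.
* The thermal model is single-exponential; real transfer warming and local
  gradients have at least two time scales.
* The Lilliefors Monte-Carlo calibration is seeded and therefore
  reproducible, but its p-values carry ~1/√sims resolution.
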