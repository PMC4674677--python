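# Methods

## The counting principle

A cell is induced to assemble one inert fluorescent particle and the
inducer is then removed. Because the particle neither replicates nor is
destroyed on ordinary experimental timescales, each division passes it to
exactly one daughter: the fraction of bright ('on') cells, *f = p/n*,
halves once per generation, and log2 *f* declines linearly in time with
slope −1/τ_ON, where τ_ON is the population doubling time. All counting in
this package reduces to estimating that slope from sampled on/off counts.
"Generations" always means dark-cell generations, μ_D·t/ln 2.

## Deterministic error model

Particles and cells obey

    dp/dt = K_split·p + K_fp·(n − p) − p/τ_p
    dn/dt = μ_B·p + μ_D·(n − p)

with at most one particle per cell, so *p* counts bright cells and
*n − p* dark ones. K_split (h⁻¹) is the rate at which a division yields
two bright daughters, K_fp (h⁻¹) the rate at which an uninduced dark cell
spontaneously assembles a particle, 1/τ_p (h⁻¹) the particle decay rate
(τ_p = ∞ is a first-class value meaning no decay), and μ_B, μ_D (h⁻¹) the
growth rates of bright and dark cells. Starred quantities are normalized
per generation (divided by μ_D). Since false production must act on cells
that lack a particle, its term carries the factor *n − p*; this is also
what makes the long-time floor equal K*_fp rather than larger.

Numerically we integrate the equivalent system in (f, ln n) — the
on-fraction and log population size — which stays conditioned over dozens
of generations of exponential growth (LSODA, rtol 1e-10, atol 1e-18; the
tight absolute tolerance keeps particle conservation to better than 1e-8
relative even at on-fractions of 1e-6).

Three analytic results are exposed:

1. **Floor / dynamic range.** As t → ∞, L = lim p/n satisfies the fixed
   point L = [K*_split·L + K*_fp·(1−L) − L/τ*_p] / [1 + (μ_B/μ_D − 1)·L]
   (L'Hôpital applied to p/n as both diverge), solved by bracketed root
   finding on [0, 1) to 1e-12. For negligible splitting and decay,
   L ≈ K*_fp — the dynamic range `log2(f₀/L)` is set entirely by false
   production, gaining one generation each time K*_fp halves. A
   normalized false-production rate ≥ 1 (marker replicating as fast as
   cells) is rejected as a violation of the counting assumption.
2. **Growth-rate disparity is transient.** The normalized population
   growth rate is 1 + (μ_B/μ_D − 1)·f; any disparity decays in lockstep
   with the on-fraction, approaching a factor-2 shrink per generation
   from below when bright cells grow slower.
3. **Error budget.** The per-capita dp/dt terms — K_split·f, −f/τ_p,
   K_fp·(1−f) — show splitting and degradation halving in importance per
   generation while false production rises to its ceiling K_fp.

## Stochastic simulator

The simulator is generation-synchronous: every cell divides once per
generation, and error events are Bernoulli draws per cell. Events are
drawn against the *start-of-generation* pools, then cells divide. This
ordering is not cosmetic: integrating the continuous false-production
rate over the exponentially growing dark pool during one generation gives
exactly K*_fp times the starting dark count, so the per-generation
probability `p_false_per_gen` corresponds one-to-one with the normalized
continuous rate, and the stochastic floor matches the deterministic one.
Splitting and decay act on the bright pool, which faithful segregation
holds constant within a generation, so their probabilities map to
ln 2 × the normalized rates; `matched_error_model` encodes both
conversions and is how simulator runs are compared against the ODE.

Differential bright/dark fitness is implemented as fractional expected
offspring: a bright lineage produces 2^(μ_B/μ_D) offspring per dark
generation, with the surplus or deficit landing in the dark daughter pool
so the bright count itself stays conserved (the deterministic model
remains the reference for growth-rate effects). With all error
probabilities zero the bright count is non-random and the on-fraction
halves exactly — the binomial oracle is exact. Populations are capped
(default 1e7) by uniform hypergeometric subsampling; cytometry-style
subsampling uses a hypergeometric draw with a binomial approximation when
the population is at least 100× the sample.

The turbidostat wrapper grows the total population exponentially between
optical-density thresholds, fires the per-generation error draws at
generation boundaries, and on crossing the top of the band thins every
cell independently down to the bottom — which leaves the expected
on-fraction unchanged (verified as a property test).

## Cytometry

Synthetic mixtures are two log-normal classes on the red channel with an
exact generator median ratio (`fold_separation`) and a shared spread
`log10_sd` = 0.25 by default. Observed bright/dark separations span
20–200-fold; the default spread is chosen so that even the conservative
20-fold end is classified nearly perfectly (AUC > 0.99 at 1e4 events per
class), which is the regime the hardware designs were selected to reach.
Events at or above threshold are 'on' (ties 'on', stated and tested). The
ROC sweep uses the distinct observed intensities plus an above-maximum
endpoint, so the trapezoidal AUC is exact for the sample and equals the
Mann–Whitney U statistic normalized by n₁·n₂ (a property test checks this
against the rank-based computation, and against scikit-learn's
independent implementation). On-fraction intervals are Wilson scores
(statsmodels), 95% by default.

## Growth estimators

`fit_on_fraction_decay` is OLS of log2(n_on/n_total) on time with three
exclusion rules, all configurable: the first two sampled points are
dropped by default (cultures take a generation or two to adapt after
transfer); points with fewer than 10 on-events carry too little signal;
and points whose Wilson 95% lower bound overlaps the configured
false-production floor (default 1e-3) are excluded, because the decay
flattens as it approaches the floor and drags the slope. A decay must be
statistically meaningful: fits where the slope's 2-SE upper bound reaches
zero raise "no decay detected", so flat series with counting noise do not
produce spurious doubling times. In-vivo red/green series (n_on = RFP⁺ &
GFP⁺, n_total = GFP⁺) are fitted per mouse and pooled as an unweighted
mean ± sd across mice.

The optical-density chain mirrors the turbidostat firmware's processing:
%T = 100·(reading/blank); raw OD = −log10(%T/100), capped at 4 for
near-opaque samples; reference OD = C1·raw + C2·raw² with the quadratic
forced through the origin (a blank must read zero); τ_OD = ln 2 / slope
of ln OD within one inter-dilution segment. A valve event row carries the
post-dilution reading and therefore starts the next segment. The α
correction, α = 1/τ_OD − 1/τ_ON, quantifies residual particle production
after washout (which inflates τ_ON); the identity α + 1/τ_ON = 1/τ_OD
holds by construction.

Transit time is the sampled time at which a mouse's GFP⁺ faecal fraction
peaks — a grid argmax, not a fitted distribution median, mirroring how
the measurement is actually read off 2-hourly samples — with the removal
rate reported as the reciprocal of the across-mouse median. A
monotonically rising series has no observed transit and is an error.

## Gut colonization models

Seven cases cover the candidate forces shaping a gavaged strain's
population (equations in the `gut_dynamics` module docstring). Default
rates are the measured ones: growth 1/3 h⁻¹, removal 1/6 h⁻¹ (median
transit 6 h), densities normalized to a carrying capacity of 1. Design
choices where the model family left room:

- **Adaptation death rate.** D(t) = d_min·(1 + d_max·e^(−t/τ_D)), so the
  maximal (initial) death rate is (d_max + 1)·d_min and the steady-state
  rate is d_min. τ_D is interpreted as a timescale in hours. With
  d_max = 30 and d_min ∈ [0, 1/3], initial death rates span 0–10 h⁻¹.
  Note d_min = 0 gives no death at all under this form — a dip requires
  d_min > (g − R)/(d_max + 1).
- **Interactions.** Both species share the carrying capacity and removal
  rate; the signed symmetric term k_p·x·y is the only death/benefit
  channel. Strong mutualism (k_p exceeding the logistic rates) produces a
  genuine finite-time blow-up of the quadratic coupling; the solver
  detects divergence past 1e9 and raises a diagnostic rather than
  overflowing, so the growth regime is inspected on short horizons.
- **Phage closure.** Free phage are washed out with gut contents at the
  same removal rate R.

No-feedback and physiological-removal trajectories are pure exponentials
and use the closed form, as does the logistic case; the rest use LSODA
(rtol 1e-8, atol 1e-10, one automatic tolerance-tightening retry,
non-negativity clipped at integrator tolerance). Regime classification
measures d(ln x)/dt over the final 20% of the trajectory (tolerance 1e-3
h⁻¹): growth/decline by sign, steady state when flat, dip-then-recover
when a flat positive plateau follows a dip below (1 − 0.05)·x₀, crash
when the final density is ≤ 1e-8 of the trajectory scale. A declining
population that has not yet neared zero classifies as exponential_decline
even when its fixed-point analysis says extinction is the only steady
state; the two views are complementary.

## Synthetic experiments

The gavage emulator encodes the in-vivo design: faecal samples every 2 h;
a GFP⁺ transit pulse rising linearly from first appearance (4 h) to its
peak (6 h) and then declining exponentially at the removal rate (the
pulse shape between those anchors is not constrained by measurement; a
linear rise is the simplest choice and the estimators only use the peak
location); a red-among-green fraction decaying two-fold per generation
from 70% induced, toward a reinduction floor of ≈ 2× the per-generation
reinduction probability (zero by default; the uninduced-control emulation
stays below 1% on-fraction). Counts are binomial/multinomial draws at 1e5
events per sample — typical for a cytometry run; the true per-sample
event count was not recorded, so this is a configurable default. What the
generator does *not* emulate: inter-mouse microbiota variation, diet,
antibiotic pretreatment, gut-specific lag, or non-stationary removal —
so passing recovery tests demonstrates estimator correctness under the
stated kinetics, not robustness to every in-vivo nuisance.

The turbidostat trace generator inverts the calibration chain (positive
root of the origin-forced quadratic, then reading = blank·10^(−raw OD))
and adds multiplicative Gaussian reading noise, with valve events at band
crossings — so the OD pipeline can be round-tripped exactly at zero noise
and to ~2% at 1% reading noise.

The fixture suite writes small CSVs (mixture, noiseless decay series at
0.5/1/2/5 h doubling times, a gavage dataset, a trace, a model spec) with
a manifest of generator parameters and SHA-256 checksums; fixtures are
regenerated programmatically, never stored.

## Problem sizes and numerical choices

Simulations in the tests and the acceptance script use 1e5-cell samples,
6–14 generations, 100-replicate ensembles for mean-vs-ODE comparisons,
and 1e4 events per class for ROC analysis — sizes at which the sampling
error of each check is comfortably below its tolerance. Fixed-point
solving uses brentq on [0, 1) with xtol 1e-12; OLS fits use
scipy.stats.linregress; quadratic calibrations use ordinary least squares
on the [x, x²] design with a rank check.

## Known limitations

- The generation-synchronous simulator matches the continuous-time error
  model to first order in the per-generation probabilities; at extreme
  rates (probabilities ≳ 0.1 per generation) the discretization bias
  becomes visible and the ODE is the reference.
- Differential-fitness simulation uses expected-offspring weighting, not
  per-cell lifetime variation; it is meant for error studies, not for
  inference about fitness itself.
- The gut models are illustrative dynamical systems with hand-set rates;
  no fitting of these models to data is provided by design.
- FCS file ingestion requires the optional `fcsparser` dependency and is
  read-only; the CSV event schema is the supported interchange format.
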