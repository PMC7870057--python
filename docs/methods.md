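# Methods

## The model

A limiting-dilution plating distributes a fraction *f* of a transfection
across *W* wells. If the transfection produced *N* independent stable
clones, each well receives a Poisson-distributed number of clones with mean
λ = *N·f/W*, and under the single-hit assumption a well scores positive iff
it received at least one clone:

    P(positive) = 1 − e^(−λ)

so the positive-well count is *k* ~ Binomial(*W*, 1 − e^(−λ)). Inverting the
observed fraction gives the per-plate MLE λ̂ = −ln(1 − k/W) and
N̂ = λ̂·W/f. When several plates (different fractions) come from one
transfection, `estimate_efficiency` maximises the joint binomial likelihood
over a shared *N* rather than averaging per-plate estimates; this uses the
information in saturated plates (k = W), whose own λ̂ is unbounded, through
their likelihood term. If *every* plate is saturated only a one-sided lower
bound is reported: the smallest *N* for which all-positive plates retain
probability at least 1 − ci_level.

The replica-plating loss model: after induction each cell has independently
lost the selectable marker with probability *q*. Cells are plated without
drug at λ cells per well; a populated well becomes drug-sensitive on the
selective replica iff **all** of its founder cells lost the marker. With
zero-truncated Poisson founders,

    P(sensitive | populated) = (e^(−λ(1−q)) − e^(−λ)) / (1 − e^(−λ))

which tends to *q* as λ → 0 (single-cell wells) and is depressed at higher
λ because crowded wells rarely lose every founder. The point estimate
inverts this at the observed sensitive fraction *s/n* in closed form:
q̂ = 1 + ln(s/n·(1 − e^(−λ)) + e^(−λ))/λ. λ itself is estimated from the
populated-well count of the same plate (*n* of *W*); the nominal plating
density (typically 1.5 cells well⁻¹) is only a fallback when *n* = 0 or
*n* = W leaves λ unidentified.

Loss is treated as complete before plating (induction precedes plating);
partial resistance, drug-concentration effects and loss during outgrowth
are not modelled.

## Confidence intervals: simulated confidence belts

Both interval procedures are Neyman belt constructions with Monte-Carlo
bands. For a grid of parameter values (λ or *N* on a log grid; *q* linearly
on [0, 1]) the outcome statistic is simulated, the equal-tailed central
interval at the nominal level recorded, and the confidence set is the set
of grid values whose band contains the observation.

Numerical choices:

- **Grids.** λ: 200 log-spaced points on [0.001, 10] cells well⁻¹ by
  default (both bounds and resolution are config parameters); *N*: the λ
  grid mapped through W/f; *q*: step 0.005 by default. The total simulation
  budget (default 10⁶) is split equally across grid points.
- **Band edges** are empirical `inverted_cdf` quantiles, isotonically
  smoothed along the grid (scipy's isotonic regression) and rounded back to
  counts; this removes Monte-Carlo ripple and guarantees the accepted set
  is an interval, not a union of intervals. With exact bands this
  construction reproduces the Clopper–Pearson interval for a single plate
  (mapped through λ = −ln(1 − p)), which is the test oracle.
- **Endpoints** are reported at the midpoint between the outermost accepted
  grid value and its first rejected neighbour (geometric midpoint on log
  grids). Reporting the accepted grid value itself truncates the acceptance
  region by up to one grid step per side and measurably under-covers
  (0.80–0.84 instead of ≈0.91 at 100 grid points in our calibration runs).
- **Multi-plate inversion** uses the single scalar statistic
  T = Σᵢ kᵢ/fᵢ (positive wells weighted by reciprocal plated fraction), so
  the belt stays one-dimensional.
- **One-sided cases.** k = 0 (or a fully sensitive/insensitive replica) is
  reported one-sided at the full level, matching how an upper bound such as
  "q ≤ 0.08" is naturally quoted. Saturated observations are truncated at
  the grid maximum and flagged.
- **Determinism.** One seeded generator per run; the seed and budget are
  echoed in every report. Identical config + seed gives identical
  intervals.

For the loss interval, λ uncertainty is propagated by resampling
λ* ~ Normal(λ̂, SE) truncated at 0 for every simulated plating, with the
delta-method spread SE = √(p̂/(W(1 − p̂))), p̂ = n/W. The belt then draws
sensitive ~ Binomial(n, P(sensitive | λ*, q)) **conditionally on the
observed populated count n** — the same count λ̂ was estimated from — and
shares the λ* and populated draws across the q grid (common random
numbers). An unconditional variant that also redraws
populated ~ Binomial(W, 1 − e^(−λ*)) is available
(`resimulate_populated=True`); it is slightly conservative because the
observed sensitive count is in fact conditional on the observed populated
count. A mid-P acceptance rule was evaluated and rejected: it under-covers
(down to 0.78) exactly where small expected counts make the standard rule
conservative.

## Calibration and its limits

Monte-Carlo calibration (500 replicates per scenario, budget scaled to
2–5 × 10⁴ platings per interval) shows:

- clone-number 90% intervals cover the truth at ≈0.91 with mean relative
  bias below 2% for truths drawn log-uniformly across 100–6000 clones under
  the {20%, 4%} two-plate design and 1000–60000 under {2%, 0.4%};
- loss-probability 90% intervals cover at 0.87–0.95 for q ∈ {0.2, 0.5, 0.8}
  across λ ∈ {0.5, 1.5, 3};
- at q = 0.05 the intervals over-cover (≈0.97) at every λ tested. This is a
  floor imposed by outcome discreteness, not a fixable defect: the expected
  sensitive count is ~1–2 wells, the interval can only exclude the truth
  when s exceeds the 95% band at q = 0.05, and that tail holds ~2–3% of the
  mass. Exact-style intervals on such coarse outcomes are necessarily
  conservative; only randomized (Stevens-type) intervals reach nominal
  coverage there, and those are unsuitable as a reporting convention.

"Accuracy" of a plating design is summarised as relative interval width
(hi − lo)/N̂; the package's working threshold is 1.25 (N pinned within
roughly ±60% at 90% confidence), which both two-fraction designs meet
across their intended ranges, with the worst case (≈1.05) at the bottom
edge where expected counts are smallest.

## The synthetic-data generators

`gen_transfection` draws plate counts Binomial(W, 1 − e^(−N·f/W)) for a
known clone number; `gen_loss_experiment` draws a populated count at a known
λ and a sensitive count with per-cell Bernoulli(q) loss applied before
plating. They emulate exactly the sampling assumptions of the inference
(Poisson filling, single-hit scoring, all-founders-lost sensitivity), so
passing calibration demonstrates internal consistency of the procedures —
it does not probe deviations real platings can show (cell clumping or
settling, partial drug kill, well-to-well volume variation, loss during the
7-day outgrowth). Generators are pure functions of (truth, seed).

## Other utilities

- Fisher's exact test (two-sided, minimum-likelihood convention, via
  scipy) for comparing sensitive-well proportions between conditions; a
  zero margin returns p = 1.
- Per-generation conversion of a total loss fraction:
  p_gen = 1 − (1 − p_total)^(doubling_h/duration_h). The doubling time is
  an explicit argument; the package does not guess it.
- Doubling time from a growth series by least squares on log₂(density)
  versus time, SE by the delta method.

## Problem sizes used in the shipped checks

The shipped test-suite and reproduction script use 10⁵ simulated platings
per q grid point (2 × 10⁷ total) for the headline bounds, 2 × 10⁵ per λ
grid point for the Clopper–Pearson comparison, and 2–5 × 10⁴ per interval
inside the 500-replicate calibration loops; these sizes give Monte-Carlo
error well inside every tolerance asserted.
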