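# Methods

This note documents the models implemented in `plaidchoice`, the assumptions
of the synthetic-session generator, the default parameters and the numerical
choices, in the package's own words.

## Task structure and data model

A session is an ordered table of trials. Each trial presents a plaid drifting
in one of two pattern directions (90° up, 270° down) with a signed
texture-cue contrast drawn from the 11-level set
(−80, −40, −20, −10, −5, 0, 5, 10, 20, 40, 80) % Michelson (transparent
negative, coherent positive); one inter-grating angle (95°–130°) holds per
session. The subject reports "coherent" or "transparent"; cue-consistent
reports are rewarded, and zero-contrast trials are rewarded with probability
0.5. Correctness is undefined at zero contrast. Spike counts are accumulated
over the whole 1.5 s stimulus epoch; firing rate = count / duration. Spike
times (ms from onset) are optional and only required by the CP time course.
Trial order is preserved because the choice-history analysis needs it.

Tuning blocks are separate fixation-only measurements: responses to sine
gratings moving in 16 directions 22.5° apart, and to sine-grating plaids with
a 135° inter-grating angle indexed by pattern direction, with a baseline rate
from flanking no-stimulus epochs.

## Psychometric model

P(coherent | c) = Φ((c − μ)/σ), fit by Bernoulli maximum likelihood with no
lapse/guess parameters; keeping the model plain preserves the identity
threshold = μ + σ ⇔ Φ(1) ≈ 84% cue-consistent choices. "Slope" is reported as
1/σ (the function's maximal derivative up to the constant φ(0)), so that
angle manipulations that *shift* the function (μ) separate from those that
*steepen or flatten* it (σ). Zero-contrast trials enter the fit — their
choices inform μ.

Numerics: L-BFGS-B on (μ, σ) with σ bounded in [10⁻², 10⁴], multi-started
from a probit-regression method-of-moments initializer plus a log-spaced σ
grid; deterministic by construction. Standard errors come from the inverse
observed information (central finite differences). A fit with σ on a bound is
flagged degenerate; all-one-choice data raise a degenerate-fit error that
carries the best bounded fit. R² is computed between observed and fitted
per-contrast proportions, unweighted — the simplest statistic for session QC.
The QC cutoff (default R² ≥ 0.6) is configuration, not a measured constant.
Inter-grating angles are min–max normalized over the configured angle set
before correlating with PSE and slope.

## Tuning model and classification

Grating tuning is fit by least squares with
R(θ) = b + a·exp(κ(cos(θ − θ_pref) − 1)), multi-started over the sampled
direction grid; FWHM = 2·acos(1 − ln2/κ) when κ ≥ ln2/2, else 360°. Curves
with ~zero variance are flagged untuned.

The pattern prediction is the grating curve itself; the component prediction
is (R(θ−67.5°) − b) + (R(θ+67.5°) − b) + b. Baseline is subtracted before
summing and added back once so the spontaneous rate is not double-counted
(a design choice; the alternative — no subtraction — only shifts the
prediction by a constant and leaves correlations unchanged). Offsets are
multiples of the 22.5° sampling, so the circular linear interpolation used
for general angles is exact at the default spacing. Plaid tuning is indexed
by pattern direction throughout.

Partial correlations Rp, Rc of the measured plaid curve with the two
predictions use the closed first-order form
Rp = (r_p − r_c·r_pc)/√((1−r_c²)(1−r_pc²)) (symmetrically for Rc); raw
correlations are clamped at |r| = 0.9999 so exact matches stay finite.
Fisher z uses n = 16, the number of tuning-curve points, as the sample size:
z = atanh(r)·√(n−3). Classification: pattern iff Zp − max(Zc, 0) ≥ 1.28 (the
one-tailed p = 0.1 z-score), component symmetrically, else unclassified; the
criterion is exposed as configuration for sensitivity analyses. PI = Zp − Zc.
The two class rules are mutually exclusive for any positive criterion.

## Signal detection

The ROC area is the tie-aware pairwise probability (ties credited 0.5),
computed from midranks — exact, not a trapezoidal approximation on binned
criteria. Cue preference comes from an OLS regression of firing rate on
signed contrast over correct, cued trials only; zero-contrast and error
trials are excluded there precisely so the later choice analyses cannot bias
the preferred/null tags.

The neurometric function takes one ROC per contrast magnitude (preferred-cue
vs null-cue correct-trial rates), mirrors each point onto the
preferred-positive axis as (+m, ROC), (−m, 1−ROC), and reuses the
psychometric fitter on these weighted proportions; the neuronal threshold is
the fitted mean + 1 SD, the same ~84% convention as behavior, so the N/P
ratio compares like with like. Thresholds extrapolating beyond five times the
largest tested contrast are flagged degenerate (a near-flat neurometric
function measures nothing) and excluded from population summaries.

Per-condition CP requires ≥ 5 choices of each type; for the CP-vs-choice-ratio
analysis the rule relaxes to at least a single error (both choice types
present). Grand CP z-scores counts within each signed-contrast condition of
one direction (conditions with zero variance are dropped and logged), pools
conditions with |c| ≤ 20%, and computes one ROC — so it is invariant to
per-condition affine transforms with positive scale. Grand CP is computed per
pattern direction (a unit can contribute two values). Optional per-unit
significance uses within-condition permutation of choice labels (seeded,
default 2000 permutations). The time course slides a 100 ms window in 10 ms
steps (both configurable; 20 ms steps are a documented alternative
convention) over spike times from 200 ms before onset to 200 ms after offset.

## Population statistics

A unit's "best" pattern direction minimizes the circular distance to its
preferred direction (exact ties broken by the lower neuronal threshold); the
normalized preferred direction is the magnitude of that difference, folded
into [0°, 180°]. Threshold-ratio profiles bin this angle in 10° bins and
normalize worst/best threshold ratios by the *global* sample maximum (the
per-bin alternative is noted as ambiguous and not used). Geometric mean
regression uses slope = sign(r)·SD(y)/SD(x) through the means. The
CP ~ {threshold, PI} partial correlations use the same closed first-order
formula with t-distributed two-sided p-values (df = n − 3). The Rayleigh test
is z = n·r̄² with the standard Zar approximation for p; the circular mean's
SEM is the angular deviation √(2(1−r̄))/√n in degrees. Routine comparisons
(ANOVA, Wilcoxon rank-sum, Kruskal–Wallis) are thin aliases to scipy.

## The synthetic-session generator

The generator emulates exactly the statistical structure the analyses
assume — and no more:

* **Tuning.** Each unit is Von Mises tuned (preferred direction uniform on
  the circle; κ ~ lognormal around 2; amplitude ~ lognormal around 30 spk/s;
  baseline ~ gamma, mean 8 spk/s). Plaid responses mix the pattern prediction
  (weight w) and the component prediction (1 − w); w comes from a three-part
  mixture (defaults 25% near 1, 25% near 0, 50% intermediate) so pattern,
  component and unclassified cells all occur.
* **Texture modulation.** Expected rate adds slope × signed contrast with an
  independent slope per pattern direction (N(0, 0.08) spk/s per %), then
  clips at zero. Linearity in contrast is an assumption of the generator,
  chosen to match the linear-regression summaries the analyses use.
* **Count noise and choice coupling.** Per trial a shared fluctuation
  η ~ N(0,1) multiplies every unit's rate by max(1 + g·η, 0) (per-unit gain
  coupling g ~ U(0.05, 0.35); clip events are counted in the ground truth).
  Counts are Poisson around rate × duration, with an optional
  negative-binomial dispersion knob for overdispersion probes. The decision
  variable is DV = β_cue·c + β_pool·η + ε, ε ~ N(0, σ_d²); choice = coherent
  iff DV > 0. This single shared fluctuation is the simplest mechanism that
  yields a tunable CP — it stands in for pooled correlated variability
  without modeling noise-correlation matrices.
* **Implied behavior.** The generative psychometric function is exactly
  Φ(c/σ*) with σ* = √(β_pool² + σ_d²)/β_cue. Defaults β_cue = 0.056,
  β_pool = 0.5, σ_d = 1 give σ* ≈ 20% contrast, in the range of measured
  monkey thresholds; trials_per_condition defaults to 20 (and is enforced
  ≥ 20), matching the task's minimum per-condition count.
* **Reward.** Cue-consistent choices are rewarded; zero-contrast trials are
  Bernoulli(0.5).
* **Spike times.** Optionally emitted: piecewise-constant Poisson over
  pre-stimulus baseline, stimulus epoch and post-stimulus baseline, with the
  gain modulation restricted to a configurable coupling window — this is what
  lets the CP time course be given a ground-truth onset.

The RNG stream is laid out so that runs differing only in β_pool share
identical units, η, counts and decision noise (common random numbers), which
makes coupling-sweep comparisons nearly deterministic.

What the generator does **not** emulate: adaptation and serial dependence,
fixation breaks and eye movements, inter-unit noise correlations beyond the
single shared gain, non-Poisson temporal spike statistics, and any
nonlinearity of the rate-contrast relationship. Recovery tests passing on
this generator therefore certify the *analysis code*, not the biology.

## Problem sizes

The default demo pipeline and the test suite run at desk scale: tens of
units, 20–100 trials per condition, 1000-instance oracle sweeps, 20-seed
Monte-Carlo ensembles. These sizes were chosen so the whole suite completes
in well under a minute while leaving the Monte-Carlo bands comfortably
narrower than the effects they test. The independence-null check uses 200
single-unit sessions of 100 zero-contrast trials each — independent sessions,
because units simulated within one session share η and their CP sampling
errors are therefore correlated, which would invalidate an across-unit
confidence band.

## Known limitations

* The neurometric threshold convention (fitted mean + 1 SD on the
  preferred-positive axis) forces μ ≈ 0 by the symmetric construction of the
  mirrored points; conventions that fit asymmetric neurometric points
  directly would differ for strongly biased units.
* Grand CP pools within direction only; pooling across directions would
  require a cross-direction z-scoring convention the analyses deliberately
  avoid.
* The permutation test permutes choice labels within condition and is
  calibrated only under exchangeability of trials within a condition.
* `SimConfig` enforces ≥ 20 trials per condition; analyses of sparser designs
  need their own power considerations.
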