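# Methods

## The task environment

The simulated task is a two-stage Markov decision problem with a single
decision per trial.  Two stimulus sets are interleaved within each block
(50 trials each out of 100, at most three consecutive trials of the same
set).  In the *predictable* set, each first-stage action leads to one of
two second-stage stimuli with probability 0.75 (common transition) and to
the other with 0.25 (rare transition), with the mapping reversed between
actions.  In the *random* set, both second-stage stimuli are equally
likely and common/rare is undefined.  Both sets share one fixed reward
structure: one second-stage stimulus yields a win (+3 ct) with
probability 0.7, the other a loss (−3 ct) with probability 0.7.  Outcome
*expectancy* is defined purely from the reward structure: wins after the
high-reward stimulus and losses after the low-reward stimulus are
"expected"; the complementary cells are "unexpected".  Because the reward
structure is identical in both conditions, expectancy effects on the
simulated EEG cannot be confounded with objective reward probabilities —
only the transition structure (and hence the internal model it supports)
differs.

Condition sequences are generated by a feasibility-checked greedy shuffle
(each placement verifies that the remaining counts are still arrangeable
under the run-length cap), which is deterministic under a seed and never
dead-ends, unlike rejection sampling.  The environment layout — which set
is predictable, the transition direction, the high-reward stimulus — is
re-randomized per block, and agent state resets at block boundaries
accordingly.  Missed responses are not modelled; agents always respond.

## The hybrid reinforcement-learning model

Five free parameters: learning rate α ∈ [0, 1], eligibility trace
λ ∈ [0, 1], inverse temperature β ≥ 0, model-basedness ω ∈ [0, 1], and an
unbounded perseveration weight ρ.

Per trial, with second-stage stimulus p_x and reward r(t) ∈ {+1, −1}:

* stage-2 TD update: `Q_S2(p_x) += α · [r − Q_S2(p_x)]`; the bracketed
  delta is the reward prediction error (RPE) used throughout the EEG
  analyses.
* stage-1 update: `Q_S1(a) += α · [Q_S2(p_x) − Q_S1(a)] + α λ · [r −
  Q_S2(p_x)]`, both deltas referencing the stage-2 value *before* the
  same trial's TD update.  This is the standard SARSA(λ) orientation of
  the first delta — written with the opposite sign the recursion diverges,
  so the convergent form is implemented.
* forgetting: every stage-1 and stage-2 value of both sets except the
  chosen action's and the presented stimulus' is multiplied by (1 − α).
* internal model: a counter n(set, a, p) accumulates observed
  transitions.  With d(set) = [n(a₀→p₀) + n(a₁→p₁)] − [n(a₀→p₁) +
  n(a₁→p₀)], the set with the strictly larger |d| is tagged predictable
  and receives 0.75/0.25 transition beliefs oriented by sign(d); the
  other set (and both sets under a tie, including the all-zero start)
  uses 0.5/0.5.  Ties resolve deterministically so the likelihood has no
  hidden randomness.
* choice: model-based values from the one-step Bellman backup
  `Q_MB(a) = Σ_p P(p|a) Q_S2(p)` are mixed as `Q_net = ω Q_MB +
  (1 − ω) Q_S1` and passed through an overflow-safe softmax
  `P(a) ∝ exp(β Q_net(a) + ρ · rep(a))`, where rep(a) marks a repeat of
  the previous same-set choice.

Rewards are coded ±1 inside the model (β absorbs scale); ct payoffs are
kept for bonus accounting only.  All values, counters and the
perseveration reference reset at block boundaries, because sets are
re-assigned per block.  Simulation and likelihood replay share one
compiled state recursion, so the likelihood is exactly the probability
law of the simulator; a test replays a simulated session and recovers its
stored choice probabilities to < 1e−10.

## Fitting

Bounded parameters are transformed (logit for α, λ, ω; log for β;
identity for ρ) and all estimation happens on the unconstrained scale
with a weakly-informative Normal(0, 1.5) prior per coordinate (the model
family is standard but no canonical priors exist; 1.5 on the logit/log
scale is diffuse over the admissible ranges).  Only first-stage choices
contribute likelihood terms; the second stage involves no decision.
Choice probabilities are clamped at 1e−12 before the log.

* **MAP/MLE**: best of n L-BFGS-B restarts from Normal(0, 1) starts;
  deterministic under a seed.  Parameter subsets can be pinned to fixed
  values to form reduced model variants for comparisons.
* **Hierarchical MCMC**: subject-level vectors θ_s ~ Normal(μ, diag σ²)
  per coordinate, with conjugate Gibbs updates for μ (Normal prior, sd
  1.5) and σ² (Inverse-Gamma(2, 0.5)), and adaptive random-walk
  Metropolis updates for θ_s.  Proposals use a per-subject covariance
  seeded from a Laplace approximation at the subject's MAP mode and
  adapted during warm-up only (Haario-style), with step sizes tuned
  towards a 0.3 acceptance rate; several Metropolis sweeps run per
  recorded iteration (default 36) to reduce autocorrelation.  Chains
  start overdispersed around the MAP modes.  Split-Rhat and effective
  sample sizes are computed with arviz; at the reference scale (8
  subjects × 400 trials, 4 chains × 2000 iterations, 1000 warm-up) the
  maximum split-Rhat is ≲ 1.07 across seeds tested, under the 1.1
  convergence threshold.  Point estimates are posterior means on the
  natural scale.
* **WAIC**: the variance-penalty form, −2 Σ_i [log mean_d exp(ll_di) −
  var_d(ll_di)], from pointwise log-likelihood draws.

Identifiability: at the design size (4 × 100 trials) MAP recovery of α,
β and ω is approximately unbiased (the acceptance suite verifies
central-95% coverage over 50 replicates).  λ and ρ are weakly identified
— λ in particular is recovered with a downward bias under hierarchical
shrinkage — which is documented rather than hidden; nothing downstream
depends on λ's point value.  Subject-level fits here use one parameter
vector per subject over all trials; set-specific vectors would double the
parameter count without changing any quantity this package tests.

Trial-wise RPEs for the EEG analyses are obtained by replaying the fitted
(not the generating) parameters through the same recursion, mirroring the
model-informed analysis chain.

## Synthetic EEG

Epochs are trials × channels (FCz, Pz) × 1280 samples at 512 Hz, spanning
−1000..+1500 ms around feedback onset, in µV.  Each epoch is 1/f
background noise (power ∝ 1/f, per-epoch SD 8 µV — a realistic scalp
spectrum, so dB baselining is meaningfully exercised) plus
Gaussian-windowed components:

| component | channel | centre | width (σ) | kind |
|---|---|---|---|---|
| P2-like positivity | FCz | 170 ms | 25 ms | phase-locked bump, +5 µV fixed |
| FRN negativity | FCz | 270 ms | 28 ms | phase-locked bump, −2 µV base |
| late positivity | FCz | 400 ms | 55 ms | phase-locked bump, +4 µV fixed |
| P3 | Pz | 400 ms | 60 ms | phase-locked bump, +6 µV base |
| theta burst | FCz | 300 ms | 60 ms | 6 Hz, random phase per trial |
| delta burst | Pz | 400 ms | 90 ms | 2.5 Hz, random phase per trial |

Per-trial component amplitudes follow `base + valence·[loss] +
expectancy(condition)·[unexpected] + gain(condition)·|RPE|`.  The default
coefficients encode the target dissociation as generative ground truth:
FRN (−0.8 valence, −1.5 expectancy, −1.5 |RPE| gain) and theta (+0.5,
+1.0, +1.5) couple in *both* conditions; P3 (+2.5 expectancy, +2.5 gain)
and delta (+1.0, +1.5, plus a +win valence effect) couple only in the
predictable condition.  Magnitudes are in the low-µV range typical of
feedback-locked components against an 8 µV single-trial background.  The
fixed P2/late-positivity bumps give the waveform the positive flanks the
peak-to-peak FRN measure presumes.  The generator returns a ground-truth
ledger of injected amplitudes; noise-free round-trip tests verify the
measurement chain recovers them linearly with the analytically expected
slope.  Between-subject heterogeneity is modelled by scaling each effect
coefficient per subject with a (1 + Normal(0, 0.3)) multiplier.

What the generator does *not* emulate: volume conduction and channel
covariance, eye/muscle artifacts with realistic morphology (artifact
injection uses square pulses that the ±300 µV rule must catch), latency
jitter of components, autocorrelated single-trial amplitude drifts, and
any genuine neural dynamics.  Passing tests therefore show that the
analysis chain recovers known ground truth embedded in realistic noise —
not that real EEG would yield these effects.

## Component quantification

* Artifact rejection removes epochs deviating > ±300 µV from the epoch's
  channel mean (frontal blink channels exemptable).  Baseline is the mean
  of −200..0 ms.  Windows are closed ms intervals mapped to samples by
  rounding half-up; time 0 is feedback onset.
* **FRN**: after a zero-phase second-order 15 Hz Butterworth low-pass
  (zero-phase to protect peak latencies), the most negative local peak in
  200–350 ms minus the mean of the most positive deflections in 100 ms
  windows before/after the peak.  A flank window whose maximum sits on
  its outer edge grows outward in 10 ms steps up to 300 ms.  Peaks are
  local extrema with plateau ties resolved to the earliest sample; a
  search window with no local minimum falls back (flagged) to the window
  minimum.
* **P3**: mean amplitude 300–500 ms at Pz, unfiltered beyond the
  generator's band.
* **Time-frequency power**: FFT convolution with complex Morlet wavelets
  e^(−i2πft)·e^(−t²/2σ²), σ = 4/(2πf), 50 logarithmically spaced
  frequencies 1–50 Hz, wavelet support ±5σ (matching the independent mne
  implementation to < 0.001 dB).  dB = 10·log₁₀(power / baseline), with
  the baseline −300..−200 ms power averaged across trials per channel ×
  frequency before normalizing each trial — single-trial baselines are
  numerically unstable at 1–4 Hz.  Note the mean of single-trial dB sits
  ≈ −2.5 dB below the dB of the mean power (Jensen's inequality); all
  analyses compare conditions within the same convention, so the offset
  cancels.  Samples within 2σ_t of the epoch edge are flagged.
* **Theta / delta**: mean dB over 4–8 Hz × 200–400 ms at FCz and 1–4 Hz ×
  300–500 ms at Pz.
* **Cell ANOVA**: per-subject cell means over condition × expectancy ×
  valence enter a fully-within-subject factorial ANOVA implemented by
  direct sums-of-squares decomposition (each effect tested against its
  subject interaction).  Writing the decomposition directly (rather than
  wrapping a library routine) lets degenerate inputs behave sensibly — a
  zero numerator yields F = 0 instead of 0/0 — and the implementation is
  cross-checked against both statsmodels' AnovaRM and a brute-force
  contrast enumeration in the tests.  Subjects missing design cells are
  dropped with a warning.

## RPE–amplitude coupling

Because RPE sign is confounded with valence, trials are partitioned by
condition × RPE sign and the component amplitude is regressed on |RPE|
per subject, both variables z-scored within the regression sample (the
slope equals the Pearson correlation and is invariant to affine
rescaling).  Cells with fewer than 8 trials are dropped per subject —
unexpected cells are the smallest, and below ~8 trials the slope estimate
is mostly noise.  Group inference: one-sample t-tests of mean slopes
(overall, per condition, per cell) and a 2 × 2 within-subject ANOVA over
sign × condition.  Degenerate zero-variance inputs give ±∞ t and F = 0 by
convention rather than NaN.

An unsigned-RPE component shows same-signed slopes in both sign
partitions; a signed-RPE component would flip sign.  The end-to-end suite
verifies that with the default generator the full chain — simulate, fit,
derive RPEs from fitted parameters, generate EEG, measure, test —
recovers the dissociation: condition × expectancy interaction on P3 but
not FRN, and an RPE-slope condition effect on P3 only.

## Stay/switch behavior

Each trial is linked to the preceding trial *of the same condition*
within its block (conditions interleave, so this is generally not the
preceding experimental trial).  Predictors are coded +1/−1 (win/loss,
common/rare), stay as 1.  The predictable model has intercept, reward,
transition and reward × transition terms; the random model omits the
transition terms.  Two estimation modes: `per_subject` (per-subject ML
logistic fits, then one-sample t-tests on the coefficients — the
two-stage summary-statistics approach) and `hierarchical` (random
coefficients per subject with Gaussian group distributions, sampled by
the same MCMC machinery; group tests are posterior z).  Separated or
non-converged subject fits are flagged and excluded from group tests, not
fatal.  Performance metrics: per-condition block bonus in EUR, and the
predictable condition's correctness curve over ten 5-trial subblocks
(correct = the action whose common transition leads to the high-reward
stimulus).  The expected random-condition payoff of a uniform policy is
exactly 0 ct by the symmetry of the ±3 structure.  Block-validity
filtering removes all trials of blocks with a failed set-identification
judgment and reports the excluded fraction.

## Problem sizes and reproducibility

Everything is seeded; features contain no hidden randomness and are
bit-reproducible.  Default study sizes mirror the reference design —
29 subjects, 4 blocks × 100 trials, hierarchical fits with 4 chains ×
2000 iterations (1000 warm-up).  The test suite exercises reduced sizes
chosen as the smallest that keep the checks statistically meaningful:
recovery over 50 replicates at 4 × 100 trials; the end-to-end
dissociation over 5 replicates of 29 subjects × 2 blocks with a
majority-vote criterion; null calibrations at 120–150 replicates.  The
acceptance script recomputes the Monte-Carlo frequencies at n = 100,000
and the hierarchical convergence diagnostic at the full reference scale.

## Known limitations

* The counter-based set inference is deterministic; real participants'
  set judgments are noisy.  Set-identification judgments consumed by the
  block filter are synthetic flags.
* λ and ρ are weakly identified at the design size; hierarchical
  estimates of λ shrink towards the group prior.
* The Gaussian-bump/burst EEG model cannot probe topography, latency
  effects, or phase-locking questions; channels are limited to the two
  measurement sites plus optional extras.
* The coupling analysis assumes linear amplitude–|RPE| relations; the dB
  transform makes the band-power couplings monotone but mildly nonlinear,
  attenuating slopes rather than biasing their sign.
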