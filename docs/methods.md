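# Methods

This note documents the models, estimators and numerical choices behind
`lipdcm`: what each statistic assumes, what the synthetic generator does and
does not emulate, and where open design choices were resolved.

## Task model

Two task variants are modelled. The *two-location* variant uses 450 ms
sample, delay and test epochs, one to four test stimuli per trial, 20%
catch trials, simultaneous distractors in the opposite hemifield, and a
50/50 split of attention IN/OUT (sample and tests inside vs outside the
recorded neuron's receptive field). The *one-location* variant uses 550 ms
epochs, one to three tests, 25% catch trials and no distractors. Stimuli
are conjunctions of 8 colors (rank 1 = yellow … 8 = red) and 8 directions
(45° spacing); sample A is yellow/downward (color 1, 270°), sample B
red/upward (color 8, 90°). Targets appear at a sequence position drawn from
a configurable bias, by default over-representing the first position
(weight 2:1:1:1), matching the schedule property that motivates excluding
first-position targets from the choice-probability analysis. Non-target
test slots are the opposite-target conjunction with probability 0.3,
otherwise uniform over the remaining conjunctions; distractors are uniform
over all 64. Completed trials split 90% hits / 6% misses / 4% false alarms;
a false alarm truncates the trial at the triggering stimulus, and a
non-catch false alarm requires a pre-target slot (otherwise the trial
becomes a miss). Catch trials run the full test sequence.

## Synthetic neurons

Each model neuron is an inhomogeneous Poisson process at 1 ms resolution.
The rate is a sum of terms, floored at zero, then multiplied by two gains:

```
rate(t) = max(0, baseline + identity(t) + match(t) + color(t) + direction(t))
          × attention_gain^[attend IN] × (1 + memory_gain·1[preferred sample])
```

- **Continuum weight `w ∈ [−1, 1]`** places the neuron between purely
  identity-coding (+1) and purely match-coding (−1); effective amplitudes
  are `amp·(1+w)/2` for sensory terms and `amp·(1−w)/2` for the match term,
  a monotone map from `w` to the expected visuo-decision index.
- **Identity term**: a step (20 ms linear rise) at `latency_identity`
  (default 100 ms) after onset of the preferred sample-conjunction in the
  RF. Steps keep latency ground truth unambiguous for estimator tests.
- **Match term**: a step at `latency_match` (default 190 ms) after target
  onset, jittered per trial by the same latent Gaussian draw that feeds the
  reaction time (below); applies to out-of-RF targets only for
  `bilateral_match` neurons.
- **Feature terms**: a linear color response (`slope·(color − 4.5)` Hz) and
  a von Mises direction tuning (`amp·exp(κ(cos Δ − 1))`, default κ = 2).
  Feature-based attention displaces tuning toward the currently relevant
  feature values: the color slope shifts down when yellow is relevant and up
  when red is, and the preferred direction is pulled along the shorter arc.
- **Gains are multiplicative on the whole response.** This is what makes
  pre-test-ratio decimation an exact correction; with additive gains the
  equalization would over- or under-correct stimulus-evoked activity.

Reaction times are Gaussian (default mean 400 ms, SD 50 ms, floored at
150 ms). A per-trial latent `j ~ N(0, rt_sd)` shifts the match-response
onset; the RT is `mean + c·j + √(1−c²)·rt_sd·ε` with coupling
`c = cp_coupling`, so RT variance is constant while the shared fraction is
`c²`.

**Canonical continuum populations** (`continuum_profiles`) carry identity
selectivity through *feature tuning* (scaled by `(1+w)/2` down to a 0.3
floor so match cells remain measurably tuned) rather than the
exact-conjunction step: a conjunction detector is super-additive by
construction (its additivity index equals twice its amplitude) and would
invert the additivity–continuum relation, whereas a feature-summing cell
is the additive coder the decomposition is designed to detect. Match
amplitude (35 Hz), RT coupling (0.8) and attention tuning shifts load on
the match-dominated end, which is the generative structure behind the sign
chain the pipeline recovers.

What the generator does **not** emulate: correlated noise across neurons
or across time, firing-rate adaptation or trial history, distractor-driven
responses (distractor influence is absorbed into the location gating),
bursting/refractoriness, and eye movements. Passing tests therefore show
estimator correctness under Poisson variability and the modelled
confounds (memory gain, attention gain, position bias, RT coupling), not
robustness to every property of real recordings.

## Estimators

**Decimation equalization.** The pre-test rate ratio is the ratio of mean
rates in the half-open 200 ms window before test onsets, over correct
trials; for attention grouping the window before the first test (the delay
epoch) is excluded so the ratio reflects visually driven activity. The
higher-rate condition's test-period spikes are thinned by independent
Bernoulli deletion with probability `1 − low/high` (an exact-count mode
removes `round(f·N)` uniformly chosen spikes instead, for sensitivity
checks). Bernoulli thinning preserves Poisson statistics exactly. Each
neuron is decimated once per grouping and seed and the result reused by all
downstream analyses, including decoding — without this the sample-memory
gain lets the match decoder reach significance from baseline differences
between target and opposite-target pools before any match signal exists.

**Sliding ROC.** The area under the ROC curve is the Mann–Whitney U
statistic over window spike counts divided by `n₁n₂` (ties half-weighted);
significance is the two-sided rank-sum test with Bonferroni correction over
the evaluated window centers (family = number of centers, default 551 for
−100…450 ms at 1 ms). The 200 ms window's value is assigned to its center,
so a strong response can reach significance up to ~100 ms before its true
onset; the latency estimator inherits this early bias (measured median
−15…−35 ms at 1.5–3× baseline amplitudes), which cancels in comparisons
between signals estimated the same way. Latency is the earliest time in
[0, session mean RT] starting ≥100 consecutive significant milliseconds.
The preferred side of each comparison is fixed from mean rates in the
100–350 ms window. VDI strengths are means of `2|ROC − 0.5|` over
100–350 ms.

**Decoding.** Pseudo-trials resample events independently per neuron from
disjoint train/test source pools (70%/30% split, resampling with
replacement inside each pool), with the composition 70 per sub-condition
for training and 30 for testing (140/60 per class for the two-sub-condition
schemes; 70/30 for sample identity). Features are window spike counts,
standardized with training statistics; the classifier is a linear SVM
(C = 1, liblinear). Default decoding steps are 10 ms (1 ms × 1000
iterations is needlessly slow; the step is a parameter). A time point is
above chance when accuracy exceeds 50% in strictly more than 99% of
iterations; the significance latency is the earliest such point ≥ 0.

**Laterality.** Match ROCs for in-RF and out-of-RF targets are compared by
bootstrap: 1000 trial-resampled ROC values per location, all 10⁶ pairwise
differences evaluated as an exact sorted tail fraction, a difference
declared significant when strictly more than 95% of differences share a
sign (ties count against significance). Because the two one-sided 5% rules
together misclassify ~10% of truly location-independent neurons, the
neuron-level classification also requires the weaker location to lack
standalone match selectivity (no Bonferroni-corrected 100 ms run) before
calling a neuron unilateral: bilateral selectivity means selectivity
independent of location, not merely equal amplitudes. The decision window
is 100–350 ms (parameterized; the aggregation epoch is otherwise
unspecified).

**Conjunction additivity.** With preferred identity P (higher mean response
to P in 100–350 ms), T is the mean response to P as a target (sample-P
trials), OT the response to the same physical stimulus P when irrelevant
(other-sample trials), and CM/DM the responses to stimuli of sample-P
trials sharing only the relevant color (7 irrelevant directions) or only
the relevant direction (7 irrelevant colors). The additivity index
`(T−OT) − [(CM−OT)+(DM−OT)]` is exactly zero when responses decompose as
`T = C+D+I`, `CM = C+I`, `DM = D+I`, `OT = I`; it is invariant to adding a
constant to all four responses, so the per-neuron normalization (division
by the grand mean rate over all test windows) affects display only.

**Tuning and attention shifts.** Color tuning is the least-squares slope of
mean response against color rank over non-match stimuli; the shift is
`slope(sample A) − slope(sample B)`, negative when tuning is attracted
toward the relevant color. Preferred direction is the angle of the
rate-weighted vector sum over the eight directions, undefined when the
resultant is below 10⁻⁶ of the total rate mass; the direction shift is the
angular separation of the two preferred directions, signed positive when
the sample-A preference lies closer to the sample-A relevant direction.

**Choice probability.** Over hits with the preferred sample and target
position ≥ 2, each trial's rate (1 ms bins, Gaussian-smoothed with
σ = 15 ms, truncated at ±4σ with edge renormalization) is correlated with
RT at each millisecond after target onset; the scalar summary is the mean
correlation over 100–350 ms. The default normalization z-scores each time
point across trials, isolating trial-to-trial fluctuations — an onset
arriving earlier on fast-RT trials gives a negative correlation. A
per-trial normalization (z-score across time within each trial) is
provided as a robustness mode: it removes per-trial offsets and gain but
also rescales transients such that early-onset and plateau effects largely
cancel, so it is not the primary statistic. Degenerate time points (zero
across-trial variance) report r = 0 and are flagged.

## Numerical conventions

All windows are half-open `[t0, t1)`; a spike exactly at the upper bound is
excluded. Analysis times are milliseconds relative to test-stimulus onset.
Rank statistics use the normal approximation with tie correction
(`scipy.stats.mannwhitneyu`, asymptotic). The paired latency test on
all-zero differences returns an explicit "no difference" flag instead of an
undefined t statistic. All random stages (generator, decimation,
bootstraps, decoding resamples) take explicit seeds and are reproducible
bit-for-bit.

## Problem sizes in the test suite

The acceptance-style tests run at desk scale, sizes chosen as a balance of
statistical power and runtime: latency-ordering recovery uses 20 seeded
populations of 48 neurons × 250 trials with decoder settings of 200
iterations and 20 ms steps over −60…320 ms; null calibrations use 200
signal-free neurons, one permuted-label decoding run (16 neurons, 200
iterations), and 100 simulated bilateral neurons; the sign chain uses ten
40-neuron × 200-trial continuum batches. The one-sided form of the latency
ordering tests reflects the directional hypothesis (identity before match).

## Known limitations

- The latency estimator's window-induced early bias means absolute
  latencies are comparable only between signals estimated identically.
- Identity-selective cells built from broad feature tuning retain a small
  positive conjunction advantage, so the additivity index of the synthetic
  identity end sits slightly above zero; the recovered additivity–VDI
  relation is a sign/ordering property, not a calibrated effect size.
- The choice-probability summary window (100–350 ms) overlaps both the
  onset-transition and plateau epochs; with strong RT–onset coupling the
  plateau dilutes the negative transient, so summary magnitudes are
  conservative.
- Pseudo-population decoding assumes exchangeability across sessions;
  correlated noise, had it been simulated, would generally reduce accuracy.
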