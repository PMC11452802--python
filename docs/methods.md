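# Methods

## Problem setting

Motor tics — sudden, rapid, non-rhythmic movements — are the defining
symptom of Gilles de la Tourette syndrome (GTS). An automated video
detector can emit, for each 1-second interval of a standardized ~2.5-minute
(150 s) video, the probability that a tic occurred. `ticscreen` implements
the downstream analysis: summarizing one video's probability trace into
five scores, classifying videos as GTS vs individually matched healthy
control (HC), and evaluating a hybrid decision scheme in which only
low-confidence automated predictions are referred to a human expert.
Because healthy controls also show spontaneous "extra movements", the HC
signal is low-rate rather than zero.

## Tic summary scores

A video of length L seconds is binarized at threshold 0.5: interval i is a
"tic interval" iff its probability ≥ 0.5. A probability exactly at the
threshold counts as a tic (inclusive convention; the threshold is
configurable). The five scores:

| score | definition | units |
|---|---|---|
| proportion_tic_intervals | 100 · (#tic intervals)/L | % |
| mean_tic_probability | mean of the raw probabilities | [0, 1] |
| max_tic_segment_s | longest run of tic intervals (0 if none) | s |
| max_ticfree_segment_s | longest run of tic-free intervals (0 if none) | s |
| clusters_per_minute | (#maximal tic runs of length ≥ 3) / (L/60) | min⁻¹ |

Conventions where a choice had to be made: clusters touching the video
boundary count; two tic runs separated by a single tic-free second are two
clusters (no gap merging); all rates normalize by the actual video length,
so L ≠ 150 is accepted; mean_tic_probability uses the raw, un-binarized
probabilities (it is a separate score from the proportion). The cluster
minimum (3 s) and the 0.5 threshold are arguments with those defaults.

## Classification

Group is regressed on one or more scores by logistic regression, GTS coded
1. The fit maximizes `loglik − ridge·‖slopes‖²` by Newton/IRLS with
step-halving; convergence at max-norm gradient < 1e-8, at most 100
iterations. The default ridge 1e-6 exists purely for numerical stability:
univariate fits on ~40-pair training sets regularly separate the classes
perfectly, where the unpenalized MLE diverges; with the tiny ridge the
maximizer is finite and a `SeparationWarning` is raised when the fitted
model classifies its training data essentially perfectly (all fitted
probabilities within 1e-3 of the labels). `ridge=0` gives the plain MLE
(verified against an independent implementation in the tests). Predictors
are not standardized by default, so coefficients are in score units; a
`standardize` flag z-scores internally and reports back-transformed
coefficients.

**Leave-pair-out cross-validation.** One fold per matched pair: the fold's
model is trained on all videos excluding those of both pair members and
applied to the held-out videos, so each video gets exactly one
cross-validated P(GTS). This preserves the matched design and avoids
class-imbalance bias. A fold whose training videos contain a single class
is an error naming the fold.

**Metrics.** Balanced accuracy = 100·(sensitivity + specificity)/2 with
decisions p ≥ 0.5 → GTS (ties to GTS), pooled over videos rather than
averaged per participant. AUROC is computed from the cross-validated
probabilities and equals the Mann–Whitney probability that a random GTS
video outscores a random HC video, ties ½. Score validity against manual
tic counts uses Pearson correlation by default (Spearman by flag).

## Hybrid human/machine decisions

Confidence of a prediction is max(p, 1−p). Videos with confidence strictly
above the threshold (default 0.9) keep their automated decision; the rest
go to an expert whose calls are simulated as independent label-flip noise
with accuracy 95% by default (no difficulty-dependent error). The analytic
combined accuracy is the n-weighted mean of the high-confidence automated
accuracy and the expert accuracy; because the published subgroup accuracies
are plain (not balanced) accuracies, the analytic combination uses plain
accuracy, while the balanced variant of the realized hybrid decisions is
additionally computed empirically. The threshold boundary is strict
(confidence exactly at the threshold → review); as a degenerate
convenience, threshold 0.5 routes only exactly-0.5 predictions to review.

## Synthetic cohort generator

Each participant's video is generated by a hidden two-state Markov chain
over seconds (0 = quiescent, 1 = tic), started from its stationary
distribution:

* P(enter tic | quiescent) = `p_enter_tic`; P(stay | tic) = `p_stay_tic`.
* Stationary tic fraction: `p_enter / (p_enter + 1 − p_stay)`; mean tic run
  length `1/(1 − p_stay)` — both recovered by the tests within Monte-Carlo
  error.
* Emission: given the state, the detector probability is
  Beta(mc, (1−m)c) with mean m = 0.8 (tic) or 0.2 (quiescent) and
  concentration c = 10, i.e. noisy traces that cross the 0.5 threshold in
  both directions, as real detector output does.
* Participant heterogeneity: each participant's `p_enter_tic` is jittered
  on the log-odds scale, logit(p) + N(0, 0.5), giving "few tics" and "many
  tics" individuals.
* Structure: `n_pairs` GTS/HC pairs (default 42); a per-pair video count
  drawn uniformly from 1–4 and copied to the matched partner (≈107 videos
  per group at the defaults, matching the real cohort's size); 150-second
  videos.

Default group parameters are well separated — GTS `p_enter=0.05,
p_stay=0.8` (≈20% tic seconds, bursts of mean 5 s), HC `p_enter=0.005,
p_stay=0.3` (≈0.7%) — chosen to land the downstream classifier in the
published operating regime (AUROC ≈ 0.95, high-confidence subgroup more
accurate than low-confidence). Seeding: one master seed spawns per-pair,
per-participant and per-video `SeedSequence` substreams, so cohorts are
reproducible and individual videos stable under partial regeneration.

What the generator does **not** emulate: tic suppression dynamics, vocal
tics, demographic matching (matching is structural only), per-body-region
signals, and any property of the raw video or detector itself. Passing
tests on synthetic cohorts therefore validate the statistical machinery
and its calibration, not the detector's real-world accuracy.

## Verification strategy and problem sizes

Every computational claim is checked against an independent route: the five
scores against an explicit per-second loop (1,000 random series), AUROC
against the exhaustive O(n²) pairwise count, each CV fold against a
from-scratch refit on its complement, the logistic optimizer against a
saturated 2×2 closed form (recovered to 1e-6 at ridge 0) and an external
MLE implementation, and the chain simulator against the two-state closed
forms at 10,000 simulated seconds. Null calibration uses cohorts with
identical group parameters (42 pairs × 5 seeds): cross-validated balanced
accuracy and AUROC must lie within 3 Monte-Carlo standard errors of 50% /
0.5. Because videos of one participant share that participant's jittered
rate, the independent unit for those error bands is the participant (42
per group), not the video.

## Known limitations

* Cross-validated null predictions carry the usual slight pessimistic bias
  of held-out evaluation (null AUROC tends to fall a little below 0.5);
  it is well inside the clustered 3-SE bands at the default sizes.
* The expert model is exchangeable label noise; real expert error
  correlates with case difficulty, so realized hybrid accuracy on real
  data may differ from the analytic combination.
* The generator's emission law is unimodal per state; multimodal or
  drifting detector noise is not modelled.
* With strongly separated defaults the synthetic cohort is somewhat easier
  to classify than the real one; regime-level properties (AUROC > 0.9,
  confidence–accuracy ordering), not the published point estimates, are
  what the synthetic experiments establish.
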