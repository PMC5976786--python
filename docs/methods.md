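# Methods

This note documents the models, conventions and numerical choices behind the
package, the behavior of the synthetic-data generator, and the limits of
what the test suite can show about real annotation data.

## Event streams and conventions

An annotation log is a CSV of coded intervals (session, participant, coder,
body-part group, behavior, modifier, start, stop in seconds, ≥ 0.01 s
precision). Within one group the behaviors are mutually exclusive and —
thanks to each group's "none" behavior — exhaustive, so a valid stream is a
partition of the observation.

* **Half-open intervals.** Events occupy `[start, stop)`; a boundary
  instant belongs to the following event. This makes mutual exclusivity
  decidable and fixes the discretization tie-break: an event boundary
  exactly at a bin midpoint assigns the bin to the later event.
* **Validation is strict.** Overlaps are always errors; uncovered gaps
  wider than a tolerance (default 0.04 s, roughly one video frame) are
  errors, narrower gaps are warnings. Nothing is auto-filled: coding errors
  must surface rather than be silently repaired.
* **Modifiers.** An empty modifier cell means neutral. "None" behaviors
  carry no affect by construction, so a modifier on a none-state is forced
  to neutral at parse time rather than silently kept: whether such
  combinations are meaningful is an open question of the coding practice,
  and the scheme resolves it conservatively.
* **Foci.** Facilitator and experimenter are one operational focus because
  every scored behavior merges them (GFE, RoFE). The scheme is a data
  object (YAML/JSON), so other activities can redefine behaviors and foci
  without code changes.
* The signs-of-affection gestures are represented for both valences
  (SOApos, SOAneg) even though negative instances are vanishingly rare in
  the activities studied; the affect score formula references both.

## Inter-rater reliability

Agreement between two coders is computed on streams discretized at a fixed
resolution (default 0.5 s — fine enough that boundary effects are small
relative to a 3 s window, coarse enough to keep session-length sequences
cheap). The exact alignment algorithm used by commercial annotation suites
is not public, so the package defines a deterministic, symmetric, bin-based
comparison:

* For each bin t, coder A's state is matched if B shows that state anywhere
  within ± the tolerance window (default 3 s); otherwise the pair
  (A[t], B[t]) is counted. The matrix is averaged with the transpose of the
  same construction run B-vs-A, so the report is invariant to swapping
  coders. At zero tolerance this reduces exactly to the textbook per-bin
  Cohen's kappa (verified against an independent implementation).
* Note the symmetrization means a pure time shift need not yield perfect
  agreement: a state present in only one coder's sequence near a sequence
  edge has no counterpart in the other's window.
* Kappa is (po − pe)/(1 − pe); when pe = 1 (both coders constant and
  identical) kappa is undefined and reported as a flag, never as 0 or 1.
* Group kappas pool each group's confusion matrix across sessions (the
  pooled matrix is the sum of per-session matrices — no averaging of
  kappas). The global kappa pools the three groups into one block-diagonal
  label space, preserving each group's marginals.
* Per-behavior kappas collapse the group matrix to 2×2 (behavior vs. rest).
  Behaviors with mean duration below 1% of the session are excluded from
  per-behavior reporting (kappa is unstable for very infrequent behaviors);
  those below 5% are flagged for cautious interpretation. Duration
  percentages average the two coders.
* Modifier agreement is off by default (reliability is reported at the
  behavior level); compound (behavior, modifier) labels are available.

## Engagement scores

Duration percentages are taken over the full observation (activity start to
end). The six scores subtract disengagement-related from
engagement-related percentages, so each lies in [−100, 100] by construction
(group sums are 100); the affect scores subtract negatively from positively
modified time, with neutral time contributing to behavior percentages only.
SOA gestures enter `RoAct_qogest` through their intrinsic valence but not
`RoAct` — the reach-out score reflects directional behaviors only — while
still counting toward the arms/hands total. Scores are carried at full
precision; reports print two decimals.

## Engagement timeline

The instant classifier is head-led: a focus counts as engaged only if the
head addresses it, because the head initiates engagement-related movement
and defines its target; torso/arms-only configurations are level 0. When
the head is at the game or the partner, levels are 1 (head only), 2 (head +
torso), 3 (head + arms/hands), 4 (all three), with task variants at the
game and social variants at the partner. Reduced active engagement (3)
ranks above readiness (2): manipulation is a constructive form of
engagement, postural attunement only a readiness to act. Affect intensity
is the signed count of positive minus negative valences over body parts
directed at the engaged focus (−3..+3); the weighted score sums head 0.50,
torso 0.10, arms/hands 0.40 over engaged parts, making it monotone in level
(0.50 < 0.60 < 0.90 < 1.00).

Body-part organization events are detected around each head turn to a
focus: *successive* (torso onset within the lag window after the head, arms
within the lag after the torso), *sequential* (arms within the lag after
the head with no intervening torso onset), *simultaneous* (all onsets
within the simultaneity window), and *space hold* (the head, and the torso
when engaged, keep the focus for a minimum duration while the arms/hands
remain active — continuous manipulation counts as gesturing). The
thresholds (ε = 0.5 s, lag = 3 s, hold ≥ 5 s) are engineering defaults
exposed in `OrganizationConfig`; no canonical values exist for them. Space
hold requires bin-level constancy of the held parts; micro-interruptions
break the hold.

## The path model and its estimation

The model is a linear Gaussian recursive system on the six observed scores
(no latent variables, uncorrelated errors): 9 edges, GAct exogenous, df =
21 − (9 coefficients + 1 exogenous variance + 5 error variances) = 6.

* **Estimation** is on the sample covariance S (n−1 denominator), means
  unstructured and ignored. F_ML is minimized by quasi-Newton (BFGS) on a
  correlation-scaled copy of the problem — F_ML and the model class are
  invariant under diagonal rescaling, and O(1) parameters condition the
  optimization — with log-variance coordinates for positivity and
  per-equation OLS start values. For a recursive DAG the likelihood
  factorizes over child-on-parents regressions, so OLS is in fact the
  global optimum; the optimizer polishes and verifies (gradient norm
  < 1e−6 required). The ML = OLS identity is kept as an independent test
  oracle, not assumed by the implementation.
* χ² = (n−1)·F_ML at the optimum; the model p-value is the χ²_df upper
  tail. Standard errors come from 2/(n−1) × the inverse finite-difference
  Hessian of F_ML; critical ratios are estimate/SE with two-sided normal
  p-values. Both unstandardized and standardized estimates (rescaled by
  model-implied standard deviations) are reported, because the two
  conventions are easy to conflate when reading published tables.
* **Fit indices** use the independence null (diagonal Σ, df_null =
  p(p−1)/2 = 15), whose discrepancy has the closed form −ln|R|. PNFI uses
  the standard parsimony ratio (df/df_null)·NFI; published values computed
  with other parsimony ratios will differ, which the fit output notes.
* **Outlier exclusion** removes whole rows by Mahalanobis D² (affine
  invariant), either the k farthest from the centroid (default, ties broken
  by key order) or above a χ² quantile.
* Follow-up simple regressions report the standardized coefficient
  (Pearson r), t = r√(df/(1−r²)) with df = n − 2, and the two-sided p.

## The synthetic-data generator

Two layers, because the path model operates on scores while reliability and
timelines operate on streams.

**Score level.** GAct is drawn from a Gaussian marginal (mean 78, SD 12 —
between the observed cognitive-games and robot-play gaze scores of roughly
81 and 74); each endogenous variable is built in topological order from the
reference path coefficients (0.372, 0.122, 0.349, 0.240, −0.255, 0.390,
0.845, 0.112, −0.218) with Gaussian errors (SD 10 per equation, a
moderate-noise choice that keeps scores comfortably inside their range).
This isolates the estimator: calibration (χ² mean ≈ df at n = 77, nominal
rejection) and coefficient recovery are tested against this generator.
Truncation to [−100, 100] is available but off by default, since
truncation biases the moments the estimator consumes.

**Stream level.** The head focus follows a semi-Markov chain with gamma
dwell times (shape 2) and uniform switching among the other foci; dwell
means are calibrated so the head is at the game ≈ 88% of the time in
cognitive games and ≈ 73% in robot play, matching the observed duration
shares. On each head turn to the game or the partner, the torso follows
with probability 0.75 after a 0.5–2.5 s lag and the arms/hands with
probability 0.90 after a further lag — the successive organization that
dominates real sessions. Affect bouts arrive at 0.2/min in cognitive games
and 2/min in robot play (rare vs. frequent, as observed), last ~4 s, and
are 85% positive. A per-participant engagement propensity tilts the
game-dwell and follow probabilities jointly, coupling the head, torso and
arm processes so cohort-level scores carry the positive head→torso
association. Sessions default to 22 min (within the 20–25 min session
range); the study-shaped cohort is 7 couples × 6 sessions alternating
activities = 42 recordings, 84 participant-sessions.

**Coder noise.** A second coder is emulated by order-preserving truncated
Gaussian jitter of event boundaries, per-event label substitution within
the group, and absorption of events shorter than a threshold into their
neighbor; the output remains a valid partition. Zero noise reproduces the
input exactly.

**What the generator does not emulate.** Real sessions have facilitator
interventions, game completions, postural drift, within-couple dependence
(an optional shared propensity exists but the default couples participants
only through the activity), and coder disagreement that is systematic
rather than random. Passing tests therefore certify the arithmetic,
the estimator and the pipeline's internal consistency — not that the coding
system is reliable on real video, which only new annotation data can show.
The stream-level cohort also does not satisfy the 9-edge model exactly
(only its sign structure), so model-level χ² checks use the score-level
generator.

## Problem sizes and tolerances

Default test and acceptance runs use: 500 replicates at n = 77 for χ²
calibration, 200 for coefficient recovery, 100 random datasets (n between
50 and 500) for the ML/OLS equivalence at 1e−6, 50 replicates per jitter
level (σ ∈ {0, 1, 2, 4} s on 4-minute sessions) for the reliability
degradation check, and exhaustive enumeration (4³ × 3³ combinations) for
the instant classifier. Optimizer tolerances: BFGS gradient tolerance
1e−10, central-difference gradients (h = 1e−6), Hessian step 1e−4.
Covariance matrices are rejected as singular above condition number 1e12.
All random draws flow from explicit integer seeds; no global state.

## Known limitations

* Only two coders are supported (no Fleiss/Krippendorff generalization).
* Only recursive path models on observed variables are fitted — no latent
  variables, correlated errors, mean structures or multi-group analysis.
* The tolerance-window comparison is one defensible reading of
  "agreement within 3 s"; onset-based definitions would differ in detail.
* Proprietary annotation project files are not parsed; only the generic
  CSV event-log dialect.
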