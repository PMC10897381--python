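# Methods

This note documents the models and procedures implemented in `moxpa`, the
assumptions behind them, the parameters that matter, and the design choices
made where the design was genuinely open.

## Minute-epoch data model and validation

A MOX2-5 minute record carries a window-start timestamp, an upload-status
flag (`H` history / `L` live), an IMA count sum, six second-valued
classification fields (weight-bearing, sedentary, standing, LPA, MPA, VPA)
and a step sum. Validation checks each second field against [0, 60],
non-negativity of counts, and the conservation identity

    sedentary + standing + weight-bearing + (LPA + MPA + VPA) = 60 s.

The identity is implemented as a *disjoint* four-term sum. Whether
weight-bearing overlaps standing/ambulation inside the device firmware is
not documented; treating the terms as disjoint is the reading under which
the printed identity can hold exactly, and the fixture generator allocates
weight-bearing seconds as a sub-share of upright time so that it does.
Default tolerance is 1 s for real files (device rounding) and 0 for
fixtures. Violations flag the record; they never drop it silently.
Timestamps parse as unix epoch integers or ISO-8601, auto-detected.

Daily aggregation groups records by calendar date and sums all fields;
days with fewer than 1440 observed minutes are retained and carry a
`minutes_observed` count, since no wear-time minimum is asserted for this
device. A units note: published per-participant tables label the activity
totals inconsistently (seconds vs minutes) while printing second-scale
magnitudes; the package records them as seconds throughout.

## Preprocessing conventions

* **Imputation** — interior gaps take the mean of the nearest preceding and
  following observations (average of a forward and a backward fill);
  leading/trailing gaps take the nearest observed value. The operation is
  idempotent and logs every fill.
* **Outliers** — boxplot fences Q1 − 1.5·IQR / Q3 + 1.5·IQR with
  linear-interpolation quartiles (the common default; no quartile
  convention is asserted upstream). Default treatment winsorizes to the
  nearer fence; a drop mode exists because "handled" does not say which.
* **Cohort summary** — per-column mean/SD/min/max over participants with
  sample SD (ddof = 1), which reproduces the published wear-duration SD
  (5.41 d). A single-participant cohort reports SD 0 with a note.

## Activity-level labeling

Each daily level 0–4 is a disjunction of a steps-and-weekly-MVPA clause and
a plain steps-band clause, with weekly MVPA = (2·VPA + MPA)·7 computed from
*daily minutes* (day-record seconds are divided by 60 first; the 90–360
weekly thresholds are then commensurate with the WHO 150–300 min guidance).
The ten disjuncts overlap; the conflict policy is **highest satisfied level
wins**, isolated behind a strategy option (`policy="lowest"` available).
The rule engine is verified against an independent evaluator that tests all
ten disjuncts on a dense grid, and satisfies: totality, `steps < 5000 ⇒
level 0`, and monotonicity in 2·VPA + MPA at fixed steps > 4999.

Intensity banding: IMA uses closed integer intervals (LPA 0–400, MPA
401–800, VPA ≥ 801); cps uses half-open intervals for an upper-leg
placement (≤ 4.5 cps is below-LPA; other placements are rejected because no
thresholds exist for them); MET boundaries go to the upper band (3 → MPA,
6 → VPA, honoring "6.0 or more").

## Fixture generator

The generator's job is to emulate the statistical structure the analysis
assumes — not physiology. Behavior is a first-order minute-level state
chain over {sleep, sedentary, standing, lpa, mpa, vpa}: a contiguous
nightly sleep block of `1440 − wake_minutes` minutes, then waking states
drawn with persistence 0.8 from per-profile stationary weights. Per state:

* sleep: 58–60 sedentary seconds, IMA ~ U{0..20}, zero steps (the device's
  sleep signature);
* activity minutes: 45–60 seconds of the dominant class, IMA uniform within
  the dominant class's band then perturbed but clipped to the band, steps
  from a gamma-mixed Poisson with state-specific per-minute means ordered
  LPA ≤ MPA ≤ VPA (defaults 60/105/150, walking-to-running cadence scale,
  dispersion 20) — giving the strong IMA–steps association real streams
  show;
* the conservation identity holds exactly on every minute by construction.

Default demo cohort: 16 participants cycling five activity archetypes whose
daily step totals land near 2.9k/6.8k/8.7k/11k/14.3k, with per-participant
wear days mirroring the published cohort (30–48, total 539 participant-
days). This spans all five daily levels. The generator does **not** emulate
raw tri-axial signals, wear-time gaps, device dropouts, or inter-day
behavioral correlation; passing tests therefore demonstrate pipeline
correctness and the augmentation mechanism on distributionally faithful
tables, not performance on real wear data.

## Gaussian-copula synthesizer

Fit: each column is mapped through its empirical CDF (plotting positions
(i − 0.5)/n; ties broken by jittered ordinal ranks so discrete columns get
non-degenerate normal scores), then through the standard-normal quantile
function; the latent correlation matrix is the Pearson correlation of these
normal scores, repaired to PSD by eigenvalue clipping (threshold 1e−8) with
the unit diagonal restored. Constant columns raise by name. Sampling draws
latent normals via Cholesky, applies the normal CDF and each marginal's
inverse CDF (linear interpolation between order statistics). Tails are
clamped to the observed min/max, so samples stay in the training support —
parametric copula toolkits can emit out-of-range values (e.g. negative
step counts); that behavior is deliberately not reproduced. Integer
columns (`Steps`, `Active`) are rounded; `Active` can instead be snapped to
the nearest observed value (`snap_columns`), and can be included in the
fit as a continuous column or left out entirely.

For the augmentation experiment the protocol fits the copula on the five
features only and labels synthetic rows with the same rule engine used for
real rows. Sampling `Active` jointly is supported but yields labels that
contradict the deterministic rules on a large share of rows, and that label
noise suppresses the augmentation benefit the protocol measures; since the
label is a function of the features in this pipeline, rule-labeling
synthetic rows is the coherent construction.

## Tabular GAN

Generator: latent (default 8) → 64 → 32 ReLU → linear output of data width,
He-uniform kernels. Discriminator: data → 64 → 32 ReLU → sigmoid scalar.
Both use binary cross-entropy and Adam (0.001, 0.9, 0.999). Features are
standardized before training (a linear output layer cannot otherwise reach
raw activity scales). Per epoch: one discriminator step on a half-real
(label 1) / half-fake (label 0) batch, then one combined step updating only
the generator through the frozen discriminator on fresh noise labelled 1.
The generator snapshot with the lowest combined loss is kept. Widths,
epochs (default 2000) and batch size (64) are desk-scale defaults — no
canonical settings exist for this pathway. Small-table GANs mode-collapse
readily; a single-valued sampled `Active` column triggers an explicit
warning, and downstream comparison reports "not compatible" instead of a
score. This failure mode is documented behavior, not a target.

## MLP classifier

Architecture 5 → 81 → 18 → 12 → 10 → 5 → 5 (ReLU ×5, softmax), exactly 2405
trainable parameters by Σ (fan_in + 1)·fan_out. The hidden widths are not
published; this tuple was found by searching descending width tuples for
the printed parameter count and is frozen in config. Training: categorical
cross-entropy on one-hot labels, Adam (α = 0.001, β₁ = 0.9, β₂ = 0.999,
ε = 1e−8, decay 0), mini-batches of 32, default 120–150 epochs, stratified
five-fold cross-validation (five classes on a few hundred rows make plain
folding risky), and plateau LR reduction monitoring validation loss with
factor 0.5 and patience 10 (the method is named upstream, its settings are
not). He-uniform init is used for all dense layers; it was the most robust
of the initializers tried on this funnel-shaped stack. Known limitation:
with unlucky initializations the narrow 10 → 5 funnel can lose a ReLU unit
and merge two adjacent classes; cross-validation and repetition averaging
make this visible rather than hiding it.

**Augmentation protocol.** Arms name training unions over {R, FGC, FC}.
The R arm is five-fold cross-validation on the real table. Synthetic-
containing arms stratified-split the real table (75/25), train on the full
synthetic tables plus the real training split, evaluate on the held-out
real split, and average four repetitions. Arm record counts report the sum
of the constituent full tables (539-row tables give 539 / 1078 / 1617).

## Metrics

Per-class one-vs-rest counts feed the standard formulas: accuracy
(TP+TN)/(TP+FP+FN+TN), precision TP/(TP+FP), recall TP/(TP+FN),
specificity TN/(TN+FP), F1 = 2PR/(P+R), MCC = (TP·TN − FP·FN)/√((TP+FP)
(TP+FN)(TN+FP)(TN+FN)). Two published-formula wrinkles are resolved here:
a printed specificity chain equating it with 1 − sensitivity is internally
inconsistent — TN/(TN+FP) is implemented — and a printed MCC numerator
carries a stray leading TP factor — the standard numerator is implemented,
matching the formula's own worked values. Zero-denominator ratios return 0
and are flagged. Headline accuracy is the multi-class fraction correct;
other headline metrics are macro-averages (micro also computed, since the
averaging convention of single-row result tables is unstated).

## Real-vs-synthetic comparison

* **Q–Q OLS** — per feature, sorted synthetic on sorted real
  (quantile-matched by interpolation when sizes differ), via statsmodels;
  R², adjusted R² with p = 1 regressor, RSE = √(RSS/df), df = N − 2, and
  the variance-ratio F (larger over smaller sample variance). A pooled fit
  stacks all features with p = number of features. The regression design is
  not recoverable from upstream descriptions; sorted-on-sorted is adopted
  as the deterministic, size-robust reading and is flagged as an
  interpretation.
* **Moment and curve distances** — per-feature |log₁₀|mean|| and
  |log₁₀|sd|| differences (zero moments flagged undefined), maximum gap
  between min-anchored normalized cumulative sums over sorted values, and
  the two-sample KS statistic.
* **Classifier panel** — logistic regression, depth-5 decision tree,
  50-tree random forest and the package MLP, each trained once on a real
  training split and once on the synthetic table, both evaluated on the
  same real test split; reported as macro-F1 pairs plus the Jaccard
  similarity of the two correctly-classified index sets. The correct-index
  Jaccard is this package's concrete operationalization of
  classifier-similarity scoring; the panel is fixture plumbing.

## Observation ontology

Project classes (PhysicalActivityObservation, ActivityLevel,
SedentaryTimeObservation, StepsObservation, Sensor) align with SOSA:
observation classes subclass `sosa:Observation`, `Sensor` subclasses
`sosa:Sensor`, `observedBySensor` subproperties `sosa:madeBySensor`, and
step/sedentary results use `sosa:hasSimpleResult`. IRIs are minted
deterministically from (person, date), so annotation is idempotent and
additive over day-sets. Consistency is verified structurally — domain/range
conformance of every project property, ≥1 sensor link and exactly one
observation time per activity observation, and pairwise disjointness of
the observation subclasses — instead of invoking a DL reasoner; these
enumerated checks cover the constraints the graph shapes here can violate,
but under-approximate full OWL semantics by construction.

## Problem sizes and determinism

Default test and demo sizes: 160-row cohorts (16 × 10 days) for training
experiments, the full 539-day cohort for scale checks and semantic export,
n = 2000/5000 for copula recovery/fidelity, ~11.6k grid points for the
labeler equivalence check. Every stochastic component takes an explicit
seed (numpy `default_rng`); identical seeds give byte-identical CSV
exports, identical fold assignments, and identical sampled tables.

## Known limitations

* Fixtures lack wear-time gaps, device noise and between-day correlation;
  real-data performance claims are out of scope.
* The GAN is a minimal dense pathway; no mode-specific normalization or
  conditional generation (those belong to external synthesizers).
* The MLP funnel is sensitive to initialization (see above).
* Structural ontology checks are weaker than DL reasoning.
* The copula treats rows as exchangeable; participant identity is not a
  modeled variable in synthesis.
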