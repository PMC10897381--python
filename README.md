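# moxpa

Analytics for minute-epoch physical-activity data from the MOX2-5 wearable
activity monitor: record validation, daily aggregation, rule-based activity-
level labeling, tabular data synthesis (Gaussian copula and GAN), MLP
activity-level classification, real-vs-synthetic comparison statistics, and
SSN/SOSA-aligned semantic export of daily observations.

## Who this is for

Researchers working with accelerometer-derived activity data who need a
tested, reproducible path from per-minute device CSVs to daily activity-level
labels, who want to augment small cohorts with synthetic tabular data, and
who want sensor observations exported as a queryable RDF knowledge graph.
Real participant data is not redistributable, so the package ships a seeded
fixture generator that emulates the statistical structure of MOX2-5 streams;
every stage is exercised end to end on those fixtures.

## The data model

The MOX2-5 reports one record per 60-second window: an IMA (inertial
movement analysis) count sum, seconds classified as weight-bearing,
sedentary, standing, LPA, MPA and VPA, and a step sum. Within each window

```
sedentary + standing + weight-bearing + (LPA + MPA + VPA) = 60 s
```

holds exactly; the validator enforces it. Per-minute IMA maps onto intensity
bands (LPA 0–400, MPA 401–800, VPA ≥ 801 counts; equivalently 1.5–3 / 3–6 /
≥ 6 METs). During sleep the device reports 58–60 sedentary seconds per
minute with IMA ≤ 20 and zero steps.

Daily totals are labelled with an activity level `Active ∈ {0..4}`
(Sedentary, Low active, Active, Medium active, Highly active) from daily
steps and weekly moderate-to-vigorous minutes

```
MVPA_week = (2·VPA + MPA) · 7     [minutes, vigorous counted double]
```

e.g. level 4 fires when `steps > 4999 ∧ MVPA_week ≥ 360` or `steps > 12499`;
overlapping rules resolve to the highest satisfied level.

The classifier is a six-layer MLP `5 → 81 → 18 → 12 → 10 → 5 → 5` (ReLU ×5,
softmax output; 2405 trainable parameters = Σ (fan_in+1)·fan_out), trained
with categorical cross-entropy, Adam (α=0.001, β₁=0.9, β₂=0.999, ε=1e−8),
stratified five-fold cross-validation and plateau learning-rate reduction.
The Gaussian-copula synthesizer couples smoothed empirical marginals through
a latent multivariate normal with the rank-estimated correlation matrix; the
tabular GAN is a dense generator/discriminator pair trained adversarially
with binary cross-entropy (its mode-collapse failure mode is detected and
reported, not hidden). Synthetic quality is scored by Q–Q OLS (R², adjusted
R², residual standard error, variance-ratio F), log-moment and
cumulative-sum distances, KS statistics, and Jaccard similarity of
correctly-classified index sets across a fixed classifier panel.

## Worked example

```python
from moxpa import (default_fixture_spec, generate_cohort, label_table,
                   fit_copula, sample_copula, cohort_summary)
from moxpa.preprocess import STUDY_COHORT_TOTALS
from moxpa.classifier import TrainingConfig, train_on_sources_evaluate_on_real

# published per-participant totals of the 16-adult cohort
s = cohort_summary(STUDY_COHORT_TOTALS)
print("records:", s.total_records)
print(s.stats.loc[["Duration", "TotalMPA", "TotalSteps"], ["mean", "sd"]].round(2))

# seeded demo cohort -> labels -> copula synthesis -> augmentation protocol
spec = default_fixture_spec(16, [10], seed=5)
_, table = generate_cohort(spec)
real = label_table(table)
print("class counts:", real["Active"].value_counts().sort_index().to_dict())

model = fit_copula(real[["Sedentary", "LPA", "MPA", "VPA", "Steps"]], seed=5)
fgc = label_table(sample_copula(model, len(real), seed=11))
fc = label_table(sample_copula(model, len(real), seed=12))
res = train_on_sources_evaluate_on_real(
    real, {"FGC": fgc, "FC": fc}, arms=["R", "FGC+FC+R"],
    config=TrainingConfig(epochs=120, seed=0), repeats=4,
)
for arm, r in res.items():
    print(f"{arm:10s} records={r['records']:4d} accuracy={100*r['report'].accuracy:.1f}%")
```

prints

```
records: 539
                 mean        sd
Duration        33.69      5.41
TotalMPA     53231.75  17965.01
TotalSteps  366703.31  87202.25
class counts: {0: 47, 1: 41, 2: 31, 3: 18, 4: 23}
R          records= 160 accuracy=87.5%
FGC+FC+R   records= 480 accuracy=94.4%
```

The cohort summary reproduces the published per-participant statistics (539
participant-days, mean wear 33.69 days). On the demo cohort, training the
MLP on the real table augmented with two copula-synthesized tables of the
same size lifts held-out-real accuracy from 87.5% to 94.4% — the
augmentation effect the protocol is designed to measure.

A CLI mirrors the stages (`moxpa fixtures | validate | aggregate | label |
synth gc|gan | train | evaluate | ontology export|query|check | run`); see
`moxpa --help`.

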