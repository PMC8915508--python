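# losnet

Predicting hospital **length of stay (LOS)** for elderly patients with
chronic diseases, using only what is known at the **point of admission
(PoA)**: demographics, hospital attributes, the patient's own admission
history, and the diagnoses flagged on arrival.

Raw diagnosis lists are hard to use directly — one-hot encoding hundreds of
ICD-10 codes explodes the feature space and ignores how diseases relate.
`losnet` turns two networks into compact, admission-time features:

- a **multimorbidity network (MN)** over chronic diseases, where the edge
  between diseases *i* and *j* carries the relative risk of co-occurrence

  RR<sub>ij</sub> = C<sub>ij</sub>·N / (C<sub>i</sub>·C<sub>j</sub>),

  with C<sub>i</sub>, C<sub>j</sub>, C<sub>ij</sub> patient counts from a
  sparse binary patient×disease matrix and N the cohort size, plus a
  multiplicative 99% confidence interval RR·exp(±2.58σ).  Node importance is
  the eigenvector centrality (EVC) of the RR-weighted adjacency, the
  principal eigenvector of A x = λ x;

- a **patient similarity network (PSN)** over training admissions, blocked
  by sex × five-year age group, with Jaccard similarity
  |d(i) ∩ d(j)| / |d(i) ∪ d(j)| over PoA diagnosis sets.  Each admission's
  100 most similar training neighbors contribute the summary statistics of
  their observed LOS.

Four feature groups feed pluggable regressors (XGBoost by default): 69
baseline columns (demographics, hospital, admission date, Elixhauser
comorbidity flags and score), 8 historical columns (3-year lookback LOS
statistics), the MN group (per-disease EVC multi-hot compressed by linear
discriminant analysis with integer LOS values as classes, plus 4 aggregates
of disease risk scores EVC(v)·mean-LOS(v)), and 5 PSN neighbor-LOS columns.
An ablation harness trains each model on feature subsets with repeated
reseeded 80/20/validation splits and reports MAE, RMSE and R².

Real discharge-record datasets are access-restricted, so the package bundles
a synthetic cohort generator with *planted* structure — exact pairwise
co-occurrence RR targets, per-disease LOS effects, patient frailty, an age
slope — giving every stage a known ground truth to be validated against.

## Worked example

```python
from datetime import date
from losnet import *
from losnet.eci import default_eci_mapping
from losnet.modeling import ModelingDataset, ExperimentPlan, run_ablation

records, truth = make_fixture("small")          # 2000 synthetic patients
kept, tally = apply_inclusion_criteria(records, truth.catalog(),
                                       InclusionConfig())

mn_era = (date(2015, 1, 1), date(2017, 12, 31))
M = build_patient_disease_matrix(kept, truth.catalog(), era=mn_era)
mn = build_mn(M)                                 # 99%-CI edge rule
evc = eigenvector_centrality(mn)

modeling = [r for r in kept if r.admission_date >= date(2018, 1, 1)]
dataset = ModelingDataset.build(modeling, evc, truth.catalog(),
                                default_eci_mapping(), history_source=kept)
plan = ExperimentPlan(subsets={"baseline": ("baseline",),
                               "full": ("baseline", "history", "mn", "psn")},
                      repeats=3, lda_components=4)
report = run_ablation(dataset, plan)
print(report.summary()[["model", "subset", "mae_mean", "r2_mean"]].round(3))
```

Output:

```
admissions kept: 3408 of 3941
multimorbidity network: 20 nodes, 2 edges
  E11–I10: RR=4.37  99% CI=(3.29, 5.82)
  I25–I50: RR=2.58  99% CI=(1.81, 3.67)
  model   subset  mae_mean  r2_mean
xgboost baseline     3.031    0.230
xgboost     full     2.668    0.379
```

The two retained edges are exactly the generator's planted pairs (targets
RR = 5 and RR = 3, attenuated here because the cohort matrix conditions on
carrying at least one chronic disease).  Adding the history, network and
neighbor features lifts test R² from 0.23 to 0.38 and cuts MAE by ~0.36
days: the network features recover the planted disease effects and the
frailty signal that admission-time demographics alone cannot see.

## Command line

Each stage of the flow — simulate, filter, build-mn, build-psn, featurize,
reduce, train, evaluate — runs from a single YAML config and writes
versioned artifacts plus a JSON manifest:

```sh
losnet all --config config.yaml
```

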