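# Methods

## Problem and data model

The unit of prediction is one hospitalization of an elderly patient (≥ 65
years).  A record carries demographics, hospital attributes, admission and
discharge dates, and up to 16 three-character ICD-10 diagnoses, each flagged
for whether it was present at the point of admission (PoA).  LOS is the
whole-day difference between discharge and admission dates (dates are only
day-precise).  Cohort inclusion applies, in order: LOS present and
non-negative; patient alive over the study period; admission date in range
and age ≥ 65; LOS at or below the 99% nearest-rank quantile (recomputed per
cohort — a fixed published cutoff is data-specific — with an override to pin
it); and at least one chronic diagnosis flagged at the PoA.  Applying the
criteria in a fixed order makes the per-criterion exclusion tally
well-defined; order affects only attribution, never the kept set.

The chronic-disease catalog is an input, not a constant: published catalogs
are external, and synthetic cohorts carry their own.

## Multimorbidity network

A binary patient×disease matrix OR-aggregates each patient's chronic
diagnoses (admission-time and in-hospital alike) over the construction era.
Pair counts come from one sparse transpose-product MᵀM, which is exact and
scales to very large cohorts.  Edges are weighted by the relative risk
RR_ij = C_ij·N/(C_i·C_j) with a multiplicative interval
RR·exp(±2.58σ).

Two dispersion conventions ship for σ.  The `as_printed` sum
1/C_ij + 1/(C_i·C_j) − 1/N − 1/N² is the historical form this package
reproduces verbatim and is the default in `katz_ci`.  It is not a variance,
and an interval built from it has essentially no coverage at moderate counts
(at C_ij ≈ 250 it covers the true RR ~12% of the time).  The `sqrt` variant
treats the sum as a variance and takes its square root, behaving like a
log-scale Wald interval; **edge retention in `build_mn` therefore defaults
to `sqrt`**, under which the null calibration (≤ 3% of candidate pairs
retained on independent-disease cohorts, nominal ≈ 1%) and planted-signal
coverage both hold.  Both modes are configurable everywhere.

The edge rule defaults to "99% CI lower bound > 1" with C_ij ≥ 1 —
standard disease-co-occurrence-network practice — and `rr_gt_1` / `all` are
available, since the retention rule used by any particular published network
is rarely reconstructible from its node and edge counts.

Eigenvector centrality is computed by power iteration on the RR-weighted
adjacency (binary mode available), per connected component, each component
Euclidean-normalized; isolated nodes score 0.  The iteration runs on A + I:
the identity shift leaves the principal eigenvector unchanged but breaks the
period-2 oscillation plain power iteration suffers on bipartite graphs.
Start vector all-ones, L1 tolerance 1e−10, max 10 000 iterations,
nonnegativity enforced on the converged vector; results match dense
eigendecomposition to < 1e−6 per component.

Note on planted-RR checks: a matrix built from admission records contains
only patients observed with ≥ 1 chronic disease, so the RR it measures is
conditional on cohort membership and is smaller than the population target
by the factor P(at least one disease).  Ground-truth validation therefore
counts over the generator's full population.

## Patient similarity

Admissions are comparable only within a sex × five-year-age-group block
(65–69 … 85–89, 90+).  Similarity is the Jaccard index of PoA diagnosis
sets; two empty sets have undefined similarity (excluded upstream by the
inclusion criteria).  The exact backend scores a query against its whole
block with sparse matrix products and returns the true top-k (k = 100 by
default); ties break by ascending admission id for reproducibility.
Zero-similarity neighbors are dropped even when k is unfilled — a
zero-overlap "neighbor" carries no disease information.  A query's own
admission is always excluded, and by default so are all training admissions
of the same patient, preventing label leakage through the patient's own past
LOS (the historical features already carry it); this exclusion can be
switched off.

The approximate backend is MinHash banding (64 permutations, 1-row bands —
the high-recall regime appropriate for the very small diagnosis sets seen
here) used only to generate candidates, which are then re-scored with exact
Jaccard; it is validated against the exact backend at ≥ 0.95 recall of the
top-100.

## Features

- **Baseline (69)** — admission year/month/weekday, age, hospital
  affiliation/level/grade, admission status, both address codes and their
  equality flag, PoA diagnosis count (all numeric/ordinal); one-hot sex (2),
  admission source (4), ethnic group (2), job (13), marital status (4);
  31 Elixhauser comorbidity flags and their van Walraven-weighted score.
  Unknown categorical levels route to a reserved `_other` column with a
  warning.  The bundled ICD-10→Elixhauser map is deliberately simplified
  (common elderly chronic conditions at the 3-character level); a complete
  map can be supplied as CSV.
- **History (8)** — count/mean/std/median/min/max of the patient's LOS over
  admissions in [t − 3 years, t), plus days since last discharge and last
  LOS; patients without window history get zeros.  The window is closed on
  the left, open on the right (an admission exactly 3 years earlier counts;
  same-day does not).
- **MN** — a multi-hot vector over the network nodes observed at the PoA in
  the modeling era, ones replaced by EVC scores, then compressed by LDA;
  plus count/max/mean/sum of disease risk scores EVC(v)·los_mean(v), where
  los_mean(v) is the mean LOS of *training* admissions carrying v at the
  PoA.  Computing los_mean on the training split (rather than the network
  era or all modeling rows) makes the no-test-leakage property provable;
  the population is configurable.
- **PSN (5)** — mean/std/median/min/max of the top-100 training neighbors'
  LOS; empty neighbor lists give zeros.

Zero is the missing value throughout; assembled tables are dense.  The
standard deviation is the population convention (n = 1 → 0), fixing the
singleton case deterministically.

## LDA compression

Integer LOS day values act directly as class labels (LOS is discrete;
binning is available but off by default), so a training split with K
distinct LOS values admits at most K − 1 discriminant directions.  The
scatter solve is scikit-learn's eigen solver with a fixed ridge shrinkage of
0.1 on the within-class scatter: sparse multi-hot blocks are rank-deficient
on small cohorts, and data-driven (Ledoit-Wolf) shrinkage can degenerate to
zero on such blocks.  The output dimension is chosen on the validation
split from the candidate grid {8, 16, 32, 64} (infeasible candidates dropped
with a warning) by training a fixed small gradient-boosted probe on the
projected training rows and taking the dimension with the lowest validation
MAE; exact ties go to the smaller dimension.

## Experiments

Rows split 80/20 train/test, then 20% of train becomes validation.  Five
canonical feature subsets (baseline; +history; +MN; +PSN; all four) feed
each configured model; a grid search minimizes validation MAE (ties keep
declared order), the winner is refit on the training rows and scored on
test with MAE, RMSE and R² (R² against the observed-y mean, so the mean
forecast scores exactly 0).  "Repeated ten times" is implemented as
reseeded splits (base seed + repeat); everything downstream of the split —
similarity index, per-disease LOS means, LDA fit — is recomputed per
repeat, so no statistic ever sees a test row.  Model internals are
delegated: XGBoost (default, small grid over tree depth), scikit-learn
gradient boosting, random forest, linear SVR behind a standardizing
pipeline, and an optional MLP following the usual taper (400-200-100-50,
ReLU, Adam at 5e-4, weight decay 1e-5, batch 4096, 200 epochs) that is not
part of default plans.  Tree models expose per-feature importances, which
the report sums per feature group and ranks top-k with min–max-normalized
relative importance; a per-integer-LOS MAE profile is produced overall and
by sex and age group.

## Synthetic cohorts

The generator emulates the structure of an elderly discharge-record cohort:

- **Diseases.**  Each patient draws a persistent chronic-disease set with
  Bernoulli marginals (default prevalence 0.10 across 20 diseases).  A
  planted pair (i, j, RR) shares a latent Bernoulli component Z with
  probability q solved (Brent) so that P(both) = RR·p_i·p_j exactly while
  marginals are preserved; infeasible targets (RR·p_i·p_j > min marginal)
  are rejected.  Each disease may join at most one planted pair.
- **Admissions.**  Counts per patient are a shifted negative binomial (mean
  2, dispersion 1 — every patient has ≥ 1 stay), dates uniform over
  2015–2019 and sorted; ages are drawn once per patient from elderly-cohort
  band proportions and advance with the calendar year.
- **LOS.**  round(base 9 d + Σ per-disease effects + 0.05 d/yr·(age−65) +
  patient frailty N(0, 2 d) + noise N(0, 2.5 d)), floored at 1 day.
  Default effects cycle 0–4.5 days unless given explicitly.
- **PoA flags.**  Each carried disease is flagged at the PoA with
  probability 0.8; if none is flagged the highest-effect disease is forced,
  so every stay of a diseased patient remains cohort-eligible.  The
  principal diagnosis is the highest-effect PoA disease.  Disease-free
  patients receive a non-chronic filler code and are removed by the
  inclusion filter.

Named presets fix the study conditions: `tiny` (50 patients, 8 diseases,
one planted pair), `small` (2000 patients, 20 diseases, pairs at RR 5 and
3), `medium` (20 000 patients, 40 diseases, pairs at RR 5, 3 and 2), with
documented seeds.  Ablation experiments and the acceptance script use
`medium` (~15 600 modeling-era admissions) — large enough for stable repeat
statistics while keeping a full 10-repeat ablation to a few minutes on one
CPU.

What the generator does **not** emulate: real marginal prevalence profiles,
higher-order (beyond pairwise) disease dependence, disease accrual dynamics
(available but defaulting to 0), mortality and transfers, hospital-level
effects on LOS, or calendar trends.  Passing tests therefore demonstrate
that the machinery recovers structure it can represent — not that the same
feature lift would be observed on any particular real cohort.

## Numerical choices and limitations

- Nearest-rank quantile for the LOS cutoff (integer-valued, no
  interpolation).
- Power iteration: identity shift, L1 tolerance 1e−10, cap 10 000;
  convergence failure raises with the residual.
- Neighbor ties and grid-search ties are broken deterministically
  (ascending id; declared order).
- The pipeline fans one global seed out to stages by stable hashing of
  stage names, so stage reruns are order-independent and bit-identical.
- The Elixhauser map bundled for tests is intentionally partial; supply a
  complete mapping for real ICD-10 data.
- Long-stay tails remain hard: with few training examples above ~30 days,
  tree ensembles average leaf values downward, a known failure mode of LOS
  regression that this package does not attempt to resample away.
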