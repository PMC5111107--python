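# Methods

## Scope and data model

`crcbench` benchmarks colon-cancer subtype classifiers on a pooled,
already-normalized expression cohort. The in-memory containers are plain
pandas objects wrapped thinly: an `ExpressionMatrix` is a log2-scale
genes × samples DataFrame with per-sample dataset/platform tags; clinical
annotations are a DataFrame keyed by sample id with relapse-free survival
time (months), event indicator, stage, MSI status, gender and age. The
package deliberately does **not** normalize raw array data: MAS5/RMA
processing is upstream, and the normalization flavor is treated as
metadata. Cross-platform batch correction is likewise out of scope; the
pooling step assumes the inputs come from compatible platforms sharing a
common probe space.

## Database construction

Probe-level matrices are collapsed to one row per gene symbol. A
preferred-probe map (the role a JetSet-style "most reliable probe set"
table plays) wins when present; otherwise the probe with the highest mean
expression represents the gene. Unmapped probes are dropped and counted.
Median centering (per gene, pooled or per dataset) brings each gene's
median to 0 within floating tolerance 1e-9; missing values are excluded
pairwise from medians and correlations throughout.

Duplicate samples across datasets are a real hazard when pooling public
series. Two samples are merged when they share an accession id, or when
their Pearson correlation over the shared genes reaches a configurable
threshold (default 0.99 — high enough that biological near-neighbours
survive, low enough to catch renormalized re-uploads of the same array).
The first-encountered sample wins; every removal is reported with the
retained partner and the correlation. No attempt is made to reproduce any
particular published removal count, since redundancy criteria are rarely
stated precisely.

## Signature rules

Every formula-specified classifier is expressed as a `Signature`: genes
with direction (`up_is_risk`, `down_is_risk`, `unsigned`) and optional
weight, a rule (kind + parameters), and output labels annotated with
prognosis. The rule kinds cover the published repertoire:

- **linear_cutoff** — `score = intercept + Σ w_g·x_g` against fixed
  cutoffs (hypoxia score: intercept 1.301, risk above 4.526; recurrence
  score: low < 30, intermediate 30–40 inclusive, high > 40; relapse hazard
  score: risk above 0), the cohort median, or tertiles. An optional ΔCt
  pre-transform emulates RT-PCR values from array data:
  `ΔCt(g) = −15 − (log2(mean(housekeeping)) − log2(g))`, with the
  housekeeping mean arithmetic on the linear scale by default (geometric
  available).
- **product_ratio** — signed absolute product/ratio terms on
  housekeeping-adjusted values (each gene minus the per-sample mean of the
  five reference genes); a zero denominator makes the sample's score
  undefined and its call NA.
- **tally** — per-gene reference levels (cohort median, or 80th/20th
  percentiles for the 13-gene relapse rule); a gene scores positive
  strictly beyond its reference in the risk direction; the tally either
  is the label (0–3 for the three-gene rule) or crosses a threshold
  (≥ 5 of 13; ≥ 3 of 7).
- **signature_mean_split** — unweighted signature mean split at the
  cohort median (chromosomal-instability score) or into tertiles
  (95-gene and stem-cell signatures).
- **group_mean_compare** — BRAF-mutant-like when mean(G1) < mean(G2),
  wild-type-like otherwise (ties inclusive).
- **dual_median** — high risk only when both sub-model scores strictly
  exceed their own cohort medians (inflammatory risk score).
- **trained_model** — delegates to a trainable engine, optionally with a
  confidence floor (0.90 for the Dukes-stage PAM classifier).

Ties at cohort-relative cutoffs always fall to the lower (non-risk) group;
one convention across all rules keeps risk calling conservative and the
rules exactly reproducible. The three-group splits published without
explicit boundaries are implemented as tertiles of the signature-mean
score, a documented config knob rather than a claim about the original
boundaries. The per-gene "poor-prognosis level" of the 7-gene rule is the
cohort median by default, configurable to percentiles.

Classifiers whose full constants appear in the primary literature (the
five-term hypoxia score, the three-gene tally, the five-gene product-ratio
score with its five reference genes, the 7-gene tally) ship as built-ins.
One published description of the hypoxia score says six genes while its
printed formula has five gene terms plus an intercept; the printed formula
is implemented. Gene lists living only in supplementary materials
(25/95/114/163/658/786-gene sets and the consensus-subtype centroids) are
config-supplied; rule skeletons carrying the published cutoff constants
can be extended with a gene list in YAML. Signature coverage on a given
matrix is reported, and a signature runs on its shared-gene subset when
coverage ≥ 0.8 (the same graceful degradation the original reduced-probe
analyses used); below the floor it is marked non-evaluable rather than
silently scored.

## Trainable engines

- **Nearest centroid**: per-class gene means; distance Euclidean or
  one-minus-Pearson (the latter the natural choice for centroid-correlation
  subtype predictors; per-signature configurable). Confidence is the
  normalized inverse distance.
- **Nearest shrunken centroid (PAM)**: standardized class-vs-overall
  contrasts `d_gk = (x̄_gk − x̄_g)/(m_k(s_g + s0))`, `m_k = √(1/n_k − 1/n)`,
  with `s0` the median of pooled within-class gene SDs, soft-thresholded
  by the shrinkage amount and rebuilt into centroids. Class posteriors are
  Gaussian-discriminant softmax of the standardized squared distances with
  uniform priors (subtype prevalences differ too much between cohorts to
  justify training-set priors). Shrinkage 0 reduces exactly to nearest
  centroid in standardized space — a tested identity.
- **Compound covariate predictor** (2 classes): pooled-variance t
  statistics as gene weights, score `Σ t_g·x_g`, threshold at the midpoint
  of the class-mean scores; a sample exactly at the midpoint goes to the
  class with the lower mean score.
- **Meta-gene linear discriminant**: meta-gene features are member-gene
  means; the pooled within-class covariance gets an additive ridge
  (default 1e-6) so singular covariance never aborts; constant features
  and uncovered meta-genes are dropped with warnings.
- **Reference engines**: KNN (majority vote, default k = 5; split votes
  break toward the class with the smaller aggregate distance, exact
  distance ties → NA) and a linear max-margin classifier (linear-kernel
  SVM, C = 1000).

Prediction ties yield NA, as do calls under a model's confidence floor —
unclassified samples are a legitimate output of subtype assignment, not an
error. Centroid-style models serialize to structured text (JSON) and
round-trip exactly; KNN/SVM reference models retrain from the labeled
matrix instead.

## Concordance and gene scores

Cramer's V uses the uncorrected χ² (the standard convention, and the one
that makes hand-checks exact). Samples unclassified by either classifier
are excluded pairwise. Per-prognosis-label agreement reduces each call
vector to an indicator for one named label and takes Cramer's V,
clamped to 0 when the observed co-occurrence falls below the independence
expectation — V is unsigned, and a negative association should not read
as agreement. This statistic restricted to a label is a package decision
(the quantity is displayed but not defined in the literature it mirrors);
it is isolated behind one function. Gene-list overlap is row-normalized
(`100·|A∩B|/|A|`, asymmetric), and the gene score is
`(number of containing signatures) × (Σ 1/signature size)`, ranked
descending with alphabetical tie order.

## Survival benchmark

All fits delegate to lifelines. Cox fits use the Efron approximation for
tied event times (ties are common in month-resolution follow-up) and Wald
CIs/p-values. The best-vs-worst reduction ranks labels by one-vs-rest log
hazard — the selection criterion is a package decision since "best and
worst outcome" is rarely operationalized in print; a KM-median ranking
would be a reasonable alternative and the ranking function is separable.
For a two-label classifier the reduction is exactly the plain two-group
fit (tested to machine precision). Per-classifier training-set exclusion
removes samples whose dataset tag appears in the signature's
`training_set_ids`, with a configurable exception list for classifiers
trained on the full pooled cohort. The univariate screen median-splits
each gene (ties low), reports per-signature proportions significant at
0.05/0.01 with constant genes excluded from the denominator, and a
Spearman correlation relates those proportions to classifier hazard
ratios. The multivariate fit adds MSI, gender and expression covariates
to the classifier indicator with listwise deletion (counted), requires
covariate availability for ≥ 50% of classified samples, and aborts on
near-collinear covariate pairs (|r| > 0.999) by name.

## Cell-line assignment

Replicate arrays of one cell line vote: the modal label is final iff it
reaches 60% of arrays, inclusive — "at least 60%" is taken at its word, so
3-of-5 passes and a 50/50 split is NA. (The equivalent ">40% disagreement
→ unclassified" phrasing found elsewhere differs only at exactly 60/40;
the inclusive reading is adopted.) NA per-array calls count in the
denominator but never win. Cohort-relative rules are computed within the
cell-line panel, not the patient cohort: the panel is classified as a
standalone set. Mutation statuses (KRAS, BRAF, PIK3CA, PTEN, TP53, APC;
codes M/WT/NA) join from a user table; conflicting duplicates are an
error, absent lines become all-NA with a warning. The
prevalence-vs-models table pairs patient label proportions (NA as its own
category, summing to 100%) with cell-line counts and flags unmodeled
subtypes.

## Synthetic cohorts

The generator emulates a pooled normalized microarray cohort: background
log2 expression ~ Normal(7, 1) — typical location and spread for
normalized chips — with an optional heavier-tailed t(5) noise flag.
Subtypes are drawn multinomially; signature genes shift by ±effect size
(direction-aware) in the samples of the highest-hazard subtype. Relapse
times are exponential with rate `baseline × hazard_map[subtype]`
(baseline 0.02/month ⇒ ~35-month median, matching mid-40s-month cohort
medians), which satisfies proportional hazards exactly and makes Cox
recovery a clean oracle. Censoring is an independent Uniform(0, H) time
with H solved numerically so the marginal censoring probability equals the
requested rate (default 20%) under the subtype mixture — keeping censoring
independent of event times so hazard estimates stay unbiased. Optional
month rounding (off by default) exercises tie handling. Clinical
covariates (stage, MSI, gender, age) are drawn with realistic marginal
frequencies but independently of outcome, so they serve as planted nulls
in multivariate checks.

What the generator does *not* emulate: platform- and batch-specific probe
effects, correlated gene-gene structure beyond the planted shifts,
non-proportional hazards, and informative censoring. Passing tests
therefore demonstrate that the machinery is correct under the stated
model, not that any classifier generalizes to real cohorts — fixed-scale
formulas (e.g. a risk score with absolute cutoffs) can be degenerate on
synthetic data whose scale they were never fit to, and the benchmark
reports exactly that.

## Problem sizes and numerical choices

Default test and acceptance problem sizes — cohorts of 200–600 samples ×
a few hundred genes, 200 replicates for CI-coverage calibration, 1000
lines for consensus-rate checks — are chosen so every stochastic check
sits well inside its statistical tolerance while the suite runs in well
under a minute on one core; they are package defaults, stated here so
results are reproducible at the same sizes. Determinism: every generator
is a pure function of its parameters and a seed; the benchmark bundle is
byte-identical across runs at fixed config and seed. Tie tolerances: exact
prediction ties use relative tolerance 1e-9–1e-12; median/percentile ties
are resolved by the strict-inequality convention above rather than by
floating comparisons.

## Known limitations

- The registry ships no supplementary-material gene lists, so out of the
  box only the fully published classifiers run; the others need one YAML
  entry each.
- The best-vs-worst label ranking refits one Cox model per label; with
  many labels and few events per label the ranking itself is noisy, and
  the resulting extreme-cohort HR inherits a selection optimism the
  package does not correct for (matching the benchmark design it mirrors).
- Multivariate adjustment codes binary covariates 0/1 and refuses > 2
  levels rather than expanding dummies.
- The duplicate detector is O(n²) in samples via a full correlation
  matrix; fine for cohorts of a few thousand samples, not for biobank
  scale.
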