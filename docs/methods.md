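# Methods

This note documents the models, algorithms and numerical choices behind
`epnsig`, including the places where the underlying procedure is
conventionally under-specified and a concrete choice had to be made.

## Marker discovery

**Input.** A probes × samples expression matrix with one entity label per
sample (tumour diagnosis). The pipeline assumes summarized, comparable
per-sample values; probe-level summarization from raw arrays is out of
scope.

**Normalization.** Quantile normalization forces every column onto the
common rank-mean distribution: the reference is the per-rank mean of the
sorted columns, and tied values within a column receive the mean of the
reference values of their tied ranks (so rank order is preserved and the
operation is idempotent). With a single sample the matrix is returned
unchanged with a warning. After log2 transformation, probes with sample
variance < 0.25 (log2²) are removed — they cannot carry a five-fold group
difference and only dilute the ranking.

**Resampled t-test.** For a target group of size *t*, each of the
`n_iterations` (default 100) iterations draws *t* samples *without
replacement* from the pooled non-target entities and computes, per probe, a
two-sided equal-variance Student t-test p-value and the linear fold-change
`2^(mean_target − mean_drawn)`. Scores are the arithmetic means of p and of
fold over iterations (the per-iteration maximum fold is kept alongside).
Resampling makes the ranking robust to the accidental composition of the
comparison set. Draws are pooled across the non-target entities rather than
stratified (stratified proportional allocation is available as an option),
and Welch's unequal-variance test is available behind a flag. Probes
mapping to the same gene are scored independently. Ranks are assigned by
ascending mean p with ties broken by larger mean fold, then probe id, so
the ranking is deterministic. Sample identities are sorted before any draw:
scores are invariant to the column order of the input matrix. No
multiple-testing correction is applied; the scheme is a *ranking* device,
not an inference procedure.

**Selection rule.** Candidates are probes with mean fold ≥ 5 whose
significance rank is within the top 20, returned by descending fold. Both
thresholds are parameters (`SelectionRule`).

Degenerate case: a probe with zero variance in both groups yields an
undefined t statistic; its p is set to 1 (no evidence of difference).

## nCounter normalization

Raw per-lane counts are scaled in two geometric-mean steps, mirroring the
vendor's default processing:

1. **Technical**: factor = (batch arithmetic mean of per-lane geometric
   means of the positive controls) / (lane's geometric mean). After
   scaling, the positive-control geometric means are equal across lanes to
   machine precision.
2. **Biological**: the same formula over the housekeeping genes (default
   ACTB, GAPDH, TBP), applied to the technically normalized counts.
   Endogenous genes are then transformed as log2(count + 1); control and
   housekeeping records are dropped from the output matrix.

Lanes with a scaling factor outside [0.3, 3] (technical) or [0.1, 10]
(biological) are *flagged, never dropped*; a zero positive-control count is
flagged and the geometric mean computed from the nonzero controls.
Background subtraction from the negative controls (per-lane mean + 2·SD,
clipped at zero) is implemented but off by default, matching the common
default. The pseudocount 1 keeps zero counts finite on the log scale.

One subtlety: because the scaling target is the *batch mean*, rescaling a
single input lane by a constant shifts every lane's normalized values by
one common log2 offset. Relative profiles — and therefore z-scores,
Euclidean distances and all downstream assignments — are exactly invariant,
and the tests check invariance at that level.

## Group assignment

All clustering is agglomerative with average linkage on Euclidean distances
over the log2 values of the relevant signature genes (ties in the merge
order resolved deterministically by pair index). A sample's *signature
score* for a group is the mean, over the group's genes, of per-gene
z-scores computed across the analysis batch (constant genes contribute 0).

**Signature panels** (defaults): RELA+ = RELA, ELL3, FBP2, PCP4L1, MYO3A;
YAP1+ = MRAP, IGF1, CAPS, WWC1; PFA = LAMA2, ALDH1L1, SLC6A13, IGSF1,
CXorf67; PFB = NELL2, DNAH1, CEP83, C9orf72, NXNL2; PFA1 = SKAP2, WIF1;
PFA2 = EN2, CNPY1. DRD1 and ANGPTL6 are deliberately absent: one
hybridizes uniformly low, the other non-specifically, so they fail probe
QC. The six-gene CNS HGNET-MN1 panel is not published with this gene set
and must be supplied by the user.

**Reference-anchored supratentorial assignment.** The tree over the
nine-gene panel is cut into k clusters (default: distinct reference groups
+ 2 — one slot for an unclassified cluster and one for a possible
singleton). A cluster containing references of exactly one group takes that
label; if references of different groups co-cluster, k is increased until
they separate (identical conflicting references raise an error). For
unreferenced clusters, two deterministic rules apply in order:

* *score rule*: if the cluster's best mean signature z-score reaches
  `z_min` (default 2.0) for a group that has **no** reference in the batch,
  it takes that label — this is how a rare group (e.g. a single
  YAP1-signature sample) is recognised without a reference;
* *nearest-reference rule*: otherwise the cluster adopts the label of the
  cophenetically nearest referenced cluster. This guards against the cut
  splitting a genuine signature cluster: the orphaned fragment re-attaches
  to its reference rather than silently becoming "not classified".

A "not classified" (NC) call therefore requires a fusion-negative reference
in the batch, which is how the assay is run in practice.

**PFA/PFB with outlier detection.** Samples carrying *neither* signature
are removed before labelling. The outlier rule dichotomizes each
signature's mean log2 expression by a two-cluster variance-minimizing 1-D
split; samples in the low cluster of both signatures are outliers. (A fixed
z-score cut-off cannot do this job: with a 42:7 group imbalance the batch
z-score of a signature-less lane on the minority signature is only ≈ −0.4,
indistinguishable from majority-group lanes, whereas the dichotomization
margin is the full planted fold.) The remaining samples are cut into two
clusters over the ten panel genes; the cluster with the larger mean
(PFA-z − PFB-z) differential is PFA, the other PFB, so a single
minority-group sample is still labelled by its signature rather than by
cluster size. A matrix with no variation at all yields all-outlier with a
warning.

**PFA1/PFA2.** The PFA-labelled samples are re-clustered on the four
subgroup genes and the two clusters labelled by the same score
differential. Fewer than three PFA samples, or four flat subgroup genes,
refuse sub-assignment (samples stay PFA, with a warning).

**NELL2/LAMA2 trichotomy.** Each gene's log2 values are dichotomized by the
same variance-minimizing split; labels compose to NELL2+/LAMA2−,
NELL2+/LAMA2+ and NELL2−/LAMA2+, and the doubly negative combination maps
to "outlier". A constant gene has no split and raises.

## Clinical statistics

* **Fisher's exact test** (two-sided) sums the hypergeometric point
  probabilities, at fixed margins, of every table whose probability does
  not exceed the observed table's (minimum-likelihood convention, 1e-7
  relative slack for near-ties; delegated to scipy and cross-checked in the
  tests against an exact-arithmetic enumeration oracle for every 2×2 with
  n ≤ 40).
* **Kaplan–Meier / log-rank** use lifelines. OS events are deaths; PFS
  events are progression or death, whichever first; records with an
  unknown follow-up time (e.g. a death with no recorded month) are kept for
  counting but excluded from time-to-event estimates.
* **Fusion concordance** builds the 2×2 with rows {signature-positive,
  not-classified} and columns {named fusion detected, not detected}; other
  groups are excluded and a *different* detected fusion (e.g. ZFTA-MAML2)
  counts as "not detected" for the named fusion.
* **Survivor counting**: a patient counts as surviving ≥ m months if their
  known follow-up time is ≥ m (alive or died at/after m); patients with
  shorter follow-up or unknown death time cannot be verified and are not
  counted.
* **Age comparisons** use the two-sided equal-variance Student t-test; the
  zero-pooled-variance degenerate case returns p = 1 for equal means.

**Clinical-table encoding** (packaged 15-patient fixture): "alive disease
free at m" → censored at m; "died of disease at m" → death event at m; a
death with no recorded month → event kept, time flagged unknown; a relapse
month → progression event at that month, otherwise progression is censored
at follow-up.

## Synthetic cohorts

The generators are pure functions of (design, seed) via
`numpy.random.default_rng`.

* **Expression cohorts**: per-probe baseline ~ N(mean 7, sd 1) on the log2
  scale; planted markers add log2(fold) in the target entity only;
  per-value Gaussian log2 noise (default sd 0.5, a typical microarray
  residual) is multiplicative on the linear scale. Noise-free designs
  reproduce their planted ratios exactly.
* **nCounter batches**: expected counts = baseline 200 (endogenous), 1500
  (housekeeping), 4 (negatives), positive controls on the conventional
  six-point geometric ladder (relative concentrations 128…0.125, scaled
  ×100); signature genes of a lane's group are elevated by
  `signature_fold` (default 6, comfortably above assay noise, matching a
  strong expression signature). Every expected count is multiplied by a
  per-lane lognormal technical factor (sd 0.25) and counts drawn negative
  binomial with NB size 20 (≈ 22% CV at depth, a realistic overdispersion);
  size = ∞ gives Poisson and `dispersion=None` gives deterministic rounded
  means — the zero-noise limit used by exactness tests.
* **Survival tables**: exponential event times from stated monthly death
  and progression hazards with uniform administrative censoring on a
  window (default 24–120 months); ages normal, truncated at 0.1 years.

What the generators deliberately do **not** emulate: probe sequence
effects, hybridisation chemistry, cartridge/batch effects beyond the single
lane factor, correlated gene–gene noise, and FFPE RNA degradation. Passing
recovery tests therefore demonstrate the *algorithms* recover planted
structure under realistic count noise — not that any particular clinical
series will classify as cleanly.

## Problem sizes and determinism

The test-suite recovery experiments use 500-probe, 40-sample cohorts with
ten planted 8-fold markers (marker discovery) and 15-lane batches over 20
seeds (classification); both sizes give the classifiers and scorers
realistic imbalance while keeping the whole suite around a minute. Marker
scoring in the recovery experiments operates directly on the simulated
log2 matrix: the generator's columns share one scale by construction, and
quantile-normalizing a matrix in which half the columns carry planted
markers would shrink the planted folds (the rank-mean reference averages
marker-high and baseline columns) — a property of the normalizer worth
knowing about, and the reason real analyses quantile-normalize *within* a
platform cohort before pooling entities. Every stochastic component takes
an explicit seed, and the pipeline runner writes byte-identical artifacts
for identical config + seed.

## Known limitations

* The reconstructed signature-vs-fusion 2×2 ([[9,1],[0,4]]) excludes the
  YAP1-signature sample; including it would change the Fisher p. The
  exclusion follows the convention that concordance is assessed between the
  RELA+ signature and its own fusion.
* The published marker fold-changes (e.g. FBP2 at 716-fold) derive from
  public microarray cohorts that this package does not download; the
  selection *rule* is implemented and validated on synthetic cohorts
  instead.
* nSolver option choices (background subtraction, mean vs geometric mean)
  are not published for the original analysis; this package uses the
  documented defaults.
* Hierarchical-cluster group labels depend on the analysis batch (z-scores
  and cut structure are batch-relative); single-sample classification is
  out of scope — include references in every batch.
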