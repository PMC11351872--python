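# Methods

This note records the statistical model behind `cpsn`, the numerical
conventions the implementation fixes where the method itself leaves a
choice open, what the synthetic-cohort generator does and does not
emulate, and the known limitations.

## 1. Encoding model

A cohort is described by a schema of *M* variables; variable *i*
contributes *Nᵢ* one-hot states, for a ΣNᵢ-column binary embedding.

**Quartile discretization.** Continuous variables are cut at the 25th,
50th and 75th percentiles of their *observed* (non-missing) values,
computed by linear interpolation between order statistics (the "type 7"
quantile convention — the default in numpy, R and most spreadsheets; fixed
and documented so that other implementations can match bit-for-bit). Bins
are upper-inclusive: a value exactly equal to a cut point falls into the
lower bin. Values outside the training range clamp into the outer bins —
an index patient more extreme than anyone in the reference cohort is still
"very low"/"very high", which is the clinically sensible reading. Fitting
requires ≥ 4 distinct observed values per continuous variable; heavily
tied data may collapse cut points, in which case the implied empty bins
are simply never activated.

**Missingness as a state.** A missing entry activates the variable's
dedicated `NA` indicator. No imputation is performed anywhere. Two
consequences are worth spelling out: (i) every encoded row sums to exactly
*M*, so all patients — however incomplete — live on the same sphere-like
shell of feature space and contribute equally to distances; (ii) two
patients *both* missing a value count as agreeing on it. That is a
modelling stance, not an accident: shared unobservedness (e.g. neither
patient was tested for a marker) is often itself clinically informative,
but see §6.

In the built-in gastric-cancer schema every continuous variable is allowed
to be missing and therefore contributes 4 + 1 states. This is what makes
the arithmetic close: 12 × (4 + 1) + 83 categorical states = 143 features
from 37 variables. The reference baseline table records no missing counts
for the continuous rows, so their `NA` indicators exist but may stay
silent on a fully observed cohort; the feature *count* is a property of
the schema, not of any particular cohort.

**Unseen levels.** At transform time a categorical level absent from the
schema raises an error by default (a clinical-safety bias: silent coercion
of a novel pathology code is worse than a crash). A `lenient` flag maps
unseen levels to `NA` when the variable allows missingness.

## 2. Distances and retrieval

Distances are plain Euclidean on the 0/1 rows; because each variable is a
unit-indicator block, each disagreeing variable contributes exactly 2 to
the squared distance (d = √(2q) for q disagreements), so no per-feature
scaling is applied — every variable has the same bounded leverage. The
network is materialized as the full n × n matrix; at the cohort sizes this
package targets (a few thousand patients) that is both simpler and faster
than sparse-graph machinery, and both clustering and KNN need the full
metric anyway.

KNN retrieval encodes the index patient with the *already fitted* model —
never refitting quartiles on a single record — and breaks distance ties by
reference-table order (stable and reproducible). `k` is deliberately
caller-controlled: it tunes how wide a circle of "similar patients" the
clinician wants to reason from.

t-SNE (scikit-learn, PCA initialization, perplexity 30, fixed seed) is
provided strictly for display. Clustering always runs in the original
feature space; the embedding is never an analysis input.

## 3. Cluster number selection

K-means uses ordinary Euclidean Lloyd updates on the binary matrix
(centroids are per-state frequency vectors), k-means++ initialization, and
the best of `n_init = 10` restarts; scikit-learn's implementation supplies
the iteration internals, including reseeding of emptied clusters. Reported
labels are renumbered by decreasing cluster size (ties by first patient
index), which makes labels invariant to restart order and gives the
`Cluster_1 … Cluster_K` naming.

**Elbow.** The scan default is K = 2…10. The elbow is formalized as the
interior K maximizing the discrete second difference
W(K−1) − 2W(K) + W(K+1) of the inertia curve — the point of maximal
curvature. A perfectly linear or flat curve has no elbow; the selector
warns and falls back to the smallest K rather than inventing structure.
(Kneedle-style normalized curvature is a reasonable alternative; the
second difference was chosen for transparency and testability.)

**Gap statistic.** Gap(K) = E_B[log W_ref(K)] − log W(K) with
s_K = sd·√(1+1/B), choosing the smallest K with Gap(K) ≥ Gap(K+1) −
s_{K+1}. The reference distribution is **marginal resampling**: each
variable's one-hot state is redrawn independently from its empirical
marginal. This preserves the block structure and per-state frequencies
while destroying co-occurrence across variables — the meaningful null
here. The classical uniform-bounding-box reference is undefined for unit
indicator rows, which is why it was not used. Zero inertias (duplicate
data) are guarded with an epsilon inside the logarithm and a warning.

## 4. Validation statistics

Kaplan–Meier and the k-sample log-rank test are implemented directly from
the product-limit and observed-minus-expected formulas (hypergeometric
covariance accumulated over distinct event times; deaths processed before
censorings at ties; quadratic form over k−1 groups, χ² with k−1 df). This
keeps the package self-contained and lets the test suite check the
implementation against hand-computed tables, a 10⁴-shuffle permutation
oracle, and the `lifelines` library as an independent reference. The
chi-square association test delegates to `scipy.stats.chi2_contingency`
(Pearson, no continuity correction), with a flag raised when any expected
cell count drops below 5.

Thresholds are fixed: log-rank p < 0.05 grants the network its "clinical"
designation; marker associations are called at p < 0.01. Raw p-values are
reported with **no multiple-testing correction** — the decision rule is
deliberately the raw per-test threshold, stated here so nobody mistakes
it for an oversight. `NA` is retained as a category in marker contingency tables by
default (consistent with the encoding philosophy; several markers are
unobserved for most patients, and dropping them would silently discard the
majority of the cohort), with a `drop_na` option. Follow-up times are
treated as months throughout.

Conventional comparators (age split at cohort quartiles, differentiation
grade, composite stage) are provided as grouping helpers so a clustering
can be benchmarked against the stratifications a clinician would use
anyway.

## 5. Synthetic-cohort generator

The generator's defaults *are* the study conditions for every recovery
test: n = 1000 patients, k_true = 5 equally mixed clusters,
separation 0.6, per-cluster exponential hazards (0.015, 0.006, 0.012,
0.018, 0.024) per month — a 4-fold spread so one cluster has clearly the
best and one the worst prognosis — and 30% censoring. Categorical
marginals equal the built-in schema's reference counts / 1000; tabulated
`NA` counts become missingness rates (e.g. Lauren 0.672, dMMR 0.630).
Continuous marginals match the reference medians: normal for age, BMI,
lymphocyte count and the expression fractions (sd = range/6, clipped to
the reference range), log-normal for the long-tailed serum markers,
leukocyte count and tumour diameter (σ = ln(max/median)/3). Follow-up
duration and censoring fraction are not derivable from any tabulated
summary; months and 30% are declared defaults, not inferences.

**Planting mechanism.** Every draw is inverse-CDF sampling from the
variable's marginal. With probability `separation` the uniform driver is
confined to the quantile slice of [0,1) owned by the patient's cluster;
slices tile the interval with widths equal to the mixing proportions and
are rotated by one position per variable so different variables favour
different states. Mixing over clusters therefore reproduces every marginal
*exactly* at any separation — an earlier point-mass-tilt design was
dropped because it traded marginal fidelity against separation, whereas
the slice construction decouples them completely. `separation = 0` is a
true null (downstream ARI ≈ 0); at the default 0.6 the full pipeline
recovers K = 5 with ARI > 0.9. Censoring times are exponential with the
rate solved numerically (Brent) so that the mixture censoring probability
Σ πⱼ c/(c+hⱼ) hits the target fraction.

Missingness is masked after the state draw, independently of cluster
(MCAR) by default; a `cluster_missingness_tilt` option scales rates
linearly across clusters for experiments with informative missingness.
A master seed spawns independent per-component streams (cluster labels,
survival, censoring, one per variable), so adding a variable leaves all
other columns unchanged.

**What the generator does not emulate.** Real inter-variable clinical
logic beyond cluster-driven dependence: there is no constraint that pT/pN
combinations imply the recorded stage, no correlation between, say, tumour
diameter and pT within a cluster, and no measurement error model. Passing
recovery tests on these cohorts therefore demonstrates that the pipeline
recovers *planted, marginal-faithful* block structure — not that five
subgroups exist in any real gastric-cancer population.

## 6. Problem sizes used in tests

The test suite runs the study-scale cohort (n = 1000) once per session for
the recovery and survival checks, a 20-replicate elbow-recovery sweep at
n = 1000, and smaller cohorts (n = 120–400) for gap-statistic, KNN and
pipeline tests; the permutation oracle uses 10⁴ shuffles on a 30-patient
fixture. These sizes were chosen so each property is tested at a scale
where its failure mode could actually appear (e.g. elbow detection needs
the full cohort; tie-handling does not).

## 7. Known limitations

* Equal leverage per variable is also equal *redundancy* blindness:
  correlated variables (the four mismatch-repair IHC stains and the
  derived dMMR status all appear separately) multiply their shared signal.
  A covariance-aware distance (Mahalanobis) would address this and is
  intentionally out of scope.
* Agreement-on-missing contributes similarity. With very high missingness
  (several variables exceed 60%) clusters can partially reflect testing
  patterns rather than biology; the informative-missingness simulation
  mode exists precisely to study this.
* The elbow second-difference rule is scale-dependent across adjacent K
  and can be indecisive on weakly structured data; the gap statistic is
  the more principled fallback and both are reported.
* Survival validation is a k-sample test only: no hazard ratios, Cox
  adjustment, or competing risks.
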