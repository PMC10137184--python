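# Methods

This note documents the statistical procedures `mirdx` implements, the
synthetic data they are exercised on, the numerical choices made where the
procedure is underdetermined, and what the tests do and do not establish.

## Differential expression and marker selection

Expression is modeled on the log2 scale throughout. For a tumor/normal
contrast the package computes, per feature:

* the mean log2 difference Δ and the fold change 2^Δ (a geometric-mean
  ratio — the natural choice on log2 data);
* a classical pooled-variance two-sample t-test (unpaired design) or a
  one-sample t-test on within-pair differences (paired design), two-sided;
* the SAM relative difference d = (x̄₁ − x̄₂)/(s + s₀), where s is the
  Tusher-style pooled standard error and s₀ is a variance-stabilizing
  offset fixed at the 5th percentile of the per-feature s distribution.
  The percentile is a design choice: the original exchangeability-factor
  search is not reproducible from the published description, and a fixed
  low percentile keeps d well-behaved for low-variance features.

SAM q-values come from permutations of the group labels (unpaired) or sign
flips of pair differences (paired). With B permutations yielding statistics
d*, the raw estimate for feature i with threshold t = |dᵢ| is

    q_raw(i) = median_B #{j : |d*_Bj| ≥ t} / #{j : |dⱼ| ≥ t},

clipped to [0, 1] and then monotonized so q never increases with |d| (each
feature takes the running minimum over itself and all less significant
features — the same ordering argument as Benjamini–Hochberg). The permutation
space is enumerated exhaustively when it holds ≤ 10,000 assignments
(C(n, n₁) label splits, or 2^k sign vectors); otherwise 1,000 seeded random
permutations are used. The π₀ proportion of true nulls is taken as 1, which
is conservative. Tests verify the q-values against a brute-force
enumeration oracle to 10⁻⁹ on small cohorts.

A feature is selected as a marker when all three gates pass: FC > 2 or
FC < 0.5, t-test p < 0.05, and q < 0.05. The selection is monotone in every
threshold (property-tested). Unions of marker sets are keyed by feature id
with provenance merged; a feature whose direction disagrees between the two
arms is excluded with a warning. Blood-sample contrasts use the same
operations without the SAM gate (tiny group sizes make permutation FDR
uninformative there; only the t-test and fold-change gates apply).

## Clustering and nearest-centroid classification

Samples are clustered on the marker submatrix with Manhattan distance and
Ward's minimum-variance linkage applied directly to the dissimilarities —
the behavior of classic `ward.D`. SciPy's `ward` squares its input inside
the Lance–Williams recurrence, so the implementation feeds it the square
roots of the Manhattan distances; the resulting merge order is exactly
`ward.D` on the original distances (heights are a monotone transform, which
does not affect the 2-cluster cut). Clusters are mapped to classes by
within-cluster majority vote, with ties labeled tumor; the confusion report
treats tumor as the positive class. Feature-side clustering is only ever a
display ordering and never affects classification.

The centroid classifier stores per-feature class means computed over all
training samples under their true labels — samples that an unsupervised
clustering would misplace are deliberately included, since the model is
defined by the recorded diagnosis. Prediction correlates (Pearson) a test
profile with each centroid over the intersected feature set, refusing fewer
than 3 shared features and flagging zero-variance profiles instead of
guessing. Ties predict tumor with a flag: in a screening context the
sensitive error is preferred, and ties have measure zero on continuous data.
The observation that samples correlating < 0.8 with the normal centroid are
almost always tumors is surfaced as a diagnostic statistic, not used in the
decision rule.

## Survival analysis and categorization

Kaplan–Meier curves and univariate Cox fits are delegated to lifelines
(Breslow tie handling, Wald intervals); the two-group log-rank statistic is
computed in-package from the risk tables because the cutoff scan evaluates
it at every candidate threshold, and is cross-checked against both hand
O−E computations and lifelines in the tests.

The optimal-cutoff procedure scans every unique observed expression value
that leaves at least 10% of the cohort on each side, takes the split with the
smallest log-rank p, and reports the Cox hazard ratio at that split. The 10%
floor is a design choice: an unrestricted scan produces degenerate
single-patient groups. No multiplicity correction is applied to the scan —
that is the procedure being modeled — so the null distribution of the
minimum p is strongly anti-conservative; this is documented, tested (the
null rejection rate is far above 5%), and flagged in every summary the scan
produces (`min_p_scan`).

A miRNA is categorized oncogenic when it is over-expressed in tumors and has
HR > 1 with p < 0.05 in all required survival cohorts (an adenocarcinoma
cohort, a squamous cohort, and their pool analyzed as one); suppressive is
the mirror; anything else, including missing cohort evidence, is neither.
A `majority` concordance policy is available as a configuration flag. Genes
are called hazardous/protective from up to five evidence categories (tumor
vs normal differential expression plus survival in four cohorts) under a
two-supporting/zero-contradicting rule; the full 3⁵ truth table is
enumerated in tests and the two calls are mutually exclusive by
construction.

## Drug response, radiotherapy and dependency screens

Cell lines are categorized per (drug, source, measure) by a tertile split of
the response values: lowest ⌊n/3⌋ sensitive, highest ⌊n/3⌋ resistant, middle
excluded; groups with under 6 lines or no ordering information are excluded
entirely. The tertile split is a deterministic, scale-free stand-in for the
categorization the upstream screens publish, and is the replaceable `method`
of `categorize_lines`. Per drug, a feature significantly higher (pooled t,
p < 0.05) in sensitive lines is a sensitive marker; multiple source/measure
tables are combined by any-source with a conflict veto.

A pan-call across the drug panel requires, for pansensitive: no resistant
call for any drug in any required layer, and at least one drug called
sensitive in every required layer (genes: mRNA and protein; miRNAs: the
miRNA layer). Requiring the supporting drug to be concordant across layers
keeps single-layer type-I errors from manufacturing pan calls: with 21 drugs
tested two-sided at α = 0.05 per layer, a rule needing only per-layer
pansensitivity would mislabel a null gene with probability ≈ 2 × (0.975²¹ −
0.95²¹)² ≈ 0.12 even with independent layers, whereas the concordant rule
keeps null genes at "neither" in ~99% of simulated panels while recovering
planted associations essentially always.

Radiotherapy association compares gene expression between long (> 58 months)
and short (< 20 months) survivors among stage III/IV patients who received
radiotherapy; the intervals are open, so boundary patients are excluded.

Dependency screens are renormalized per cell line by the unique affine map
sending that line's essential-anchor median to −1 and non-essential median
to 0 (x ↦ (x − m_non)/(m_non − m_ess)); anchor medians are exact after the
map, coincident anchor medians are a hard error naming the line. A
normalized score strictly below −0.5 is a significant effect; per-gene
fractions of affected lines per assay feed the profile classes both_major
(> 50% in every assay), either_major (> 50% in at least one),
none_significant (zero affected lines everywhere), and other.

## Signature lists

Two up/down list pairs are assembled from prognostic calls × dependence
profiles: list 1 pairs protective genes with < 50% dependence in both assays
(up) against hazardous genes with > 50% in both (down); list 2 pairs
protective genes with no dependence at all (up) against hazardous genes with
> 50% in at least one assay (down). Genes with a `neither` prognostic call
never enter a list; order follows the input; within-list up/down
disjointness is enforced by the container. Lists are written as GRP files
(one symbol per line, no header). Executing connectivity queries is out of
scope; result tables are consumed back and filtered at score > 0.9 (strict)
and p ≤ 0.05 (inclusive).

## Synthetic data

The generators define the conditions every test and the acceptance script
run under:

* **Expression cohorts** — i.i.d. Gaussian noise on the log2 scale around
  per-feature baselines ~N(8, 1) (arrays quantile-normalized and
  log-transformed justify the Gaussian choice; the baseline spread gives
  profiles realistic feature-to-feature structure for correlation-based
  classification). Defaults mirror the training design: 87 tumors vs 22
  normals, all normals paired, 40 planted markers at ±2 log2 units (4-fold),
  noise sd 1. Paired samples share a random intercept with sd = noise_sd/2,
  so paired tests gain power the way matched-tissue designs do. A
  `baseline_seed` lets two cohorts share feature baselines — the same
  biology sampled twice — which is what makes cross-cohort centroid
  validation meaningful; validation runs intersect ~65% of the markers to
  emulate a platform change.
* **Survival** — exponential proportional hazards with the linear predictor
  β × (centered driver expression), baseline median 30 months; censoring is
  independent uniform-administrative with the horizon solved numerically so
  the expected censoring fraction equals the requested rate. Any independent
  censoring keeps the log-rank null exact.
* **Drug panels** — per-drug log-responses share a line-level
  general-sensitivity factor (variance fraction 0.5), as broadly sensitive
  and broadly resistant lines do in real panels; linked genes track their
  drug's full response with a 2-log2-unit effect and unit noise, giving an
  mRNA–protein correlation of 0.8 from the shared signal while measurement
  noise stays independent per layer. The protein layer is mean-centered at 0.
* **Dependency screens** — latent normalized scores (essential ≈ −1,
  non-essential ≈ 0, dependent genes ≈ −0.9 in a planted fraction of lines,
  sd 0.1) distorted per line by a random gain in [0.5, 2] and offset in
  [−0.5, 0.5], so anchor renormalization is non-trivial and exactly
  invertible.

What the generators do **not** emulate: probe chemistry and detection
thresholds, quantile-normalization internals, heavy-tailed or
intensity-dependent noise, correlated marker blocks, non-proportional
hazards, dose–response curve fitting, and batch structure. Passing tests
therefore demonstrate that the procedures are implemented correctly and
behave as designed under their own assumptions — not that the pipeline's
operating characteristics transfer to any particular real cohort.

## Problem sizes and determinism

Simulation-backed checks use deliberate sizes: 20 seeded cohorts (87 vs 22,
200 features) for marker recovery; 200 replicates of n = 300 for Cox
coverage; 10⁵ sampled call vectors for the pan-call truth table; and a
scaled pipeline configuration (80 features, 40 vs 16 samples, 60-line
panels, 120-patient survival cohorts) for the end-to-end run, which the
tests execute twice and compare byte for byte. All randomness flows from a
single seed through SHA-256-derived per-stage seeds (< 2³¹), so every stage
is independently reproducible.

## Known limitations

* The min-p cutoff scan inherits its anti-conservatism from the procedure it
  models; its p-values must not be read as calibrated.
* The tertile response categorization is a stand-in for an upstream
  published method that is not reproducible from its description; results
  depending on the sensitive/resistant boundary should be checked against
  the alternative categorization before interpretation.
* Pan-calls depend on the 21-drug panel composition; the mutual-exclusivity
  and monotonicity properties hold for any panel, but the null rates quoted
  above are specific to 21 drugs at α = 0.05.
* Cox fits use a binary covariate only; multivariable adjustment, competing
  risks, and interval censoring are out of scope.
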