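# Methods

This note documents the statistical procedures `gemcov` implements, the
conventions chosen where a design decision was genuinely open, what the
synthetic cohort generator does and does not emulate, and known
limitations.

## Preprocessing

Every feature (each gene within each per-cell-type pseudo-bulk matrix, and
each metabolite of the bulk metabolome) is processed as: **saturate** at
the feature's 95th quantile (values ≥ Q₀.₉₅ are set to Q₀.₉₅, damping
right-tail outliers typical of expression averages and LC-MS peak areas),
then **standardize** to mean 0 and sample (n−1) standard deviation 1.

Conventions, chosen where the procedure admits variants:

- Quantiles use linear interpolation between closest order statistics
  (numpy's default, "type 7") — the dominant default in scientific
  software. All quantiles in the package (saturation cap, the 75th-quantile
  metabolite split) share this convention.
- Zero-variance features are kept as all-zero columns and *flagged*, then
  excluded from testing, rather than dropped — column indexing stays stable
  across cell types.
- Highly variable features (2000 genes, 1000 metabolites by default) are
  ranked by plain sample variance on saturated, unstandardized values, ties
  broken by feature id. This is a deterministic stand-in for upstream
  single-cell HVG selectors (which fit a mean–variance trend); selection
  happens before standardization since unit-variance features cannot be
  ranked by variance.
- Pseudo-bulk is the arithmetic mean of a patient's cells of one type;
  (patient, type) combinations with zero cells are missing and are dropped
  patient-wise from that cell type's tests, not imputed.

## Association map

Per metabolite, patients split at Q₀.₇₅ of abundance: Group 1 (high,
abundance ≥ threshold) vs Group 2. A metabolite is skipped (logged) when
either side has fewer than `min_group` = 5 patients — constant vectors in
particular, where every value ties the threshold and Group 2 is empty.
The 5-patient floor is a guard against tiny-df tests; it is not active at
the default cohort shape (119 patients split 30/89).

Per (gene, cell type), a **pooled-variance Student's t** (two-sided)
compares the two groups; Welch's t is available via `welch=True`. A zero
pooled variance yields the degenerate (t=0, p=1, direction 0), flagged.
Direction is the sign of (mean Group 1 − mean Group 2): direction = −1
means expression is higher in the *low*-metabolite group.

Significance is `p ≤ 0.005` — one operator everywhere. Benjamini–Hochberg
adjustment is applied within each cell type across all of its
gene × metabolite tests (the most conservative scope consistent with
per-cell-type reporting); the nominal threshold defines "associated", the
adjusted column is reported alongside.

## Hub statistics

- Per-cell-type hubs: top 50 metabolites / top 100 genes by association
  count (top 5% of the default 1000/2000 universes). Ties at the cutoff
  break lexicographically by id, so hub sets have exactly the configured
  size and are deterministic.
- Specificity of entity e for cell type i:
  `count_e(i) − (1/(C−1))·Σ_{j≠i} count_e(j)`; top 10 positive scorers per
  cell type.
- Pan-cell-type ranking: per cell type, rank entities by degree (rank 1 =
  most associations, average ranks on ties), then sort by the geometric
  mean of ranks; geometric-mean ties break by smaller minimum rank, then
  id. Top 50 reported.
- Hub interconnection: density = realized edges / (|gene set| ×
  |metabolite set|) in the cell type's association graph. The permutation
  p-value draws 200 random non-hub sets of the same sizes (without
  replacement) and counts the fraction with density strictly above the
  observed — resolution 1/200. Because hubs are selected from the same
  map, the observed density is biased upward by construction; the p-value
  is a descriptive interconnection score, not a calibrated test (the
  package's calibration suite therefore checks uniformity with *randomly
  designated* node sets on null cohorts, where exchangeability holds).
- Hub sharing across cell types is compared to Binomial(C, 0.05): the null
  where each cell type independently grants hub status to a random 5%.

## High-confidence pathway map

Associated triples whose gene and metabolite are co-members of a pathway
become (metabolite, gene, cell type, pathway) quadruplets — one per shared
pathway, so a pair in k pathways contributes k quadruplets. Frequency
rankings count quadruplets by default (`count_distinct_pairs` switches to
distinct triples). Annotations are local files (GMT + pathway→metabolite
TSV); in the intended use they are exports of curated resources (KEGG-style
pathway gene lists, Metabolomics Workbench-style metabolite memberships) —
no network access is performed. Over-representation uses the upper-tail
hypergeometric P(X ≥ k); the universe defaults to the highly-variable gene
list, the set membership being intersected with it. Fisher's one-sided
exact test coincides with this tail.

## Metabolite ↔ cell type attribution (random forest)

Per (metabolite, cell type), `rf_repeats_metabolite` = 100 repeats of:

1. stratified 70/30 train/test split (stratification preserves the ~25/75
   group imbalance; a plain random split risks single-class test sets);
2. DE feature selection *inside the training split only*: genes with
   pooled-t p ≤ 0.05 between groups; an empty selection falls back to the
   10 smallest-p genes (logged);
3. hyperparameter search: randomized, 20 candidates over {trees: 100/300/
   500, max depth: 3/5/10/unbounded, min leaf: 1/3/5}, 5-fold CV on the
   training set, balanced-accuracy scoring;
4. balanced accuracy = (sensitivity + specificity)/2 on the test set.

The reporting rule: â = mean accuracy; sd = sqrt(â(1−â)/n_eff); 95% CI =
â ± 1.96·sd. If the CI's lower end is < 0.5 the mean is reported, otherwise
the median of the 20 largest accuracies. `n_eff` defaults to the number of
repeats (100) — a standard-error-of-the-mean construction. The literal
sd = sqrt(â(1−â)) (n_eff = 1) makes the upper branch unreachable for
â < 0.93 and is kept as the config option `ci_n_eff="one"`, with
`"test_size"` (binomial on the test count) the third variant.

Linking: reported accuracy ≥ 0.65 links a metabolite to a cell type; ≥ 4
links flags it pan-cell-type; a *specific* link requires exactly one
qualifying cell type with no other within `specific_link_margin` (default
0) of the threshold. The confounder baseline runs the identical protocol
with the patient's cell-type proportion vector as features (all columns,
no DE selection). A one-sided exact binomial test against 0.5 on the raw
correct count is provided for per-run significance statements.

Runtime knobs (`rf_search`, `rf_search_candidates`, `rf_cv_folds`,
`rf_n_estimators_fixed`, `predict_max_metabolites`) scale the search and
the stage's scope without altering the protocol structure; the test suite
runs with the search disabled and fixed 100-tree forests.

## Severity analyses

- KL binarization: grade == target (2 or 4) vs the other two grades.
- Per-cell-type classifier: features restricted to that cell type's hub
  genes; 30 repeats of the split/DE-select/fit protocol above; the run
  whose balanced accuracy is the **lower median** (15th-ranked of 30,
  deterministic) supplies the test-set scores for the reported ROC and
  trapezoidal AUROC (equal to the tie-corrected Mann–Whitney concordance).
  A bulk baseline (cell-type matrices averaged, all HVGs as the feature
  pool) is included for comparison.
- Metabolite–severity: one-sided two-proportion test of
  P(high | KL-target) > P(high | rest), as the continuity-corrected
  chi-square construction of the classical prop.test: Yates term
  min(0.5, |O₁₁−E₁₁|), one-sided p = upper normal tail of
  sign(p̂₁−p̂₂)·√X². The correction makes the test conservative at small
  counts (verified ≤ nominal in the suite).
- Overlap: metabolites with reported accuracy > 0.6 from the focal cell
  type AND confounder accuracy < 0.6, intersected with
  severity-associated metabolites (p < 0.05); upper-tail hypergeometric
  with the metabolite universe (default: all 1000 highly variable
  metabolites) as population. The pipeline picks the focal cell type as
  the one with the best KL-4 AUROC.

## Synthetic cohort generator

What it emulates: ~119 patients from 5 sites; 17 cell types whose mean
proportions are dominated by lymphocytes/monocytes with three anchored rare
populations (HSPC 1.8%, megakaryocytes 0.67%, MSC 0.12%), drawn from a
Dirichlet with concentration 300; per-metabolite log-normal abundance
(log-sd 1) — right-skewed like LC-MS peak areas, making the top-quartile
split non-degenerate; Gaussian pseudo-bulk expression (sd 1); KL grades
drawn near-uniformly from {2, 3, 4} (each grade forced non-empty).

Planted structure:

- **Pairs**: for a planted (gene, metabolite, cell type), patients in the
  metabolite's top abundance quartile get the gene's mean shifted by
  ±δ·noise_sd in that cell type only. The effect acts on the *discretized*
  grouping — exactly the contrast the association test measures — so
  detection power is analytically computable (at δ=2, n=200, group sizes
  50/150, the noncentrality exceeds 9 and power at p ≤ 0.005 is ≈ 1).
  The sign is negative with probability `negative_sign_fraction` (default
  0.72, matching the inverse enzyme–metabolite trend the analysis is meant
  to surface).
- **Hubs**: a planted hub entity receives `hub_fanout` planted partners in
  one cell type. Note the fanout shifts overlap on one entity and act as
  extra variance for each other's per-pair tests; hub *identity* recovery
  is near-certain while per-pair TPR within a hub is lower — measure pair
  TPR on cohorts without planted hubs.
- **Severity**: selected metabolites shifted by `kl_effect` log-sd in one
  KL grade; optionally `n_kl_genes` genes shifted by `kl_gene_effect`·sd
  in one cell type for one grade (a cell type-specific severity
  footprint).
- **Pathways**: a configurable fraction of planted pairs is made
  co-members of emitted pathway annotations (GMT + membership TSV), plus
  random filler members.

All draws derive from one master seed via named `SeedSequence` sub-streams
(`gemcov.util.STREAMS`), so adding a draw never perturbs earlier ones and
every run is exactly reproducible.

What it does **not** emulate — and what passing tests therefore do not
show about real data: no negative-binomial UMI counts or cell-level
sampling noise in the default cohort (pseudo-bulk is drawn directly; a
separate cell-level generator exists for exercising the averaging path);
homoscedastic Gaussian expression with no gene–gene correlation, no batch
structure beyond the site label, no instrument drift; planted effects are
exactly the contrast the test measures, so recovery results certify
implementation correctness and calibration, not real-world discovery
power.

## Problem sizes used in validation

The validation suite runs at reduced dimensions chosen to keep the planted
effects' analytic power near 1 while exercising every code path: type-I
calibration on 120 patients × 500 genes × 100 metabolites (50,000 pairs);
recovery at 200 patients × 300 genes × 100 metabolites × 3 cell types
(single seed for pair TPR, 20 seeds for hub recovery); permutation
calibration over 100 null cohorts of 60 × 200 × 40; leakage checks over 30
shuffled metabolites with 10-repeat search-free forests.

## Known limitations

- The per-cell-type BH scope, the pooled (rather than Welch) t default,
  and the type-7 quantile convention are documented conventions; other
  choices change borderline calls.
- The density permutation score is descriptive when applied to hubs
  selected from the same map (see above).
- The hub-gene feature pool for severity classifiers couples the severity
  stage to the covariation stage; a cell type with a weak association map
  gets a weak feature pool regardless of its severity signal.
- The generator's homoscedastic, uncorrelated Gaussian expression is a
  stand-in; per-cell-type variance structure of real cohorts is not
  modeled.
- `evaluate_recovery`'s false-discovery proportion counts truly-null
  significant pairs as discoveries at the nominal (not adjusted)
  threshold; at 0.005 over millions of pairs this is dominated by the
  expected nominal false positives, by design.
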