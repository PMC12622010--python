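# gemcov — cell type-resolved gene–metabolite covariation analysis

`gemcov` maps covariation between a patient cohort's bulk metabolome and its
cell type-resolved transcriptome. The setting it targets: ~120 patients with
bulk LC-MS metabolite abundances (~1000 named metabolites), single-cell
RNA-seq summarized into per-cell-type pseudo-bulk expression (17 cell types,
2000 highly variable genes), and an ordinal disease-severity label per
patient (Kellgren–Lawrence grade 2/3/4, from an osteoarthritis cohort). The
package asks, per cell type: which genes covary with which metabolites,
which genes/metabolites are covariation *hubs*, which gene–metabolite pairs
share a metabolic pathway (a "high-confidence" map), which metabolites are
predictable from a cell type's transcriptome, and which molecular features
track disease severity.

## The statistics at the core

**Association map.** For metabolite *m*, patients are split at the 75th
quantile of abundance: Group 1 = {abundance ≥ Q₀.₇₅}, Group 2 = rest
(abundance values are noisy; the high/low split is robust). For each gene
*g* and cell type *c*, a pooled two-sample t-test compares pseudo-bulk
expression between the groups; the triple (g, m, c) is *associated* when
the nominal p ≤ 0.005 (BH-adjusted p-values are reported alongside, per
cell type).

**Hubs.** Per cell type, degree(entity) = number of associated partners.
Hub metabolites = top 50 of 1000 by degree; hub genes = top 100 of 2000
(the top 5%). Specificity score for cell type *i*:
`count(i) − (1/(C−1))·Σ_{j≠i} count(j)`; the top 10 positive scorers are
cell type-specific hubs. Pan-cell-type hubs are ranked by the geometric
mean of per-cell-type degree ranks (rank 1 = most associations). Hub
interconnection is summarized by the bipartite edge density between hub
genes and hub metabolites, with a permutation p-value from 200 random
non-hub sets of the same sizes; the number of cell types an entity is a hub
for is compared to a Binomial(17, 0.05) null.

**High-confidence map.** An associated pair (g, m, c) that is co-member of
a metabolic pathway P (gene sets from GMT, metabolite membership from a
two-column table) yields the quadruplet (m, g, c, P). The fraction of
quadruplets where higher enzyme expression accompanies *lower* metabolite
abundance is reported, plus frequency rankings along each axis and
hypergeometric over-representation of hub genes in pathway gene sets.

**Metabolite ↔ cell type attribution.** A random-forest classifier
predicts a metabolite's high/low group from one cell type's pseudo-bulk
transcriptome: 100 repeats of (stratified 70/30 split → within-train DE
gene selection at p ≤ 0.05 → CV-tuned random forest → balanced test
accuracy). A 95% CI around the mean accuracy decides the report (mean if
the CI reaches below 0.5, else the median of the top 20 accuracies). A
metabolite is linked to a cell type at reported accuracy ≥ 0.65, and is
"pan-cell-type" at ≥ 4 links. A proportion-only model (features = cell-type
composition) is the confounder baseline.

**Severity.** Per cell type, a random forest classifies KL-target vs rest
from that cell type's hub genes (30 repeats; the median-accuracy run's ROC
and AUROC are reported). Per metabolite, a one-sided continuity-corrected
two-proportion test asks whether high abundance is over-represented in a
KL grade. Transcriptome-predictable metabolites (confounder-filtered at
0.6) are intersected with severity-associated ones and scored by an
upper-tail hypergeometric test.

Because the cohort the design emulates is not distributable, the package
ships a first-class synthetic cohort generator (`gemcov.simulate`) with
planted associations, hubs, pathway co-memberships and severity signals,
plus ground-truth tables, so every stage is validated by parameter
recovery, type-I-error calibration and permutation-null calibration.

## Worked example

```python
from gemcov import AnalysisConfig, SimConfig, generate_cohort, evaluate_recovery
from gemcov.preprocess import preprocess_cohort
from gemcov.covariation import (build_association_map, compute_degrees,
                                select_hub_sets, density_permutation_pvalue)

sim = SimConfig(n_patients=119, n_celltypes=3, n_genes=300, n_metabolites=100,
                n_planted_pairs=25, effect_size=2.0,
                n_planted_hub_genes=1, n_planted_hub_metabolites=1,
                hub_fanout=40, seed=42)
cfg = AnalysisConfig(n_hvg_genes=300, n_hvg_metabolites=100, seed=42)

cohort, truth, gene_sets, met_sets = generate_cohort(sim)
pre = preprocess_cohort(cohort, cfg)
assoc = build_association_map(pre, cfg)
degrees = compute_degrees(assoc, cfg.assoc_alpha, gene_universe=pre.genes,
                          metabolite_universe=list(pre.metabolites.columns),
                          cell_types=pre.cell_types)
hubs = select_hub_sets(degrees, cfg)
report = evaluate_recovery(truth, assoc, hubs, cfg.assoc_alpha)
ct = truth.planted_hub_genes[0][1]
obs, p = density_permutation_pvalue(
    assoc, hubs["gene"][ct], hubs["metabolite"][ct], ct,
    cfg.n_density_perms, seed=cfg.seed, alpha=cfg.assoc_alpha,
    gene_pool=pre.genes, metabolite_pool=list(pre.metabolites.columns))

print(f"tested pairs:        {len(assoc)}")
print(f"significant (p<=0.005): {int((assoc['p'] <= 0.005).sum())}")
print(f"planted-pair TPR:    {report['tpr']:.2f}")
print(f"hub recovery:        genes {report['hub_gene_recovery']:.0%}, "
      f"metabolites {report['hub_metabolite_recovery']:.0%}")
print(f"hub density in {ct}: {obs:.3f} (permutation p = {p:.3f})")
```

Output:

```
tested pairs:        90000
significant (p<=0.005): 527
planted-pair TPR:    0.67
hub recovery:        genes 100%, metabolites 100%
hub density in celltype_00: 0.028 (permutation p = 0.000)
```

90,000 (cell type, gene, metabolite) triples are tested; 527 pass the
0.005 threshold (the 25 isolated planted pairs, most of the 80 hub-partner
pairs, plus ≈ 450 expected false positives at this nominal level — hub
statistics, not single pairs, are the unit of interpretation). The overall
planted-pair TPR is 0.67 rather than ≈ 1 because the 40 shifts planted on
each hub entity overlap on one gene/metabolite and act as extra variance
for one another; the hub entities themselves are nevertheless recovered in
the hub sets every time, and the hub–hub density (0.028 vs ≈ 0.005
background) is never exceeded by random non-hub sets.

## Command line

The same pipeline is available as subcommands:

```sh
gemcov simulate --seed 1 --out cohort/           # write a synthetic cohort
gemcov all --in cohort/ --out results/           # preprocess ... severity
gemcov associate --in cohort/ --out assoc/       # any single stage
```

`results/` contains `associations.tsv`, `hubs_*.tsv`, `density_test.tsv`,
`highconf.tsv`, `enrichment.tsv`, `predictions.tsv`, `links.tsv`,
`severity.tsv`, `met_kl.tsv`, ROC tables and a `summary.json` echoing the
effective configuration. Runs are byte-reproducible given (inputs, config,
seed).

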