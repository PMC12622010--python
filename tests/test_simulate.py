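"""Synthetic cohort generator: composition, planted structure, calibration,
cell-level consistency, recovery evaluation."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from gemcov.config import AnalysisConfig, SimConfig
from gemcov.covariation import build_association_map
from gemcov.preprocess import preprocess_cohort, pseudobulk_average
from gemcov.simulate import (evaluate_recovery, generate_cell_level,
                             generate_cohort, generate_null_cohort)


class TestCohortStructure:
    def test_proportions_rows_sum_to_one(self, toy_data):
        cohort, *_ = toy_data
        np.testing.assert_allclose(cohort.proportions.sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_rare_celltype_mean_proportion(self):
        """With the default 17-type composition, the rarest population
        (0.12% mean) is recovered within 3 standard errors."""
        sim = SimConfig(n_genes=20, n_metabolites=10, n_planted_pairs=0,
                        n_planted_hub_genes=0, n_planted_hub_metabolites=0,
                        n_kl_metabolites=0, seed=21)
        cohort, *_ = generate_cohort(sim)
        msc = cohort.proportions["MSC"]
        se = msc.std(ddof=1) / np.sqrt(len(msc))
        assert abs(msc.mean() - 0.0012) < 3 * se

    def test_metadata_grades_valid(self, toy_data):
        cohort, *_ = toy_data
        assert set(cohort.metadata["kl_grade"]) <= {2, 3, 4}

    def test_same_seed_reproduces_cohort(self, toy_sim):
        c1, *_ = generate_cohort(toy_sim)
        c2, *_ = generate_cohort(toy_sim)
        ct = c1.cell_types[0]
        np.testing.assert_array_equal(c1.pseudobulk[ct].to_numpy(),
                                      c2.pseudobulk[ct].to_numpy())
        np.testing.assert_array_equal(c1.metabolites.to_numpy(),
                                      c2.metabolites.to_numpy())

    def test_excessive_planting_is_an_error(self):
        with pytest.raises(ValueError):
            generate_cohort(SimConfig(n_genes=10, n_metabolites=10,
                                      n_celltypes=2, n_planted_pairs=50))


class TestTruthConsistency:
    def test_pathway_pairs_appear_in_annotations(self, toy_data):
        _, truth, gene_sets, met_sets = toy_data
        assert truth.planted_pathway_pairs
        for g, m, ct, pw in truth.planted_pathway_pairs:
            assert g in gene_sets[pw]
            assert m in met_sets[pw]

    def test_pathway_pairs_subset_of_planted_pairs(self, toy_data):
        _, truth, *_ = toy_data
        planted = {(g, m, ct) for g, m, ct, _ in truth.planted_pairs}
        for g, m, ct, _ in truth.planted_pathway_pairs:
            assert (g, m, ct) in planted

    def test_all_truth_ids_exist(self, toy_data):
        cohort, truth, *_ = toy_data
        genes, mets = set(cohort.genes), set(cohort.metabolites.columns)
        for g, m, ct, _ in truth.planted_pairs:
            assert g in genes and m in mets and ct in cohort.cell_types


class TestNullCalibration:
    def test_null_pvalues_uniform_across_seeds(self):
        """On null cohorts, association p-values pass a KS test against
        Uniform(0,1) in at least 8 of 10 seeds at level 0.01."""
        cfg = AnalysisConfig(n_hvg_genes=50, n_hvg_metabolites=20,
                            min_group=5)
        passed = 0
        for seed in range(10):
            sim = SimConfig(n_patients=60, n_celltypes=1, n_genes=50,
                            n_metabolites=20, seed=100 + seed)
            cohort = generate_null_cohort(sim)
            pre = preprocess_cohort(cohort, cfg)
            assoc = build_association_map(pre, cfg)
            ks = stats.kstest(assoc["p"].to_numpy(), "uniform")
            passed += ks.pvalue > 0.01
        assert passed >= 8

    def test_tpr_monotone_in_effect_size(self):
        """Planted-pair recovery is non-decreasing over a 3-point effect
        grid (within simulation noise)."""
        cfg = AnalysisConfig(n_hvg_genes=80, n_hvg_metabolites=30)
        tprs = []
        for effect in (0.3, 1.0, 2.5):
            sim = SimConfig(n_patients=119, n_celltypes=2, n_genes=80,
                            n_metabolites=30, n_planted_pairs=20,
                            effect_size=effect, n_planted_hub_genes=0,
                            n_planted_hub_metabolites=0,
                            n_kl_metabolites=0, seed=33)
            cohort, truth, *_ = generate_cohort(sim)
            pre = preprocess_cohort(cohort, cfg)
            assoc = build_association_map(pre, cfg)
            rep = evaluate_recovery(truth, assoc, None, cfg.assoc_alpha)
            tprs.append(rep["tpr"])
        assert tprs[0] <= tprs[1] + 0.1
        assert tprs[1] <= tprs[2] + 0.1
        assert tprs[2] > tprs[0]


class TestCellLevel:
    def test_zero_noise_even_counts_recovers_means_exactly(self):
        sim = SimConfig(n_patients=5, n_celltypes=3, n_genes=10,
                        n_metabolites=5, n_planted_pairs=2,
                        n_planted_hub_genes=0, n_planted_hub_metabolites=0,
                        n_kl_metabolites=0, seed=40)
        cells, ann = generate_cell_level(sim, cells_per_patient=3,
                                         cell_noise_sd=0.0, even_counts=True)
        pb = pseudobulk_average(cells, ann["cell_type"].to_numpy(),
                                ann["patient_id"].to_numpy())
        # with one cell per (patient, type) and zero noise, the pseudo-bulk
        # equals the generating mean, which is 0 except planted shifts
        _, truth, *_ = generate_cohort(sim)
        planted = {(g, ct) for g, _, ct, _ in truth.planted_pairs}
        for ct, mat in pb.items():
            for g in mat.columns:
                if (g, ct) not in planted:
                    np.testing.assert_allclose(mat[g].to_numpy(), 0.0)

    def test_many_cells_recover_means_within_standard_error(self):
        sim = SimConfig(n_patients=4, n_celltypes=2, n_genes=8,
                        n_metabolites=5, n_planted_pairs=0,
                        n_planted_hub_genes=0, n_planted_hub_metabolites=0,
                        n_kl_metabolites=0, noise_sd=1.0, seed=41)
        cells, ann = generate_cell_level(sim, cells_per_patient=500)
        pb = pseudobulk_average(cells, ann["cell_type"].to_numpy(),
                                ann["patient_id"].to_numpy())
        for ct, mat in pb.items():
            counts = (ann["cell_type"] == ct).groupby(
                ann["patient_id"]).sum()
            for p in mat.index:
                if counts.get(p, 0) < 10:
                    continue
                bias = np.abs(mat.loc[p].to_numpy()).mean()
                assert bias < 3.0 / np.sqrt(counts[p])

    def test_sparse_coverage_gives_missing_entries(self):
        sim = SimConfig(n_patients=6, n_celltypes=4, n_genes=5,
                        n_metabolites=5, n_planted_pairs=0,
                        n_planted_hub_genes=0, n_planted_hub_metabolites=0,
                        n_kl_metabolites=0, seed=42)
        cells, ann = generate_cell_level(sim, cells_per_patient=2)
        pb = pseudobulk_average(cells, ann["cell_type"].to_numpy(),
                                ann["patient_id"].to_numpy())
        n_missing = sum(int(mat.isna().any(axis=1).sum())
                        for mat in pb.values())
        assert n_missing > 0


class TestEvaluateRecovery:
    def test_zero_planted_reports_na_tpr(self, fast_config):
        sim = SimConfig(n_patients=60, n_celltypes=1, n_genes=30,
                        n_metabolites=10, n_planted_pairs=0,
                        n_planted_hub_genes=0, n_planted_hub_metabolites=0,
                        n_kl_metabolites=0, seed=50)
        cohort, truth, *_ = generate_cohort(sim)
        cfg = dataclasses.replace(fast_config, n_hvg_genes=30,
                                  n_hvg_metabolites=10)
        pre = preprocess_cohort(cohort, cfg)
        assoc = build_association_map(pre, cfg)
        rep = evaluate_recovery(truth, assoc, None, cfg.assoc_alpha)
        assert rep["tpr"] is None
        assert 0.0 <= rep["fdp"] <= 1.0

    def test_id_mismatch_is_fatal(self, toy_data, toy_assoc, fast_config):
        import copy
        _, truth, *_ = toy_data
        wrong = copy.deepcopy(truth)
        wrong.planted_pairs[0] = ("no_such_gene", "no_such_met",
                                  "no_such_ct", 2.0)
        with pytest.raises(ValueError):
            evaluate_recovery(wrong, toy_assoc, None, fast_config.assoc_alpha)
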