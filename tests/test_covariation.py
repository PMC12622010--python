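"""Association mapping and hub statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gemcov.covariation import (DegreeTable, adjust_bh, bipartite_density,
                                build_association_map, compute_degrees,
                                density_permutation_pvalue,
                                discretize_metabolite, hub_sharing_counts,
                                hub_sharing_null_pmf, pan_celltype_ranks,
                                select_hub_sets, specificity_scores,
                                two_sample_t)


def _assoc(rows):
    """Helper: association frame from (cell_type, gene, metabolite, p) rows."""
    df = pd.DataFrame(rows, columns=["cell_type", "gene", "metabolite", "p"])
    df["t"] = 1.0
    df["p_adj"] = df["p"]
    df["direction"] = 1
    df["n1"] = 5
    df["n2"] = 15
    return df


class TestDiscretize:
    def test_interpolated_threshold_and_groups(self):
        s = pd.Series(np.arange(1.0, 9.0), index=[f"p{i}" for i in range(8)])
        g = discretize_metabolite(s, q=0.75, min_group=2)
        assert g.threshold_value == pytest.approx(6.25)
        assert set(g.group1) == {"p6", "p7"}
        assert len(g.group2) == 6

    def test_119_distinct_values_gives_30_high(self):
        rng = np.random.default_rng(0)
        s = pd.Series(rng.permutation(np.arange(119.0)))
        g = discretize_metabolite(s, q=0.75)
        assert len(g.group1) == 30

    def test_constant_vector_skipped(self):
        s = pd.Series(np.ones(20))
        assert discretize_metabolite(s, q=0.75) is None

    def test_min_group_guard(self):
        # 8 values: Group 1 has 2 < min_group=5
        s = pd.Series(np.arange(8.0))
        assert discretize_metabolite(s, q=0.75, min_group=5) is None


class TestTwoSampleT:
    def test_hand_computed_pooled_t(self):
        # pooled s^2 = 1, se = sqrt(2/3), t = -3/0.8165 = -3.674, df = 4
        t, p, d = two_sample_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742346, abs=1e-6)
        assert p == pytest.approx(0.0213116, abs=1e-6)
        assert d == -1

    def test_identical_groups(self):
        t, p, d = two_sample_t([1, 2, 3], [1, 2, 3])
        assert (t, p, d) == (0.0, 1.0, 0)

    def test_zero_variance_degenerate(self):
        t, p, d = two_sample_t([2, 2, 2], [2, 2, 2])
        assert (t, p, d) == (0.0, 1.0, 0)

    def test_undersized_group_is_an_error(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1, 2, 3])

    def test_matches_scipy_on_random_data(self):
        from scipy import stats
        rng = np.random.default_rng(5)
        for _ in range(20):
            x1, x2 = rng.normal(size=12), rng.normal(1, 2, size=20)
            t, p, _ = two_sample_t(x1, x2)
            ref = stats.ttest_ind(x1, x2, equal_var=True)
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)


class TestAdjustBH:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_one(self):
        np.testing.assert_allclose(adjust_bh([1.0]), [1.0])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_brute_force_definition(self, pvals):
        p = np.asarray(pvals)
        got = adjust_bh(p)
        n = len(p)
        order = np.argsort(p, kind="stable")
        expected = np.empty(n)
        running_min = 1.0
        for rank_from_top in range(n, 0, -1):
            i = order[rank_from_top - 1]
            running_min = min(running_min, p[i] * n / rank_from_top)
            expected[i] = running_min
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestDegreesAndHubs:
    def test_empty_map_all_zero(self):
        deg = compute_degrees(_assoc([]), 0.005,
                              gene_universe=["g1"], metabolite_universe=["m1"],
                              cell_types=["T"])
        assert (deg.genes.to_numpy() == 0).all()

    def test_hand_tally(self):
        rows = [("T", "g1", "m1", 0.001), ("T", "g1", "m2", 0.001),
                ("T", "g2", "m1", 0.5), ("B", "g1", "m1", 0.001)]
        deg = compute_degrees(_assoc(rows), 0.005)
        assert deg.genes.loc["g1", "T"] == 2
        assert deg.genes.loc["g2", "T"] == 0
        assert deg.metabolites.loc["m1", "B"] == 1

    def test_random_map_matches_groupby_oracle(self):
        rng = np.random.default_rng(6)
        rows = [(rng.choice(["T", "B"]), f"g{rng.integers(5)}",
                 f"m{rng.integers(5)}", rng.random())
                for _ in range(300)]
        df = _assoc(rows)
        deg = compute_degrees(df, 0.3)
        sig = df[df["p"] <= 0.3]
        for g in deg.genes.index:
            for ct in deg.genes.columns:
                expected = ((sig["gene"] == g) & (sig["cell_type"] == ct)).sum()
                assert deg.genes.loc[g, ct] == expected

    def test_hub_set_sizes_and_tie_rule(self, fast_config):
        counts = pd.DataFrame(
            0, index=[f"m{i}" for i in range(20)], columns=["T"])
        deg = DegreeTable(
            genes=pd.DataFrame(0, index=[f"g{i}" for i in range(20)],
                               columns=["T"]),
            metabolites=counts)
        hubs = select_hub_sets(deg, fast_config)
        assert len(hubs["metabolite"]["T"]) == fast_config.n_hub_metabolites
        # all-equal degrees: lexicographically first ids
        assert hubs["metabolite"]["T"] == sorted(counts.index)[
            :fast_config.n_hub_metabolites]

    def test_too_few_entities_is_an_error(self, fast_config):
        deg = DegreeTable(
            genes=pd.DataFrame(0, index=["g1"], columns=["T"]),
            metabolites=pd.DataFrame(0, index=["m1"], columns=["T"]))
        with pytest.raises(ValueError):
            select_hub_sets(deg, fast_config)


class TestSpecificity:
    def _deg(self, counts: dict) -> DegreeTable:
        g = pd.DataFrame(counts).T
        return DegreeTable(genes=g, metabolites=g.copy())

    def test_formula(self):
        deg = self._deg({"g1": {"A": 10, "B": 1, "C": 1}})
        scores, top = specificity_scores(deg, "gene", n_top=1)
        assert scores.loc["g1", "A"] == pytest.approx(9.0)
        assert top["A"] == ["g1"]

    def test_equal_counts_score_zero(self):
        deg = self._deg({"g1": {"A": 4, "B": 4, "C": 4}})
        scores, _ = specificity_scores(deg, "gene")
        assert (scores.loc["g1"] == 0).all()

    def test_shift_invariance(self):
        base = {"g1": {"A": 10, "B": 2, "C": 5},
                "g2": {"A": 1, "B": 7, "C": 3}}
        shifted = {g: {ct: c + 13 for ct, c in row.items()}
                   for g, row in base.items()}
        s1, _ = specificity_scores(self._deg(base), "gene")
        s2, _ = specificity_scores(self._deg(shifted), "gene")
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy())


class TestPanRanks:
    def _deg(self, counts: dict) -> DegreeTable:
        g = pd.DataFrame(counts).T
        return DegreeTable(genes=g, metabolites=g.copy())

    def test_top_everywhere_is_combined_rank_one(self):
        deg = self._deg({"g1": {"A": 10, "B": 10}, "g2": {"A": 1, "B": 2},
                         "g3": {"A": 2, "B": 1}})
        out = pan_celltype_ranks(deg, "gene")
        assert out.iloc[0]["entity"] == "g1"
        assert out.iloc[0]["geom_mean_rank"] == pytest.approx(1.0)

    def test_geometric_mean_tie_broken_by_min_rank(self):
        # A ranks (1, 4), B ranks (2, 2): both gm = 2, A wins on min rank
        deg = self._deg({"A": {"x": 40, "y": 10}, "B": {"x": 30, "y": 30},
                         "C": {"x": 20, "y": 40}, "D": {"x": 10, "y": 20}})
        out = pan_celltype_ranks(deg, "gene")
        gm = dict(zip(out["entity"], out["geom_mean_rank"]))
        assert gm["A"] == pytest.approx(2.0)
        assert gm["B"] == pytest.approx(2.0)
        assert list(out["entity"]).index("A") < list(out["entity"]).index("B")

    def test_celltype_axis_permutation_invariant(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(rng.integers(0, 50, size=(12, 4)),
                              index=[f"g{i}" for i in range(12)],
                              columns=list("ABCD"))
        d1 = DegreeTable(genes=counts, metabolites=counts)
        d2 = DegreeTable(genes=counts[list("DCBA")], metabolites=counts)
        out1 = pan_celltype_ranks(d1, "gene")
        out2 = pan_celltype_ranks(d2, "gene")
        assert list(out1["entity"]) == list(out2["entity"])


class TestDensity:
    def test_complete_bipartite(self):
        rows = [("T", g, m, 0.001) for g in ["g1", "g2"] for m in ["m1", "m2"]]
        assert bipartite_density(_assoc(rows), ["g1", "g2"], ["m1", "m2"],
                                 "T", 0.005) == 1.0

    def test_no_edges(self):
        rows = [("T", "g1", "m1", 0.9)]
        assert bipartite_density(_assoc(rows), ["g1"], ["m1"], "T",
                                 0.005) == 0.0

    def test_half_density(self):
        rows = [("T", "g1", "m1", 0.001), ("T", "g2", "m2", 0.001)]
        assert bipartite_density(_assoc(rows), ["g1", "g2"], ["m1", "m2"],
                                 "T", 0.005) == 0.5

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            bipartite_density(_assoc([]), [], ["m1"], "T", 0.005)

    def test_observed_density_one_gives_p_zero(self):
        genes = [f"g{i}" for i in range(6)]
        mets = [f"m{i}" for i in range(4)]
        rows = [("T", "g0", "m0", 0.001), ("T", "g0", "m1", 0.001),
                ("T", "g1", "m0", 0.001), ("T", "g1", "m1", 0.001)]
        rows += [("T", g, m, 0.9) for g in genes[2:] for m in mets[2:]]
        obs, p = density_permutation_pvalue(
            _assoc(rows), ["g0", "g1"], ["m0", "m1"], "T", n_perm=50,
            seed=1, alpha=0.005, gene_pool=genes, metabolite_pool=mets)
        assert obs == 1.0
        assert p == 0.0

    def test_insufficient_non_hubs_is_an_error(self):
        with pytest.raises(ValueError):
            density_permutation_pvalue(
                _assoc([("T", "g1", "m1", 0.001)]), ["g1"], ["m1"], "T",
                n_perm=10, seed=1, alpha=0.005,
                gene_pool=["g1"], metabolite_pool=["m1", "m2"])


class TestHubSharing:
    def test_counts(self):
        counts = hub_sharing_counts({"A": ["g1", "g2"], "B": ["g1"]})
        assert counts["g1"] == 2
        assert counts["g2"] == 1

    def test_null_pmf_values(self):
        pmf = hub_sharing_null_pmf(17, 0.05)
        assert pmf[0] == pytest.approx(0.95 ** 17)
        assert pmf.sum() == pytest.approx(1.0)

    def test_n_one_is_bernoulli(self):
        np.testing.assert_allclose(hub_sharing_null_pmf(1, 0.3), [0.7, 0.3])


class TestAssociationMap:
    def test_toy_map_has_one_record_per_triple(self, toy_pre, fast_config):
        assoc = build_association_map(toy_pre, fast_config)
        n_ct = len(toy_pre.cell_types)
        n_g = len(toy_pre.genes)
        n_m = toy_pre.metabolites.shape[1]
        assert len(assoc) == n_ct * n_g * n_m
        assert not assoc.duplicated(["cell_type", "gene", "metabolite"]).any()
        assert (assoc["p_adj"] >= assoc["p"] - 1e-15).all()
        assert assoc["p"].between(0, 1).all()

    def test_entity_relabeling_equivariance(self, toy_assoc, fast_config):
        """Hub selection commutes with renaming entities."""
        mapping = {g: f"X{g}" for g in toy_assoc["gene"].unique()}
        renamed = toy_assoc.assign(gene=toy_assoc["gene"].map(mapping))
        d1 = compute_degrees(toy_assoc, fast_config.assoc_alpha)
        d2 = compute_degrees(renamed, fast_config.assoc_alpha)
        h1 = select_hub_sets(d1, fast_config)
        h2 = select_hub_sets(d2, fast_config)
        for ct in h1["gene"]:
            assert [mapping[g] for g in h1["gene"][ct]] == h2["gene"][ct]
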