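"""Identity gene sets, trajectory archetypes, element linking and memory counts."""

import numpy as np
import pandas as pd
import pytest

from rejuvkit import memory as mem
from rejuvkit import synthetic as syn
from rejuvkit.errors import ConfigurationError, DataError


class TestGeneSets:
    @pytest.fixture()
    def fib_ipsc(self, rng):
        genes = ["fib_gene", "ipsc_gene", "shared", "small_fc"]
        fib = pd.DataFrame(
            np.column_stack([
                rng.normal(8.0, 0.1, 6),   # high in fibroblasts
                rng.normal(2.0, 0.1, 6),   # low in fibroblasts
                rng.normal(5.0, 0.1, 6),
                rng.normal(5.5, 0.1, 6),
            ]), columns=genes)
        ipsc = pd.DataFrame(
            np.column_stack([
                rng.normal(2.0, 0.1, 6),
                rng.normal(8.0, 0.1, 6),
                rng.normal(5.0, 0.1, 6),
                rng.normal(5.0, 0.1, 6),   # |lfc| = 0.5 < 2
            ]), columns=genes)
        return fib, ipsc

    def test_specific_sets_are_disjoint_and_correct(self, fib_ipsc):
        fib, ipsc = fib_ipsc
        fset, iset = mem.define_specific_gene_sets(fib, ipsc)
        assert "fib_gene" in fset.index and "fib_gene" not in iset.index
        assert "ipsc_gene" in iset.index and "ipsc_gene" not in fset.index
        assert "shared" not in fset.index and "shared" not in iset.index
        assert "small_fc" not in fset.index

    def test_ranksum_variant_agrees_on_strong_signal(self, fib_ipsc):
        fib, ipsc = fib_ipsc
        fset, iset = mem.define_specific_gene_sets(fib, ipsc, test="ranksum")
        assert "fib_gene" in fset.index and "ipsc_gene" in iset.index

    def test_zero_variance_distinct_means_called(self):
        fib = pd.DataFrame({"g": np.full(4, 9.0)})
        ipsc = pd.DataFrame({"g": np.full(4, 2.0)})
        fset, _ = mem.define_specific_gene_sets(fib, ipsc)
        assert "g" in fset.index

    def test_single_sample_group_rejected(self):
        fib = pd.DataFrame({"g": [5.0]})
        ipsc = pd.DataFrame({"g": [5.0, 5.1]})
        with pytest.raises(DataError):
            mem.define_specific_gene_sets(fib, ipsc)

    def test_unknown_test_rejected(self, fib_ipsc):
        fib, ipsc = fib_ipsc
        with pytest.raises(ConfigurationError):
            mem.define_specific_gene_sets(fib, ipsc, test="anova")


class TestTrajectoryClustering:
    @pytest.fixture()
    def staged_expr(self, rng):
        stages = ["start", "mid", "end"]
        sample_stages = pd.Series(
            np.repeat(stages, 5),
            index=[f"s{i}" for i in range(15)])
        base = 6.0
        patterns = {
            "down": [0.0, -4.0, 0.0],
            "up": [0.0, 3.0, 0.0],
            "flat": [0.0, 0.0, 0.0],
        }
        cols = {}
        truth = {}
        for kind, offsets in patterns.items():
            for j in range(20):
                per_stage = np.repeat(base + np.array(offsets), 5)
                cols[f"{kind}{j}"] = per_stage + rng.normal(0, 0.2, 15)
                truth[f"{kind}{j}"] = {
                    "down": "temporarily_down", "up": "temporarily_up",
                    "flat": "persistent"}[kind]
        expr = pd.DataFrame(cols, index=sample_stages.index)
        return expr, sample_stages, pd.Series(truth)

    def test_archetypes_recovered(self, staged_expr):
        expr, sample_stages, truth = staged_expr
        res = mem.cluster_gene_trajectories(expr, sample_stages,
                                            ["start", "mid", "end"], k=3)
        assert (res["archetype"].reindex(truth.index) == truth).all()

    def test_gene_subset_respected(self, staged_expr):
        expr, sample_stages, truth = staged_expr
        subset = truth.index[:10]
        res = mem.cluster_gene_trajectories(expr, sample_stages,
                                            ["start", "mid", "end"],
                                            genes=subset, k=2)
        assert set(res.index) == set(subset)

    def test_too_few_stages_rejected(self, staged_expr):
        expr, sample_stages, _ = staged_expr
        with pytest.raises(DataError):
            mem.cluster_gene_trajectories(expr, sample_stages, ["start", "end"])

    def test_bad_k_rejected(self, staged_expr):
        expr, sample_stages, _ = staged_expr
        with pytest.raises(ConfigurationError):
            mem.cluster_gene_trajectories(expr, sample_stages,
                                          ["start", "mid", "end"], k=0)


class TestElementLinking:
    def test_promoter_window_enforced(self, tiny_tss):
        elements = pd.DataFrame({
            "chrom": ["chr1", "chr1"],
            "start": [400, 2_600],
            "end": [800, 3_000],
            "class": ["promoter", "promoter"],
        }, index=["near", "far"])
        links, unlinked = mem.link_elements_to_genes(elements, tiny_tss)
        assert "near" in links.index and links.loc["near", "gene"] == "geneA"
        assert "far" in unlinked  # midpoint 2800 is 1800 bp from the TSS

    def test_enhancer_window_is_a_megabase(self, tiny_tss):
        elements = pd.DataFrame({
            "chrom": ["chr1", "chr1"],
            "start": [900_000, 1_200_000],
            "end": [900_400, 1_200_400],
            "class": ["enhancer", "enhancer"],
        }, index=["in_window", "out_window"])
        links, unlinked = mem.link_elements_to_genes(elements, tiny_tss)
        assert "in_window" in links.index
        assert "out_window" in unlinked

    def test_unknown_class_rejected(self, tiny_tss):
        elements = pd.DataFrame({
            "chrom": ["chr1"], "start": [0], "end": [10], "class": ["silencer"],
        }, index=["e1"])
        with pytest.raises(ConfigurationError):
            mem.link_elements_to_genes(elements, tiny_tss)


class TestElementMethylation:
    @pytest.fixture()
    def element_data(self):
        cpgs = ["c1", "c2", "c3", "c4"]
        locs = pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "pos": [100, 150, 5_000, 100],
        }, index=pd.Index(cpgs, name="cpg_id"))
        elements = pd.DataFrame({
            "chrom": ["chr1", "chr1"],
            "start": [50, 4_900],
            "end": [200, 5_100],
            "class": ["promoter", "enhancer"],
        }, index=["e1", "e2"])
        betas = pd.DataFrame(
            [[0.1, 0.2, 0.8, 0.5],
             [0.1, 0.2, 0.8, 0.5],
             [0.5, 0.6, 0.9, 0.5],
             [0.5, 0.6, 0.9, 0.5]],
            index=["a1", "a2", "b1", "b2"], columns=cpgs)
        groups = pd.Series(["ga", "ga", "gb", "gb"], index=betas.index)
        return betas, locs, elements, groups

    def test_group_means_per_element(self, element_data):
        betas, locs, elements, groups = element_data
        summ = mem.summarize_element_methylation(betas, locs, elements, groups)
        assert summ.loc["e1", "ga"] == pytest.approx(0.15)
        assert summ.loc["e1", "gb"] == pytest.approx(0.55)
        assert summ.loc["e2", "ga"] == pytest.approx(0.8)
        assert summ.loc["e1", "n_cpgs"] == 2

    def test_hypermethylated_count(self, element_data):
        betas, locs, elements, groups = element_data
        summ = mem.summarize_element_methylation(betas, locs, elements, groups)
        n_hyper, n_total = mem.count_hypermethylated(summ, "ga", "gb",
                                                     gain_min=0.2)
        assert (n_hyper, n_total) == (1, 2)

    def test_missing_group_column_rejected(self, element_data):
        betas, locs, elements, groups = element_data
        summ = mem.summarize_element_methylation(betas, locs, elements, groups)
        with pytest.raises(DataError):
            mem.count_hypermethylated(summ, "ga", "nope")


class TestClassifyEnhancers:
    def test_lost_activity_detected(self):
        elements = pd.DataFrame({
            "chrom": ["chr1"] * 3,
            "start": [0, 100, 200], "end": [50, 150, 250],
            "class": ["enhancer", "enhancer", "promoter"],
            "activity_fibroblast": ["active", "active", "active"],
            "activity_ipsc": ["repressed", "active", "repressed"],
        }, index=["lost", "kept", "prom"])
        res = mem.classify_fibroblast_enhancers(elements)
        assert "lost" in res.index
        assert "kept" not in res.index
        assert "prom" not in res.index  # promoters are out of scope here

    def test_missing_activity_column_rejected(self):
        elements = pd.DataFrame({
            "chrom": ["chr1"], "start": [0], "end": [10],
            "class": ["enhancer"], "activity_fibroblast": ["active"],
        }, index=["e1"])
        with pytest.raises(DataError):
            mem.classify_fibroblast_enhancers(elements)


class TestEndToEndMemorySignal:
    def test_transient_arm_retains_fibroblast_methylation(self):
        _, _, gt = syn.simulate_aging_expression(
            syn.ExpressionSpec(n_genes=60, n_aging_genes=20, seed=7))
        els = syn.simulate_regulatory_elements(gt["gene_params"], seed=3)
        betas, locs, groups = syn.simulate_element_methylation(els, seed=4)
        summ = mem.summarize_element_methylation(
            betas, locs, els, groups["group"])
        lost = mem.classify_fibroblast_enhancers(els)
        lost_idx = summ.index.intersection(lost.index)
        n_ipsc, n_tot = mem.count_hypermethylated(
            summ.loc[lost_idx], "fibroblast", "ipsc")
        n_trans, _ = mem.count_hypermethylated(
            summ.loc[lost_idx], "fibroblast", "transient")
        assert n_ipsc > 0.8 * n_tot
        assert n_trans < 0.1 * n_tot
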