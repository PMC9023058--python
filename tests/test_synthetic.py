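"""Synthetic-data generators: determinism, planted signal, physical validity."""

import numpy as np
import pandas as pd
import pytest

from rejuvkit import synthetic as syn
from rejuvkit.errors import ConfigurationError


class TestSpecs:
    def test_invalid_age_range_rejected(self):
        with pytest.raises(ConfigurationError):
            syn.CohortSpec(age_range=(50.0, 10.0))

    def test_more_aging_cpgs_than_cpgs_rejected(self):
        with pytest.raises(ConfigurationError):
            syn.CohortSpec(n_cpgs=10, n_aging_cpgs=20)

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigurationError):
            syn.CohortSpec(noise_sd=-0.1)

    def test_archetype_props_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            syn.CourseSpec(archetype_props=(0.5, 0.5, 0.5))


class TestMethylationCohort:
    def test_betas_in_unit_interval(self, small_cohort):
        _, betas, _, _ = small_cohort
        vals = betas.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_deterministic_for_same_seed(self):
        spec = syn.CohortSpec(n_samples=20, n_cpgs=50, n_aging_cpgs=10, seed=5)
        b1, s1, _ = syn.simulate_aging_methylation(spec)
        b2, s2, _ = syn.simulate_aging_methylation(spec)
        pd.testing.assert_frame_equal(b1, b2)
        pd.testing.assert_frame_equal(s1, s2)

    def test_different_seed_changes_data(self):
        b1, _, _ = syn.simulate_aging_methylation(syn.CohortSpec(seed=5, n_samples=20))
        b2, _, _ = syn.simulate_aging_methylation(syn.CohortSpec(seed=6, n_samples=20))
        assert not b1.equals(b2)

    def test_planted_slope_count(self, small_cohort):
        spec, _, _, gt = small_cohort
        n_aging = (gt["cpg_params"]["slope"] != 0).sum()
        assert n_aging == spec.n_aging_cpgs

    def test_noiseless_values_follow_linear_model(self, small_cohort):
        _, betas, samples, gt = small_cohort
        params = gt["cpg_params"]
        cg = params.index[params["slope"] != 0][0]
        expected = params.loc[cg, "baseline"] + params.loc[cg, "slope"] * samples["age"]
        assert np.allclose(betas[cg], expected, atol=1e-12)

    def test_slope_recoverable_by_regression(self, small_cohort):
        _, betas, samples, gt = small_cohort
        params = gt["cpg_params"]
        cg = params.index[params["slope"] != 0][5]
        slope = np.polyfit(samples["age"], betas[cg], 1)[0]
        assert slope == pytest.approx(params.loc[cg, "slope"], abs=1e-10)

    def test_explicit_ages_respected(self):
        ages = np.array([5.0, 30.0, 70.0])
        betas, samples, _ = syn.simulate_aging_methylation(
            syn.CohortSpec(n_samples=3, n_cpgs=20, n_aging_cpgs=5), ages=ages
        )
        assert np.array_equal(samples["age"].to_numpy(), ages)


class TestExpressionCohort:
    def test_planted_gene_kinds(self, small_expression):
        spec, _, _, gt = small_expression
        kinds = gt["gene_params"]["kind"].value_counts()
        assert kinds.get("linear", 0) + kinds.get("ramp", 0) == spec.n_aging_genes

    def test_null_genes_flat_in_age(self):
        spec = syn.ExpressionSpec(n_genes=50, n_aging_genes=10, noise_sd=0.0, seed=3)
        expr, samples, gt = syn.simulate_aging_expression(spec)
        null_gene = gt["gene_params"].index[gt["gene_params"]["kind"] == "null"][0]
        assert expr[null_gene].std() == pytest.approx(0.0, abs=1e-12)

    def test_ramp_genes_switch_between_plateaus(self):
        spec = syn.ExpressionSpec(n_genes=60, n_aging_genes=30, noise_sd=0.0, seed=4)
        expr, samples, gt = syn.simulate_aging_expression(
            spec, ages=np.linspace(0, 94, 200)
        )
        params = gt["gene_params"]
        gene = params.index[params["kind"] == "ramp"][0]
        onset = params.loc[gene, "onset"]
        duration = params.loc[gene, "duration"]
        before = expr.loc[samples["age"] < onset - 1, gene]
        after = expr.loc[samples["age"] > onset + duration + 1, gene]
        if len(before) > 1 and len(after) > 1:
            assert before.std() == pytest.approx(0.0, abs=1e-9)
            assert after.std() == pytest.approx(0.0, abs=1e-9)
            assert abs(after.mean() - before.mean()) == pytest.approx(
                abs(params.loc[gene, "effect"]), abs=1e-9
            )

    def test_effect_40y_zero_for_null_genes(self, small_expression):
        _, _, _, gt = small_expression
        params = gt["gene_params"]
        nulls = params.index[params["kind"] == "null"]
        assert (gt["effect_40y"].loc[nulls] == 0).all()


class TestArchetypeAllocation:
    def test_counts_follow_largest_remainder(self):
        labels = syn.allocate_archetypes(1000, (0.67, 0.23, 0.10))
        counts = labels.value_counts()
        assert counts["temporarily_down"] == 670
        assert counts["temporarily_up"] == 230
        assert counts["persistent"] == 100

    def test_total_preserved_with_awkward_fractions(self):
        labels = syn.allocate_archetypes(7, (1 / 3, 1 / 3, 1 / 3))
        assert len(labels) == 7


@pytest.fixture(scope="module")
def course_data():
    cohort = syn.CohortSpec(n_samples=30, n_cpgs=100, n_aging_cpgs=30,
                            noise_sd=0.0, seed=11)
    espec = syn.ExpressionSpec(n_genes=80, n_aging_genes=30, noise_sd=0.0, seed=12)
    course = syn.CourseSpec(n_donors=3, seed=13)
    return cohort, espec, course, syn.simulate_reprogramming_course(cohort, espec, course)


class TestReprogrammingCourse:
    def test_sample_table_shape(self, course_data):
        cohort, espec, course, (betas, expr, samples, gt) = course_data
        n_expected = len(course.groups) * course.n_donors * len(course.timepoints)
        assert len(samples) == n_expected
        assert set(samples["group"]) == set(course.groups)

    def test_rejuvenation_only_after_baseline(self, course_data):
        _, _, _, (_, _, samples, _) = course_data
        base = samples[samples["timepoint_index"] == 0]
        assert (base["rejuvenation_applied"] == 0).all()
        later = samples[(samples["timepoint_index"] > 0) & (samples["group"] == "transient")]
        assert (later["rejuvenation_applied"] == 30.0).all()

    def test_effective_age_is_age_minus_rejuvenation(self, course_data):
        _, _, _, (_, _, samples, _) = course_data
        expected = samples["age"] - samples["rejuvenation_applied"]
        assert np.allclose(samples["effective_age"], expected)

    def test_negative_control_unchanged_across_timepoints(self, course_data):
        _, _, _, (betas, _, samples, _) = course_data
        ctrl = samples[samples["group"] == "negative_control"]
        donor = ctrl["donor"].iloc[0]
        rows = ctrl[ctrl["donor"] == donor]
        vals = betas.loc[rows.index]
        assert np.allclose(vals.iloc[0], vals.iloc[-1], atol=1e-12)

    def test_treated_cpgs_shift_by_slope_times_delta(self, course_data):
        cohort, _, course, (betas, _, samples, gt) = course_data
        params = gt["cpg_params"]
        cg = params.index[params["slope"] != 0][0]
        slope = params.loc[cg, "slope"]
        tr = samples[samples["group"] == "transient"]
        donor = tr["donor"].iloc[0]
        s0 = tr[(tr["donor"] == donor) & (tr["timepoint_index"] == 0)].index[0]
        s1 = tr[(tr["donor"] == donor) & (tr["timepoint_index"] == 2)].index[0]
        shift = betas.loc[s1, cg] - betas.loc[s0, cg]
        assert shift == pytest.approx(-30.0 * slope, abs=1e-10)

    def test_excessive_rejuvenation_clamped_with_warning(self):
        cohort = syn.CohortSpec(n_samples=10, n_cpgs=40, n_aging_cpgs=10, seed=1)
        espec = syn.ExpressionSpec(n_genes=40, n_aging_genes=10, seed=2)
        course = syn.CourseSpec(
            n_donors=2, seed=3, donor_age_range=(30.0, 35.0),
            groups={"negative_control": 0.0, "over": 80.0},
        )
        with pytest.warns(UserWarning):
            _, _, samples, _ = syn.simulate_reprogramming_course(cohort, espec, course)
        assert samples["effective_age"].min() >= 0.0

    def test_identity_genes_recover_in_transient_arm(self, course_data):
        _, espec, course, (_, expr, samples, gt) = course_data
        labels = gt["identity_labels"]
        gene = labels.index[labels == "temporarily_down"][0]
        tr = samples[samples["group"] == "transient"]
        start = expr.loc[tr.index[tr["timepoint_index"] == 0], gene].mean()
        mid = expr.loc[tr.index[tr["timepoint_index"] == 1], gene].mean()
        end = expr.loc[tr.index[tr["timepoint_index"] == 2], gene].mean()
        assert mid < start - 1.0
        assert abs(end - start) < 0.5

    def test_feature_parameters_shared_with_reference_cohort(self, course_data):
        cohort, espec, _, (_, _, _, gt) = course_data
        _, _, ref_gt = syn.simulate_aging_methylation(cohort)
        pd.testing.assert_frame_equal(gt["cpg_params"], ref_gt["cpg_params"])


@pytest.fixture(scope="module")
def elements():
    _, _, gt = syn.simulate_aging_expression(
        syn.ExpressionSpec(n_genes=40, n_aging_genes=10, seed=7))
    return gt["gene_params"], syn.simulate_regulatory_elements(gt["gene_params"], seed=3)


class TestRegulatoryElements:
    def test_one_promoter_and_enhancer_per_gene(self, elements):
        gene_params, els = elements
        assert (els["class"] == "promoter").sum() == len(gene_params)
        assert (els["class"] == "enhancer").sum() == len(gene_params)

    def test_promoters_within_kilobase_of_tss(self, elements):
        gene_params, els = elements
        prom = els[els["class"] == "promoter"]
        for eid, row in prom.head(10).iterrows():
            gene = eid.split("_")[1]
            tss = gene_params.loc[gene, "tss"]
            mid = 0.5 * (row["start"] + row["end"])
            assert abs(mid - tss) <= 1000

    def test_element_methylation_gains_in_ipsc(self, elements):
        _, els = elements
        betas, locs, groups = syn.simulate_element_methylation(els, seed=4)
        lost = els.index[(els["activity_fibroblast"] == "active")
                         & (els["activity_ipsc"] != "active")
                         & (els["class"] == "enhancer")]
        assert len(lost) > 0
        eid = lost[0]
        cols = [c for c in betas.columns if c.startswith(f"enh_{eid.split('_')[1]}_")]
        fib = betas.loc[groups.index[groups["group"] == "fibroblast"], cols].mean().mean()
        ipsc = betas.loc[groups.index[groups["group"] == "ipsc"], cols].mean().mean()
        assert ipsc > fib + 0.2


class TestWoundSeries:
    def test_noiseless_edge_positions_match_ground_truth(self):
        series, gt = syn.simulate_wound_series(speed=5.0, noise=0.0, seed=0)
        assert len(series.frames) == len(gt["edge_columns"])

    def test_gap_width_sets_initial_edge(self):
        series, gt = syn.simulate_wound_series(speed=0.0, gap_width=500.0,
                                               noise=0.0, seed=0)
        w = series.frames.shape[2]
        assert gt["edge_columns"][0] == w - 500 - 1

    def test_edge_advances_at_planted_speed(self):
        series, gt = syn.simulate_wound_series(speed=10.0, noise=0.0, seed=0)
        edges = np.asarray(gt["edge_columns"], dtype=float)
        slope = np.polyfit(np.arange(len(edges)) * series.frame_interval, edges, 1)[0]
        assert slope == pytest.approx(10.0, rel=0.01)


class TestCellMasks:
    def test_labels_do_not_overlap(self):
        lab, _, _ = syn.simulate_cell_masks(n_cells=6, seed=2)
        assert lab.labels.max() == 6

    def test_ground_truth_has_roundness(self):
        _, _, gt = syn.simulate_cell_masks(n_cells=4, seed=2)
        shapes = gt["shapes"]
        assert np.allclose(shapes["roundness"],
                           shapes["major_um"] / shapes["minor_um"])

    def test_intensity_levels_piecewise_constant(self):
        lab, img, gt = syn.simulate_cell_masks(n_cells=4, seed=2)
        shapes = gt["shapes"]
        for lid in shapes.index:
            vals = img[lab.labels == lid]
            assert np.all(vals == shapes.loc[lid, "intensity"])
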