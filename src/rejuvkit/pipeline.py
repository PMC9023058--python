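"""End-to-end demo pipeline over pure simulation.

``run_pipeline`` wires the stages in dependency order — simulate →
clocks / transcriptome → rejuvenated-CpG calling → identity memory →
phenotypes — on fully synthetic data with planted ground truth, writes every
intermediate as TSV/BED/JSON/PNG under the configured output directory, and
records a manifest (tool version, config digest, per-output SHA-256 hashes,
headline numbers) sufficient to check a re-run bit for bit.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from . import __version__, clocks, imaging, io, memory, methylation, synthetic, transcriptome
from .config import RunConfig
from .errors import RejuvkitError

logger = logging.getLogger(__name__)


def _specs(cfg: RunConfig):
    c = cfg["cohort"]
    cohort = synthetic.CohortSpec(
        n_samples=c["n_samples"],
        age_range=tuple(c["age_range"]),
        n_cpgs=c["n_cpgs"],
        n_aging_cpgs=c["n_aging_cpgs"],
        aging_slope_range=tuple(c["aging_slope_range"]),
        baseline_range=tuple(c["baseline_range"]),
        noise_sd=c["noise_sd"],
        seed=cfg.seed,
    )
    e = cfg["expression"]
    espec = synthetic.ExpressionSpec(
        n_genes=e["n_genes"],
        n_aging_genes=e["n_aging_genes"],
        ramp_fraction=e["ramp_fraction"],
        noise_sd=e["noise_sd"],
        seed=cfg.seed + 1,
    )
    co = cfg["course"]
    course = synthetic.CourseSpec(
        groups=dict(co["groups"]),
        timepoints=tuple(co["timepoints"]),
        n_donors=co["n_donors"],
        donor_age_range=tuple(co["donor_age_range"]),
        archetype_props=tuple(co["archetype_props"]),
        n_identity_genes=co["n_identity_genes"],
        seed=cfg.seed + 2,
    )
    return cohort, espec, course


def _group_at_end(samples: pd.DataFrame, group: str) -> pd.Index:
    last = samples["timepoint_index"].max()
    return samples.index[(samples["group"] == group) & (samples["timepoint_index"] == last)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest (also written)."""
    t0 = time.time()
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config["stages"])
    manifest: dict = {
        "tool": "rejuvkit",
        "version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    results: dict = {}

    def record(name, path):
        manifest["outputs"][name] = {"path": str(path), "sha256": io.sha256_file(path)}

    try:
        cohort_spec, espec, course_spec = _specs(config)

        # --- simulate -----------------------------------------------------
        ref_betas, ref_samples, meth_gt = synthetic.simulate_aging_methylation(cohort_spec)
        ref_expr, ref_expr_samples, expr_gt = synthetic.simulate_aging_expression(
            espec, n_samples=cohort_spec.n_samples, age_range=cohort_spec.age_range
        )
        crs_betas, crs_expr, crs_samples, crs_gt = synthetic.simulate_reprogramming_course(
            cohort_spec, espec, course_spec
        )
        if "simulate" in stages:
            io.write_matrix(ref_betas, out / "reference_betas.tsv")
            io.write_table(ref_samples, out / "reference_samples.tsv")
            io.write_matrix(ref_expr, out / "reference_expression.tsv")
            io.write_table(ref_expr_samples, out / "reference_expression_samples.tsv")
            io.write_matrix(crs_betas, out / "course_betas.tsv")
            io.write_matrix(crs_expr, out / "course_expression.tsv")
            io.write_table(crs_samples, out / "course_samples.tsv")
            io.write_json(
                {
                    "planted_rejuvenation_years": dict(course_spec.groups),
                    "archetype_counts": crs_gt["identity_labels"].value_counts().to_dict(),
                },
                out / "ground_truth.json",
            )
            for name in ("reference_betas", "reference_samples", "reference_expression",
                         "course_betas", "course_expression", "course_samples",
                         "ground_truth"):
                suffix = ".json" if name == "ground_truth" else ".tsv"
                record(name, out / f"{name}{suffix}")
            manifest["stages"]["simulate"] = {"ok": True}

        ages = ref_samples["age"].to_numpy()
        control_end = _group_at_end(crs_samples, "negative_control")
        transient_end = _group_at_end(crs_samples, "transient")

        # --- clocks -------------------------------------------------------
        if "clocks" in stages:
            model, cv = clocks.train_linear_clock(
                ref_betas, ages,
                l1_ratio=config["clocks"]["l1_ratio"],
                cv_folds=config["clocks"]["cv_folds"],
                seed=config.seed,
            )
            io.save_clock_model(model, out / "trained_clock.csv", out / "trained_clock.json")
            preds = clocks.apply_clock(model, crs_betas)
            io.write_table(preds, out / "course_clock_predictions.tsv")
            gap = float(
                preds.loc[control_end, "predicted"].mean()
                - preds.loc[transient_end, "predicted"].mean()
            )
            results["meth_clock"] = {"cv": cv, "rejuvenation_gap_years": gap}
            record("trained_clock", out / "trained_clock.csv")
            record("course_clock_predictions", out / "course_clock_predictions.tsv")
            manifest["stages"]["clocks"] = {
                "ok": True, "medae_years": cv["medae_years"],
                "rejuvenation_gap_years": gap,
            }

        # --- transcript ---------------------------------------------------
        if "transcript" in stages:
            tc = config["transcript"]
            clock = transcriptome.train_transcript_clock(
                ref_expr, ref_expr_samples["age"].to_numpy(),
                kind=tc["kind"], cv=(tc["cv_folds"], tc["cv_repeats"]),
                seed=config.seed,
            )
            tpred = transcriptome.predict_transcript_age(clock, crs_expr)
            io.write_table(tpred.to_frame(), out / "course_transcript_age.tsv")
            tgap = float(tpred.loc[control_end].mean() - tpred.loc[transient_end].mean())

            traj = transcriptome.fit_aging_trajectory(
                ref_expr, ref_expr_samples["age"].to_numpy(), alpha=tc["alpha"]
            )
            proj = transcriptome.project_onto_trajectory(traj, crs_expr)
            io.write_table(proj, out / "course_trajectory_projection.tsv")
            pgap = float(
                proj.loc[control_end, "inferred_age"].mean()
                - proj.loc[transient_end, "inferred_age"].mean()
            )
            results["transcript"] = {
                "cv_mae_years": clock.cv_mae,
                "rejuvenation_gap_years": tgap,
                "trajectory_gap_years": pgap,
                "n_trajectory_genes": int(len(traj.genes)),
            }
            record("course_transcript_age", out / "course_transcript_age.tsv")
            record("course_trajectory_projection", out / "course_trajectory_projection.tsv")
            manifest["stages"]["transcript"] = {"ok": True, **results["transcript"]}

        # --- rejuvenation -------------------------------------------------
        if "rejuvenation" in stages:
            rj = config["rejuvenation"]
            slopes = methylation.estimate_aging_slopes(ref_betas, ages)
            calls = methylation.call_rejuvenated_cpgs(
                slopes, crs_betas.loc[control_end], crs_betas.loc[transient_end],
                threshold_per_40y=rj["threshold_per_40y"],
                reversal_min=rj["reversal_min"],
            )
            locations = meth_gt["cpg_params"][["chrom", "pos"]]
            regions = methylation.cluster_rejuvenated_regions(
                calls, locations, max_gap=rj["max_gap"], min_sites=rj["min_sites"]
            )
            tss = expr_gt["gene_params"][["chrom", "tss"]]
            annotated = methylation.annotate_nearest_gene(
                calls[calls["rejuvenated"]], locations, tss
            )
            gene_effects = methylation.estimate_aging_slopes(
                ref_expr, ref_expr_samples["age"].to_numpy()
            )["slope"] * 40.0
            gene_calls = methylation.call_rejuvenated_genes(
                gene_effects, crs_expr.loc[control_end], crs_expr.loc[transient_end],
                effect_min=rj["effect_min"], alpha=rj["alpha"],
            )
            meth_genes = set(annotated["nearest_gene"].dropna())
            expr_genes = set(gene_calls.index[gene_calls["rejuvenated"]])
            universe = set(tss.index)
            overlap = methylation.test_overlap(meth_genes & universe,
                                               expr_genes & universe, universe)
            io.write_table(calls, out / "rejuvenated_cpgs.tsv", index_label="cpg_id")
            io.write_regions_bed(regions, out / "rejuvenated_regions.bed")
            io.write_table(gene_calls, out / "rejuvenated_genes.tsv", index_label="gene_id")
            results["rejuvenation"] = {
                "n_rejuvenated_cpgs": int(calls["rejuvenated"].sum()),
                "n_regions": int(len(regions)),
                "n_rejuvenated_genes": int(len(expr_genes)),
                "overlap": overlap.__dict__,
            }
            record("rejuvenated_cpgs", out / "rejuvenated_cpgs.tsv")
            record("rejuvenated_genes", out / "rejuvenated_genes.tsv")
            manifest["stages"]["rejuvenation"] = {"ok": True, **{
                k: v for k, v in results["rejuvenation"].items() if k != "overlap"
            }, "overlap_p": overlap.p_value}

        # --- memory -------------------------------------------------------
        if "memory" in stages:
            me = config["memory"]
            fib_idx = crs_samples.index[
                (crs_samples["group"] == "negative_control")
                & (crs_samples["timepoint_index"] == 0)
            ]
            ipsc_idx = _group_at_end(crs_samples, "complete")
            fib_set, ipsc_set = memory.define_specific_gene_sets(
                crs_expr.loc[fib_idx], crs_expr.loc[ipsc_idx],
                lfc_min=me["lfc_min"], alpha=me["alpha"],
            )
            tr_idx = crs_samples.index[crs_samples["group"] == "transient"]
            labels = memory.cluster_gene_trajectories(
                crs_expr.loc[tr_idx],
                crs_samples.loc[tr_idx, "timepoint"],
                list(course_spec.timepoints),
                genes=fib_set.index,
                k=me["k"],
            )
            elements = synthetic.simulate_regulatory_elements(
                expr_gt["gene_params"], seed=config.seed + 3
            )
            links, unlinked = memory.link_elements_to_genes(
                elements, expr_gt["gene_params"][["chrom", "tss"]].rename(
                    columns={"tss": "tss"}),
                promoter_window=me["promoter_window"],
                enhancer_window=me["enhancer_window"],
            )
            el_betas, el_locs, el_samples = synthetic.simulate_element_methylation(
                elements, seed=config.seed + 4
            )
            summaries = memory.summarize_element_methylation(
                el_betas, el_locs, elements, el_samples["group"]
            )
            fib_enh = memory.classify_fibroblast_enhancers(elements)
            enh_summ = summaries.loc[summaries.index.intersection(fib_enh.index)]
            n_hyper, n_total = memory.count_hypermethylated(
                enh_summ, "fibroblast", "ipsc", gain_min=me["gain_min"]
            )
            n_hyper_tr, _ = memory.count_hypermethylated(
                enh_summ, "fibroblast", "transient", gain_min=me["gain_min"]
            )
            io.write_table(labels, out / "identity_gene_archetypes.tsv",
                           index_label="gene_id")
            io.write_elements_bed(elements, out / "regulatory_elements.bed")
            io.write_table(summaries, out / "element_methylation.tsv")
            results["memory"] = {
                "n_fibroblast_genes": int(len(fib_set)),
                "n_ipsc_genes": int(len(ipsc_set)),
                "archetype_counts": labels["archetype"].value_counts().to_dict(),
                "n_linked_elements": int(len(links)),
                "n_unlinked_elements": int(len(unlinked)),
                "fibroblast_enhancers": int(n_total),
                "hypermethylated_in_ipsc": int(n_hyper),
                "hypermethylated_in_transient": int(n_hyper_tr),
            }
            record("identity_gene_archetypes", out / "identity_gene_archetypes.tsv")
            record("element_methylation", out / "element_methylation.tsv")
            manifest["stages"]["memory"] = {"ok": True, **results["memory"]}

        # --- phenotype ----------------------------------------------------
        if "phenotype" in stages:
            ph = config["phenotype"]
            speeds = {}
            for i, speed in enumerate(ph["wound_speeds"]):
                series, wgt = synthetic.simulate_wound_series(
                    speed, pixel_size=ph["pixel_size"],
                    frame_interval=ph["frame_interval"],
                    n_frames=ph["n_frames"], noise=ph["wound_noise"],
                    seed=config.seed + 10 + i,
                )
                trace = imaging.compute_migration_speed(series, ph["coverage_min"])
                speeds[str(speed)] = trace.speed_um_per_h
            mask, intens, cgt = synthetic.simulate_cell_masks(
                n_cells=ph["n_cells"], pixel_size=ph["pixel_size"],
                seed=config.seed + 20,
            )
            io.save_label_mask(mask, out / "cell_labels.png")
            shapes = imaging.measure_roundness(mask)
            nuc = imaging.measure_nuclear_intensity(intens, mask)
            io.write_table(shapes.join(nuc), out / "cell_measurements.tsv")
            truth = cgt["shapes"]
            rerr = float(np.nanmax(np.abs(
                shapes["roundness"].reindex(truth.index) - truth["roundness"]
            )))
            results["phenotype"] = {
                "measured_speeds_um_per_h": speeds,
                "max_roundness_abs_error": rerr,
            }
            record("cell_measurements", out / "cell_measurements.tsv")
            record("cell_labels", out / "cell_labels.png")
            manifest["stages"]["phenotype"] = {"ok": True, **results["phenotype"]}

    except RejuvkitError as exc:
        stage = next((s for s in stages if s not in manifest["stages"]), "?")
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    manifest["results"] = results
    io.write_json(manifest, out / "manifest.json")
    return manifest
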