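"""Cell-identity gene sets, trajectory archetypes, and enhancer memory.

Transiently reprogrammed cells temporarily lose and then reacquire their
somatic identity.  This module quantifies the candidate sources of that
memory: it defines cell-type-specific gene sets by differential expression,
classifies each identity gene's trajectory across ordered reprogramming
stages into archetypes (temporarily down, temporarily up, persistent),
links regulatory elements to their nearest transcription start site
(1 kb window for promoters, 1 Mb for enhancers), and summarizes DNA
methylation over elements to count enhancers that gain methylation between
the somatic start state and the pluripotent endpoint.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError
from .synthetic import ARCHETYPES

logger = logging.getLogger(__name__)

ACTIVITY_STATES = ("active", "inactive", "poised", "repressed")
INACTIVE_STATES = ("inactive", "poised", "repressed")


def define_specific_gene_sets(
    fib: pd.DataFrame,
    ipsc: pd.DataFrame,
    lfc_min: float = 2.0,
    alpha: float = 0.05,
    test: str = "welch",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential expression between fibroblasts and iPSCs (log2 matrices).

    Returns (fibroblast_specific, ipsc_specific) tables indexed by gene with
    columns ``log2_fc`` (fib - ipsc) and ``p_adj``.  Membership requires
    ``|log2_fc| >= lfc_min`` and BH-adjusted p <= ``alpha``; the two sets are
    disjoint by the sign of the fold change.  ``test`` is ``welch`` (Welch t
    on log2 values) or ``ranksum``.
    """
    if len(fib) < 2 or len(ipsc) < 2:
        raise DataError("need at least 2 samples per group")
    shared = fib.columns.intersection(ipsc.columns)
    if len(shared) == 0:
        raise DataError("no shared genes")
    F = fib[shared].to_numpy(dtype=float)
    I = ipsc[shared].to_numpy(dtype=float)
    lfc = F.mean(axis=0) - I.mean(axis=0)
    if test == "welch":
        with np.errstate(invalid="ignore", divide="ignore"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = stats.ttest_ind(F, I, axis=0, equal_var=False).pvalue
        # degenerate zero-variance genes: decide by whether the means differ
        zero_var = (F.std(axis=0) == 0) & (I.std(axis=0) == 0)
        p = np.where(zero_var & (lfc != 0), 0.0, np.where(zero_var, 1.0, p))
        p = np.where(np.isnan(p), 1.0, p)
    elif test == "ranksum":
        p = np.ones(len(shared))
        for i in range(len(shared)):
            if np.ptp(np.concatenate([F[:, i], I[:, i]])) == 0:
                p[i] = 1.0
            else:
                p[i] = stats.mannwhitneyu(F[:, i], I[:, i], alternative="two-sided").pvalue
    else:
        raise ConfigurationError(f"unknown test {test!r}")
    padj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({"log2_fc": lfc, "p": p, "p_adj": padj}, index=shared)
    fib_set = table[(table["log2_fc"] >= lfc_min) & (table["p_adj"] <= alpha)].copy()
    ipsc_set = table[(table["log2_fc"] <= -lfc_min) & (table["p_adj"] <= alpha)].copy()
    return fib_set, ipsc_set


def stage_mean_trajectories(
    expr: pd.DataFrame, sample_stages: pd.Series, stages: list[str]
) -> pd.DataFrame:
    """Genes x stages matrix of per-stage mean expression."""
    cols = {}
    for st in stages:
        idx = sample_stages.index[sample_stages == st]
        idx = expr.index.intersection(idx)
        if len(idx) == 0:
            raise DataError(f"no samples for stage {st!r}")
        cols[st] = expr.loc[idx].mean(axis=0)
    return pd.DataFrame(cols)


def cluster_gene_trajectories(
    expr: pd.DataFrame,
    sample_stages: pd.Series,
    stages: list[str],
    genes=None,
    k: int = 3,
    flat_amplitude: float = 0.5,
) -> pd.DataFrame:
    """Cluster identity-gene trajectories across ordered stages into archetypes.

    Per-gene stage-mean trajectories are centred and scaled by a single
    global factor (the median per-gene standard deviation across stages), so
    amplitude is preserved: per-gene unit-variance scaling would blow flat
    trajectories up to pure noise.  Agglomerative (Ward, Euclidean)
    clustering is cut at ``k`` and each cluster is auto-labelled by its shape:
    centroids whose amplitude stays below ``flat_amplitude`` (log2 units) are
    ``persistent``; otherwise the interior-vs-endpoint contrast decides
    ``temporarily_down`` vs ``temporarily_up``.

    Returns a per-gene DataFrame with ``cluster`` and ``archetype`` columns.
    """
    if len(stages) < 3:
        raise DataError("need at least 3 ordered stages (start, intermediate, end)")
    traj = stage_mean_trajectories(expr, sample_stages, list(stages))
    if genes is not None:
        genes = pd.Index(genes).intersection(traj.index)
        if len(genes) == 0:
            raise DataError("none of the requested genes are in the matrix")
        traj = traj.loc[genes]
    if k < 1 or k > len(traj):
        raise ConfigurationError(f"k={k} out of range for {len(traj)} genes")

    M = traj.to_numpy(dtype=float)
    centred = M - M.mean(axis=1, keepdims=True)
    scale = float(np.median(M.std(axis=1, ddof=0)))
    if scale <= 0:
        scale = 1.0
    Z = centred / scale

    if k == 1 or len(traj) == 1:
        labels = np.zeros(len(traj), dtype=int)
    else:
        labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(Z)

    archetypes = {}
    amplitudes = {}
    for c in np.unique(labels):
        cen = centred[labels == c].mean(axis=0)
        amp = float(cen.max() - cen.min())
        amplitudes[c] = amp
        if amp < flat_amplitude:
            archetypes[c] = "persistent"
        else:
            interior = cen[1:-1].mean()
            ends = 0.5 * (cen[0] + cen[-1])
            archetypes[c] = "temporarily_down" if interior < ends else "temporarily_up"
    if all(v == "persistent" for v in archetypes.values()):
        warnings.warn("all trajectory clusters are flat; labelling everything persistent",
                      stacklevel=2)
    out = pd.DataFrame(
        {
            "cluster": labels,
            "archetype": [archetypes[c] for c in labels],
        },
        index=traj.index,
    )
    assert set(out["archetype"]) <= set(ARCHETYPES)
    return out


def link_elements_to_genes(
    elements: pd.DataFrame,
    tss_table: pd.DataFrame,
    promoter_window: int = 1_000,
    enhancer_window: int = 1_000_000,
) -> tuple[pd.DataFrame, pd.Index]:
    """Link each regulatory element to its nearest TSS within a class window.

    ``elements`` is indexed by element id with columns ``chrom``, ``start``,
    ``end`` (0-based half-open) and ``class`` (promoter/enhancer); distance
    is measured from the element midpoint.  Returns (links DataFrame with
    ``gene`` and ``distance``, index of unlinked element ids).
    """
    if tss_table.empty:
        raise DataError("TSS table is empty")
    windows = {"promoter": promoter_window, "enhancer": enhancer_window}
    by_chrom = {c: g.sort_values("tss") for c, g in tss_table.groupby("chrom")}
    links = []
    unlinked = []
    for eid, row in elements.iterrows():
        cls = row["class"]
        if cls not in windows:
            raise ConfigurationError(f"unknown element class {cls!r}")
        mid = 0.5 * (float(row["start"]) + float(row["end"]))
        grp = by_chrom.get(row["chrom"])
        if grp is None:
            unlinked.append(eid)
            continue
        tss = grp["tss"].to_numpy(dtype=float)
        d = np.abs(tss - mid)
        dmin = d.min()
        if dmin <= windows[cls]:
            winners = grp.index[d == dmin]
            links.append({"element_id": eid, "gene": min(winners), "distance": float(dmin),
                          "class": cls})
        else:
            unlinked.append(eid)
    links_df = pd.DataFrame(links, columns=["element_id", "gene", "distance", "class"])
    if len(links_df):
        links_df = links_df.set_index("element_id")
    else:
        links_df.index.name = "element_id"
    return links_df, pd.Index(unlinked, name="element_id")


def summarize_element_methylation(
    betas: pd.DataFrame,
    cpg_locations: pd.DataFrame,
    elements: pd.DataFrame,
    groups: pd.Series,
) -> pd.DataFrame:
    """Mean beta per element per sample group.

    CpGs are assigned to an element when their position falls in
    ``[start, end)`` on the same chromosome.  Elements covering no CpG are
    omitted (count logged).  Returns a DataFrame indexed by element id with
    one column per group plus ``n_cpgs``.
    """
    loc = cpg_locations.reindex(betas.columns).dropna(subset=["chrom", "pos"])
    group_names = sorted(pd.Series(groups).dropna().unique())
    group_means = {
        g: betas.loc[betas.index.intersection(groups.index[groups == g])].mean(axis=0)
        for g in group_names
    }
    rows = []
    omitted = 0
    by_chrom = {c: g for c, g in loc.groupby("chrom")}
    for eid, el in elements.iterrows():
        grp = by_chrom.get(el["chrom"])
        if grp is None:
            omitted += 1
            continue
        pos = grp["pos"].to_numpy(dtype=float)
        inside = grp.index[(pos >= float(el["start"])) & (pos < float(el["end"]))]
        if len(inside) == 0:
            omitted += 1
            continue
        row = {"element_id": eid, "n_cpgs": len(inside)}
        for g in group_names:
            row[g] = float(group_means[g].loc[inside].mean())
        rows.append(row)
    if omitted:
        logger.info("element summaries: %d elements had no covered CpGs", omitted)
    out = pd.DataFrame(rows, columns=["element_id", "n_cpgs", *group_names])
    return out.set_index("element_id") if len(out) else out


def classify_fibroblast_enhancers(
    elements: pd.DataFrame,
    start_state: str = "fibroblast",
    end_state: str = "ipsc",
) -> pd.DataFrame:
    """Enhancers active in the start cell state but not in the end state.

    Activity is read from ``activity_<state>`` columns; elements missing
    either annotation are skipped (logged).
    """
    c_start, c_end = f"activity_{start_state}", f"activity_{end_state}"
    for col in (c_start, c_end):
        if col not in elements.columns:
            raise DataError(f"missing activity column {col!r}")
    enh = elements[elements["class"] == "enhancer"]
    missing = enh[c_start].isna() | enh[c_end].isna()
    if missing.any():
        logger.warning("%d enhancers lack activity annotation; skipped", int(missing.sum()))
        enh = enh[~missing]
    keep = (enh[c_start] == "active") & enh[c_end].isin(INACTIVE_STATES)
    return enh[keep]


def count_hypermethylated(
    summaries: pd.DataFrame,
    start_group: str,
    end_group: str,
    gain_min: float = 0.2,
) -> tuple[int, int]:
    """Count elements gaining >= ``gain_min`` mean beta from start to end group.

    Returns (n_hypermethylated, n_total).
    """
    if start_group not in summaries.columns or end_group not in summaries.columns:
        raise DataError("summaries lack the requested group columns")
    gain = summaries[end_group] - summaries[start_group]
    return int((gain >= gain_min).sum()), int(len(summaries))
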