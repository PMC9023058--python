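"""Rejuvenated-CpG and rejuvenated-gene calling.

A CpG site is *rejuvenated* when its age-associated methylation change is at
least 10% (beta fraction) per 40 years of aging and treatment moves it in
the opposite direction.  Aging change is measured as the per-CpG OLS slope
of beta on age in a reference cohort, times 40 years; the treatment change
is the treated-minus-control mean beta difference.  Called sites can be
clustered into genomic regions, annotated with the nearest transcription
start site, and the resulting gene set tested for overlap with
expression-level rejuvenation by a one-sided Fisher exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError

logger = logging.getLogger(__name__)

_EPS = 1e-12


def estimate_aging_slopes(betas: pd.DataFrame, ages) -> pd.DataFrame:
    """Per-CpG ordinary-least-squares slope of beta on age.

    Returns a DataFrame indexed by CpG with columns ``slope`` (beta fraction
    per year), ``intercept``, ``n`` and ``r``.
    """
    ages = np.asarray(ages, dtype=float)
    if len(ages) != len(betas):
        raise DataError("ages and beta matrix must align")
    if len(ages) < 2:
        raise DataError("need at least 2 samples")
    if np.ptp(ages) == 0:
        raise DataError("ages are constant; cannot estimate aging slopes")
    X = betas.to_numpy(dtype=float)
    a = ages - ages.mean()
    var_a = (a**2).sum()
    Xc = X - X.mean(axis=0)
    slope = (Xc * a[:, None]).sum(axis=0) / var_a
    intercept = X.mean(axis=0) - slope * ages.mean()
    sd_x = X.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = slope * ages.std(ddof=0) / sd_x
    r = np.where(sd_x > 0, r, 0.0)
    return pd.DataFrame(
        {"slope": slope, "intercept": intercept, "n": len(ages), "r": np.clip(r, -1, 1)},
        index=betas.columns,
    )


def call_rejuvenated_cpgs(
    slopes: pd.DataFrame,
    control: pd.DataFrame,
    treated: pd.DataFrame,
    threshold_per_40y: float = 0.10,
    reversal_min: float = 0.0,
) -> pd.DataFrame:
    """Apply the rejuvenation rule to every CpG shared across inputs.

    A site is rejuvenated iff ``|slope * 40| >= threshold_per_40y``
    (inclusive) and the treated-minus-control mean beta difference opposes
    the sign of the aging slope with magnitude > ``reversal_min``.

    Returns a DataFrame with columns ``aging_delta_40y``,
    ``reprogramming_delta``, ``direction`` (age_hyper / age_hypo) and
    ``rejuvenated``.
    """
    shared = slopes.index.intersection(control.columns).intersection(treated.columns)
    if len(shared) == 0:
        raise DataError("no CpGs shared between slope table, control and treated")
    s = slopes.loc[shared, "slope"].to_numpy(dtype=float)
    delta = (
        treated[shared].mean(axis=0).to_numpy() - control[shared].mean(axis=0).to_numpy()
    )
    aging_40 = s * 40.0
    opposes = (np.sign(delta) == -np.sign(s)) & (s != 0)
    rejuvenated = (
        (np.abs(aging_40) >= threshold_per_40y - _EPS)
        & opposes
        & (np.abs(delta) > reversal_min)
    )
    direction = np.where(s >= 0, "age_hyper", "age_hypo")
    return pd.DataFrame(
        {
            "aging_delta_40y": aging_40,
            "reprogramming_delta": delta,
            "direction": direction,
            "rejuvenated": rejuvenated,
        },
        index=shared,
    )


def cluster_rejuvenated_regions(
    calls: pd.DataFrame,
    locations: pd.DataFrame,
    max_gap: int = 1000,
    min_sites: int = 2,
) -> pd.DataFrame:
    """Merge rejuvenated CpGs within ``max_gap`` bp into regions.

    ``locations`` is indexed by CpG id with columns ``chrom`` and ``pos``
    (0-based).  Sites without a location are skipped (logged).  Regions with
    fewer than ``min_sites`` members are discarded.  Returns a BED-like
    DataFrame (chrom, start, end half-open, n_sites, cpgs).
    """
    hits = calls.index[calls["rejuvenated"].astype(bool)]
    missing = hits.difference(locations.index)
    if len(missing):
        logger.warning("clustering: %d rejuvenated CpGs lack locations; skipped", len(missing))
    loc = locations.loc[hits.intersection(locations.index), ["chrom", "pos"]].copy()
    loc = loc.sort_values(["chrom", "pos"])
    regions = []
    for chrom, grp in loc.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        ids = grp.index.to_numpy()
        start_i = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > max_gap:
                members = ids[start_i:i]
                if len(members) >= min_sites:
                    regions.append(
                        {
                            "chrom": chrom,
                            "start": int(pos[start_i]),
                            "end": int(pos[i - 1]) + 1,
                            "n_sites": len(members),
                            "cpgs": ",".join(map(str, members)),
                        }
                    )
                start_i = i
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "n_sites", "cpgs"])


def annotate_nearest_gene(
    calls: pd.DataFrame, locations: pd.DataFrame, tss_table: pd.DataFrame
) -> pd.DataFrame:
    """Annotate each called CpG with its nearest-TSS gene.

    ``tss_table`` is indexed by gene id with columns ``chrom`` and ``tss``.
    Equidistant TSSs are resolved to the lexicographically smallest gene id.
    CpGs on chromosomes with no TSS are left unannotated (logged).  Returns
    ``calls`` with added ``nearest_gene`` and ``tss_distance`` columns.
    """
    if tss_table.empty:
        raise DataError("TSS table is empty")
    out = calls.copy()
    out["nearest_gene"] = pd.NA
    out["tss_distance"] = np.nan
    loc = locations.reindex(calls.index)
    n_unannotated = 0
    by_chrom = {
        chrom: grp.sort_values("tss") for chrom, grp in tss_table.groupby("chrom")
    }
    for cpg, row in loc.iterrows():
        chrom = row.get("chrom")
        if pd.isna(chrom) or chrom not in by_chrom:
            n_unannotated += 1
            continue
        grp = by_chrom[chrom]
        tss = grp["tss"].to_numpy(dtype=np.int64)
        pos = int(row["pos"])
        j = np.searchsorted(tss, pos)
        cand = [k for k in (j - 1, j) if 0 <= k < len(tss)]
        dists = np.abs(tss[cand] - pos)
        dmin = dists.min()
        # all TSSs at the minimum distance (ties can involve duplicates)
        all_d = np.abs(tss - pos)
        winners = grp.index[all_d == dmin]
        out.loc[cpg, "nearest_gene"] = min(winners)
        out.loc[cpg, "tss_distance"] = int(dmin)
    if n_unannotated:
        logger.warning("nearest-gene annotation: %d CpGs had no TSS on their chromosome",
                       n_unannotated)
    return out


def call_rejuvenated_genes(
    aging_effects: pd.Series,
    control: pd.DataFrame,
    treated: pd.DataFrame,
    effect_min: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Call genes whose age-associated expression change is reversed.

    ``aging_effects`` holds the per-gene log2 change over 40 years of aging.
    A gene is called iff ``|effect| >= effect_min``, the treated-vs-control
    mean log2 difference opposes the aging direction, and the two-sided
    rank-sum p-value passes Benjamini-Hochberg at ``alpha``.  Returns a
    per-gene table with a ``rejuvenated`` flag.
    """
    shared = aging_effects.index.intersection(control.columns).intersection(treated.columns)
    if len(shared) == 0:
        raise DataError("no shared genes")
    if len(control) < 2 or len(treated) < 2:
        raise DataError("need at least 2 samples per group")
    eff = aging_effects.loc[shared].to_numpy(dtype=float)
    c = control[shared].to_numpy(dtype=float)
    t = treated[shared].to_numpy(dtype=float)
    delta = t.mean(axis=0) - c.mean(axis=0)
    pvals = np.ones(len(shared))
    for i in range(len(shared)):
        if np.ptp(np.concatenate([c[:, i], t[:, i]])) == 0:
            pvals[i] = 1.0
        else:
            pvals[i] = stats.mannwhitneyu(t[:, i], c[:, i], alternative="two-sided").pvalue
    padj = multipletests(pvals, method="fdr_bh")[1]
    opposes = (np.sign(delta) == -np.sign(eff)) & (eff != 0)
    called = (np.abs(eff) >= effect_min - _EPS) & opposes & (padj <= alpha)
    return pd.DataFrame(
        {
            "aging_effect_40y": eff,
            "treatment_delta": delta,
            "p": pvals,
            "p_adj": padj,
            "rejuvenated": called,
        },
        index=shared,
    )


@dataclass(frozen=True)
class OverlapResult:
    """One-sided Fisher exact test of the overlap between two gene sets."""

    a: int
    b: int
    overlap: int
    universe: int
    odds_ratio: float
    p_value: float


def test_overlap(set_a, set_b, universe) -> OverlapResult:
    """Enrichment Fisher exact test for the overlap of two sets in a universe.

    The 2x2 table is (in both / only a / only b / in neither); the p-value is
    the one-sided (greater) hypergeometric tail.  The odds ratio uses a
    Haldane 0.5 correction when any cell is zero.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not universe:
        raise DataError("empty universe")
    if not set_a <= universe or not set_b <= universe:
        raise DataError("sets must be subsets of the universe")
    k = len(set_a & set_b)
    a_only = len(set_a) - k
    b_only = len(set_b) - k
    neither = len(universe) - len(set_a) - len(set_b) + k
    table = np.array([[k, a_only], [b_only, neither]], dtype=float)
    p = float(stats.fisher_exact(table, alternative="greater")[1])
    if np.any(table == 0):
        table = table + 0.5
    odds = float((table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0]))
    return OverlapResult(
        a=len(set_a), b=len(set_b), overlap=k, universe=len(universe),
        odds_ratio=odds, p_value=p,
    )
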