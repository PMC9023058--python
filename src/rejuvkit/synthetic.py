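"""Seeded synthetic cohorts, reprogramming time courses, and images.

Every downstream stage of the package is testable without downloads because
this module plants known ground truth:

- an aging fibroblast cohort (donors ~1-94 years) whose CpGs drift linearly
  in age and whose genes carry age signal, either linear on the log2 scale or
  as a gene-specific onset/saturation ramp (real age-associated expression
  changes switch on and plateau at gene-specific ages rather than drifting
  without bound — and step-like dynamics are what binarized transcriptome
  clocks exploit);
- a reprogramming time course with four arms (negative control, failed,
  transient, complete) where treatment shifts age-linked features to the
  values expected at ``age - rejuvenation_years``, and cell-identity genes
  follow archetype trajectories (down-then-recover, transient-up, persistent);
- wound-mask time series with a planted edge speed;
- elliptical cell/nucleus label masks with planted axes and intensities.

Feature-level parameters (slopes, baselines, gene effects) are derived from
the spec's seed alone, so a cohort and a time course built from the same spec
share the same underlying features and planted effects are exactly
recoverable.  Identical specs and seeds give byte-identical outputs.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping as MappingABC
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .errors import ConfigurationError, PlacementError

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
ARCHETYPES = ("temporarily_down", "temporarily_up", "persistent")


class GroundTruth(MappingABC):
    """Read-only mapping of planted quantities, retrievable by key."""

    def __init__(self, data: Mapping):
        self._data = dict(data)

    def __getitem__(self, key):
        return self._data[key]

    def __iter__(self) -> Iterator:
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def __repr__(self) -> str:
        return f"GroundTruth(keys={sorted(self._data)})"


def _check_range(name: str, rng: tuple[float, float]) -> tuple[float, float]:
    lo, hi = float(rng[0]), float(rng[1])
    if lo > hi:
        raise ConfigurationError(f"{name}: min {lo} > max {hi}")
    return lo, hi


@dataclass(frozen=True)
class CohortSpec:
    """Aging-cohort methylation generator settings.

    Aging CpGs drift ``slope`` beta-fraction per year from a baseline chosen
    so that the noiseless value stays inside (0.02, 0.98) over ``age_range``;
    the remaining CpGs have slope 0.  Gaussian noise (sd ``noise_sd``) is
    added and values are clipped to [0, 1].
    """

    n_samples: int = 200
    age_range: tuple[float, float] = (1.0, 94.0)
    n_cpgs: int = 2000
    n_aging_cpgs: int = 500
    aging_slope_range: tuple[float, float] = (0.001, 0.004)
    baseline_range: tuple[float, float] = (0.05, 0.95)
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_cpgs <= 0:
            raise ConfigurationError("counts must be positive")
        if not (0 <= self.n_aging_cpgs <= self.n_cpgs):
            raise ConfigurationError("need 0 <= n_aging_cpgs <= n_cpgs")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        _check_range("age_range", self.age_range)
        _check_range("aging_slope_range", self.aging_slope_range)
        _check_range("baseline_range", self.baseline_range)


@dataclass(frozen=True)
class ExpressionSpec:
    """Aging-cohort expression generator settings (log2 scale).

    ``ramp_fraction`` of the aging genes switch between two plateaus over a
    short gene-specific window (onset to onset+duration) — the switch-like
    dynamics that give binarized clocks their per-gene crossing ages; the
    rest drift linearly in age on the log2 scale.
    """

    n_genes: int = 1200
    n_aging_genes: int = 300
    ramp_fraction: float = 0.5
    linear_effect_range: tuple[float, float] = (0.01, 0.03)  # |log2 units| / year
    ramp_effect_range: tuple[float, float] = (1.0, 3.0)  # total |log2| change
    ramp_onset_range: tuple[float, float] = (0.0, 85.0)  # years
    ramp_duration_range: tuple[float, float] = (5.0, 15.0)  # years
    baseline_range: tuple[float, float] = (3.0, 8.0)  # log2 units
    noise_sd: float = 0.3  # log2 units
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if not (0 <= self.n_aging_genes <= self.n_genes):
            raise ConfigurationError("need 0 <= n_aging_genes <= n_genes")
        if not (0.0 <= self.ramp_fraction <= 1.0):
            raise ConfigurationError("ramp_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


DEFAULT_GROUPS = {
    "negative_control": 0.0,
    "failed": 10.0,
    "transient": 30.0,
    "complete": 38.0,
}


@dataclass(frozen=True)
class CourseSpec:
    """Reprogramming time-course generator settings.

    Each group is assigned a planted rejuvenation (years); the negative
    control must be 0.  Timepoints are ordered stages (start, reprogramming
    intermediate, post-reversion endpoint).  Cell-identity genes are split
    into archetypes by ``archetype_props`` (temporarily_down, temporarily_up,
    persistent) with deterministic largest-remainder allocation.
    """

    groups: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    timepoints: tuple[str, ...] = ("day0", "day13", "day50")
    n_donors: int = 6
    donor_age_range: tuple[float, float] = (38.0, 53.0)
    archetype_props: tuple[float, float, float] = (0.67, 0.23, 0.10)
    n_identity_genes: int = 300
    identity_baseline_range: tuple[float, float] = (4.0, 8.0)
    down_delta: float = -4.0  # log2 shift of down-archetype genes mid-course
    up_delta: float = 3.0  # log2 shift of up-archetype genes mid-course
    identity_noise_sd: float = 0.3
    seed: int = 2

    def __post_init__(self) -> None:
        groups = dict(self.groups)
        if "negative_control" in groups and groups["negative_control"] != 0:
            raise ConfigurationError("rejuvenation_years(negative_control) must be 0")
        if any(v < 0 for v in groups.values()):
            raise ConfigurationError("rejuvenation_years must be >= 0")
        if len(self.timepoints) < 2:
            raise ConfigurationError("need at least 2 timepoints")
        if abs(sum(self.archetype_props) - 1.0) > 1e-9:
            raise ConfigurationError("archetype proportions must sum to 1")
        if self.n_donors <= 0 or self.n_identity_genes < 0:
            raise ConfigurationError("counts must be positive")


# ---------------------------------------------------------------------------
# feature parameters (deterministic given the spec seed)
# ---------------------------------------------------------------------------


def methylation_values(baseline, slope, ages, noise_sd: float = 0.0, rng=None):
    """Noiseless-core generative formula: clip(baseline + slope*age + noise, 0, 1)."""
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    baseline = np.atleast_1d(np.asarray(baseline, dtype=float))
    slope = np.atleast_1d(np.asarray(slope, dtype=float))
    vals = baseline[None, :] + ages[:, None] * slope[None, :]
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    return np.clip(vals, 0.0, 1.0)


def cpg_parameters(spec: CohortSpec) -> pd.DataFrame:
    """Per-CpG baseline, slope and synthetic genomic location for a cohort spec."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    n = spec.n_cpgs
    ids = [f"cg{i:06d}" for i in range(n)]
    slopes = np.zeros(n)
    aging_idx = rng.choice(n, size=spec.n_aging_cpgs, replace=False)
    mag = rng.uniform(*spec.aging_slope_range, size=spec.n_aging_cpgs)
    sign = rng.choice([-1.0, 1.0], size=spec.n_aging_cpgs)
    slopes[aging_idx] = mag * sign

    a_lo, a_hi = spec.age_range
    b_lo, b_hi = spec.baseline_range
    # baseline window keeping the noiseless value inside (0.02, 0.98) over age_range
    drift_lo = np.minimum(slopes * a_lo, slopes * a_hi)
    drift_hi = np.maximum(slopes * a_lo, slopes * a_hi)
    lo = np.maximum(b_lo, 0.02 - drift_lo)
    hi = np.minimum(b_hi, 0.98 - drift_hi)
    bad = lo >= hi
    mid = 0.5 * (np.clip(lo, 0, 1) + np.clip(hi, 0, 1))
    u = rng.uniform(size=n)
    baseline = np.where(bad, mid, lo + u * np.maximum(hi - lo, 0.0))

    chrom = rng.choice(AUTOSOMES, size=n)
    pos = rng.integers(1, 100_000_000, size=n)
    return pd.DataFrame(
        {"baseline": baseline, "slope": slopes, "chrom": chrom, "pos": pos},
        index=pd.Index(ids, name="cpg_id"),
    )


def gene_parameters(spec: ExpressionSpec) -> pd.DataFrame:
    """Per-gene aging model (kind, baseline, effect, onset, duration, TSS)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 10]))
    n = spec.n_genes
    ids = [f"gene{i:05d}" for i in range(n)]
    kind = np.array(["null"] * n, dtype=object)
    aging_idx = rng.choice(n, size=spec.n_aging_genes, replace=False)
    n_ramp = int(round(spec.ramp_fraction * spec.n_aging_genes))
    ramp_idx = aging_idx[:n_ramp]
    lin_idx = aging_idx[n_ramp:]
    kind[ramp_idx] = "ramp"
    kind[lin_idx] = "linear"

    baseline = rng.uniform(*spec.baseline_range, size=n)
    effect = np.zeros(n)
    sign = rng.choice([-1.0, 1.0], size=n)
    effect[lin_idx] = rng.uniform(*spec.linear_effect_range, size=len(lin_idx)) * sign[lin_idx]
    effect[ramp_idx] = rng.uniform(*spec.ramp_effect_range, size=len(ramp_idx)) * sign[ramp_idx]
    onset = np.zeros(n)
    duration = np.ones(n)
    onset[ramp_idx] = rng.uniform(*spec.ramp_onset_range, size=len(ramp_idx))
    duration[ramp_idx] = rng.uniform(*spec.ramp_duration_range, size=len(ramp_idx))

    chrom = rng.choice(AUTOSOMES, size=n)
    tss = rng.integers(1, 100_000_000, size=n)
    return pd.DataFrame(
        {
            "kind": kind,
            "baseline": baseline,
            "effect": effect,
            "onset": onset,
            "duration": duration,
            "chrom": chrom,
            "tss": tss,
        },
        index=pd.Index(ids, name="gene_id"),
    )


def expression_profile(params: pd.DataFrame, ages) -> np.ndarray:
    """Noiseless log2 expression (samples x genes) implied by gene parameters."""
    ages = np.asarray(ages, dtype=float)[:, None]
    base = params["baseline"].to_numpy()[None, :]
    eff = params["effect"].to_numpy()[None, :]
    kind = params["kind"].to_numpy()
    onset = params["onset"].to_numpy()[None, :]
    dur = params["duration"].to_numpy()[None, :]
    lin = base + eff * ages
    frac = np.clip((ages - onset) / dur, 0.0, 1.0)
    ramp = base + eff * frac
    out = np.where(kind[None, :] == "linear", lin, np.where(kind[None, :] == "ramp", ramp, base))
    return out


def gene_aging_effect_per_40y(params: pd.DataFrame, age_ref: float = 50.0) -> pd.Series:
    """Planted log2 change over 40 years of aging, centred at ``age_ref``."""
    lo = expression_profile(params, [age_ref - 20.0])[0]
    hi = expression_profile(params, [age_ref + 20.0])[0]
    return pd.Series(hi - lo, index=params.index, name="effect_40y")


# ---------------------------------------------------------------------------
# cohort simulators
# ---------------------------------------------------------------------------


def simulate_aging_methylation(
    spec: CohortSpec,
    ages=None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate an aging cohort beta matrix.

    Returns (betas samples x CpGs, sample table with true ages, ground truth
    with the per-CpG parameters).  If ``ages`` is given it overrides the
    spec's ``n_samples``/``age_range``.
    """
    params = cpg_parameters(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
    if ages is None:
        ages = rng.uniform(*spec.age_range, size=spec.n_samples)
    else:
        ages = np.asarray(ages, dtype=float)
    noise_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 2]))
    betas = methylation_values(
        params["baseline"].to_numpy(), params["slope"].to_numpy(), ages, spec.noise_sd, noise_rng
    )
    sample_ids = [f"ref{i:04d}" for i in range(len(ages))]
    bdf = pd.DataFrame(betas, index=pd.Index(sample_ids, name="sample_id"), columns=params.index)
    samples = pd.DataFrame({"age": ages}, index=bdf.index)
    gt = GroundTruth({"cpg_params": params, "ages": samples["age"].copy()})
    return bdf, samples, gt


def simulate_aging_expression(
    spec: ExpressionSpec,
    n_samples: int = 200,
    age_range: tuple[float, float] = (1.0, 94.0),
    ages=None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate an aging cohort expression matrix on the log2 scale.

    If ``ages`` is given it overrides ``n_samples``/``age_range``.
    """
    params = gene_parameters(spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 11]))
    if ages is None:
        _check_range("age_range", age_range)
        ages = rng.uniform(*age_range, size=n_samples)
    else:
        ages = np.asarray(ages, dtype=float)
    noise_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 12]))
    vals = expression_profile(params, ages)
    if spec.noise_sd > 0:
        vals = vals + noise_rng.normal(0.0, spec.noise_sd, size=vals.shape)
    vals = np.clip(vals, 0.0, None)
    sample_ids = [f"exr{i:04d}" for i in range(len(ages))]
    edf = pd.DataFrame(vals, index=pd.Index(sample_ids, name="sample_id"), columns=params.index)
    edf.attrs["scale"] = "log2"
    samples = pd.DataFrame({"age": ages}, index=edf.index)
    gt = GroundTruth(
        {
            "gene_params": params,
            "ages": samples["age"].copy(),
            "effect_40y": gene_aging_effect_per_40y(params),
        }
    )
    return edf, samples, gt


def allocate_archetypes(n_genes: int, props=(0.67, 0.23, 0.10)) -> pd.Series:
    """Deterministic largest-remainder allocation of archetype labels."""
    props = np.asarray(props, dtype=float)
    raw = props * n_genes
    counts = np.floor(raw).astype(int)
    rem = n_genes - counts.sum()
    order = np.argsort(-(raw - counts))  # largest fractional part first
    for i in range(rem):
        counts[order[i % len(props)]] += 1
    labels = np.repeat(list(ARCHETYPES), counts)
    ids = [f"idgene{i:05d}" for i in range(n_genes)]
    return pd.Series(labels, index=pd.Index(ids, name="gene_id"), name="archetype")


def _identity_trajectory(
    course: CourseSpec, labels: pd.Series, baselines: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-archetype log2 level at (start, intermediate stages, end)."""
    n_tp = len(course.timepoints)
    delta = np.zeros((len(labels), n_tp))
    mid = slice(1, n_tp - 1)
    down = labels.to_numpy() == "temporarily_down"
    up = labels.to_numpy() == "temporarily_up"
    delta[down, mid] = course.down_delta
    delta[up, mid] = course.up_delta
    return {"delta": delta}


def simulate_reprogramming_course(
    cohort: CohortSpec,
    espec: ExpressionSpec,
    course: CourseSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the four-arm reprogramming time course.

    Returns (betas, expression, sample table, ground truth).  The CpG and
    aging-gene parameters are shared with cohorts built from the same
    ``cohort``/``espec`` (same seeds), so a clock trained on the reference
    cohort sees the same feature model here.  Treated samples' age-linked
    features take the values expected at ``age - rejuvenation_years``
    (clamped at 0 with a warning) at every post-baseline timepoint.
    Identity genes follow their archetype trajectory in the transient arm,
    stay flat in the control and failed arms, and are repressed at the end of
    the complete arm.
    """
    cpgs = cpg_parameters(cohort)
    genes = gene_parameters(espec)
    labels = allocate_archetypes(course.n_identity_genes, course.archetype_props)

    rng = np.random.default_rng(np.random.SeedSequence([int(course.seed), 20]))
    donor_ages = rng.uniform(*course.donor_age_range, size=course.n_donors)
    id_base = rng.uniform(*course.identity_baseline_range, size=course.n_identity_genes)
    noise_rng = np.random.default_rng(np.random.SeedSequence([int(course.seed), 21]))

    n_tp = len(course.timepoints)
    groups = dict(course.groups)
    rows = []
    eff_ages = []
    rejuv_applied = []
    clamped = False
    for group, rejuv in groups.items():
        for d in range(course.n_donors):
            age = donor_ages[d]
            for ti, tp in enumerate(course.timepoints):
                r = rejuv if ti > 0 else 0.0
                eff = age - r
                if eff < 0:
                    clamped = True
                    eff = 0.0
                rows.append(
                    {
                        "sample_id": f"{group}_d{d}_{tp}",
                        "group": group,
                        "donor": f"d{d}",
                        "timepoint": tp,
                        "timepoint_index": ti,
                        "age": age,
                    }
                )
                eff_ages.append(eff)
                rejuv_applied.append(age - eff)
    if clamped:
        warnings.warn(
            "rejuvenation_years exceeds donor age for some samples; clamped at age 0",
            stacklevel=2,
        )
    samples = pd.DataFrame(rows).set_index("sample_id")
    samples["effective_age"] = eff_ages
    samples["rejuvenation_applied"] = rejuv_applied
    eff_ages = np.asarray(eff_ages)

    betas = methylation_values(
        cpgs["baseline"].to_numpy(), cpgs["slope"].to_numpy(), eff_ages, cohort.noise_sd, noise_rng
    )
    bdf = pd.DataFrame(betas, index=samples.index, columns=cpgs.index)

    aging_expr = expression_profile(genes, eff_ages)
    if espec.noise_sd > 0:
        aging_expr = aging_expr + noise_rng.normal(0.0, espec.noise_sd, size=aging_expr.shape)

    # identity genes: baseline + archetype delta at interior timepoints
    delta = _identity_trajectory(course, labels, id_base)["delta"]
    id_expr = np.zeros((len(samples), course.n_identity_genes))
    lab = labels.to_numpy()
    for si, (grp, ti) in enumerate(zip(samples["group"], samples["timepoint_index"])):
        lev = id_base.copy()
        if grp == "transient":
            lev = lev + delta[:, ti]
        elif grp == "complete":
            if 0 < ti < n_tp - 1:
                lev = lev + delta[:, ti]
            elif ti == n_tp - 1:
                lev = lev + course.down_delta  # fibroblast identity repressed in iPSCs
        # negative_control and failed arms keep their fibroblast program
        id_expr[si] = lev
    if course.identity_noise_sd > 0:
        id_expr = id_expr + noise_rng.normal(0.0, course.identity_noise_sd, size=id_expr.shape)

    expr = np.clip(np.concatenate([aging_expr, id_expr], axis=1), 0.0, None)
    edf = pd.DataFrame(
        expr, index=samples.index, columns=list(genes.index) + list(labels.index)
    )
    edf.attrs["scale"] = "log2"

    gt = GroundTruth(
        {
            "cpg_params": cpgs,
            "gene_params": genes,
            "effect_40y": gene_aging_effect_per_40y(genes),
            "identity_labels": labels,
            "donor_ages": pd.Series(donor_ages, index=[f"d{i}" for i in range(course.n_donors)]),
            "rejuvenation_per_sample": samples["rejuvenation_applied"].copy(),
            "effective_ages": samples["effective_age"].copy(),
        }
    )
    return bdf, edf, samples, gt


# ---------------------------------------------------------------------------
# regulatory elements (for the identity-memory analyses)
# ---------------------------------------------------------------------------


def simulate_regulatory_elements(
    gene_params: pd.DataFrame,
    hyper_fraction: float = 0.5,
    seed: int = 3,
) -> pd.DataFrame:
    """Synthetic promoter/enhancer annotation around planted gene TSSs.

    Each gene gets a promoter straddling its TSS and an enhancer within the
    1 Mb linking window.  Enhancers are active in fibroblasts; a
    ``hyper_fraction`` of them become repressed in iPSCs (the arm expected to
    gain methylation during complete reprogramming).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, (gid, g) in enumerate(gene_params.iterrows()):
        tss = int(g["tss"])
        rows.append(
            {
                "element_id": f"prom_{gid}",
                "chrom": g["chrom"],
                "start": max(tss - 400, 0),
                "end": tss + 400,
                "class": "promoter",
                "activity_fibroblast": "active",
                "activity_ipsc": "active",
            }
        )
        offset = int(rng.integers(5_000, 500_000)) * int(rng.choice([-1, 1]))
        start = max(tss + offset, 0)
        lost = rng.uniform() < hyper_fraction
        rows.append(
            {
                "element_id": f"enh_{gid}",
                "chrom": g["chrom"],
                "start": start,
                "end": start + 1500,
                "class": "enhancer",
                "activity_fibroblast": "active",
                "activity_ipsc": "repressed" if lost else "active",
            }
        )
    return pd.DataFrame(rows).set_index("element_id")


def simulate_element_methylation(
    elements: pd.DataFrame,
    group_sizes: Mapping[str, int] | None = None,
    cpgs_per_element: int = 3,
    base_level: float = 0.15,
    gain: float = 0.5,
    noise_sd: float = 0.03,
    seed: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Methylation over regulatory-element CpGs with planted enhancer memory.

    Places ``cpgs_per_element`` CpGs inside every element and draws betas
    around ``base_level`` (active somatic elements are hypomethylated).  In
    the ``ipsc`` group, enhancers whose activity is lost
    (``activity_ipsc != 'active'``) gain ``gain`` beta fraction — the
    epigenetic change that transient reprogramming does *not* make, which is
    what the memory analysis counts.  Returns (betas samples x CpGs, CpG
    location table, sample table with a ``group`` column).
    """
    if group_sizes is None:
        group_sizes = {"fibroblast": 4, "transient": 4, "ipsc": 4}
    rng = np.random.default_rng(seed)
    loc_rows = []
    hyper = []
    for eid, el in elements.iterrows():
        span = int(el["end"]) - int(el["start"])
        step = max(span // (cpgs_per_element + 1), 1)
        lost = el["class"] == "enhancer" and el.get("activity_ipsc") != "active"
        for k in range(cpgs_per_element):
            loc_rows.append(
                {
                    "cpg_id": f"{eid}_cpg{k}",
                    "chrom": el["chrom"],
                    "pos": int(el["start"]) + (k + 1) * step,
                }
            )
            hyper.append(lost)
    locations = pd.DataFrame(loc_rows).set_index("cpg_id")
    hyper = np.asarray(hyper)

    sample_rows = []
    betas = []
    for group, n in group_sizes.items():
        for i in range(n):
            level = np.full(len(locations), base_level)
            if group == "ipsc":
                level = level + np.where(hyper, gain, 0.0)
            betas.append(np.clip(level + rng.normal(0, noise_sd, len(level)), 0, 1))
            sample_rows.append({"sample_id": f"{group}_{i}", "group": group})
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    bdf = pd.DataFrame(betas, index=samples.index, columns=locations.index)
    return bdf, locations, samples


# ---------------------------------------------------------------------------
# image simulators
# ---------------------------------------------------------------------------


@dataclass
class MaskSeries:
    """Time-ordered binary masks with physical calibration."""

    frames: np.ndarray  # (n_frames, height, width) bool
    pixel_size: float  # um / pixel
    frame_interval: float  # hours
    wound_side: str = "right"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=bool)
        if self.frames.ndim != 3:
            raise ConfigurationError("MaskSeries frames must be (n, h, w)")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ConfigurationError("pixel_size and frame_interval must be > 0")

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass
class LabelMask:
    """2D integer label image (0 = background) with pixel calibration."""

    labels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ConfigurationError("LabelMask must be 2D")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be > 0")
        if self.labels.min() < 0:
            raise ConfigurationError("labels must be non-negative")


def simulate_wound_series(
    speed: float,
    gap_width: float = 500.0,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0 / 3.0,
    n_frames: int = 61,
    noise: float = 0.0,
    frame_shape: tuple[int, int] = (150, 800),
    seed: int = 0,
) -> tuple[MaskSeries, GroundTruth]:
    """Simulate a scratch-assay mask series with the wound on the right.

    The cell-covered region initially spans the left of the frame, leaving a
    ``gap_width`` um wound; its right edge advances ``speed`` um/h.  ``noise``
    is the probability of an i.i.d. pixel flip (salt-and-pepper).
    """
    if speed < 0:
        raise ConfigurationError("speed must be >= 0")
    if not (0 <= noise < 1):
        raise ConfigurationError("noise must be in [0, 1)")
    h, w = frame_shape
    gap_px = int(round(gap_width / pixel_size))
    if gap_px >= w:
        raise ConfigurationError(
            f"gap ({gap_px} px) is wider than the frame ({w} px)"
        )
    edge0 = w - gap_px - 1
    rng = np.random.default_rng(seed)
    frames = np.zeros((n_frames, h, w), dtype=bool)
    edges = []
    for k in range(n_frames):
        e = min(edge0 + int(round(speed * k * frame_interval / pixel_size)), w - 1)
        frames[k, :, : e + 1] = True
        edges.append(e)
    if noise > 0:
        flips = rng.uniform(size=frames.shape) < noise
        frames ^= flips
    series = MaskSeries(frames, pixel_size=pixel_size, frame_interval=frame_interval)
    gt = GroundTruth(
        {
            "speed_um_per_h": float(speed),
            "edge_columns": np.asarray(edges),
            "gap_width_um": float(gap_width),
        }
    )
    return series, gt


def simulate_cell_masks(
    n_cells: int = 10,
    major_range: tuple[float, float] = (20.0, 40.0),
    minor_range: tuple[float, float] = (8.0, 16.0),
    intensity_levels: tuple[float, ...] = (50.0, 100.0, 150.0, 200.0),
    image_shape: tuple[int, int] = (512, 512),
    pixel_size: float = 1.0,
    rotate: bool = True,
    max_tries: int = 500,
    seed: int = 0,
) -> tuple[LabelMask, np.ndarray, GroundTruth]:
    """Rasterize non-overlapping ellipses with recorded axes and intensities.

    Axis ranges are full lengths in um.  Returns (label mask, intensity image,
    ground truth with per-label major/minor axes, roundness = major/minor and
    intensity).  Raises :class:`PlacementError` if cells cannot be placed
    without overlap within ``max_tries`` attempts each.
    """
    lo, hi = _check_range("major_range", major_range)
    if lo <= 0 or _check_range("minor_range", minor_range)[0] <= 0:
        raise ConfigurationError("axis lengths must be > 0")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    labels = np.zeros((h, w), dtype=np.int32)
    intensity = np.zeros((h, w), dtype=float)
    records = []
    for lab in range(1, n_cells + 1):
        major = rng.uniform(*major_range)
        minor = rng.uniform(*minor_range)
        if minor > major:
            major, minor = minor, major
        level = float(rng.choice(intensity_levels))
        theta = rng.uniform(0, np.pi) if rotate else 0.0
        a_px = major / (2 * pixel_size)
        b_px = minor / (2 * pixel_size)
        placed = False
        for _ in range(max_tries):
            margin = int(np.ceil(a_px)) + 2
            if 2 * margin >= min(h, w):
                raise ConfigurationError("cells too large for the image")
            r0 = rng.integers(margin, h - margin)
            c0 = rng.integers(margin, w - margin)
            rr, cc = draw_ellipse(r0, c0, a_px, b_px, shape=(h, w), rotation=theta)
            if len(rr) < 4:
                continue
            if np.any(labels[rr, cc] != 0):
                continue
            labels[rr, cc] = lab
            intensity[rr, cc] = level
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {lab} without overlap after {max_tries} tries"
            )
        records.append(
            {
                "label": lab,
                "major_um": major,
                "minor_um": minor,
                "roundness": major / minor,
                "intensity": level,
                "rotation_rad": theta,
            }
        )
    shapes = pd.DataFrame(records).set_index("label")
    gt = GroundTruth({"shapes": shapes})
    return LabelMask(labels, pixel_size=pixel_size), intensity, gt
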