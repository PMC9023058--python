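"""Transcriptome age prediction and the aging-trajectory PCA.

Two trainable transcriptome clocks are provided, both regressing on the
piecewise log/linear transformed age (see :mod:`rejuvkit.clocks`):

- ``forest``: random-forest regression with a small grid search over the
  features-per-split fraction (5 settings) and repeated k-fold
  cross-validation for the error estimate;
- ``binarized_linear``: gene expression is binarized against per-gene
  training medians and an elastic net is fitted to the binary matrix, in the
  style of binarized transcriptome clocks.

Reported errors are median absolute errors in *years* on back-transformed
held-out predictions.

The aging trajectory selects genes whose expression has a Bonferroni-
significant Pearson correlation with age, z-scores them, and takes the first
principal component, oriented to increase with age.  Age is then inferred
for query samples from an ordinary-least-squares fit of age on PC1 over the
reference cohort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold, RepeatedKFold, cross_val_score

from .clocks import AgeTransform
from .errors import ConfigurationError, CoverageError, DataError, SelectionError

logger = logging.getLogger(__name__)

CLOCK_KINDS = ("forest", "binarized_linear")


def validate_expression_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    if expr.index.duplicated().any():
        raise DataError("duplicate sample ids in expression matrix")
    if expr.columns.duplicated().any():
        raise DataError("duplicate gene ids in expression matrix")
    if (expr.to_numpy(dtype=float) < 0).any():
        raise DataError("expression values must be >= 0")
    return expr


def batch_adjust(
    reference: pd.DataFrame, target: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene location/scale adjustment of ``target`` onto ``reference``.

    Both matrices must be on the log2 scale.  For every shared gene the
    target batch is recentred and rescaled to the reference mean and standard
    deviation; zero-variance target genes are recentred only.  Genes absent
    from either matrix are dropped (count logged).  This is a deliberately
    simple documented alternative to empirical-Bayes batch correction.
    """
    shared = reference.columns.intersection(target.columns)
    if len(shared) == 0:
        raise DataError("no shared genes between reference and target")
    dropped = (len(reference.columns) - len(shared)) + (len(target.columns) - len(shared))
    if dropped:
        logger.info("batch_adjust: dropped %d genes absent from one batch", dropped)
    ref = reference[shared]
    tgt = target[shared]
    mu_r = ref.mean(axis=0)
    sd_r = ref.std(axis=0, ddof=0)
    mu_t = tgt.mean(axis=0)
    sd_t = tgt.std(axis=0, ddof=0)
    scale = np.where(sd_t.to_numpy() > 0, sd_r.to_numpy() / np.where(sd_t > 0, sd_t, 1.0), 1.0)
    adj = (tgt - mu_t) * scale + mu_r
    adj.attrs["scale"] = "log2"
    out_ref = ref.copy()
    out_ref.attrs["scale"] = "log2"
    return out_ref, adj


def binarize_expression(expr: pd.DataFrame, thresholds=None) -> pd.DataFrame:
    """Binarize expression: 1 iff value > per-gene threshold (ties -> 0).

    ``thresholds`` may be a per-gene Series or None, in which case the
    per-gene median of ``expr`` is used (a training-time policy: fit the
    thresholds on the training cohort and reuse them on queries).
    """
    if thresholds is None:
        thresholds = expr.median(axis=0)
    thresholds = pd.Series(thresholds, dtype=float)
    missing = expr.columns.difference(thresholds.index)
    if len(missing):
        raise ConfigurationError(
            f"no binarization threshold for {len(missing)} genes (e.g. {missing[0]!r})"
        )
    th = thresholds.reindex(expr.columns)
    return (expr > th).astype(int)


@dataclass
class TranscriptClock:
    """A fitted transcriptome age predictor."""

    kind: str
    genes: pd.Index
    estimator: object
    transform: AgeTransform
    cv_mae: float
    training_means: pd.Series
    thresholds: pd.Series | None = None
    best_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLOCK_KINDS:
            raise ConfigurationError(f"unknown clock kind {self.kind!r}")
        if len(self.genes) == 0:
            raise ConfigurationError("gene list must be non-empty")


def _design_matrix(clock: TranscriptClock, expr: pd.DataFrame) -> np.ndarray:
    X = expr.reindex(columns=clock.genes)
    n_missing = int(X.isna().any(axis=0).sum())
    if n_missing:
        logger.warning("imputing %d missing clock genes by training means", n_missing)
        X = X.fillna(clock.training_means.reindex(clock.genes))
    if clock.kind == "binarized_linear":
        X = binarize_expression(X, clock.thresholds)
    return X.to_numpy(dtype=float)


def train_transcript_clock(
    expr: pd.DataFrame,
    ages,
    kind: str = "forest",
    cv: tuple[int, int] | None = (10, 3),
    transform: AgeTransform | None = None,
    seed: int = 0,
    n_estimators: int = 100,
) -> TranscriptClock:
    """Train a transcriptome clock on transformed age.

    ``cv = (folds, repeats)`` controls the held-out error estimate
    (median absolute error in years, stored as ``cv_mae``); pass None to skip
    it.  The forest kind tunes the features-per-split fraction over a grid of
    5 settings by 3-fold cross-validation before the final fit.
    """
    if kind not in CLOCK_KINDS:
        raise ConfigurationError(f"unknown clock kind {kind!r}")
    validate_expression_matrix(expr)
    transform = transform or AgeTransform()
    ages = np.asarray(ages, dtype=float)
    if len(ages) != len(expr):
        raise DataError("ages and expression matrix must align")
    if len(ages) < 4:
        raise DataError("too few samples to train a transcriptome clock")
    if np.any(~np.isfinite(ages)):
        raise DataError("ages must be finite")

    y = transform.transform(ages)
    means = expr.mean(axis=0)
    thresholds = expr.median(axis=0) if kind == "binarized_linear" else None
    if kind == "binarized_linear":
        X = binarize_expression(expr, thresholds).to_numpy(dtype=float)
    else:
        X = expr.to_numpy(dtype=float)

    constant_target = np.ptp(y) == 0

    def make_estimator(params: dict):
        if kind == "forest":
            return RandomForestRegressor(
                n_estimators=n_estimators, random_state=seed, n_jobs=1, **params
            )
        return ElasticNetCV(
            l1_ratio=0.5,
            alphas=np.logspace(-4, 0, 15),
            cv=KFold(min(5, max(2, len(ages) // 2)), shuffle=True, random_state=seed),
            max_iter=20000,
            random_state=seed,
        )

    best_params: dict = {}
    if kind == "forest" and not constant_target:
        grid = [0.1, 0.3, 0.5, 0.7, 1.0]  # features-per-split fractions, 5 settings
        best_score = -np.inf
        for mf in grid:
            est = RandomForestRegressor(
                n_estimators=max(25, n_estimators // 2),
                max_features=mf,
                random_state=seed,
                n_jobs=1,
            )
            score = cross_val_score(
                est, X, y, cv=KFold(3, shuffle=True, random_state=seed),
                scoring="neg_mean_squared_error",
            ).mean()
            if score > best_score:
                best_score, best_params = score, {"max_features": mf}

    final = make_estimator(best_params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)

    cv_mae = 0.0
    if cv is not None and not constant_target:
        folds, repeats = cv
        folds = min(folds, len(ages) // 2)
        splitter = RepeatedKFold(n_splits=max(2, folds), n_repeats=repeats, random_state=seed)
        abs_err = []
        for tr, te in splitter.split(X):
            est = make_estimator(best_params)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X[tr], y[tr])
            pred = transform.inverse(est.predict(X[te]))
            abs_err.extend(np.abs(np.asarray(pred) - ages[te]))
        cv_mae = float(np.median(abs_err))

    return TranscriptClock(
        kind=kind,
        genes=expr.columns,
        estimator=final,
        transform=transform,
        cv_mae=cv_mae,
        training_means=means,
        thresholds=thresholds,
        best_params=best_params,
    )


def predict_transcript_age(
    clock: TranscriptClock, expr: pd.DataFrame, coverage_min: float = 0.9
) -> pd.Series:
    """Predict age in years for each sample of a query expression matrix.

    At least ``coverage_min`` of the clock genes must be present; missing
    genes are imputed by their training means (logged).
    """
    if len(expr) == 0:
        return pd.Series(dtype=float, name="predicted_age")
    validate_expression_matrix(expr)
    present = clock.genes.intersection(expr.columns)
    coverage = len(present) / len(clock.genes)
    if coverage < coverage_min:
        raise CoverageError(
            f"only {coverage:.1%} of clock genes present (< {coverage_min:.0%})"
        )
    X = _design_matrix(clock, expr)
    pred = clock.transform.inverse(clock.estimator.predict(X))
    return pd.Series(np.asarray(pred), index=expr.index, name="predicted_age")


@dataclass
class TrajectoryModel:
    """Aging-trajectory PCA fitted on a reference cohort."""

    genes: pd.Index
    gene_stats: pd.DataFrame  # per selected gene: r, p, p_bonferroni
    means: pd.Series
    sds: pd.Series
    loadings: np.ndarray  # PC1 loading vector over selected genes
    age_fit: tuple[float, float]  # (intercept, slope) of age ~ PC1
    explained_variance_ratio: float


def _pearson_by_gene(X: np.ndarray, ages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-column Pearson r and two-sided p against age."""
    n = len(ages)
    a = ages - ages.mean()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((Xc**2).sum(axis=0) * (a**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * a[:, None]).sum(axis=0) / denom
    r = np.clip(np.where(np.isfinite(r), r, 0.0), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p


def fit_aging_trajectory(
    expr: pd.DataFrame, ages, alpha: float = 0.05
) -> TrajectoryModel:
    """Select Bonferroni-significant age-correlated genes and fit the PC1 axis.

    Genes with ``p * G <= alpha`` (G genes tested) are kept, z-scored with
    the reference mean/sd, and decomposed by PCA.  PC1 is oriented so its
    correlation with age is positive; an OLS fit of age on PC1 provides the
    age-equivalent mapping for query samples.
    """
    validate_expression_matrix(expr)
    ages = np.asarray(ages, dtype=float)
    if len(expr) < 3:
        raise DataError("need at least 3 samples for the trajectory fit")
    if np.ptp(ages) == 0:
        raise DataError("ages must vary")

    X = expr.to_numpy(dtype=float)
    r, p = _pearson_by_gene(X, ages)
    G = X.shape[1]
    p_bonf = np.minimum(p * G, 1.0)
    keep = p_bonf <= alpha
    if not keep.any():
        diag = pd.DataFrame({"r": r, "p": p, "p_bonferroni": p_bonf}, index=expr.columns)
        raise SelectionError(
            f"no gene passed Bonferroni selection at alpha={alpha}; "
            f"min adjusted p = {diag['p_bonferroni'].min():.3g}"
        )
    genes = expr.columns[keep]
    stats_df = pd.DataFrame(
        {"r": r[keep], "p": p[keep], "p_bonferroni": p_bonf[keep]}, index=genes
    )

    sub = X[:, keep]
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (sub - mu) / sd
    # PC1 via SVD of the centred (already z-scored) matrix
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    loading = Vt[0]
    scores = Z @ loading
    if np.corrcoef(scores, ages)[0, 1] < 0:
        loading = -loading
        scores = -scores
    slope, intercept = np.polyfit(scores, ages, 1)
    evr = float(s[0] ** 2 / (s**2).sum())
    return TrajectoryModel(
        genes=genes,
        gene_stats=stats_df,
        means=pd.Series(mu, index=genes),
        sds=pd.Series(sd, index=genes),
        loadings=loading,
        age_fit=(float(intercept), float(slope)),
        explained_variance_ratio=evr,
    )


def project_onto_trajectory(model: TrajectoryModel, expr: pd.DataFrame) -> pd.DataFrame:
    """Project query samples onto the reference PC1 and infer their age.

    Missing trajectory genes are imputed by the reference mean (logged).
    Returns a DataFrame with columns ``pc1`` and ``inferred_age``.
    """
    X = expr.reindex(columns=model.genes)
    n_missing = int(X.isna().any(axis=0).sum())
    if n_missing:
        logger.warning("projection: imputing %d trajectory genes by reference means", n_missing)
        X = X.fillna(model.means)
    Z = (X.to_numpy(dtype=float) - model.means.to_numpy()) / model.sds.to_numpy()
    scores = Z @ model.loadings
    intercept, slope = model.age_fit
    return pd.DataFrame(
        {"pc1": scores, "inferred_age": intercept + slope * scores}, index=expr.index
    )
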