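"""Transformed-age machinery and a generic linear methylation clock engine.

Age clocks in this package are linear predictors over CpG beta values.  Most
published clocks regress not on chronological age directly but on a
*transformed age* that is logarithmic before adulthood (to account for the
accelerated pace of molecular aging during childhood) and linear afterwards:

    F(a) = log_b(a + 1) - log_b(adult_age + 1)      if a <= adult_age
    F(a) = (a - adult_age) / (adult_age + 1)        if a >  adult_age

with ``adult_age = 20`` years by convention.  ``F`` is continuous and strictly
increasing, with ``F(adult_age) = 0``, so it has a closed-form inverse used to
report predictions in years.

A :class:`ClockModel` is agnostic about which published coefficient set it
carries: the engine accepts any feature-weight table (age clocks, telomere
length clocks, ...) and only the ``output_kind`` decides whether the raw linear
score is passed through the inverse age transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .errors import ConfigurationError, CoverageError, DataError

logger = logging.getLogger(__name__)

OUTPUT_KINDS = ("transformed_age", "years", "length_kb")
MISSING_POLICIES = ("impute_training_mean", "impute_value", "drop_feature")


@dataclass(frozen=True)
class AgeTransform:
    """Piecewise log/linear rescaling of chronological age around ``adult_age``."""

    adult_age: float = 20.0
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if not (self.adult_age > 0):
            raise ConfigurationError(f"adult_age must be > 0, got {self.adult_age}")
        if not (self.log_base > 1):
            raise ConfigurationError(f"log_base must be > 1, got {self.log_base}")

    def transform(self, age):
        """Map chronological age (years) to the transformed-age scale.

        Accepts scalars or arrays; negative ages are a domain error.
        """
        a = np.asarray(age, dtype=float)
        if np.any(~np.isfinite(a)) or np.any(a < 0):
            raise ValueError("ages must be finite and >= 0")
        lb = np.log(self.log_base)
        adult = self.adult_age
        young = (np.log(a + 1.0) - np.log(adult + 1.0)) / lb
        old = (a - adult) / (adult + 1.0)
        out = np.where(a <= adult, young, old)
        return float(out) if np.isscalar(age) or np.ndim(age) == 0 else out

    def inverse(self, t_value):
        """Map transformed age back to years (exact inverse of :meth:`transform`)."""
        t = np.asarray(t_value, dtype=float)
        if np.any(~np.isfinite(t)):
            raise ValueError("transformed-age values must be finite")
        adult = self.adult_age
        young = (adult + 1.0) * np.power(self.log_base, t) - 1.0
        old = t * (adult + 1.0) + adult
        out = np.where(t <= 0, young, old)
        return float(out) if np.isscalar(t_value) or np.ndim(t_value) == 0 else out


def transform_age(age, t: AgeTransform | None = None):
    """Functional form of :meth:`AgeTransform.transform`."""
    return (t or AgeTransform()).transform(age)


def inverse_transform_age(t_value, t: AgeTransform | None = None):
    """Functional form of :meth:`AgeTransform.inverse`."""
    return (t or AgeTransform()).inverse(t_value)


@dataclass
class ClockModel:
    """Named linear predictor over features, with an intercept.

    ``output_kind`` controls interpretation of the raw linear score:
    ``transformed_age`` scores are passed through the inverse age transform,
    while ``years`` and ``length_kb`` scores are reported directly.
    ``training_means`` (optional) back the default missing-feature imputation.
    """

    name: str
    intercept: float
    weights: pd.Series
    output_kind: str = "transformed_age"
    training_means: pd.Series | None = None
    transform: AgeTransform = field(default_factory=AgeTransform)

    def __post_init__(self) -> None:
        self.weights = pd.Series(self.weights, dtype=float)
        if self.weights.empty:
            raise ConfigurationError("clock weights must be non-empty")
        if self.weights.index.duplicated().any():
            raise ConfigurationError("clock feature ids must be unique")
        if self.output_kind not in OUTPUT_KINDS:
            raise ConfigurationError(
                f"unknown output_kind {self.output_kind!r}; expected one of {OUTPUT_KINDS}"
            )
        if self.training_means is not None:
            self.training_means = pd.Series(self.training_means, dtype=float)

    @property
    def features(self) -> pd.Index:
        return self.weights.index


def validate_beta_matrix(betas: pd.DataFrame) -> pd.DataFrame:
    """Check a samples x CpGs beta matrix: unique ids, values in [0,1] or NaN."""
    if betas.index.duplicated().any():
        raise DataError("duplicate sample ids in beta matrix")
    if betas.columns.duplicated().any():
        raise DataError("duplicate CpG ids in beta matrix")
    vals = betas.to_numpy(dtype=float)
    bad = (vals < 0) | (vals > 1)
    if np.any(bad & ~np.isnan(vals)):
        raise DataError("beta values outside [0, 1]")
    return betas


def apply_clock(
    model: ClockModel,
    betas: pd.DataFrame,
    missing_policy: str = "impute_training_mean",
    impute_value: float | None = None,
) -> pd.DataFrame:
    """Apply a linear clock to a samples x CpGs beta matrix.

    Returns a DataFrame indexed by sample id with columns ``raw_score``,
    ``predicted`` (years or kb, depending on ``model.output_kind``) and
    ``n_missing_features``.  Features absent from the matrix, or NaN for a
    given sample, are handled per ``missing_policy``:

    - ``impute_training_mean``: use the model's stored training means, falling
      back to the cohort mean of the present features with a logged warning;
    - ``impute_value``: substitute a fixed beta value;
    - ``drop_feature``: exclude the feature's term from that sample's score.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ConfigurationError(f"unknown missing_policy {missing_policy!r}")
    if missing_policy == "impute_value" and impute_value is None:
        raise ConfigurationError("impute_value policy requires an impute_value")
    validate_beta_matrix(betas)

    feats = model.features
    present = feats.intersection(betas.columns)
    if len(present) == 0:
        raise CoverageError(
            f"none of the {len(feats)} model features are present in the matrix"
        )
    n_absent = len(feats) - len(present)
    if n_absent:
        logger.warning(
            "clock %s: %d of %d features missing from matrix", model.name, n_absent, len(feats)
        )

    X = betas.reindex(columns=feats).to_numpy(dtype=float)
    missing = np.isnan(X)
    n_missing = missing.sum(axis=1)

    if missing_policy == "impute_training_mean":
        if model.training_means is not None:
            fill = model.training_means.reindex(feats).to_numpy(dtype=float)
        else:
            fill = np.full(len(feats), np.nan)
        # fall back to cohort means for features without a stored training mean
        no_mean = np.isnan(fill)
        if np.any(no_mean & missing.any(axis=0)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cohort = np.nanmean(X, axis=0)
            cohort = np.where(np.isnan(cohort), 0.5, cohort)
            fill = np.where(no_mean, cohort, fill)
            logger.warning(
                "clock %s: no training means for some missing features; used cohort means",
                model.name,
            )
        X = np.where(missing, fill[None, :], X)
    elif missing_policy == "impute_value":
        X = np.where(missing, float(impute_value), X)
    else:  # drop_feature
        X = np.where(missing, 0.0, X)  # weight * 0 contributes nothing

    w = model.weights.to_numpy(dtype=float)
    raw = model.intercept + X @ w
    if model.output_kind == "transformed_age":
        predicted = model.transform.inverse(raw)
    else:
        predicted = raw
    if not np.all(np.isfinite(predicted)):
        raise DataError("non-finite clock prediction")
    return pd.DataFrame(
        {"raw_score": raw, "predicted": predicted, "n_missing_features": n_missing},
        index=betas.index,
    )


def train_linear_clock(
    betas: pd.DataFrame,
    ages,
    l1_ratio: float = 0.5,
    alphas=None,
    transform: AgeTransform | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    name: str = "trained_clock",
) -> tuple[ClockModel, dict]:
    """Train an elastic-net clock of transformed age on beta values.

    Regularization strength is selected by ``cv_folds``-fold cross-validation
    over a small alpha grid.  The returned ``cv_summary`` reports the held-out
    median absolute error in years of the back-transformed predictions
    (``medae_years``), computed by an outer cross-validation at the selected
    penalty.  The model stores per-feature training means for imputation.
    """
    transform = transform or AgeTransform()
    validate_beta_matrix(betas)
    ages = np.asarray(ages, dtype=float)
    if len(ages) != len(betas):
        raise DataError("ages and beta matrix must have the same number of samples")
    if len(ages) < 2:
        raise DataError("need at least 2 samples to train a clock")
    if np.any(~np.isfinite(ages)):
        raise DataError("ages must be finite")

    X = betas.to_numpy(dtype=float)
    if np.isnan(X).any():
        col_means = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_means[None, :], X)
        logger.warning("training matrix contains missing betas; imputed column means")
    means = pd.Series(X.mean(axis=0), index=betas.columns)

    if np.ptp(ages) == 0:
        warnings.warn("constant ages: returning an intercept-only clock", stacklevel=2)
        t0 = transform.transform(float(ages[0]))
        model = ClockModel(
            name=name,
            intercept=float(t0),
            weights=pd.Series(0.0, index=betas.columns),
            output_kind="transformed_age",
            training_means=means,
            transform=transform,
        )
        return model, {"medae_years": 0.0, "alpha": 0.0, "l1_ratio": l1_ratio}

    folds = min(cv_folds, len(ages) // 2)
    if folds < 2:
        folds = 2
    y = transform.transform(ages)
    if alphas is None:
        alphas = np.logspace(-4, 0, 20)
    enet = ElasticNetCV(
        l1_ratio=l1_ratio,
        alphas=alphas,
        cv=KFold(folds, shuffle=True, random_state=seed),
        max_iter=20000,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enet.fit(X, y)
    alpha = float(enet.alpha_)

    # held-out error at the selected penalty
    abs_err = []
    for tr, te in KFold(folds, shuffle=True, random_state=seed + 1).split(X):
        est = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=20000, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X[tr], y[tr])
        pred = transform.inverse(est.predict(X[te]))
        abs_err.extend(np.abs(np.asarray(pred) - ages[te]))
    medae = float(np.median(abs_err))

    model = ClockModel(
        name=name,
        intercept=float(enet.intercept_),
        weights=pd.Series(enet.coef_, index=betas.columns),
        output_kind="transformed_age",
        training_means=means,
        transform=transform,
    )
    summary = {
        "medae_years": medae,
        "alpha": alpha,
        "l1_ratio": l1_ratio,
        "n_nonzero": int(np.sum(enet.coef_ != 0)),
        "cv_folds": folds,
    }
    return model, summary
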