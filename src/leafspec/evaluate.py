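"""Train/test splitting, calibration metrics and model grading.

Metrics follow standard chemometric reporting for leaf-trait calibration:

* RMSE = sqrt(mean((yhat - y)^2))
* MAPE(%) = 100 * mean(|yhat - y|) / mean(y)  — note the single division by
  the mean of the measured values, not the textbook per-sample percentage
  error; the two definitions collide in name but differ numerically.
* RPD = SD(measured) / RMSE, with the sample (n-1) standard deviation.
* R^2: primarily the squared Pearson correlation between measured and
  predicted (affine-invariant, as used for measured-vs-estimated scatter
  reporting); the 1 - SSres/SStot variant is co-reported.

RPD grades a calibration into four tiers: Excellent (> 3.5, quantitative use),
Very Good (2.5-3.5), Good (1.5-2.5, qualitative screening), Fair (< 1.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from enum import IntEnum

import numpy as np

__all__ = [
    "RPDCategory",
    "EvalReport",
    "train_test_split",
    "rmse",
    "mape",
    "rpd",
    "classify_rpd",
    "r_squared",
    "evaluate_predictions",
    "pca_scores",
]


class RPDCategory(IntEnum):
    """Model quality tiers by RPD; ordering Fair < Good < VeryGood < Excellent."""

    Fair = 0
    Good = 1
    VeryGood = 2
    Excellent = 3


def train_test_split(sample_ids, train_fraction: float = 0.6, seed: int = 0):
    """Seeded random partition into train/test id lists.

    Train size is round(fraction * n); the split is disjoint and exhaustive.
    """
    ids = list(sample_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    train = [ids[i] for i in perm[:n_train]]
    test = [ids[i] for i in perm[n_train:]]
    return train, test


def _pair(measured, predicted):
    y = np.asarray(measured, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty input")
    if y.size != yhat.size:
        raise ValueError(f"length mismatch: {y.size} measured vs {yhat.size} predicted")
    return y, yhat


def rmse(measured, predicted) -> float:
    y, yhat = _pair(measured, predicted)
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def mape(measured, predicted) -> float:
    """Mean absolute error as a percentage of the mean measured value."""
    y, yhat = _pair(measured, predicted)
    ybar = y.mean()
    if ybar == 0:
        raise ValueError("mean of measured values is zero; MAPE undefined")
    return float(100.0 * np.mean(np.abs(yhat - y)) / ybar)


def rpd(measured, predicted) -> float:
    """SD(measured) / RMSE; +inf when predictions are exact."""
    y, yhat = _pair(measured, predicted)
    if y.size < 2:
        raise ValueError("RPD needs at least 2 measured values")
    sd = float(np.std(y, ddof=1))
    if sd == 0:
        raise ValueError("measured values are constant; RPD undefined")
    err = rmse(y, yhat)
    if err == 0:
        return math.inf
    return sd / err


def classify_rpd(value: float) -> RPDCategory:
    """Grade an RPD value; exact tier boundaries resolve downward."""
    if not value > 0:
        raise ValueError("RPD must be positive")
    if value > 3.5:
        return RPDCategory.Excellent
    if value > 2.5:
        return RPDCategory.VeryGood
    if value > 1.5:
        return RPDCategory.Good
    return RPDCategory.Fair


def r_squared(measured, predicted, definition: str = "correlation") -> float:
    """Coefficient of determination of measured vs predicted.

    ``definition="correlation"``: squared Pearson r (affine-invariant).
    ``definition="ss"``: 1 - SSres/SStot.
    """
    y, yhat = _pair(measured, predicted)
    if y.size < 2:
        raise ValueError("R^2 needs at least 2 pairs")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("measured values are constant; R^2 undefined")
    if definition == "ss":
        return 1.0 - float(np.sum((yhat - y) ** 2)) / sst
    if definition != "correlation":
        raise ValueError(f"unknown R^2 definition {definition!r}")
    if np.std(yhat) == 0:
        return 0.0
    r = float(np.corrcoef(y, yhat)[0, 1])
    return r * r


@dataclass
class EvalReport:
    """Test-set performance of one calibration for one trait."""

    trait: str
    n_test: int
    r2: float
    rmse: float
    mape_pct: float
    rpd: float
    category: str
    r2_ss: float  # the 1 - SSres/SStot variant, co-reported
    rpd_infinite: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_predictions(trait: str, measured, predicted) -> EvalReport:
    """Compute the full metric panel for one trait on one split."""
    y, yhat = _pair(measured, predicted)
    value = rpd(y, yhat)
    infinite = math.isinf(value)
    return EvalReport(
        trait=trait,
        n_test=int(y.size),
        r2=r_squared(y, yhat),
        rmse=rmse(y, yhat),
        mape_pct=mape(y, yhat),
        rpd=value,
        category=classify_rpd(value).name if not infinite else RPDCategory.Excellent.name,
        r2_ss=r_squared(y, yhat, definition="ss"),
        rpd_infinite=infinite,
    )


def pca_scores(values: np.ndarray, n_components: int = 2):
    """Principal-component scores of a sample-by-band matrix.

    Column-centered SVD; returns (scores, explained variance fractions) with
    fractions non-increasing and summing to <= 1.
    """
    X = np.atleast_2d(np.asarray(values, dtype=float))
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}"
        )
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    total = float(np.sum(s**2))
    fractions = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return scores, fractions
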