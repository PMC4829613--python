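"""Two-stage cross-individual pain prediction with leave-one-individual-out CV.

Stage 1 is a one-dimensional Gaussian equal-variance LDA separating low-pain
(NRS <= 4) from high-pain (NRS > 4) trials on a single magnitude feature.
Stage 2 fits, on the training individuals' *true* high-pain trials, the
linear model

    rating = alpha * feature + c

and predicts ratings (clipped to [0, 10]) for the held-out individual's
trials — both for trials *predicted* high by stage 1 and for trials *truly*
high, each evaluated by mean absolute error (MAE).

Normalization baselines use only each individual's own spontaneous data, so
no rating information from the held-out individual ever enters training or
normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, DomainError, IntegrityError

__all__ = [
    "CVPartition",
    "loio_partitions",
    "LDA1D",
    "train_lda_1d",
    "PredictionOutcome",
    "two_stage_predict",
    "run_loio",
    "evaluate_and_compare",
]


@dataclass(frozen=True)
class CVPartition:
    held_out: str
    training_ids: tuple[str, ...]


def loio_partitions(individual_ids) -> list[CVPartition]:
    """One partition per individual, in first-appearance order."""
    ids = [str(i) for i in individual_ids]
    if len(set(ids)) != len(ids):
        raise IntegrityError("duplicate individual ids in partition request")
    if len(ids) < 2:
        raise DomainError("leave-one-individual-out needs >= 2 individuals")
    return [
        CVPartition(held_out=h, training_ids=tuple(i for i in ids if i != h)) for h in ids
    ]


@dataclass(frozen=True)
class LDA1D:
    """Gaussian equal-variance discriminant on a single feature.

    With equal priors the decision boundary is the midpoint of the class
    means; unequal priors shift it by ``var * log(prior_low/prior_high) /
    (mean_high - mean_low)``.
    """

    mean_low: float
    mean_high: float
    var_pooled: float
    prior_low: float
    prior_high: float

    @property
    def boundary(self) -> float:
        mid = (self.mean_low + self.mean_high) / 2.0
        shift = (
            self.var_pooled
            * math.log(self.prior_low / self.prior_high)
            / (self.mean_high - self.mean_low)
        )
        return mid + shift

    def discriminants(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linear discriminant scores (delta_low, delta_high) for each value."""
        x = np.asarray(x, dtype=float)
        d_low = (
            x * self.mean_low / self.var_pooled
            - self.mean_low**2 / (2 * self.var_pooled)
            + math.log(self.prior_low)
        )
        d_high = (
            x * self.mean_high / self.var_pooled
            - self.mean_high**2 / (2 * self.var_pooled)
            + math.log(self.prior_high)
        )
        return d_low, d_high

    def predict_high(self, x: np.ndarray) -> np.ndarray:
        """True where the high-pain discriminant wins (ties go to low-pain)."""
        d_low, d_high = self.discriminants(x)
        return d_high > d_low


def train_lda_1d(
    values: np.ndarray, is_high: np.ndarray, priors: str | tuple[float, float] = "empirical"
) -> LDA1D:
    """Fit the 1-D LDA from labelled training values.

    ``priors`` is ``"empirical"`` (class frequencies, the default),
    ``"equal"`` (reproduces the midpoint rule exactly), or an explicit
    ``(prior_low, prior_high)`` pair.
    """
    values = np.asarray(values, dtype=float)
    is_high = np.asarray(is_high, dtype=bool)
    n_high = int(is_high.sum())
    n_low = int(values.size - n_high)
    if n_low < 2 or n_high < 2:
        raise DegenerateDataError(
            f"LDA training needs >= 2 trials per class (got low={n_low}, high={n_high})"
        )
    low, high = values[~is_high], values[is_high]
    var_pooled = (
        (n_low - 1) * low.var(ddof=1) + (n_high - 1) * high.var(ddof=1)
    ) / (n_low + n_high - 2)
    if var_pooled <= 0:
        raise DegenerateDataError("zero pooled within-class variance")
    if priors == "empirical":
        p_low, p_high = n_low / values.size, n_high / values.size
    elif priors == "equal":
        p_low = p_high = 0.5
    else:
        p_low, p_high = priors
        if not (p_low > 0 and p_high > 0 and abs(p_low + p_high - 1) < 1e-9):
            raise DomainError("explicit priors must be positive and sum to 1")
    return LDA1D(
        mean_low=float(low.mean()),
        mean_high=float(high.mean()),
        var_pooled=float(var_pooled),
        prior_low=float(p_low),
        prior_high=float(p_high),
    )


@dataclass
class PredictionOutcome:
    """Per-individual result of the two-stage predictor."""

    individual_id: str
    trials: pd.DataFrame          # trial_index, rating, predicted_high, predicted_rating
    accuracy: float               # stage-1 accuracy over all held-out trials
    mae_predicted_high: float     # MAE over trials *predicted* high (NaN if none)
    mae_real_high: float          # MAE over trials with true rating > 4 (NaN if none)
    n_predicted_high: int
    n_real_high: int


def _stage2_fit(train: pd.DataFrame, feature: str) -> tuple[float, float]:
    """OLS rating ~ feature on the training individuals' true high-pain trials."""
    high = train[train["rating"] > 4]
    if len(high) < 3:
        raise DegenerateDataError("stage 2 needs >= 3 high-pain training trials")
    x = high[feature].to_numpy(float)
    y = high["rating"].to_numpy(float)
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise DegenerateDataError("stage 2 regression: constant feature in training")
    alpha = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    c = float(y.mean() - alpha * x.mean())
    return alpha, c


def two_stage_predict(
    partition: CVPartition,
    features: pd.DataFrame,
    feature: str = "nrms_p",
    priors: str | tuple[float, float] = "empirical",
    rating_range: tuple[float, float] = (0.0, 10.0),
) -> PredictionOutcome:
    """Classify then regress for one held-out individual."""
    ids = features["individual_id"].astype(str)
    train = features[ids.isin(partition.training_ids)]
    test = features[ids == partition.held_out]
    if test.empty:
        raise IntegrityError(f"no trials for held-out individual {partition.held_out!r}")

    clf = train_lda_1d(train[feature].to_numpy(float), train["rating"].to_numpy() > 4, priors)
    alpha, c = _stage2_fit(train, feature)

    x = test[feature].to_numpy(float)
    true_high = test["rating"].to_numpy() > 4
    pred_high = clf.predict_high(x)
    predicted_rating = np.clip(alpha * x + c, *rating_range)

    trials = pd.DataFrame(
        {
            "individual_id": partition.held_out,
            "trial_index": test["trial_index"].to_numpy(),
            "rating": test["rating"].to_numpy(),
            "predicted_high": pred_high,
            "predicted_rating": np.where(pred_high, predicted_rating, np.nan),
        }
    )
    err = np.abs(predicted_rating - test["rating"].to_numpy(float))
    mae_pred = float(err[pred_high].mean()) if pred_high.any() else float("nan")
    mae_real = float(err[true_high].mean()) if true_high.any() else float("nan")
    return PredictionOutcome(
        individual_id=partition.held_out,
        trials=trials,
        accuracy=float(np.mean(pred_high == true_high)),
        mae_predicted_high=mae_pred,
        mae_real_high=mae_real,
        n_predicted_high=int(pred_high.sum()),
        n_real_high=int(true_high.sum()),
    )


def run_loio(
    features: pd.DataFrame,
    feature: str = "nrms_p",
    priors: str | tuple[float, float] = "empirical",
) -> list[PredictionOutcome]:
    """Two-stage prediction for every individual under leave-one-individual-out CV."""
    ids = list(dict.fromkeys(features["individual_id"].astype(str)))
    return [
        two_stage_predict(p, features, feature, priors) for p in loio_partitions(ids)
    ]


def outcomes_frame(outcomes: list[PredictionOutcome]) -> pd.DataFrame:
    """Per-individual metric table from a list of outcomes."""
    return pd.DataFrame(
        [
            {
                "individual_id": o.individual_id,
                "accuracy": o.accuracy,
                "mae_predicted_high": o.mae_predicted_high,
                "mae_real_high": o.mae_real_high,
                "n_predicted_high": o.n_predicted_high,
                "n_real_high": o.n_real_high,
            }
            for o in outcomes
        ]
    )


def _paired_t(diff: np.ndarray) -> tuple[float, float, bool]:
    diff = diff[~np.isnan(diff)]
    if diff.size < 2 or np.all(diff == 0):
        return 0.0, 1.0, True
    sd = diff.std(ddof=1)
    if sd == 0:
        return float("inf"), 0.0, False
    t = float(diff.mean() / (sd / np.sqrt(diff.size)))
    return t, float(2 * stats.t.sf(abs(t), diff.size - 1)), False


def evaluate_and_compare(
    outcomes_raw: list[PredictionOutcome], outcomes_norm: list[PredictionOutcome]
) -> pd.DataFrame:
    """Summary table comparing the raw and normalized features.

    One row per metric (accuracy, MAE on predicted-high trials, MAE on real
    high-pain trials) with mean ± SD across individuals for each feature and
    a two-sided paired t-test between them.
    """
    raw = outcomes_frame(outcomes_raw).set_index("individual_id")
    norm = outcomes_frame(outcomes_norm).set_index("individual_id")
    if set(raw.index) != set(norm.index):
        raise IntegrityError("raw and normalized outcomes cover different individuals")
    norm = norm.loc[raw.index]
    rows = []
    for metric in ("accuracy", "mae_predicted_high", "mae_real_high"):
        a = raw[metric].to_numpy(float)
        b = norm[metric].to_numpy(float)
        t, p, degenerate = _paired_t(a - b)
        rows.append(
            {
                "metric": metric,
                "mean_raw": np.nanmean(a),
                "sd_raw": np.nanstd(a, ddof=1),
                "mean_norm": np.nanmean(b),
                "sd_norm": np.nanstd(b, ddof=1),
                "t_stat": t,
                "p_value": p,
                "degenerate": degenerate,
                "n_individuals": int(np.sum(~np.isnan(a - b))),
            }
        )
    return pd.DataFrame(rows)
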