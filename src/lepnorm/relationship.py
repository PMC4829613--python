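"""Descriptive analyses of the spontaneous-evoked and pain-evoked relationships.

Two findings are reproduced on any feature table:

1. At each pain level, the per-individual mean (and SD) of spontaneous
   magnitude RMS_S correlates across individuals with the mean (and SD) of
   evoked magnitude RMS_P — the empirical basis for using spontaneous EEG as
   a normalizing scale.
2. The rating->RMS_P relationship is flat below the pinprick threshold
   (NRS 4) and linear above it, so a two-piecewise linear model (two
   independent OLS lines split at NRS = 4, no continuity constraint) fits
   better than one global line; the two are compared per individual by MSE
   with a paired t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateDataError, DomainError

__all__ = [
    "PainLevelBin",
    "default_unit_bins",
    "aggregate_bins",
    "bin_by_pain_level",
    "level_summaries",
    "correlate_level_summaries",
    "LinearFit",
    "PiecewiseFit",
    "fit_global_linear",
    "fit_piecewise_linear",
    "per_individual_model_comparison",
    "compare_fit_models",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PainLevelBin:
    """Half-open rating interval (lower, upper]."""

    label: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ConfigurationError(f"bin {self.label!r}: lower must be < upper")

    def contains(self, rating: float) -> bool:
        return self.lower < rating <= self.upper


def default_unit_bins() -> list[PainLevelBin]:
    """Unit bins (0,1] ... (7,8] plus the combined (8,10] bin."""
    bins = [PainLevelBin(f"({k},{k + 1}]", k, k + 1) for k in range(8)]
    bins.append(PainLevelBin("(8,10]", 8, 10))
    return bins


def aggregate_bins() -> list[PainLevelBin]:
    """Low-pain (0,4] and high-pain (4,10] aggregates."""
    return [PainLevelBin("(0,4]", 0, 4), PainLevelBin("(4,10]", 4, 10)]


def bin_by_pain_level(
    records: pd.DataFrame, bins: list[PainLevelBin] | None = None
) -> dict[str, pd.DataFrame]:
    """Group records into every bin containing their rating.

    Unit bins are disjoint; aggregates overlap them. Rating-0 records fall in
    no default bin (they are kept for classification, not for binned
    descriptive statistics).
    """
    if bins is None:
        bins = default_unit_bins() + aggregate_bins()
    ratings = records["rating"].to_numpy()
    if ratings.size and (ratings.min() < 0 or ratings.max() > 10):
        raise DomainError("ratings must lie in [0, 10]")
    return {
        b.label: records[(ratings > b.lower) & (ratings <= b.upper)] for b in bins
    }


def level_summaries(
    records: pd.DataFrame,
    bins: list[PainLevelBin] | None = None,
    min_trials: int = 2,
) -> pd.DataFrame:
    """Per-bin, per-individual mean and SD of RMS_S and RMS_P.

    Individuals with fewer than ``min_trials`` trials in a bin are omitted
    from that bin's summary.
    """
    grouped = bin_by_pain_level(records, bins)
    rows = []
    for label, sub in grouped.items():
        for ind, g in sub.groupby("individual_id", sort=False):
            if len(g) < min_trials:
                continue
            rows.append(
                {
                    "bin": label,
                    "individual_id": ind,
                    "mean_rms_s": g["rms_s"].mean(),
                    "sd_rms_s": g["rms_s"].std(ddof=1),
                    "mean_rms_p": g["rms_p"].mean(),
                    "sd_rms_p": g["rms_p"].std(ddof=1),
                    "n_trials": len(g),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "bin",
            "individual_id",
            "mean_rms_s",
            "sd_rms_s",
            "mean_rms_p",
            "sd_rms_p",
            "n_trials",
        ],
    )


def correlate_level_summaries(summaries: pd.DataFrame) -> pd.DataFrame:
    """Cross-individual Pearson correlation of spontaneous vs evoked summaries.

    Per bin: r and two-sided p between the individuals' mean_rms_s and
    mean_rms_p, and likewise between their SDs. Bins with fewer than three
    individuals are skipped with a logged notice.
    """
    rows = []
    for label, g in summaries.groupby("bin", sort=False):
        if len(g) < 3:
            log.info("bin %s skipped: only %d individuals", label, len(g))
            continue
        r_mean, p_mean = stats.pearsonr(g["mean_rms_s"], g["mean_rms_p"])
        r_sd, p_sd = stats.pearsonr(g["sd_rms_s"], g["sd_rms_p"])
        rows.append(
            {
                "bin": label,
                "n_individuals": len(g),
                "r_mean": r_mean,
                "p_mean": p_mean,
                "r_sd": r_sd,
                "p_sd": p_sd,
            }
        )
    return pd.DataFrame(rows, columns=["bin", "n_individuals", "r_mean", "p_mean", "r_sd", "p_sd"])


@dataclass(frozen=True)
class LinearFit:
    """OLS line: response = slope * rating + intercept, with MSE = SSE/n."""

    slope: float
    intercept: float
    mse: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class PiecewiseFit:
    """Two independent OLS segments split at the break point (no continuity)."""

    low_fit: LinearFit   # ratings <= break_point
    high_fit: LinearFit  # ratings > break_point
    break_point: float
    mse: float           # pooled SSE / pooled n

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.where(x <= self.break_point, self.low_fit.predict(x), self.high_fit.predict(x))


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and SSE for y ~ x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    resid = y - (slope * x + intercept)
    return slope, intercept, float(np.sum(resid**2))


def fit_global_linear(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """Single OLS line over all points; MSE uses divisor n."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise DegenerateDataError(f"global fit needs >= 3 points, got {x.size}")
    if np.unique(x).size < 2:
        raise DegenerateDataError("global fit needs >= 2 distinct rating values")
    slope, intercept, sse = _ols(x, y)
    return LinearFit(slope, intercept, sse / x.size)


def _segment_fit(x: np.ndarray, y: np.ndarray) -> tuple[LinearFit, float]:
    """OLS on a segment, falling back to the segment mean when x is degenerate."""
    if y.size == 0:
        return LinearFit(0.0, 0.0, 0.0), 0.0
    if np.unique(x).size < 2:
        mean = float(y.mean())
        sse = float(np.sum((y - mean) ** 2))
        return LinearFit(0.0, mean, sse / y.size), sse
    slope, intercept, sse = _ols(x, y)
    return LinearFit(slope, intercept, sse / y.size), sse


def fit_piecewise_linear(
    x: np.ndarray, y: np.ndarray, break_point: float = 4.0
) -> PiecewiseFit:
    """Independent OLS per segment (x <= break vs x > break); pooled MSE.

    A segment with fewer than two distinct ratings falls back to its mean
    (slope 0); both segments empty is a domain error. Since the single global
    line is a member of this family, the pooled MSE never exceeds the global
    fit's MSE on the same data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise DomainError("piecewise fit needs at least one point")
    low = x <= break_point
    high = ~low
    low_fit, sse_low = _segment_fit(x[low], y[low])
    high_fit, sse_high = _segment_fit(x[high], y[high])
    return PiecewiseFit(low_fit, high_fit, break_point, (sse_low + sse_high) / x.size)


def per_individual_model_comparison(
    features: pd.DataFrame,
    feature: str = "rms_p",
    break_point: float = 4.0,
    use_level_means: bool = True,
) -> pd.DataFrame:
    """Global vs piecewise MSE per individual.

    By default each individual's response is first averaged across trials at
    each identical pain level (ratings >= 1; rating-0 trials are excluded from
    descriptive fits) and the models are fitted to those level means; set
    ``use_level_means=False`` to fit raw trials. Individuals with too few
    levels for a global fit are skipped with a logged notice.
    """
    rows = []
    for ind, g in features.groupby("individual_id", sort=False):
        g = g[g["rating"] >= 1]
        if use_level_means:
            pts = g.groupby("rating")[feature].mean().reset_index()
            x, y = pts["rating"].to_numpy(float), pts[feature].to_numpy(float)
        else:
            x, y = g["rating"].to_numpy(float), g[feature].to_numpy(float)
        try:
            glob = fit_global_linear(x, y)
        except DegenerateDataError as exc:
            log.info("individual %s skipped in model comparison: %s", ind, exc)
            continue
        piece = fit_piecewise_linear(x, y, break_point)
        rows.append(
            {
                "individual_id": ind,
                "mse_global": glob.mse,
                "mse_piecewise": piece.mse,
                "slope_global": glob.slope,
                "slope_high": piece.high_fit.slope,
                "n_points": x.size,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id",
            "mse_global",
            "mse_piecewise",
            "slope_global",
            "slope_high",
            "n_points",
        ],
    )


@dataclass(frozen=True)
class ModelComparison:
    """Paired comparison of per-individual global vs piecewise MSEs."""

    mean_mse_global: float
    sd_mse_global: float
    mean_mse_piecewise: float
    sd_mse_piecewise: float
    t_stat: float
    p_value: float
    df: int
    degenerate: bool  # all per-individual differences exactly zero


def compare_fit_models(
    mse_global: np.ndarray, mse_piecewise: np.ndarray
) -> ModelComparison:
    """Two-sided paired t-test on per-individual MSE differences."""
    a = np.asarray(mse_global, dtype=float)
    b = np.asarray(mse_piecewise, dtype=float)
    if a.shape != b.shape:
        raise DomainError("paired comparison requires equal-length MSE vectors")
    if a.size < 3:
        raise DomainError(f"paired comparison needs >= 3 individuals, got {a.size}")
    diff = a - b
    degenerate = bool(np.all(diff == 0))
    if degenerate or diff.std(ddof=1) == 0:
        t, p = (0.0, 1.0) if degenerate else (np.inf, 0.0)
    else:
        t = float(diff.mean() / (diff.std(ddof=1) / np.sqrt(diff.size)))
        p = float(2 * stats.t.sf(abs(t), diff.size - 1))
    return ModelComparison(
        mean_mse_global=float(a.mean()),
        sd_mse_global=float(a.std(ddof=1)),
        mean_mse_piecewise=float(b.mean()),
        sd_mse_piecewise=float(b.std(ddof=1)),
        t_stat=t,
        p_value=p,
        df=int(diff.size - 1),
        degenerate=degenerate,
    )
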