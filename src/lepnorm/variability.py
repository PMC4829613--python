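"""Inter-individual variability before vs after spontaneous-EEG normalization.

Three complementary views, each computed for the raw evoked magnitude
(rms_p) and its normalized counterpart (nrms_p):

* one-way ANOVA across individuals at each pain level — the F statistic is
  the between-individual variability relative to the within-individual one;
* the per-individual optimal low/high-pain classification threshold on the
  feature axis, whose cross-individual variance measures how portable a
  single cut would be;
* per-individual linear fits of the feature on rating over high-pain trials
  (NRS > 4), whose slope and intercept variances measure how portable a
  single regression would be.

Variances are compared with a two-sample variance-ratio F-test. Raw and
normalized parameters live on different scales (µV vs z-units), so a
scale-free coefficient-of-variation diagnostic is reported alongside, as an
extension clearly separated from the variance-ratio comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, DomainError
from .relationship import LinearFit, PainLevelBin, default_unit_bins, fit_global_linear

__all__ = [
    "AnovaResult",
    "anova_f_by_level",
    "ThresholdResult",
    "optimal_binary_threshold",
    "thresholds_by_individual",
    "individual_highpain_fit",
    "highpain_fits_by_individual",
    "VarianceComparison",
    "compare_variances",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnovaResult:
    bin_label: str
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    n_individuals: int
    n_trials: int


def anova_f_by_level(
    features: pd.DataFrame,
    feature: str = "rms_p",
    bins: list[PainLevelBin] | None = None,
    min_trials: int = 2,
) -> list[AnovaResult]:
    """One-way ANOVA with individual as the factor, per pain-level bin.

    Within each bin only individuals contributing at least ``min_trials``
    trials form groups; bins with fewer than two such groups are skipped with
    a logged notice.
    """
    if bins is None:
        bins = default_unit_bins()
    ratings = features["rating"].to_numpy()
    results = []
    for b in bins:
        sub = features[(ratings > b.lower) & (ratings <= b.upper)]
        groups = [
            g[feature].to_numpy(float)
            for _, g in sub.groupby("individual_id", sort=False)
            if len(g) >= min_trials
        ]
        if len(groups) < 2:
            log.info("bin %s skipped for ANOVA: %d eligible groups", b.label, len(groups))
            continue
        f, p = stats.f_oneway(*groups)
        n = sum(len(g) for g in groups)
        results.append(
            AnovaResult(
                bin_label=b.label,
                f_stat=float(f),
                df_between=len(groups) - 1,
                df_within=n - len(groups),
                p_value=float(p),
                n_individuals=len(groups),
                n_trials=n,
            )
        )
    return results


@dataclass(frozen=True)
class ThresholdResult:
    individual_id: str
    threshold: float
    accuracy: float


def optimal_binary_threshold(
    values: np.ndarray, is_high: np.ndarray, individual_id: str = ""
) -> ThresholdResult:
    """Exhaustive search for the accuracy-maximizing cut on one feature axis.

    Candidates are the midpoints between consecutive distinct sorted values
    plus one cut below the minimum and one above the maximum; the decision
    rule is feature > threshold => high-pain. Ties in accuracy break toward
    the smallest threshold, making the output deterministic.
    """
    values = np.asarray(values, dtype=float)
    is_high = np.asarray(is_high, dtype=bool)
    if values.size != is_high.size or values.size == 0:
        raise DomainError("values and labels must be non-empty and equal-length")
    if is_high.all() or (~is_high).all():
        raise DegenerateDataError(
            f"individual {individual_id or '?'} has a single class; threshold undefined"
        )
    distinct = np.unique(values)
    candidates = np.concatenate(
        ([distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0])
    )
    best_t, best_acc = candidates[0], -1.0
    for t in candidates:
        acc = float(np.mean((values > t) == is_high))
        if acc > best_acc + 1e-12:
            best_acc, best_t = acc, t
    return ThresholdResult(individual_id, float(best_t), float(best_acc))


def thresholds_by_individual(features: pd.DataFrame, feature: str = "rms_p") -> pd.DataFrame:
    """Optimal threshold per individual; single-class individuals are excluded."""
    rows = []
    for ind, g in features.groupby("individual_id", sort=False):
        try:
            res = optimal_binary_threshold(
                g[feature].to_numpy(float), g["rating"].to_numpy() > 4, str(ind)
            )
        except DegenerateDataError as exc:
            log.info("threshold search: %s", exc)
            continue
        rows.append({"individual_id": ind, "threshold": res.threshold, "accuracy": res.accuracy})
    return pd.DataFrame(rows, columns=["individual_id", "threshold", "accuracy"])


def individual_highpain_fit(
    records: pd.DataFrame, feature: str = "rms_p"
) -> LinearFit:
    """OLS of the feature on rating over one individual's high-pain trials."""
    high = records[records["rating"] > 4]
    if len(high) < 3 or high["rating"].nunique() < 2:
        raise DegenerateDataError(
            "high-pain fit needs >= 3 trials spanning >= 2 rating values"
        )
    return fit_global_linear(high["rating"].to_numpy(float), high[feature].to_numpy(float))


def highpain_fits_by_individual(features: pd.DataFrame, feature: str = "rms_p") -> pd.DataFrame:
    """Slope/intercept/MSE of the high-pain fit per individual (failures logged)."""
    rows = []
    for ind, g in features.groupby("individual_id", sort=False):
        try:
            fit = individual_highpain_fit(g, feature)
        except DegenerateDataError as exc:
            log.info("high-pain fit for %s skipped: %s", ind, exc)
            continue
        rows.append(
            {"individual_id": ind, "slope": fit.slope, "intercept": fit.intercept, "mse": fit.mse}
        )
    return pd.DataFrame(rows, columns=["individual_id", "slope", "intercept", "mse"])


@dataclass(frozen=True)
class VarianceComparison:
    parameter_name: str
    var_raw: float
    var_norm: float
    f_stat: float        # larger variance / smaller variance, >= 1
    p_value: float | None
    df_num: int
    df_den: int
    cv_raw: float        # |SD/mean| scale-free diagnostics (extension)
    cv_norm: float
    degenerate: bool


def compare_variances(
    values_raw: np.ndarray, values_norm: np.ndarray, parameter_name: str = ""
) -> VarianceComparison:
    """Two-sample variance-ratio F-test between raw and normalized parameters.

    F is the larger sample variance over the smaller with degrees of freedom
    ordered to match; the two-sided p doubles the one-tailed tail probability
    (capped at 1). Zero variance in either sample sets a degeneracy flag and
    omits the p-value.
    """
    a = np.asarray(values_raw, dtype=float)
    b = np.asarray(values_norm, dtype=float)
    if a.size < 3 or b.size < 3:
        raise DomainError("variance comparison needs >= 3 individuals per set")
    var_a = float(a.var(ddof=1))
    var_b = float(b.var(ddof=1))
    cv = lambda v: float(abs(v.std(ddof=1) / v.mean())) if v.mean() != 0 else float("inf")
    if var_a == 0 or var_b == 0:
        return VarianceComparison(
            parameter_name, var_a, var_b, float("inf") if var_a != var_b else 1.0,
            None, a.size - 1, b.size - 1, cv(a), cv(b), True,
        )
    if var_a >= var_b:
        f, dfn, dfd = var_a / var_b, a.size - 1, b.size - 1
    else:
        f, dfn, dfd = var_b / var_a, b.size - 1, a.size - 1
    p = min(1.0, 2.0 * float(stats.f.sf(f, dfn, dfd)))
    return VarianceComparison(
        parameter_name, var_a, var_b, float(f), p, dfn, dfd, cv(a), cv(b), False
    )
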