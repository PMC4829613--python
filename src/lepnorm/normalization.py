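"""Normalization of evoked magnitudes by the individual's spontaneous baseline.

The central transform expresses each trial's evoked magnitude RMS_P as a
z-score of the *same individual's* distribution of spontaneous magnitudes
RMS_S over all of their trials:

    nRMS_P(i) = (RMS_P(i) - mu(RMS_S)) / sigma(RMS_S)

Because any individual-specific multiplicative factor (skull thickness,
electrode impedance) scales RMS_P, mu and sigma alike, the z-score is
invariant to it — which is the mechanism by which inter-individual scale
variability is removed. Two simpler modes (divide by the mean, subtract the
mean) are available for comparison. Only spontaneous data enter the
baseline, so normalizing a new individual needs no pain ratings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, DomainError, IntegrityError

__all__ = [
    "IndividualBaseline",
    "fit_baseline",
    "fit_baselines",
    "normalize_value",
    "normalize_table",
    "check_normality",
    "NORMALIZATION_MODES",
]

NORMALIZATION_MODES = ("zscore", "divide_mean", "subtract_mean")


@dataclass(frozen=True)
class IndividualBaseline:
    """Mean and SD of one individual's spontaneous-magnitude distribution."""

    individual_id: str
    mu_s: float     # µV, mean of RMS_S over all trials
    sigma_s: float  # µV, sample SD (divisor n-1) of RMS_S
    n_trials: int


def fit_baseline(rms_s: np.ndarray, individual_id: str = "") -> IndividualBaseline:
    """Estimate the spontaneous baseline from one individual's RMS_S values."""
    values = np.asarray(rms_s, dtype=float)
    if values.size < 2:
        raise DegenerateDataError(
            f"baseline for {individual_id or 'individual'} needs >= 2 trials, got {values.size}"
        )
    mu = float(values.mean())
    sigma = float(values.std(ddof=1))
    if sigma <= 0 or not np.isfinite(sigma):
        raise DegenerateDataError(
            f"zero-variance spontaneous magnitudes for {individual_id or 'individual'}"
        )
    return IndividualBaseline(individual_id, mu, sigma, int(values.size))


def fit_baselines(features: pd.DataFrame) -> dict[str, IndividualBaseline]:
    """Fit one baseline per individual from a feature table."""
    return {
        str(ind): fit_baseline(group["rms_s"].to_numpy(), str(ind))
        for ind, group in features.groupby("individual_id", sort=False)
    }


def normalize_value(rms_p: float, baseline: IndividualBaseline, mode: str = "zscore") -> float:
    """Normalize one evoked magnitude against a spontaneous baseline."""
    if mode == "zscore":
        return (rms_p - baseline.mu_s) / baseline.sigma_s
    if mode == "divide_mean":
        return rms_p / baseline.mu_s
    if mode == "subtract_mean":
        return rms_p - baseline.mu_s
    raise DomainError(f"unknown normalization mode {mode!r}; expected one of {NORMALIZATION_MODES}")


def normalize_table(
    features: pd.DataFrame,
    mode: str = "zscore",
    baselines: dict[str, IndividualBaseline] | None = None,
) -> pd.DataFrame:
    """Return the feature table with an ``nrms_p`` column appended.

    Baselines default to per-individual fits on the table itself; externally
    supplied baselines must match the individuals present.
    """
    if mode not in NORMALIZATION_MODES:
        raise DomainError(f"unknown normalization mode {mode!r}")
    if baselines is None:
        baselines = fit_baselines(features)
    out = features.copy()
    nrms = np.empty(len(out))
    for i, (ind, rms_p) in enumerate(zip(out["individual_id"], out["rms_p"])):
        b = baselines.get(str(ind))
        if b is None:
            raise IntegrityError(f"no baseline for individual {ind!r}")
        if b.individual_id and b.individual_id != str(ind):
            raise IntegrityError(f"baseline for {b.individual_id!r} applied to {ind!r}")
        nrms[i] = normalize_value(float(rms_p), b, mode)
    out["nrms_p"] = nrms
    return out


def check_normality(values: np.ndarray) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test of the standardized sample vs N(0,1).

    Parameters are estimated from the sample first, which inflates p-values
    (Lilliefors effect); this is reported as a diagnostic only — no trial is
    ever excluded on its outcome.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 8:
        raise DomainError(f"normality check needs >= 8 values, got {values.size}")
    sd = values.std(ddof=1)
    if sd <= 0:
        raise DegenerateDataError("constant sample: normality test undefined")
    z = (values - values.mean()) / sd
    stat, p = stats.kstest(z, "norm")
    return float(stat), float(p)
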