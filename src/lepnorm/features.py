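"""Signal preprocessing and per-trial magnitude features.

Each trial is reduced to two root-mean-square magnitudes: RMS_S of the
pre-stimulus (spontaneous) segment and RMS_P of the post-stimulus
(pain-evoked) segment. Preprocessing is the conventional ERP chain:
zero-phase 1-30 Hz band-pass, ±0.5 s epoching, baseline correction by the
pre-stimulus mean.
"""

from __future__ import annotations

from functools import lru_cache
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import DomainError, IntegrityError, TruncationError

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import EpochedTrial

__all__ = [
    "bandpass_filter",
    "epoch_and_baseline",
    "baseline_correct",
    "compute_rms",
    "build_feature_table",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = ["individual_id", "trial_index", "energy_J", "rating", "rms_s", "rms_p"]


@lru_cache(maxsize=32)
def design_bandpass(sampling_rate: float, low: float, high: float):
    """Fourth-order Butterworth band-pass in second-order sections."""
    if not (0 < low < high < sampling_rate / 2):
        raise DomainError(
            f"band edges must satisfy 0 < low < high < Nyquist "
            f"(got low={low}, high={high}, fs={sampling_rate})"
        )
    return sps.butter(4, [low, high], btype="bandpass", output="sos", fs=sampling_rate)


def sos_filtfilt(x: np.ndarray, sampling_rate: float, low: float, high: float) -> np.ndarray:
    sos = design_bandpass(sampling_rate, low, high)
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def bandpass_filter(
    x: np.ndarray, sampling_rate: float, low: float = 1.0, high: float = 30.0
) -> np.ndarray:
    """Zero-phase band-pass filter (forward-backward Butterworth, order 4/pass).

    Output has the same length as the input, unit passband gain (within a few
    percent mid-band) and strong attenuation one octave outside the band.
    Applied to the continuous record before epoching to keep filter
    transients away from epoch edges.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise DomainError("bandpass_filter expects a 1-D sample vector")
    return sos_filtfilt(x, sampling_rate, low, high)


def epoch_and_baseline(
    continuous: np.ndarray,
    event_index: int,
    sampling_rate: float,
    epoch_halfwidth: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a ±halfwidth epoch around ``event_index`` and baseline-correct it.

    The pre segment covers [-halfwidth, 0) and the post segment [0,
    +halfwidth) — half-open, so the stimulus sample starts the post segment.
    The mean of the pre segment is subtracted from both segments.
    """
    continuous = np.asarray(continuous, dtype=float)
    k = int(round(sampling_rate * epoch_halfwidth))
    if event_index - k < 0 or event_index + k > len(continuous):
        raise TruncationError(
            f"epoch window [{event_index - k}, {event_index + k}) exceeds record "
            f"of length {len(continuous)}"
        )
    pre = continuous[event_index - k : event_index].copy()
    post = continuous[event_index : event_index + k].copy()
    baseline = pre.mean()
    return pre - baseline, post - baseline


def baseline_correct(trial: "EpochedTrial") -> "EpochedTrial":
    """Subtract the pre-segment mean from both segments of an epoched trial."""
    from dataclasses import replace

    baseline = trial.pre_samples.mean()
    return replace(
        trial,
        pre_samples=trial.pre_samples - baseline,
        post_samples=trial.post_samples - baseline,
    )


def compute_rms(segment: np.ndarray) -> float:
    """Root mean square of a sample vector: sqrt(sum(x_k^2)/K)."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise DomainError("compute_rms requires a non-empty segment")
    return float(np.sqrt(np.mean(np.square(segment))))


def build_feature_table(trials: Iterable["EpochedTrial"]) -> pd.DataFrame:
    """One row per trial: RMS_S of the pre segment, RMS_P of the post segment.

    Order-preserving; the normalized column (nrms_p) is absent until the
    normalization stage adds it.
    """
    rows = []
    seen: set[tuple[str, int]] = set()
    for t in trials:
        key = (t.individual_id, t.trial_index)
        if key in seen:
            raise IntegrityError(f"duplicate trial {key}")
        seen.add(key)
        rows.append(
            {
                "individual_id": t.individual_id,
                "trial_index": t.trial_index,
                "energy_J": t.energy,
                "rating": t.rating,
                "rms_s": compute_rms(t.pre_samples),
                "rms_p": compute_rms(t.post_samples),
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
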