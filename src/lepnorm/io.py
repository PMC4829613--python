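"""Reading and writing the trial container and feature tables.

The trial container is a directory holding:

* ``trials.csv`` — per-trial metadata (individual_id, trial_index, energy_J,
  rating) with a header row;
* ``segments.npz`` — float64 arrays ``pre`` and ``post`` of shape
  (n_trials, K), row-aligned with trials.csv;
* ``profiles.csv`` — optional ground-truth generator parameters for
  parameter-recovery tests.

Round-trip fidelity is bit-exact: float64 segments are stored losslessly and
metadata columns are plain integers/floats.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import EpochedTrial, IndividualProfile
from .errors import IntegrityError

__all__ = [
    "write_trial_container",
    "read_trial_container",
    "write_profiles",
    "read_profiles",
    "write_feature_table",
    "read_feature_table",
]

_META_COLUMNS = ["individual_id", "trial_index", "energy_J", "rating"]


def write_trial_container(
    trials: list[EpochedTrial],
    path: str | Path,
    profiles: list[IndividualProfile] | None = None,
) -> Path:
    """Write trials (and optionally ground-truth profiles) under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = pd.DataFrame(
        {
            "individual_id": [t.individual_id for t in trials],
            "trial_index": [t.trial_index for t in trials],
            "energy_J": [t.energy for t in trials],
            "rating": [t.rating for t in trials],
        }
    )
    meta.to_csv(path / "trials.csv", index=False)
    np.savez(
        path / "segments.npz",
        pre=np.stack([t.pre_samples for t in trials]) if trials else np.empty((0, 0)),
        post=np.stack([t.post_samples for t in trials]) if trials else np.empty((0, 0)),
    )
    if profiles is not None:
        write_profiles(profiles, path / "profiles.csv")
    return path


def read_trial_container(path: str | Path) -> list[EpochedTrial]:
    """Read a trial container written by :func:`write_trial_container`."""
    path = Path(path)
    meta_path = path / "trials.csv"
    if not meta_path.exists() or meta_path.stat().st_size == 0:
        raise IntegrityError(f"empty or missing trial container at {path}")
    meta = pd.read_csv(meta_path)
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise IntegrityError(
            f"trial container {meta_path} is missing column(s): {', '.join(missing)}"
        )
    if meta.empty:
        raise IntegrityError(f"trial container {meta_path} holds no trials")
    with np.load(path / "segments.npz") as arrays:
        pre, post = arrays["pre"], arrays["post"]
    if len(pre) != len(meta) or len(post) != len(meta):
        raise IntegrityError("segment arrays and metadata table disagree on trial count")
    return [
        EpochedTrial(
            individual_id=str(row.individual_id),
            trial_index=int(row.trial_index),
            pre_samples=pre[i],
            post_samples=post[i],
            rating=int(row.rating),
            energy=float(row.energy_J),
        )
        for i, row in enumerate(meta.itertuples(index=False))
    ]


def write_profiles(profiles: list[IndividualProfile], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([dataclasses.asdict(p) for p in profiles]).to_csv(path, index=False)
    return path


def read_profiles(path: str | Path) -> list[IndividualProfile]:
    df = pd.read_csv(path)
    return [
        IndividualProfile(**{**row, "individual_id": str(row["individual_id"])})
        for row in df.to_dict("records")
    ]


def write_feature_table(features: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features.to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"individual_id", "rating", "rms_s", "rms_p"}
    missing = required - set(df.columns)
    if missing:
        raise IntegrityError(f"feature table {path} missing column(s): {', '.join(sorted(missing))}")
    df["individual_id"] = df["individual_id"].astype(str)
    return df
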