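#!/usr/bin/env python
"""Reduce each trial to its two RMS magnitudes.

Baseline-corrects every epoch by its pre-stimulus mean, then computes RMS_S
(spontaneous, pre-stimulus) and RMS_P (pain-evoked, post-stimulus) per
trial, writing the feature table that every downstream analysis consumes.
"""

from pathlib import Path

from lepnorm import baseline_correct, build_feature_table
from lepnorm.io import read_trial_container, write_feature_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    trials = read_trial_container(ROOT / "scratch" / "trials")
    table = build_feature_table([baseline_correct(t) for t in trials])
    out = write_feature_table(table, ROOT / "results" / "features.csv")
    print(f"extracted features for {len(table)} trials -> {out}")
    by_ind = table.groupby("individual_id")[["rms_s", "rms_p"]].mean()
    print("per-individual mean RMS_S spans "
          f"{by_ind['rms_s'].min():.1f}-{by_ind['rms_s'].max():.1f} uV, "
          f"mean RMS_P {by_ind['rms_p'].min():.1f}-{by_ind['rms_p'].max():.1f} uV "
          "(the shared individual scale factor drives both)")


if __name__ == "__main__":
    main()
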