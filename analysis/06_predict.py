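#!/usr/bin/env python
"""Two-stage cross-individual pain prediction, raw vs normalized features.

Leave-one-individual-out: an LDA classifier separates low-pain (NRS <= 4)
from high-pain trials on one magnitude feature, then a linear model trained
on the training individuals' true high-pain trials predicts ratings for the
held-out individual's trials predicted high and truly high. Accuracy and
both MAEs are compared between RMS_P and nRMS_P with paired t-tests.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from lepnorm.io import read_feature_table
from lepnorm.prediction import evaluate_and_compare, outcomes_frame, run_loio

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    table = read_feature_table(ROOT / "results" / "features_normalized.csv")
    out_raw = run_loio(table, "rms_p")
    out_norm = run_loio(table, "nrms_p")

    outcomes = outcomes_frame(out_raw).merge(
        outcomes_frame(out_norm), on="individual_id", suffixes=("_rms_p", "_nrms_p")
    )
    outcomes.to_csv(ROOT / "results" / "prediction_outcomes.csv", index=False)
    summary = evaluate_and_compare(out_raw, out_norm)
    summary.to_csv(ROOT / "results" / "prediction_summary.csv", index=False)

    high_frac = (table["rating"] > 4).mean()
    print(f"majority-class baseline accuracy: {max(high_frac, 1 - high_frac):.1%}")
    for _, row in summary.iterrows():
        unit = "%" if row["metric"] == "accuracy" else " NRS"
        scale = 100 if row["metric"] == "accuracy" else 1
        print(f"{row['metric']}: RMS_P {scale * row['mean_raw']:.2f} ± {scale * row['sd_raw']:.2f}{unit}"
              f" vs nRMS_P {scale * row['mean_norm']:.2f} ± {scale * row['sd_norm']:.2f}{unit}"
              f" (paired t, p = {row['p_value']:.2g})")
    better = np.nanmean(outcomes["mae_real_high_nrms_p"]) < np.nanmean(
        outcomes["mae_real_high_rms_p"]
    )
    print("normalization "
          + ("reduced" if better else "did not reduce")
          + " the cross-individual prediction error")


if __name__ == "__main__":
    main()
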