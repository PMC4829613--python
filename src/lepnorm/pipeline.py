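"""End-to-end orchestration: simulate -> features -> normalize -> analyses -> predict.

Every stage is a thin wrapper over the library functions; `run_pipeline`
chains them, writes each result as a delimited text table under the output
directory, and records a machine-readable manifest (config + seed +
versions) so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, simulate_cohort
from .errors import LepnormError
from .features import baseline_correct, build_feature_table
from .io import (
    read_feature_table,
    read_trial_container,
    write_feature_table,
    write_trial_container,
)
from .normalization import check_normality, normalize_table
from .prediction import evaluate_and_compare, outcomes_frame, run_loio
from .relationship import (
    compare_fit_models,
    correlate_level_summaries,
    level_summaries,
    per_individual_model_comparison,
)
from .variability import (
    anova_f_by_level,
    compare_variances,
    highpain_fits_by_individual,
    thresholds_by_individual,
)

__all__ = ["PipelineConfig", "run_pipeline", "analysis_tables"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to run the full pipeline."""

    outdir: Path = Path("results")
    cohort: CohortConfig = field(default_factory=CohortConfig)
    normalization_mode: str = "zscore"
    priors: str = "empirical"          # "empirical" | "equal"
    skip_simulate: bool = False
    trial_container: Path | None = None  # read trials here when skip_simulate
    feature_table: Path | None = None    # or start directly from features
    write_trials: bool = True
    seed: int | None = None              # overrides cohort.seed when given

    def resolved_cohort(self) -> CohortConfig:
        if self.seed is not None:
            return self.cohort.with_(seed=self.seed)
        return self.cohort


def _features_stage(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    if cfg.feature_table is not None:
        log.info("features: loading precomputed table %s", cfg.feature_table)
        return read_feature_table(cfg.feature_table)
    if cfg.skip_simulate:
        if cfg.trial_container is None:
            raise ValueError("skip_simulate requires trial_container or feature_table")
        trials = read_trial_container(cfg.trial_container)
        log.info("features: read %d trials from %s", len(trials), cfg.trial_container)
    else:
        cohort_cfg = cfg.resolved_cohort()
        trials, profiles = simulate_cohort(cohort_cfg)
        log.info(
            "simulate: %d trials from %d individuals (seed %d)",
            len(trials), len(profiles), cohort_cfg.seed,
        )
        if cfg.write_trials:
            write_trial_container(trials, outdir / "trials", profiles)
    trials = [baseline_correct(t) for t in trials]
    features = build_feature_table(trials)
    write_feature_table(features, outdir / "features.csv")
    log.info("features: %d rows", len(features))
    return features


def analysis_tables(normalized: pd.DataFrame, priors: str = "empirical") -> dict[str, pd.DataFrame]:
    """All downstream analysis tables from a normalized feature table."""
    tables: dict[str, pd.DataFrame] = {}

    # Spontaneous vs evoked correlation per pain level
    tables["correlations"] = correlate_level_summaries(level_summaries(normalized))

    # Global vs piecewise model comparison per individual
    fits = per_individual_model_comparison(normalized, "rms_p")
    tables["model_fits"] = fits
    try:
        cmp_models = compare_fit_models(
            fits["mse_global"].to_numpy(), fits["mse_piecewise"].to_numpy()
        )
        tables["model_comparison"] = pd.DataFrame([dataclasses.asdict(cmp_models)])
    except LepnormError as exc:
        log.warning("model comparison skipped: %s", exc)
        tables["model_comparison"] = pd.DataFrame()

    # Normality diagnostics per individual
    norm_rows = []
    for ind, g in normalized.groupby("individual_id", sort=False):
        for col in ("rms_s", "rms_p"):
            stat, p = check_normality(g[col].to_numpy())
            norm_rows.append({"individual_id": ind, "feature": col, "ks_stat": stat, "p": p})
    tables["normality"] = pd.DataFrame(norm_rows)

    # ANOVA F per unit bin, raw vs normalized
    anova_rows = []
    for feat in ("rms_p", "nrms_p"):
        for r in anova_f_by_level(normalized, feat):
            anova_rows.append({"feature": feat, **dataclasses.asdict(r)})
    tables["anova_f"] = pd.DataFrame(anova_rows)

    # Per-individual thresholds and high-pain fits; variance comparison
    var_rows = []
    thr = {f: thresholds_by_individual(normalized, f) for f in ("rms_p", "nrms_p")}
    fits_hp = {f: highpain_fits_by_individual(normalized, f) for f in ("rms_p", "nrms_p")}
    common_thr = sorted(set(thr["rms_p"]["individual_id"]) & set(thr["nrms_p"]["individual_id"]))
    common_fit = sorted(
        set(fits_hp["rms_p"]["individual_id"]) & set(fits_hp["nrms_p"]["individual_id"])
    )
    pick = lambda df, ids, col: df.set_index("individual_id").loc[ids, col].to_numpy()
    for name, col, ids, source in (
        ("threshold", "threshold", common_thr, thr),
        ("slope", "slope", common_fit, fits_hp),
        ("intercept", "intercept", common_fit, fits_hp),
    ):
        try:
            vc = compare_variances(
                pick(source["rms_p"], ids, col), pick(source["nrms_p"], ids, col), name
            )
            var_rows.append(dataclasses.asdict(vc))
        except LepnormError as exc:
            log.warning("variance comparison for %s skipped: %s", name, exc)
    tables["thresholds"] = thr["rms_p"].merge(
        thr["nrms_p"], on="individual_id", suffixes=("_rms_p", "_nrms_p")
    )
    tables["highpain_fits"] = fits_hp["rms_p"].merge(
        fits_hp["nrms_p"], on="individual_id", suffixes=("_rms_p", "_nrms_p")
    )
    tables["variance_comparison"] = pd.DataFrame(var_rows)

    # Two-stage LOIO prediction, raw vs normalized
    out_raw = run_loio(normalized, "rms_p", priors)
    out_norm = run_loio(normalized, "nrms_p", priors)
    tables["prediction_outcomes"] = outcomes_frame(out_raw).merge(
        outcomes_frame(out_norm), on="individual_id", suffixes=("_rms_p", "_nrms_p")
    )
    tables["prediction_summary"] = evaluate_and_compare(out_raw, out_norm)
    return tables


def run_pipeline(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every stage and write all tables plus a run manifest under outdir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    features = _features_stage(cfg, outdir)
    normalized = normalize_table(features, cfg.normalization_mode)
    write_feature_table(normalized, outdir / "features_normalized.csv")
    log.info("normalize: mode=%s, %d rows", cfg.normalization_mode, len(normalized))

    tables = analysis_tables(normalized, cfg.priors)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
        log.info("%s: %d rows -> %s.csv", name, len(df), name)

    cohort_cfg = cfg.resolved_cohort()
    manifest = {
        "lepnorm_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cohort_cfg.seed,
        "normalization_mode": cfg.normalization_mode,
        "priors": cfg.priors,
        "cohort": dataclasses.asdict(cohort_cfg),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    tables["features"] = features
    tables["features_normalized"] = normalized
    return tables
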