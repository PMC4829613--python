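"""Pain-level binning, cross-individual correlations, and the two fit models."""

import numpy as np
import pandas as pd
import pytest
from numpy.random import default_rng

from lepnorm.errors import ConfigurationError, DegenerateDataError, DomainError
from lepnorm.relationship import (
    PainLevelBin,
    aggregate_bins,
    bin_by_pain_level,
    compare_fit_models,
    correlate_level_summaries,
    default_unit_bins,
    fit_global_linear,
    fit_piecewise_linear,
    level_summaries,
    per_individual_model_comparison,
)


def _records(ratings):
    return pd.DataFrame(
        {
            "individual_id": "A",
            "trial_index": range(len(ratings)),
            "rating": ratings,
            "rms_s": 1.0,
            "rms_p": 1.0,
        }
    )


class TestBinning:
    def test_rating_4_is_low_pain(self):
        grouped = bin_by_pain_level(_records([4]))
        assert len(grouped["(3,4]"]) == 1
        assert len(grouped["(0,4]"]) == 1
        assert len(grouped["(4,10]"]) == 0

    def test_rating_5_is_high_pain(self):
        grouped = bin_by_pain_level(_records([5]))
        assert len(grouped["(4,5]"]) == 1
        assert len(grouped["(4,10]"]) == 1

    def test_rating_0_falls_in_no_default_bin(self):
        grouped = bin_by_pain_level(_records([0]))
        assert all(len(g) == 0 for g in grouped.values())

    def test_malformed_bin_rejected(self):
        with pytest.raises(ConfigurationError):
            PainLevelBin("bad", 3, 3)


class TestCorrelations:
    def _summary(self, pairs, bin_label="(0,4]"):
        return pd.DataFrame(
            [
                {
                    "bin": bin_label,
                    "individual_id": f"S{i}",
                    "mean_rms_s": s,
                    "sd_rms_s": s,
                    "mean_rms_p": p,
                    "sd_rms_p": p,
                    "n_trials": 5,
                }
                for i, (s, p) in enumerate(pairs)
            ]
        )

    def test_exact_proportionality_gives_unit_correlation(self):
        out = correlate_level_summaries(self._summary([(1, 2), (2, 4), (3, 6)]))
        assert out["r_mean"].iloc[0] == pytest.approx(1.0)

    def test_anticorrelated_pairs(self):
        out = correlate_level_summaries(self._summary([(1, 6), (2, 4), (3, 2)]))
        assert out["r_mean"].iloc[0] == pytest.approx(-1.0)

    def test_bins_with_fewer_than_three_individuals_skipped(self):
        out = correlate_level_summaries(self._summary([(1, 2), (2, 4)]))
        assert out.empty

    def test_summaries_require_two_trials_per_individual(self, small_features):
        summ = level_summaries(small_features)
        assert (summ["n_trials"] >= 2).all()
        assert summ["sd_rms_s"].notna().all()

    def test_default_cohort_low_pain_bin_positively_correlated(self, small_features):
        out = correlate_level_summaries(
            level_summaries(small_features, aggregate_bins())
        )
        row = out[out["bin"] == "(0,4]"].iloc[0]
        assert row["r_mean"] > 0
        assert row["p_mean"] < 0.05


class TestGlobalFit:
    def test_collinear_points(self):
        fit = fit_global_linear([5, 6, 7], [1, 2, 3])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(-4.0)
        assert fit.mse == pytest.approx(0.0, abs=1e-12)

    def test_hand_solved_normal_equations(self):
        fit = fit_global_linear([0, 1, 2], [0, 1, 0])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1 / 3)
        assert fit.mse == pytest.approx(2 / 9)

    def test_single_rating_value_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_global_linear([2, 2, 2], [1, 2, 3])

    def test_matches_polyfit_oracle(self):
        rng = default_rng(0)
        for _ in range(50):
            x = rng.integers(0, 11, 20).astype(float)
            if np.unique(x).size < 2:
                continue
            y = rng.normal(0, 3, 20)
            fit = fit_global_linear(x, y)
            slope, intercept = np.polyfit(x, y, 1)
            assert fit.slope == pytest.approx(slope, abs=1e-9)
            assert fit.intercept == pytest.approx(intercept, abs=1e-9)


class TestPiecewiseFit:
    def test_exact_flat_then_linear_data(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8], dtype=float)
        y = np.where(x <= 4, 1.0, x - 3.0)
        fit = fit_piecewise_linear(x, y)
        assert fit.mse == pytest.approx(0.0, abs=1e-12)
        assert fit.low_fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.high_fit.slope == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            fit_piecewise_linear([], [])

    def test_nested_model_inequality_and_bruteforce_sse(self):
        rng = default_rng(42)
        for _ in range(100):
            n = rng.integers(6, 25)
            x = rng.integers(1, 11, n).astype(float)
            y = rng.normal(0, 2, n) + 0.5 * x
            piece = fit_piecewise_linear(x, y)
            if np.unique(x).size >= 2:
                glob = fit_global_linear(x, y)
                assert piece.mse <= glob.mse + 1e-12
            # brute-force least squares per segment via lstsq (independent route)
            sse = 0.0
            for mask in (x <= 4, x > 4):
                if mask.sum() == 0:
                    continue
                if np.unique(x[mask]).size < 2:
                    sse += np.sum((y[mask] - y[mask].mean()) ** 2)
                    continue
                design = np.column_stack([x[mask], np.ones(mask.sum())])
                coef, *_ = np.linalg.lstsq(design, y[mask], rcond=None)
                sse += np.sum((y[mask] - design @ coef) ** 2)
            assert piece.mse * n == pytest.approx(sse, abs=1e-8)

    def test_noise_free_cohort_recovers_generator_parameters(self):
        from lepnorm import CohortConfig, baseline_correct, build_feature_table, simulate_cohort

        cfg = CohortConfig(
            n_individuals=3,
            sampling_rate=200.0,
            noise_sd=1e-9,
            rating_noise_sd=0.0,
            trial_jitter_sd=0.0,
            seed=21,
        )
        trials, profiles = simulate_cohort(cfg)
        table = build_feature_table([baseline_correct(t) for t in trials])
        for p in profiles:
            g = table[table["individual_id"] == p.individual_id]
            pts = g.groupby("rating")["rms_p"].mean().reset_index()
            fit = fit_piecewise_linear(pts["rating"].to_numpy(float), pts["rms_p"].to_numpy())
            assert fit.high_fit.slope == pytest.approx(p.scale * p.evoked_slope, rel=0.01)
            assert fit.low_fit.intercept == pytest.approx(p.scale * p.evoked_base, rel=0.01)


class TestModelComparison:
    def test_identical_mse_vectors_flagged_degenerate(self):
        out = compare_fit_models([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out.degenerate
        assert out.t_stat == 0.0
        assert out.p_value == 1.0

    def test_hand_computed_paired_t(self):
        out = compare_fit_models([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])  # differences 1,2,3
        assert out.t_stat == pytest.approx(2 * np.sqrt(3))
        assert out.df == 2

    def test_piecewise_beats_global_on_synthetic_cohort(self, small_normalized):
        fits = per_individual_model_comparison(small_normalized, "rms_p")
        out = compare_fit_models(
            fits["mse_global"].to_numpy(), fits["mse_piecewise"].to_numpy()
        )
        assert out.mean_mse_piecewise < out.mean_mse_global
        assert out.p_value < 0.05
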