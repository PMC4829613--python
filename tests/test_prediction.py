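"""Leave-one-individual-out partitions, 1-D LDA, and the two-stage predictor."""

import numpy as np
import pandas as pd
import pytest
from numpy.random import default_rng

from lepnorm.errors import DegenerateDataError, DomainError, IntegrityError
from lepnorm.normalization import normalize_table
from lepnorm.prediction import (
    CVPartition,
    evaluate_and_compare,
    loio_partitions,
    outcomes_frame,
    run_loio,
    train_lda_1d,
    two_stage_predict,
)


class TestPartitions:
    def test_one_partition_per_individual(self):
        ids = [f"S{i}" for i in range(34)]
        parts = loio_partitions(ids)
        assert len(parts) == 34
        assert sorted(p.held_out for p in parts) == sorted(ids)
        for p in parts:
            assert p.held_out not in p.training_ids
            assert len(p.training_ids) == 33

    def test_two_individuals(self):
        parts = loio_partitions(["A", "B"])
        assert parts[0] == CVPartition("A", ("B",))
        assert parts[1] == CVPartition("B", ("A",))

    def test_duplicates_and_singletons_rejected(self):
        with pytest.raises(IntegrityError):
            loio_partitions(["A", "A", "B"])
        with pytest.raises(DomainError):
            loio_partitions(["A"])


class TestLDA1D:
    def test_equal_priors_boundary_is_midpoint_of_means(self):
        clf = train_lda_1d(
            np.array([0.0, 1.0, 3.0, 4.0]),
            np.array([False, False, True, True]),
            priors="equal",
        )
        assert clf.boundary == pytest.approx(2.0, abs=1e-12)

    def test_decisions_match_sklearn_oracle(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = default_rng(8)
        for _ in range(20):
            x = np.concatenate([rng.normal(0, 1, 15), rng.normal(2, 1, 15)])
            y = np.concatenate([np.zeros(15, bool), np.ones(15, bool)])
            clf = train_lda_1d(x, y, priors="empirical")
            sk = LinearDiscriminantAnalysis().fit(x.reshape(-1, 1), y)
            grid = rng.normal(1, 2, 50)
            np.testing.assert_array_equal(
                clf.predict_high(grid), sk.predict(grid.reshape(-1, 1)).astype(bool)
            )

    def test_direction_flips_when_classes_swap_in_magnitude(self):
        x = np.array([0.0, 1.0, 3.0, 4.0])
        low_is_small = train_lda_1d(x, np.array([False, False, True, True]))
        low_is_large = train_lda_1d(x, np.array([True, True, False, False]))
        probe = np.array([0.5, 3.5])
        np.testing.assert_array_equal(
            low_is_small.predict_high(probe), ~low_is_large.predict_high(probe)
        )

    def test_boundary_converges_to_midpoint_for_gaussian_classes(self):
        rng = default_rng(9)
        n = 10_000
        x = np.concatenate([rng.normal(0, 1, n), rng.normal(4, 1, n)])
        y = np.concatenate([np.zeros(n, bool), np.ones(n, bool)])
        clf = train_lda_1d(x, y, priors="equal")
        assert clf.boundary == pytest.approx(2.0, rel=0.02)

    def test_single_class_training_rejected(self):
        with pytest.raises(DegenerateDataError):
            train_lda_1d(np.array([1.0, 2.0, 3.0]), np.array([True, True, True]))
        with pytest.raises(DegenerateDataError):
            train_lda_1d(np.full(6, 2.0), np.array([True] * 3 + [False] * 3))


def _toy_features(rng, n_ind=4, n_trials=40, scale_jitter=0.0):
    """Feature table with a linear rating->feature rule plus optional scaling."""
    rows = []
    for j in range(n_ind):
        scale = np.exp(scale_jitter * rng.normal())
        for i in range(n_trials):
            rating = int(rng.integers(1, 11))
            rms_s = scale * (10 + rng.normal(0, 1))
            rms_p = scale * (15 + 10 * max(0, rating - 4) + rng.normal(0, 1))
            rows.append(
                {
                    "individual_id": f"S{j}",
                    "trial_index": i,
                    "rating": rating,
                    "rms_s": rms_s,
                    "rms_p": rms_p,
                }
            )
    return pd.DataFrame(rows)


class TestTwoStage:
    def test_stage2_matches_closed_form_ols(self):
        rng = default_rng(1)
        df = _toy_features(rng)
        from lepnorm.prediction import _stage2_fit

        train = df[df["individual_id"] != "S0"]
        alpha, c = _stage2_fit(train, "rms_p")
        high = train[train["rating"] > 4]
        x, y = high["rms_p"].to_numpy(), high["rating"].to_numpy(float)
        slope, intercept = np.polyfit(x, y, 1)
        assert alpha == pytest.approx(slope, abs=1e-9)
        assert c == pytest.approx(intercept, abs=1e-9)

    def test_no_leakage_from_held_out_ratings(self):
        rng = default_rng(2)
        df = _toy_features(rng)
        part = CVPartition("S0", ("S1", "S2", "S3"))
        out1 = two_stage_predict(part, df, "rms_p")
        corrupted = df.copy()
        mask = corrupted["individual_id"] == "S0"
        corrupted.loc[mask, "rating"] = rng.integers(0, 11, mask.sum())
        out2 = two_stage_predict(part, corrupted, "rms_p")
        # same features, possibly different labels: predictions bit-identical
        np.testing.assert_array_equal(
            out1.trials["predicted_high"], out2.trials["predicted_high"]
        )
        np.testing.assert_array_equal(
            out1.trials["predicted_rating"].to_numpy(),
            out2.trials["predicted_rating"].to_numpy(),
        )

    def test_noise_free_unit_scale_cohort_predicts_exactly(self):
        from lepnorm import CohortConfig, baseline_correct, build_feature_table, simulate_cohort

        cfg = CohortConfig(
            n_individuals=4, sampling_rate=200.0, noise_sd=1e-9, scale_sigma=0.0,
            profile_cv=0.0, rating_noise_sd=0.0, trial_jitter_sd=0.0, seed=17,
        )
        trials, _ = simulate_cohort(cfg)
        table = build_feature_table([baseline_correct(t) for t in trials])
        outcomes = run_loio(table, "rms_p")
        for o in outcomes:
            assert o.mae_real_high == pytest.approx(0.0, abs=1e-6)

    def test_perfect_predictions_give_unit_accuracy_and_zero_mae(self):
        # degenerate sanity check of the metric definitions
        rng = default_rng(3)
        df = _toy_features(rng, n_ind=3)
        out = two_stage_predict(CVPartition("S0", ("S1", "S2")), df, "rms_p")
        manual_acc = np.mean(
            out.trials["predicted_high"].to_numpy()
            == (out.trials["rating"].to_numpy() > 4)
        )
        assert out.accuracy == pytest.approx(manual_acc)
        pred = out.trials.dropna(subset=["predicted_rating"])
        manual_mae = np.abs(pred["predicted_rating"] - pred["rating"]).mean()
        assert out.mae_predicted_high == pytest.approx(manual_mae)


class TestEvaluateAndCompare:
    def test_identical_outcomes_have_zero_difference(self):
        rng = default_rng(4)
        df = _toy_features(rng)
        out = run_loio(df, "rms_p")
        summary = evaluate_and_compare(out, out)
        assert (summary["mean_raw"] == summary["mean_norm"]).all()
        assert summary["degenerate"].all()
        assert (summary["p_value"] == 1.0).all()

    def test_mismatched_individual_sets_rejected(self):
        rng = default_rng(5)
        df = _toy_features(rng)
        out = run_loio(df, "rms_p")
        with pytest.raises(IntegrityError):
            evaluate_and_compare(out, out[:-1])

    def test_paired_t_hand_value(self):
        from lepnorm.prediction import _paired_t

        t, p, degenerate = _paired_t(np.array([1.0, 2.0, 3.0]))
        assert t == pytest.approx(2 * np.sqrt(3))
        assert not degenerate

    def test_scale_jitter_degrades_raw_but_not_normalized(self, small_normalized):
        rng = default_rng(6)
        base = small_normalized
        out_raw_0 = run_loio(base, "rms_p")
        out_norm_0 = run_loio(base, "nrms_p")
        jittered = base.drop(columns="nrms_p").copy()
        factors = {
            ind: float(np.exp(rng.normal(0, 0.6)))
            for ind in jittered["individual_id"].unique()
        }
        jittered[["rms_s", "rms_p"]] = jittered[["rms_s", "rms_p"]].mul(
            jittered["individual_id"].map(factors), axis=0
        )
        jittered = normalize_table(jittered)
        out_raw_1 = run_loio(jittered, "rms_p")
        out_norm_1 = run_loio(jittered, "nrms_p")
        mae = lambda outs: np.nanmean(outcomes_frame(outs)["mae_real_high"])
        assert mae(out_raw_1) > mae(out_raw_0)
        assert mae(out_norm_1) == pytest.approx(mae(out_norm_0), abs=1e-9)
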