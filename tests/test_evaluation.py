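"""Evaluation reports: metric closed forms, correlation oracle, gender
statistics, PMV comparison and signal ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thermosense.evaluation import (
    DEFAULT_RANK_GROUPS,
    compare_with_pmv,
    correlation_table,
    gender_error_test,
    mann_whitney_z,
    metrics,
    rank_signals,
    ttest_type1_rate,
)
from thermosense.selection import ModelSpec, Protocol


class TestMetrics:
    def test_perfect_prediction(self):
        assert metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_mean_predictor_r2_zero(self):
        truth = np.array([1.0, 2.0, 3.0, 6.0])
        rmse, r2 = metrics(np.full(4, truth.mean()), truth)
        assert r2 == pytest.approx(0.0)

    def test_closed_form_pair(self):
        rmse, r2 = metrics([0.0, 0.0], [1.0, -1.0])
        assert rmse == pytest.approx(1.0)
        assert r2 == pytest.approx(0.0)

    def test_zero_variance_truth_signalled(self):
        with pytest.warns(UserWarning, match="undefined"):
            rmse, r2 = metrics([1.0, 2.0], [3.0, 3.0])
        assert np.isnan(r2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            metrics([1.0], [1.0, 2.0])


class TestCorrelationTable:
    def test_identity_feature(self):
        df = pd.DataFrame({"reported_ts": [1.0, 2.0, 3.0, 5.0], "f": [1.0, 2.0, 3.0, 5.0]})
        row = correlation_table(df).iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-6
        assert row["sig"] == "**"

    def test_collinear_hand_table(self):
        df = pd.DataFrame({"reported_ts": [2.0, 4.0, 6.0], "f": [1.0, 2.0, 3.0]})
        assert correlation_table(df).iloc[0]["r"] == pytest.approx(1.0)

    def test_independent_noise_small_r(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "reported_ts": rng.integers(-3, 4, 90).astype(float),
            "f": rng.standard_normal(90),
        })
        assert abs(correlation_table(df).iloc[0]["r"]) < 0.3

    def test_agrees_with_covariance_oracle(self):
        """Pearson r must equal the explicit covariance formula to 1e-9."""
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "reported_ts": rng.normal(size=50),
            "a": rng.normal(size=50),
            "b": rng.uniform(size=50),
        })
        out = correlation_table(df).set_index("feature")
        y = df["reported_ts"].to_numpy()
        for f in ("a", "b"):
            x = df[f].to_numpy()
            oracle = (
                np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
            )
            assert out.loc[f, "r"] == pytest.approx(oracle, abs=1e-9)

    def test_constant_feature_flagged(self):
        df = pd.DataFrame({"reported_ts": [1.0, 2.0, 3.0], "f": [4.0, 4.0, 4.0]})
        row = correlation_table(df).iloc[0]
        assert np.isnan(row["r"]) and row["flag"] == "constant"

    def test_stars_match_pvalues(self, clean_feature_table):
        out = correlation_table(clean_feature_table)
        for _, row in out.dropna(subset=["p"]).iterrows():
            expected = "**" if row["p"] < 0.01 else ("*" if row["p"] < 0.05 else "")
            assert row["sig"] == expected


class TestMannWhitney:
    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=14)
        b = rng.normal(0.4, 1.0, size=11)
        u, z, p = mann_whitney_z(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert u == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_tie_correction_applied(self):
        a = [1.0, 1.0, 2.0, 2.0, 5.0]
        b = [1.0, 2.0, 2.0, 3.0]
        u, z, p = mann_whitney_z(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_all_tied_degenerate(self):
        u, z, p = mann_whitney_z([1.0, 1.0], [1.0, 1.0, 1.0])
        assert z == 0.0 and p == 1.0


class TestGender:
    def test_identical_errors_give_t_zero(self):
        """Hand-built identical male/female error samples: t = 0, p = 1."""
        t, p = stats.ttest_ind([-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0], equal_var=True)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_report_structure_and_counts(self, feature_table):
        rep = gender_error_test(
            feature_table, ModelSpec("linear"), ["EnvTemp", "T3_calf"], seed=0
        )
        n_test = sum(rep.test_counts)
        n_total = len(feature_table)
        assert sum(rep.train_counts) + n_test == n_total
        assert set(rep.group_summary["group"]) == {"male", "female"}
        assert rep.rmse_overall > 0

    def test_stratified_split_preserves_sex(self, feature_table):
        rep = gender_error_test(
            feature_table, ModelSpec("linear"), ["EnvTemp"], seed=1
        )
        n_m = (feature_table["sex"] == "male").sum()
        n_f = (feature_table["sex"] == "female").sum()
        assert rep.train_counts[0] + rep.test_counts[0] == n_m
        assert rep.train_counts[1] + rep.test_counts[1] == n_f

    def test_impossible_counts_rejected(self, feature_table):
        with pytest.raises(ValueError, match="empty group"):
            gender_error_test(feature_table, ModelSpec("linear"), ["EnvTemp"],
                              train_counts=(10_000, 1), seed=0)

    def test_type1_error_calibrated(self):
        """Pooled t-test rejects a true null at about the nominal 5% rate."""
        rate = ttest_type1_rate(n_a=10, n_b=8, repeats=1000, seed=0)
        assert 0.03 <= rate <= 0.07

    def test_deterministic_for_seed(self, feature_table):
        a = gender_error_test(feature_table, ModelSpec("linear"), ["EnvTemp"], seed=5)
        b = gender_error_test(feature_table, ModelSpec("linear"), ["EnvTemp"], seed=5)
        assert a.t_stat == b.t_stat and a.u_stat == b.u_stat


class TestCompareWithPMV:
    def test_oracle_features_give_zero_rmse(self, feature_table):
        tab = feature_table.copy()
        tab["oracle"] = tab["reported_ts"].astype(float)
        rep = compare_with_pmv(tab, ModelSpec("linear"), ["oracle"], seed=0)
        assert np.allclose(rep.trials["model_rmse"], 0.0, atol=1e-9)
        assert np.allclose(rep.trials["model_r2"], 1.0, atol=1e-9)

    def test_constant_pmv_r2_nonpositive(self, feature_table):
        # a single-setting table makes PMV a constant predictor
        one = feature_table[feature_table["EnvTemp"] == 23.0]
        one = one[one["EnvWind"] == one["EnvWind"].iloc[0]]
        one = one[one["EnvRH"] == one["EnvRH"].iloc[0]]
        if len(one) >= 10:
            rep = compare_with_pmv(one, ModelSpec("linear"), ["EnvTemp"],
                                   n_trials=1, seed=0)
            assert rep.trials["pmv_r2"].iloc[0] <= 0.0

    def test_averages_recompute_from_trials(self, feature_table):
        rep = compare_with_pmv(feature_table, ModelSpec("linear"),
                               ["EnvTemp", "T3_calf"], seed=2)
        for col, val in rep.averages.items():
            assert val == pytest.approx(rep.trials[col].mean())

    def test_split_sizes(self, feature_table):
        rep = compare_with_pmv(feature_table, ModelSpec("linear"), ["EnvTemp"], seed=0)
        assert rep.train_n == int(round(0.8 * len(feature_table)))
        assert rep.train_n + rep.test_n == len(feature_table)


class TestRankSignals:
    def test_single_group_two_rows(self, feature_table):
        out = rank_signals(feature_table, ModelSpec("linear"),
                           groups=(("EMG", ("EMG_MAV", "EMG_RMS")),),
                           protocol=Protocol(5, 1, 0))
        assert len(out) == 2
        assert out.iloc[0]["signals"] == "Environment"
        assert out.iloc[1]["signals"] == "Environment, EMG"

    def test_mocked_equal_performance_tie_by_declared_order(self, monkeypatch):
        calls = []

        def fake_eval(features, table, model, protocol, target="reported_ts"):
            from thermosense.selection import PerformanceEstimate

            calls.append(tuple(sorted(features)))
            return PerformanceEstimate(rmse=1.0, r2=0.0, protocol=protocol)

        import thermosense.evaluation as ev

        monkeypatch.setattr(ev, "evaluate_subset", fake_eval)
        df = pd.DataFrame({c: [0.0] for c in
                           ("EnvTemp", "EnvWind", "EnvRH", "A", "B", "reported_ts")})
        out = ev.rank_signals(df, ModelSpec("linear"),
                              groups=(("G1", ("A",)), ("G2", ("B",))))
        assert out.iloc[1]["signals"] == "Environment, G1"
        assert out.iloc[2]["signals"] == "Environment, G1, G2"

    def test_full_ranking_structure(self, feature_table):
        out = rank_signals(feature_table, ModelSpec("linear"),
                           protocol=Protocol(5, 1, 0))
        assert len(out) == len(DEFAULT_RANK_GROUPS) + 1
        assert list(out["n_signals"]) == list(range(len(DEFAULT_RANK_GROUPS) + 1))

    def test_strongest_injected_signal_added_first(self):
        """A cohort where EMG carries by far the strongest response must
        rank the EMG group ahead of the others."""
        import warnings

        from thermosense.cohort import GeneratorConfig, generate_cohort
        from thermosense.features import build_feature_table

        cfg = GeneratorConfig.compact(
            corruption_prob=0.0,
            emg_decay=0.5, emg_trial_sigma=0.0,
            gain_sigma={"ECG_RR": 0.3, "EMG": 0.02, "EEG": 0.3, "GSR": 0.3},
            temp_slope={"TEMP_CHEST": 0.01, "TEMP_FOREARM": 0.01, "TEMP_CALF": 0.02},
            eeg_beta_slope=0.01, sdnn_ts_slope=0.0, lfhf_c1=0.05,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = build_feature_table(generate_cohort(cfg, 0), screen=False)
            out = rank_signals(table, ModelSpec("linear"), protocol=Protocol(5, 1, 0))
        assert out.iloc[1]["signals"] == "Environment, EMG"

    def test_missing_group_feature_rejected(self, feature_table):
        with pytest.raises(KeyError, match="ghost"):
            rank_signals(feature_table, ModelSpec("linear"),
                         groups=(("X", ("ghost",)),))
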