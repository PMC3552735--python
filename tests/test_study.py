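import numpy as np
import pandas as pd
import pytest

import modedif as md
from modedif.bayes import McmcSchedule
from modedif.study import (
    ConditionSpec,
    auc_difference_test,
    classification_metrics,
    condition_summary,
    describe_statistics,
    roc_auc,
    run_condition,
    _quadratic_logit_probs,
)


def _records(truth, flag_rz=None, flag_cri=None, rz=None, delta_cri=None, **cond):
    n = len(truth)
    base = dict(model="1PL", dif_size=0.42, dif_pct=10, mu_cat=0.0, rep=0)
    base.update(cond)
    return pd.DataFrame(
        {
            **{k: [v] * n for k, v in base.items()},
            "item": np.arange(1, n + 1),
            "dif_truth": truth,
            "usage": 100,
            "rz": rz if rz is not None else np.zeros(n),
            "delta_cri": delta_cri if delta_cri is not None else np.zeros(n),
            "flag_rz": flag_rz if flag_rz is not None else np.zeros(n, dtype=int),
            "flag_cri": flag_cri if flag_cri is not None else np.zeros(n, dtype=int),
        }
    )


class TestClassificationMetrics:
    def test_all_correct(self):
        rec = _records([1, 1, 0, 0], flag_rz=[1, 1, 0, 0])
        m = classification_metrics(rec, "rz")
        assert m["sensitivity"] == m["specificity"] == m["correct_classification"] == 100.0

    def test_hand_count(self):
        rec = _records([1, 1, 0, 0], flag_rz=[1, 0, 0, 1])
        m = classification_metrics(rec, "rz")
        assert m["sensitivity"] == 50.0
        assert m["specificity"] == 50.0
        assert m["correct_classification"] == 50.0

    def test_random_flags_near_fifty_percent(self):
        rng = np.random.default_rng(0)
        n = 20000
        rec = _records(
            rng.integers(0, 2, n).tolist(), flag_cri=rng.integers(0, 2, n).tolist()
        )
        m = classification_metrics(rec, "cri")
        assert m["sensitivity"] == pytest.approx(50.0, abs=1.5)
        assert m["specificity"] == pytest.approx(50.0, abs=1.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(_records([]), "rz")

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(_records([1, 0]), "wald")


class TestRocAuc:
    def test_constant_scores_give_half(self):
        rec = _records([1, 0, 1, 0] * 10, rz=np.ones(40))
        assert roc_auc(rec, "rz") == pytest.approx(0.5)

    def test_truth_as_scores_gives_one(self):
        truth = [1, 0] * 20
        rec = _records(truth, rz=np.array(truth, dtype=float) * 3.0)
        assert roc_auc(rec, "rz") == pytest.approx(1.0)

    def test_matches_all_pairs_oracle(self):
        """Mann-Whitney pair counting on the fitted probabilities."""
        rng = np.random.default_rng(11)
        truth = rng.integers(0, 2, 20)
        truth[:2] = [0, 1]
        rec = _records(truth.tolist(), rz=rng.normal(truth * 2.0, 1.0))
        probs = _quadratic_logit_probs(rec, "rz")
        pos = probs[truth == 1]
        neg = probs[truth == 0]
        wins = sum(
            1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
        )
        oracle = wins / (len(pos) * len(neg))
        assert roc_auc(rec, "rz") == pytest.approx(oracle, abs=1e-10)

    def test_quadratic_fit_preserves_absolute_ranking(self):
        rng = np.random.default_rng(13)
        truth = rng.integers(0, 2, 400)
        rz = rng.normal(0, 1, 400) + truth * rng.choice([-2.5, 2.5], 400)
        rec = _records(truth.tolist(), rz=rz)
        from sklearn.metrics import roc_auc_score

        raw = roc_auc_score(truth, np.abs(rz))
        assert roc_auc(rec, "rz") >= raw - 0.02

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(_records([1, 1, 1], rz=np.ones(3)), "rz")


class TestAucDifferenceTest:
    def test_identical_scores(self):
        rng = np.random.default_rng(17)
        truth = rng.integers(0, 2, 60)
        truth[:2] = [0, 1]
        s = rng.normal(truth * 2.0, 1.0)
        rec = _records(truth.tolist(), rz=s, delta_cri=s)
        out = auc_difference_test(rec)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_null_rejection_rate_near_alpha(self):
        """Independent random scores reject at ~the nominal 5% level."""
        rng = np.random.default_rng(19)
        n, rejections, sims = 150, 0, 400
        for _ in range(sims):
            truth = np.r_[np.ones(40, dtype=int), np.zeros(n - 40, dtype=int)]
            rec = _records(
                truth.tolist(), rz=rng.normal(size=n), delta_cri=rng.normal(size=n)
            )
            if auc_difference_test(rec, fit_quadratic=False)["p"] < 0.05:
                rejections += 1
        assert 0.02 <= rejections / sims <= 0.09


class TestDescribeStatistics:
    def test_constant_vector(self):
        rec = _records([0] * 50, rz=np.full(50, 0.7))
        out = describe_statistics(rec)
        row = out[out.statistic == "rz"].iloc[0]
        assert row["sd"] == pytest.approx(0.0, abs=1e-12)
        assert row["p2.5"] == row["p97.5"] == 0.7

    def test_standard_normal_moments(self):
        rng = np.random.default_rng(23)
        n = 200000
        rec = _records([0] * n, rz=rng.standard_normal(n))
        row = describe_statistics(rec).iloc[0]
        assert row["mean"] == pytest.approx(0.0, abs=0.02)
        assert row["sd"] == pytest.approx(1.0, abs=0.02)
        assert row["p2.5"] == pytest.approx(-1.96, abs=0.03)
        assert row["excess_kurtosis"] == pytest.approx(0.0, abs=0.06)

    def test_requires_non_dif_records(self):
        with pytest.raises(ValueError):
            describe_statistics(_records([1, 1]))


class TestConditionSummary:
    def test_rates_complement_within_condition(self):
        rng = np.random.default_rng(29)
        truth = rng.integers(0, 2, 200).tolist()
        rec = _records(truth, flag_rz=rng.integers(0, 2, 200).tolist())
        row = condition_summary(rec).iloc[0]
        dif = rec[rec.dif_truth == 1]
        non = rec[rec.dif_truth == 0]
        fn_pct = 100.0 * (1 - dif.flag_rz).mean()
        tn_pct = 100.0 * (1 - non.flag_rz).mean()
        assert row["tp_rz"] + fn_pct == pytest.approx(100.0)
        assert row["fp_rz"] + tn_pct == pytest.approx(100.0)

    def test_no_dif_items_gives_nan_tp(self):
        rec = _records([0] * 30)
        row = condition_summary(rec).iloc[0]
        assert np.isnan(row["tp_rz"]) and row["fp_rz"] == 0.0


class TestRunCondition:
    TINY = ConditionSpec(
        model="1PL", dif_size=0.63, dif_pct=25, mu_cat=0.0, n_reps=1,
        n_items=16, n_pp=80, n_cat=120, test_length=8,
    )
    SCHED = McmcSchedule(n_chains=1, burn_in=60, keep=60)

    def test_deterministic_given_master_seed(self):
        a = run_condition(self.TINY, 5, schedule=self.SCHED, min_usage=5)
        b = run_condition(self.TINY, 5, schedule=self.SCHED, min_usage=5)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_record_structure(self):
        res = run_condition(self.TINY, 5, schedule=self.SCHED, min_usage=5)
        rec = res.records
        assert len(rec) == 16
        assert rec.dif_truth.sum() == 4  # 25% of 16
        assert rec.usage.sum() == 120 * 8
        assert set(rec.columns) >= {"rz", "delta_cri", "flag_rz", "flag_cri", "beta_pp"}
        assert res.summary.shape[0] == 1
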