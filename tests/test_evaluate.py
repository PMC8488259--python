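"""Cross-validation protocol, AUC, aggregation, ANOVA/Tukey comparisons,
LR importance and the dummy baseline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

import _oracles
from gazespeech.errors import (
    CohortCompositionError,
    ContractViolationError,
    StratificationError,
)
from gazespeech.evaluate import (
    aggregate,
    auc,
    compare_models,
    dummy_baseline,
    lr_importance,
    odds_ratio_ci,
    per_repeat_means,
    repeated_stratified_cv,
)


class TestRepeatedStratifiedCV:
    def test_balanced_20_into_10_folds(self):
        y = np.array([0, 1] * 10)
        cv = repeated_stratified_cv(y, k=10, repeats=1, seed=0)
        for _, test_idx in cv[0]:
            assert len(test_idx) == 2
            assert y[test_idx].sum() == 1  # exactly 1 patient + 1 control

    def test_partition_laws(self):
        y = np.array([0] * 13 + [1] * 17)
        cv = repeated_stratified_cv(y, k=5, repeats=3, seed=1)
        assert len(cv) == 3
        for folds in cv:
            tests = [set(te) for _, te in folds]
            union = set().union(*tests)
            assert union == set(range(30))
            assert sum(len(t) for t in tests) == 30  # pairwise disjoint

    def test_records_count_k_times_repeats(self):
        y = np.array([0, 1] * 20)
        cv = repeated_stratified_cv(y, k=10, repeats=10, seed=2)
        assert sum(len(folds) for folds in cv) == 100

    def test_reproducible_and_repeats_distinct(self):
        y = np.array([0, 1] * 15)
        a = repeated_stratified_cv(y, k=5, repeats=2, seed=9)
        b = repeated_stratified_cv(y, k=5, repeats=2, seed=9)
        for fa, fb in zip(a[0] + a[1], b[0] + b[1]):
            assert np.array_equal(fa[1], fb[1])
        assert any(
            not np.array_equal(x[1], y_[1]) for x, y_ in zip(a[0], a[1])
        )

    def test_small_class_raises(self):
        y = np.array([0] * 20 + [1] * 3)
        with pytest.raises(StratificationError):
            repeated_stratified_cv(y, k=10, repeats=1, seed=0)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_pair_counting_example(self):
        scores = [0.9, 0.6, 0.7, 0.1]
        labels = [1, 1, 0, 0]
        assert auc(scores, labels) == pytest.approx(0.75)

    def test_all_ties_is_half(self):
        assert auc([0.5] * 6, [0, 1] * 3) == pytest.approx(0.5)

    def test_single_class_undefined(self):
        with pytest.raises(CohortCompositionError):
            auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_brute_force_and_library(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        scores = np.round(rng.uniform(size=n), 2)  # rounding forces ties
        ours = auc(scores, labels)
        assert ours == pytest.approx(_oracles.auc_pair_counting(scores, labels))
        assert ours == pytest.approx(roc_auc_score(labels, scores))


class TestAggregate:
    def _records(self, aucs):
        rows = []
        for r in range(len(aucs)):
            for f in range(len(aucs[r])):
                rows.append({"model": "m", "algorithm": "LR", "repeat": r,
                             "fold": f, "auc": aucs[r][f]})
        return pd.DataFrame(rows)

    def test_constant_aucs(self):
        out = aggregate(self._records([[0.7] * 5] * 3))
        assert out["mean_auc"].iloc[0] == pytest.approx(0.7)
        assert out["sd"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_mean_and_sd_by_hand(self):
        aucs = [[0.6, 0.8], [0.5, 0.7]]
        out = aggregate(self._records(aucs))
        assert out["mean_auc"].iloc[0] == pytest.approx(0.65)
        per_repeat = [0.7, 0.6]
        assert out["sd"].iloc[0] == pytest.approx(np.std(per_repeat, ddof=1))

    def test_missing_folds_refused(self):
        rec = self._records([[0.6, np.nan]])
        with pytest.raises(ContractViolationError):
            aggregate(rec)


class TestCompareModels:
    def _two_group_records(self, a, b):
        rows = []
        for name, vals in (("model_a", a), ("model_b", b)):
            for r, v in enumerate(vals):
                rows.append({"model": name, "algorithm": "LR", "repeat": r,
                             "fold": 0, "auc": v})
        return pd.DataFrame(rows)

    def test_one_way_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.7, 0.02, 10)
        b = rng.normal(0.74, 0.02, 10)
        anova, _ = compare_models(self._two_group_records(a, b))
        t, _ = sps.ttest_ind(a, b)
        assert anova["F"].iloc[0] == pytest.approx(t ** 2)

    def test_identical_groups_f_near_zero(self):
        vals = np.full(10, 0.7) + np.tile([0.001, -0.001], 5)
        rec = self._two_group_records(vals, vals)
        anova, pairs = compare_models(rec)
        assert anova["F"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert float(pairs["p_adj"].iloc[0]) > 0.9

    def test_tukey_matches_studentized_range_oracle(self):
        rng = np.random.default_rng(7)
        groups = {
            "g1": rng.normal(0.60, 0.02, 10),
            "g2": rng.normal(0.65, 0.02, 10),
            "g3": rng.normal(0.72, 0.02, 10),
        }
        rows = []
        for name, vals in groups.items():
            for r, v in enumerate(vals):
                rows.append({"model": name, "algorithm": "LR", "repeat": r,
                             "fold": 0, "auc": v})
        rec = pd.DataFrame(rows)
        _, pairs = compare_models(rec)
        df = per_repeat_means(rec)
        k, n = 3, 10
        grand = df.groupby("model_id")["auc"].mean()
        mse = df.groupby("model_id")["auc"].var(ddof=1).mean()
        df_err = k * (n - 1)
        for _, row in pairs.iterrows():
            expected = _oracles.tukey_pvalue(
                grand[row["group1"]], grand[row["group2"]], mse, n, k, df_err
            )
            assert float(row["p_adj"]) == pytest.approx(expected, abs=2e-3)

    def test_unbalanced_design_refused(self):
        rec = self._two_group_records(np.full(10, 0.7), np.full(10, 0.7))
        rec = rec.iloc[:-1]
        with pytest.raises(ContractViolationError):
            compare_models(rec)


class TestLrImportance:
    def test_odds_ratio_closed_form(self):
        or_, (lo, hi) = odds_ratio_ci(np.log(2.0), 0.1)
        assert or_ == pytest.approx(2.0)
        assert lo < 2.0 < hi
        assert lo == pytest.approx(np.exp(np.log(2) - 1.96 * 0.1))

    def test_zero_coefficient_unit_odds_ratio(self):
        assert odds_ratio_ci(0.0)[0] == 1.0

    def test_table_shape_and_internal_consistency(self):
        rng = np.random.default_rng(12)
        n = 120
        y = np.array([0, 1] * (n // 2))
        X = pd.DataFrame({
            "informative": y + rng.normal(0, 1.0, n),
            "noise": rng.normal(0, 1.0, n),
        })
        table = lr_importance(X, y)
        assert list(table["feature"])[0] == "informative"
        for _, row in table.iterrows():
            assert row["odds_ratio"] == pytest.approx(np.exp(row["coefficient"]))
            if not row["separation_flag"]:
                assert row["ci_low"] <= row["odds_ratio"] <= row["ci_high"]
            assert row["direction"] == ("+" if row["coefficient"] >= 0 else "-")


class TestDummyBaseline:
    def test_seeded_rerun_identical(self):
        y = np.array([0, 1] * 20)
        cv = repeated_stratified_cv(y, k=5, repeats=2, seed=0)
        a = dummy_baseline(y, cv, seed=3)
        b = dummy_baseline(y, cv, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_fold_aucs_symmetric_about_half(self):
        y = np.array([0, 1] * 40)
        cv = repeated_stratified_cv(y, k=10, repeats=10, seed=1)
        rec = dummy_baseline(y, cv, seed=5)
        devs = rec["auc"] - 0.5
        n_pos = (devs > 0).sum()
        n = (devs != 0).sum()
        p = sps.binomtest(int(n_pos), int(n)).pvalue
        assert p > 0.01
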