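"""Labeling, feature selection, nested CV, threshold calibration, filtering."""

import numpy as np
import pandas as pd
import pytest

from pinpool import PoolCallSet, calibrate_thresholds
from pinpool.filtering import (
    CVSpec,
    FilterModel,
    PoolVariantFilter,
    apply_filter,
    default_hard_filters,
    hard_filter,
    label_calls,
    load_model,
    mrmr_select,
    prune_correlated,
    save_model,
    train_nested_cv,
)
from pinpool.variants import AnnotatedCall, VariantKey


def make_calls(specs, pool_id="p1"):
    """specs: list of (pos, ref, alt, annotations)"""
    return PoolCallSet.from_calls(
        pool_id,
        "row",
        1,
        [AnnotatedCall(VariantKey("chr1", pos, ref, alt), ann, pool_id) for pos, ref, alt, ann in specs],
    )


GOOD_SNV = {"QD": 20.0, "FS": 1.0, "MQ": 60.0, "MQRankSum": 0.0, "ReadPosRankSum": 0.0, "SOR": 1.0}


class TestLabelCalls:
    def test_membership_labels_and_row_count(self):
        calls = make_calls(
            [(10, "A", "G", {"QD": 5.0}), (20, "C", "T", {"QD": 6.0}), (30, "G", "A", {"QD": 7.0})]
        )
        truth = {VariantKey("chr1", 10, "A", "G"), VariantKey("chr1", 30, "G", "A"),
                 VariantKey("chr1", 99, "T", "C")}  # the FN produces no row
        table = label_calls(calls, truth, features=["QD", "FS"])
        assert len(table) == 3
        assert table.set_index("pos")["label"].to_dict() == {10: 1, 20: 0, 30: 1}
        assert table["FS"].isna().all()  # missing features explicit


class TestPruneCorrelated:
    def _table(self, cols):
        df = pd.DataFrame(cols)
        df["label"] = 0
        return df

    def test_duplicated_column_dropped(self, rng):
        x = rng.normal(size=100)
        table = self._table({"A": x, "B": x, "C": rng.normal(size=100)})
        assert prune_correlated(table, features=["A", "B", "C"]) == ["A", "C"]

    def test_independent_noise_kept(self, rng):
        table = self._table({"A": rng.normal(size=200), "B": rng.normal(size=200)})
        assert prune_correlated(table, features=["A", "B"]) == ["A", "B"]

    def test_constant_feature_excluded_with_warning(self, rng):
        table = self._table({"A": np.ones(50), "B": rng.normal(size=50)})
        with pytest.warns(UserWarning, match="constant"):
            assert prune_correlated(table, features=["A", "B"]) == ["B"]


class TestMRMR:
    def _table(self, rng, n=200):
        y = rng.integers(0, 2, size=n)
        return pd.DataFrame(
            {
                "label": y,
                "signal": y * 3.0 + rng.normal(0, 0.3, n),
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
            }
        )

    def test_separating_feature_selected_first(self, rng):
        table = self._table(rng)
        assert mrmr_select(table, 1, features=["noise1", "signal", "noise2"]) == ["signal"]

    def test_k_zero_empty(self, rng):
        assert mrmr_select(self._table(rng), 0) == []

    def test_k_all_returns_everything_once(self, rng):
        table = self._table(rng)
        sel = mrmr_select(table, 3, features=["signal", "noise1", "noise2"])
        assert sorted(sel) == ["noise1", "noise2", "signal"]
        assert sel[0] == "signal"

    def test_k_too_large_raises(self, rng):
        with pytest.raises(ValueError):
            mrmr_select(self._table(rng), 10, features=["signal"])


class TestCalibrateThresholds:
    def test_enumerated_toy_example(self):
        t_f1, t_s99 = calibrate_thresholds([0.9, 0.8, 0.7, 0.4, 0.3], [1, 1, 0, 1, 0])
        assert t_f1 == pytest.approx(0.4)
        assert t_s99 == pytest.approx(0.4)
        # F1 at that threshold is 6/7
        passed_tp, passed_fp, fn = 3, 1, 0
        assert 2 * passed_tp / (2 * passed_tp + passed_fp + fn) == pytest.approx(6 / 7)

    def test_perfect_separation_keeps_full_sensitivity(self):
        t_f1, t_s99 = calibrate_thresholds([1.0, 1.0, 0.0, 0.0], [1, 1, 0, 0])
        probs = np.array([1.0, 1.0, 0.0, 0.0])
        labels = np.array([1, 1, 0, 0])
        for t in (t_f1, t_s99):
            sens = ((probs >= t) & (labels == 1)).sum() / labels.sum()
            assert sens == 1.0

    def test_all_positive_labels(self):
        t_f1, t_s99 = calibrate_thresholds([0.2, 0.5, 0.9], [1, 1, 1])
        assert t_s99 == pytest.approx(0.2)

    def test_pass_count_monotone_in_threshold(self, rng):
        probs = rng.random(100)
        thresholds = np.sort(rng.random(20))
        counts = [(probs >= t).sum() for t in thresholds]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            calibrate_thresholds([1.5], [1])


def separable_table(rng, n=300):
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
    return pd.DataFrame({"f1": y * 4.0 + rng.normal(0, 0.5, n), "f2": rng.normal(size=n)}), y


class TestPoolVariantFilter:
    @pytest.mark.parametrize("family", ["lr", "rf", "xgb", "gmm"])
    def test_all_families_learn_separable_data(self, family, rng):
        X, y = separable_table(rng, 160)
        est = PoolVariantFilter(family=family, repetitions=1, outer_folds=3,
                                inner_folds=2, random_state=0).fit(X, y)
        assert est.n_outer_models_ == 3
        assert est.oof_auroc() > 0.95
        assert 0.0 <= est.t_f1_ <= 1.0 and 0.0 <= est.t_s99_ <= 1.0

    def test_oof_covers_every_row_every_repetition(self, rng):
        X, y = separable_table(rng, 120)
        est = PoolVariantFilter(repetitions=2, outer_folds=4, inner_folds=2,
                                random_state=1).fit(X, y)
        per_rep = est.oof_.groupby("repetition")["row"].apply(lambda s: sorted(s))
        for rows in per_rep:
            assert rows == list(range(120))

    def test_single_class_rejected(self):
        X = pd.DataFrame({"f": np.arange(30.0)})
        with pytest.raises(ValueError, match="both labels"):
            PoolVariantFilter().fit(X, np.ones(30, dtype=int))

    def test_too_small_minority_class_explicit_message(self):
        X = pd.DataFrame({"f": np.arange(40.0)})
        y = np.r_[np.zeros(37), np.ones(3)].astype(int)
        with pytest.raises(ValueError, match="minority class"):
            PoolVariantFilter(outer_folds=10).fit(X, y)

    def test_sklearn_params_roundtrip(self):
        est = PoolVariantFilter(family="rf", repetitions=2)
        params = est.get_params()
        assert params["family"] == "rf"
        est.set_params(family="lr")
        assert est.family == "lr"

    def test_persistence_bit_identical(self, rng, tmp_path):
        X, y = separable_table(rng, 100)
        _, model = train_nested_cv(
            pd.concat([X, pd.Series(y, name="label")], axis=1),
            "rf",
            CVSpec(1, 3, 2),
            seed=0,
            features=["f1", "f2"],
        )
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        probe = X.iloc[:20]
        np.testing.assert_array_equal(
            model.estimator.predict_proba(probe), loaded.estimator.predict_proba(probe)
        )
        assert loaded.t_f1 == model.t_f1 and loaded.t_s99 == model.t_s99


def _toy_models(rng):
    """One SNV and one INDEL model trained on small separable tables."""
    models = {}
    for vtype in ("SNV", "INDEL"):
        X, y = separable_table(rng, 80)
        table = pd.concat([X, pd.Series(y, name="label")], axis=1)
        _, model = train_nested_cv(table, "lr", CVSpec(1, 3, 2), seed=0,
                                   features=["f1", "f2"], vtype=vtype)
        models[vtype] = model
    return models["SNV"], models["INDEL"]


class TestApplyFilter:
    def _calls(self):
        return make_calls(
            [
                (10, "A", "G", {"f1": 5.0, "f2": 0.0}),   # SNV, clearly class 1
                (20, "C", "T", {"f1": -1.0, "f2": 0.0}),  # SNV, clearly class 0
                (30, "CA", "C", {"f1": 5.0, "f2": 0.0}),  # INDEL, class 1
            ]
        )

    def test_zero_thresholds_pass_everything(self, rng):
        snv, indel = _toy_models(rng)
        snv.estimator.t_f1_ = indel.estimator.t_f1_ = 0.0
        filtered, sidecar = apply_filter(self._calls(), snv, indel, "F1")
        assert filtered.keys() == self._calls().keys()
        assert sidecar["passed"].all()

    def test_threshold_above_max_empties_output(self, rng):
        snv, indel = _toy_models(rng)
        snv.estimator.t_f1_ = indel.estimator.t_f1_ = 1.0 + 1e-9
        filtered, _ = apply_filter(self._calls(), snv, indel, "F1")
        assert len(filtered) == 0

    def test_pass_set_matches_manual_threshold_comparison(self, rng):
        snv, indel = _toy_models(rng)
        calls = self._calls()
        filtered, sidecar = apply_filter(calls, snv, indel, "S99")
        for _, row in sidecar.iterrows():
            model = snv if row["vtype"] == "SNV" else indel
            assert row["passed"] == (row["prob"] >= model.t_s99)
        assert filtered.keys() == {
            VariantKey("chr1", int(r["pos"]), r["ref"], r["alt"])
            for _, r in sidecar[sidecar["passed"]].iterrows()
        }

    def test_missing_model_passes_with_warning(self, rng):
        snv, _ = _toy_models(rng)
        with pytest.warns(UserWarning, match="no INDEL model"):
            filtered, _ = apply_filter(self._calls(), snv, None, "F1")
        assert VariantKey("chr1", 30, "CA", "C") in filtered.keys()

    def test_wrong_scope_rejected(self, rng):
        snv, indel = _toy_models(rng)
        with pytest.raises(ValueError, match="scope"):
            apply_filter(self._calls(), indel, snv, "F1")


class TestHardFilter:
    def test_comfortable_call_passes(self):
        calls = make_calls([(10, "A", "G", dict(GOOD_SNV))])
        assert hard_filter(calls).keys() == calls.keys()

    def test_low_quality_by_depth_fails(self):
        ann = dict(GOOD_SNV, QD=1.0)
        calls = make_calls([(10, "A", "G", ann)])
        assert len(hard_filter(calls)) == 0

    def test_missing_annotation_does_not_fail(self):
        calls = make_calls([(10, "A", "G", {"QD": 25.0})])
        assert len(hard_filter(calls)) == 1

    def test_rule_by_rule_toy_set(self):
        """10 calls, 4 violating exactly one rule each -> 6 survive."""
        violations = [
            dict(GOOD_SNV, QD=0.5),
            dict(GOOD_SNV, FS=100.0),
            dict(GOOD_SNV, MQ=20.0),
            dict(GOOD_SNV, SOR=5.0),
        ]
        specs = [(10 * (i + 1), "A", "G", dict(GOOD_SNV)) for i in range(6)]
        specs += [(100 + 10 * i, "A", "G", ann) for i, ann in enumerate(violations)]
        assert len(hard_filter(make_calls(specs))) == 6

    def test_indel_table_is_separate(self):
        # FS of 100 fails an SNV (cutoff 60) but passes an indel (cutoff 200)
        snv = make_calls([(10, "A", "G", {"FS": 100.0})])
        indel = make_calls([(10, "CA", "C", {"FS": 100.0})])
        assert len(hard_filter(snv)) == 0
        assert len(hard_filter(indel)) == 1

    def test_unknown_comparator_rejected(self):
        calls = make_calls([(10, "A", "G", {"QD": 5.0})])
        with pytest.raises(ValueError, match="comparator"):
            hard_filter(calls, {"SNV": {"QD": ("<=", 2.0)}})

    def test_default_tables_are_copies(self):
        t = default_hard_filters()
        t["SNV"]["QD"] = ("<", 99.0)
        assert default_hard_filters()["SNV"]["QD"] == ("<", 2.0)
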