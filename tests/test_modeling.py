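import numpy as np
import pandas as pd
import pytest

from rotomics.modeling import (
    CLASSIFIER_NAMES,
    PipelineConfig,
    evaluate_rotated,
    fine_select,
    macro_metrics,
    partition_columns,
    performance_trend,
    prelim_filter,
    run_repeated_cv,
    train_classifiers,
    wide_tables,
)


def _toy_long_df(n_pat=21, labels=(0, 10, 20), seed=0, signal=True):
    """Small synthetic feature table with WD + nWD + shape channels.

    Class signal lives in two WD and two nWD columns; everything else noise.
    """
    rng = np.random.default_rng(seed)
    channels = {
        "wavelet-LLH": ["s1", "s2", "n1", "n2"],
        "wavelet-HLL": ["n3", "n4"],
        "original": ["t1", "t2", "m1"],
        "gradient": ["m2", "m3"],
        "shape": ["sh1"],
    }
    rows = []
    classes = rng.integers(0, 3, size=n_pat)
    for pid in range(n_pat):
        y = classes[pid]
        for lab in labels:
            for ch, feats in channels.items():
                for f in feats:
                    if signal and f in ("s1", "s2", "t1", "t2"):
                        v = y * 2.0 + rng.normal(0, 0.3) + 0.01 * lab
                    else:
                        v = rng.normal(0, 1)
                    rows.append({"patient_id": f"P{pid:02d}", "rotation_label": lab,
                                 "class_label": y,
                                 "channel": ch, "category": "x", "feature": f,
                                 "value": v})
    return pd.DataFrame(rows)


class TestTables:
    def test_wide_tables(self):
        tables, labels = wide_tables(_toy_long_df())
        assert set(tables) == {0, 10, 20}
        assert tables[0].shape == (21, 12)
        assert len(labels) == 21
        assert list(tables[0].columns) == list(tables[10].columns)

    def test_partition_columns(self):
        tables, _ = wide_tables(_toy_long_df())
        wd = partition_columns(tables[0].columns, "WD")
        nwd = partition_columns(tables[0].columns, "nWD")
        assert all(c.startswith("wavelet-") for c in wd)
        assert len(wd) == 6
        assert len(nwd) == 6  # incl. shape
        assert len(partition_columns(tables[0].columns, "nWD",
                                     include_shape=False)) == 5


class TestPrelimFilter:
    def test_drops_constant_and_duplicate(self, rng):
        df = pd.DataFrame({
            "original|x|a": rng.normal(size=20),
            "original|x|const": np.ones(20),
            "original|x|c": rng.normal(size=20),
        }, index=[f"P{i}" for i in range(20)])
        df["original|x|b"] = df["original|x|a"] * 2.0 + 1.0  # rank-identical dup
        df = df[sorted(df.columns)]
        kept = prelim_filter(df, "nWD")
        assert "original|x|const" not in kept
        assert "original|x|a" in kept and "original|x|b" not in kept  # keep-first
        assert "original|x|c" in kept

    def test_wd_partition_only_wavelet(self):
        tables, _ = wide_tables(_toy_long_df())
        kept = prelim_filter(tables[0], "WD")
        assert kept and all(c.startswith("wavelet-") for c in kept)


class TestFineSelect:
    def test_finds_signal_and_respects_cap(self):
        rng = np.random.default_rng(1)
        n = 40
        y = np.repeat([0, 1, 2], [14, 13, 13])
        data = {f"noise{i}": rng.normal(size=n) for i in range(50)}
        for j in range(5):
            data[f"signal{j}"] = y * 3.0 + rng.normal(0, 0.5, n)
        x = pd.DataFrame(data)
        sel = fine_select(x, y, max_features=10, seed=0)
        assert 1 <= len(sel) <= 10
        assert any(c.startswith("signal") for c in sel)

    def test_max_features_one(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1, 2], 8)
        x = pd.DataFrame({f"f{i}": rng.normal(size=24) for i in range(10)})
        assert len(fine_select(x, y, max_features=1, seed=0)) <= 1

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1, 2], 8)
        x = pd.DataFrame({f"f{i}": rng.normal(size=24) for i in range(20)})
        assert fine_select(x, y, 5, seed=9) == fine_select(x, y, 5, seed=9)

    def test_single_class_raises(self):
        x = pd.DataFrame({"f0": np.arange(6, dtype=float)})
        with pytest.raises(ValueError, match="2 classes"):
            fine_select(x, np.zeros(6, dtype=int), 5)


class TestClassifiersAndMetrics:
    def test_separable_logistic(self):
        rng = np.random.default_rng(4)
        y = np.repeat([0, 1, 2], 20)
        x = pd.DataFrame({"a": y * 5.0 + rng.normal(0, 0.2, 60),
                          "b": rng.normal(size=60)})
        scaler, bundle = train_classifiers(x, y, classifiers=("logistic",), seed=0)
        acc = (bundle["logistic"].predict(scaler.transform(x)) == y).mean()
        assert acc >= 0.9

    def test_same_seed_same_predictions(self):
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1, 2], 10)
        x = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        _, b1 = train_classifiers(x, y, classifiers=("random_forest",), seed=3)
        _, b2 = train_classifiers(x, y, classifiers=("random_forest",), seed=3)
        xs = x.to_numpy()
        assert np.array_equal(b1["random_forest"].predict(xs),
                              b2["random_forest"].predict(xs))

    def test_macro_metrics_hand_confusion(self):
        # y_true: 0,0,1,1,2,2 ; y_pred: 0,1,1,1,2,0
        y_true = np.array([0, 0, 1, 1, 2, 2])
        y_pred = np.array([0, 1, 1, 1, 2, 0])
        out = macro_metrics(y_true, y_pred, np.array([0, 1, 2]))
        recalls = [1 / 2, 2 / 2, 1 / 2]
        assert out["macro_sensitivity"] == pytest.approx(np.mean(recalls))
        assert out["accuracy"] == pytest.approx(4 / 6)
        specs = [3 / 4, 3 / 4, 4 / 4]  # TN/(TN+FP) one-vs-rest, by hand
        assert out["macro_specificity"] == pytest.approx(np.mean(specs))

    def test_perfect_classifier_specificity_one(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        out = macro_metrics(y, y, np.array([0, 1, 2]))
        assert out["macro_specificity"] == 1.0
        assert out["macro_f1"] == 1.0


class TestEvaluateRotated:
    def test_rotation_invariant_features_identical_metrics(self):
        df = _toy_long_df(labels=(0, 10, 20))
        tables, labels = wide_tables(df)
        # copy R0 features into every label: metrics must match across labels
        tables = {k: tables[0] for k in tables}
        ids = tables[0].index.to_numpy()
        train, test = ids[:14], ids[14:]
        cols = list(tables[0].columns[:5])
        scaler, bundle = train_classifiers(tables[0].loc[train, cols],
                                           labels.loc[train].to_numpy(),
                                           classifiers=("KNN",), seed=0)
        recs = evaluate_rotated(bundle, scaler, cols, tables, labels, test,
                                np.array([0, 1, 2]))
        accs = {r["rotation_label"]: r["accuracy"] for r in recs}
        assert len(set(accs.values())) == 1


class TestRepeatedCV:
    def test_cycle_counting(self):
        df = _toy_long_df()
        config = PipelineConfig(n_repeats=2, n_folds=5, classifiers=("KNN",),
                                max_features=4, kw_top_k=6, seed=1)
        records = run_repeated_cv(df, config)
        cycles = records[["partition", "repeat_idx", "fold_idx"]].drop_duplicates()
        assert len(cycles) == 2 * 2 * 5  # partitions x repeats x folds
        # one record per cycle x classifier x label
        assert len(records) == 2 * 2 * 5 * 1 * 3
        assert records.accuracy.between(0, 1).all()
        assert (records.n_selected_features <= 4).all()

    def test_default_protocol_is_50x5(self):
        config = PipelineConfig()
        assert config.n_repeats * config.n_folds == 250
        assert config.classifiers == CLASSIFIER_NAMES

    def test_no_leakage_canary(self):
        """A label-revealing feature confined to the test rows must not give
        the model perfect R0 accuracy: selection/scaling only see train rows."""
        df = _toy_long_df(n_pat=21, labels=(0, 10), signal=False)
        tables, labels = wide_tables(df)
        ids = tables[0].index.to_numpy()
        train, test = ids[:14], ids[14:]
        canary = "original|x|canary"
        for k in tables:
            t = tables[k].copy()
            t[canary] = 0.0
            t.loc[test, canary] = labels.loc[test].astype(float)  # test rows only
            tables[k] = t
        sel = fine_select(tables[0].loc[train], labels.loc[train].to_numpy(),
                          max_features=5, seed=0)
        scaler, bundle = train_classifiers(tables[0].loc[train, sel],
                                           labels.loc[train].to_numpy(),
                                           classifiers=("logistic",), seed=0)
        recs = evaluate_rotated(bundle, scaler, sel, tables, labels, test,
                                np.array([0, 1, 2]))
        r0 = [r for r in recs if r["rotation_label"] == 0][0]
        assert r0["accuracy"] < 1.0


class TestPerformanceTrend:
    def test_decreasing_metric_cc_minus_one(self):
        rows = []
        for lab in range(0, 90, 10):  # one cycle: no tied x ranks
            rows.append({"partition": "WD", "classifier": "KNN",
                         "repeat_idx": 0, "fold_idx": 0,
                         "rotation_label": lab,
                         "accuracy": 1.0 - lab / 100,
                         "macro_f1": 0.5, "macro_sensitivity": 0.5,
                         "macro_specificity": 0.5})
        trend = performance_trend(pd.DataFrame(rows), metrics=("accuracy",))
        row = trend[(trend.classifier == "KNN")].iloc[0]
        assert row.spearman_cc == pytest.approx(-1.0, abs=1e-9)
        assert row.n == 9

    def test_pooled_row_n_accounting(self):
        df = _toy_long_df()
        config = PipelineConfig(n_repeats=2, n_folds=5,
                                classifiers=("KNN", "logistic"),
                                max_features=4, kw_top_k=6, seed=1)
        records = run_repeated_cv(df, config)
        trend = performance_trend(records, metrics=("accuracy",))
        sub = trend[trend.partition == "WD"].set_index("classifier")
        n_single = 2 * 5 * 3  # cycles x labels
        assert sub.loc["KNN", "n"] == n_single
        assert sub.loc["All", "n"] == 2 * n_single
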