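import numpy as np
import pandas as pd
import pytest

from ginet.classifier import (
    InteractionForest,
    bootstrap_select,
    correlation_screen,
    error_vs_trees,
    load_model,
    save_model,
)
from ginet.dataset import GIDataset, split
from ginet.errors import ConfigError, DataError, GuardrailError
from ginet.stats import roc_curve


def _dataset(rows: int, seed=0, informative=True) -> GIDataset:
    """3-class dataset: `signal` determines the label, `noise*` do not."""
    rng = np.random.default_rng(seed)
    labels = np.array(["SL", "SV", "NOT"])[np.arange(rows) % 3]
    signal = {"SL": 0.0, "SV": 4.0, "NOT": 8.0}
    df = pd.DataFrame(
        {
            "gene_a": [f"a{i}" for i in range(rows)],
            "gene_b": [f"b{i}" for i in range(rows)],
            "label": labels,
            "signal": [signal[l] + rng.normal(0, 0.3) for l in labels]
            if informative
            else rng.normal(size=rows),
            "noise1": rng.normal(size=rows),
            "noise2": rng.normal(size=rows),
        }
    )
    return GIDataset(df)


class TestTraining:
    def test_separable_data_high_training_accuracy(self, separable_dataset):
        res = InteractionForest(separable_dataset, n_trees=100, seed=0).fit()
        pred = res.predict(separable_dataset.features)
        assert (pred["label"] == separable_dataset.labels).mean() >= 0.99
        assert res.oob_error_ < 0.05

    def test_same_seed_identical_predictions(self, separable_dataset):
        r1 = InteractionForest(separable_dataset, n_trees=50, seed=7).fit()
        r2 = InteractionForest(separable_dataset, n_trees=50, seed=7).fit()
        p1 = r1.predict_proba(separable_dataset.features)
        p2 = r2.predict_proba(separable_dataset.features)
        pd.testing.assert_frame_equal(p1, p2)

    def test_single_class_rejected(self):
        ds = _dataset(30)
        sl_only = ds.subset(ds.df.index[ds.df["label"] == "SL"])
        with pytest.raises(DataError, match="two classes"):
            InteractionForest(sl_only)

    def test_nan_features_rejected(self):
        df = _dataset(30).df.copy()
        df.loc[0, "signal"] = np.nan
        with pytest.raises(DataError, match="missing"):
            GIDataset(df)

    def test_summary_mentions_key_facts(self, separable_dataset):
        res = InteractionForest(separable_dataset, n_trees=50, seed=0).fit()
        text = res.summary()
        assert "OOB error" in text and "f1, f2" in text


class TestPrediction:
    def test_probabilities_sum_to_one(self, separable_dataset):
        res = InteractionForest(separable_dataset, n_trees=50, seed=0).fit()
        proba = res.predict_proba(separable_dataset.features)
        assert proba.columns.tolist() == ["SL", "SV", "NOT"]
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_argmax_and_tie_break_order(self, separable_dataset):
        res = InteractionForest(separable_dataset, n_trees=50, seed=0).fit()
        # bypass the forest: the labeling rule itself is under test
        by_class = {
            "SL": [0.5, 0.4, 0.2, 0.3],
            "SV": [0.3, 0.4, 0.4, 0.3],
            "NOT": [0.2, 0.2, 0.4, 0.4],
        }
        fixed = np.column_stack([by_class[c] for c in res.estimator.classes_])
        res.estimator.predict_proba = lambda X: fixed[: len(X)]
        pred = res.predict(separable_dataset.features.iloc[:4])
        # plain argmax; SL wins the SL/SV tie, SV wins the SV/NOT tie
        assert pred["label"].tolist() == ["SL", "SL", "SV", "NOT"]

    def test_feature_mismatch_rejected(self, separable_dataset):
        res = InteractionForest(separable_dataset, n_trees=50, seed=0).fit()
        with pytest.raises(DataError, match="missing feature"):
            res.predict(pd.DataFrame({"f1": [0.1]}))


class TestEvaluation:
    def test_perfect_classifier(self, separable_dataset):
        sp = split(separable_dataset, 0.7, seed=0)
        res = InteractionForest(sp.train, n_trees=100, seed=0).fit()
        rep = res.evaluate(sp.test)
        assert rep.accuracy == 1.0
        assert all(a == 1.0 for a in rep.per_class_auc.values())

    def test_confusion_rows_conserve_class_counts(self, benchmark_core5):
        sp = split(benchmark_core5, 0.7, seed=1)
        res = InteractionForest(sp.train, n_trees=100, seed=1).fit()
        rep = res.evaluate(sp.test)
        for c, n in sp.test.class_counts.items():
            assert rep.confusion.loc[c].sum() == n
        assert rep.accuracy == pytest.approx(
            np.trace(rep.confusion.to_numpy()) / sp.test.n
        )
        assert rep.accuracy_ci90[0] < rep.accuracy < rep.accuracy_ci90[1]

    def test_shuffled_labels_auc_is_chance(self, separable_dataset):
        res = InteractionForest(separable_dataset, n_trees=50, seed=0).fit()
        rng = np.random.default_rng(5)
        rows = 3000
        noise = pd.DataFrame(
            {
                "gene_a": [f"x{i}" for i in range(rows)],
                "gene_b": [f"y{i}" for i in range(rows)],
                "label": np.array(["SL", "SV", "NOT"])[rng.integers(0, 3, rows)],
                "f1": rng.normal(2, 3, rows),
                "f2": rng.normal(2, 3, rows),
            }
        )
        rep = res.evaluate(GIDataset(noise))
        assert rep.macro_auc == pytest.approx(0.5, abs=0.03)

    def test_empty_test_class_rejected(self, separable_dataset):
        sp = split(separable_dataset, 0.7, seed=0)
        only_two = sp.test.subset(sp.test.df.index[sp.test.df["label"] != "NOT"])
        res = InteractionForest(sp.train, n_trees=50, seed=0).fit()
        with pytest.raises(DataError, match="absent"):
            res.evaluate(only_two)

    def test_threshold_sweep_shape(self, separable_dataset):
        sp = split(separable_dataset, 0.7, seed=0)
        res = InteractionForest(sp.train, n_trees=50, seed=0).fit()
        rep = res.evaluate(sp.test)
        sweep = rep.threshold_sweep
        assert len(sweep) == 9
        assert sweep["threshold"].iloc[0] == pytest.approx(0.1)
        assert sweep["threshold"].iloc[-1] == pytest.approx(0.9)
        assert ((sweep[["SL", "SV", "NOT"]] >= 0) & (sweep[["SL", "SV", "NOT"]] <= 1)).all().all()

    def test_binary_mode_matches_dedicated_binary_models(self, benchmark_core5):
        """Multi-class scores lose < 0.05 AUC to dedicated binary models."""
        sp = split(benchmark_core5, 0.7, seed=1)
        multi = InteractionForest(sp.train, n_trees=300, seed=1).fit()
        for pos, neg in [("SL", "NOT"), ("SV", "NOT"), ("SL", "SV")]:
            tr = sp.train.subset(sp.train.df.index[sp.train.df["label"].isin([pos, neg])])
            te = sp.test.subset(sp.test.df.index[sp.test.df["label"].isin([pos, neg])])
            binary = InteractionForest(tr, n_trees=300, seed=1).fit()
            y = (te.labels == pos).astype(int).to_numpy()
            auc_bin = roc_curve(binary.predict_proba(te.features)[pos].to_numpy(), y).auc
            auc_multi = roc_curve(multi.predict_proba(te.features)[pos].to_numpy(), y).auc
            assert auc_multi >= auc_bin - 0.05


@pytest.fixture(scope="module")
def fitted():
    ds = _dataset(600, seed=1)
    res = InteractionForest(ds, n_trees=100, seed=1).fit()
    return ds, res


class TestPermutationImportance:

    def test_constant_feature_has_zero_drop(self):
        ds = _dataset(300, seed=2)
        df = ds.df.copy()
        df["flat"] = 1.0
        ds2 = GIDataset(df)
        res = InteractionForest(ds2, n_trees=100, seed=2).fit()
        drops = res.permutation_importance(ds2, repeats=3, seed=0)
        assert abs(drops["flat"]) < 0.01

    def test_informative_feature_drops_to_chance(self, fitted):
        ds, res = fitted
        drops = res.permutation_importance(ds, repeats=5, seed=0)
        baseline = (res.predict(ds.features)["label"] == ds.labels).mean()
        assert baseline - drops["signal"] == pytest.approx(1 / 3, abs=0.05)
        assert drops["noise1"] < 0.05

    def test_all_columns_permuted_gives_majority_rate(self, fitted):
        ds, res = fitted
        rng = np.random.default_rng(0)
        accs = []
        for _ in range(10):
            X = ds.features.copy()
            for c in X.columns:
                X[c] = X[c].sample(frac=1, random_state=rng.integers(2**31)).to_numpy()
            accs.append((res.predict(X)["label"] == ds.labels).mean())
        majority = max(ds.class_counts.values()) / ds.n
        assert np.mean(accs) == pytest.approx(majority, abs=0.05)


class TestBootstrapSelect:
    def test_planted_signal_always_selected(self):
        ds = _dataset(300, seed=3)
        rep = bootstrap_select(ds, b=10, k_top=1, seed=0, n_trees=50)
        assert rep.table.at["signal", "selection_fraction"] == 1.0
        assert rep.selected_features == ["signal"]

    def test_unreachable_threshold_selects_nothing(self):
        ds = _dataset(150, seed=4)
        rep = bootstrap_select(ds, b=3, freq_threshold=1.1, seed=0, n_trees=25)
        assert rep.selected_features == []

    def test_single_model_fractions_are_binary(self):
        ds = _dataset(150, seed=5)
        rep = bootstrap_select(ds, b=1, seed=0, n_trees=25)
        assert set(rep.table["selection_fraction"]) <= {0.0, 1.0}

    def test_budget_guardrail(self):
        ds = _dataset(60, seed=6)
        with pytest.raises(GuardrailError, match="guardrail"):
            bootstrap_select(ds, b=5000, seed=0)


class TestErrorVsTrees:
    def test_single_point_and_sorting(self):
        ds = _dataset(200, seed=7)
        curve = error_vs_trees(ds, [50], seed=0)
        assert curve["n_trees"].tolist() == [50]
        curve2 = error_vs_trees(ds, [100, 20], seed=0)
        assert curve2["n_trees"].tolist() == [20, 100]
        assert ((curve2["oob_error"] >= 0) & (curve2["oob_error"] <= 1)).all()


class TestCorrelationScreen:
    def test_identical_negated_and_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": -x, "flat": np.ones(200)})
        corr, flags = correlation_screen(df, threshold=0.9)
        assert corr.at["a", "b"] == pytest.approx(1.0)
        assert corr.at["a", "c"] == pytest.approx(-1.0)
        assert np.isnan(corr.at["a", "flat"])
        flagged = {frozenset((f1, f2)) for f1, f2, _ in flags}
        assert {frozenset(("a", "b")), frozenset(("a", "c"))} <= flagged

    def test_independent_columns_uncorrelated(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.uniform(size=(1000, 2)), columns=["u", "v"])
        corr, _ = correlation_screen(df)
        assert abs(corr.at["u", "v"]) < 0.1

    def test_too_small_input_rejected(self):
        with pytest.raises(DataError):
            correlation_screen(pd.DataFrame({"a": [1.0, 2.0]}))


class TestPersistence:
    def test_roundtrip_and_feature_guard(self, separable_dataset, tmp_path):
        res = InteractionForest(separable_dataset, n_trees=50, seed=0).fit()
        path = tmp_path / "model.joblib"
        save_model(res, path)
        loaded = load_model(path, expected_features=["f1", "f2"])
        p1 = res.predict_proba(separable_dataset.features)
        p2 = loaded.predict_proba(separable_dataset.features)
        pd.testing.assert_frame_equal(p1, p2)
        with pytest.raises(DataError, match="feature names"):
            load_model(path, expected_features=["f1", "other"])
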