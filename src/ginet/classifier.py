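"""Multi-class random-forest classifier of genetic interactions.

The modelling surface follows the statsmodels convention: an
:class:`InteractionForest` model object is built from a training
:class:`~ginet.dataset.GIDataset` and ``fit()`` returns an
:class:`InteractionForestResults` object carrying the fitted forest, the
out-of-bag error, and methods for prediction, evaluation (confusion matrix,
per-class one-vs-rest AUC, threshold sweep), permutation importance and a
``summary()`` table. On top of those sit the bootstrap feature-selection
procedure (re-drawing the NOT set and re-balancing for every one of B models,
counting how often each feature ranks in the permutation-importance top k)
and the OOB-error-versus-trees saturation curve.

The forest defaults to 500 trees with sqrt-of-p feature subsampling and
unlimited depth. Probability ties are broken by the fixed class order
SL < SV < NOT. Restricting the labels to two classes yields an ordinary
binary classifier (used for SL-vs-NOT style comparisons).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.proportion import proportion_confint

from .dataset import CLASS_ORDER, GIDataset, balance, split
from .errors import ConfigError, DataError, GuardrailError
from .stats import roc_curve

__all__ = [
    "InteractionForest",
    "InteractionForestResults",
    "EvaluationReport",
    "ImportanceReport",
    "train",
    "predict",
    "evaluate",
    "permutation_importance",
    "bootstrap_select",
    "error_vs_trees",
    "correlation_screen",
    "save_model",
    "load_model",
]

_MODEL_FORMAT_VERSION = 1
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.1, 0.91, 0.1), 10))


@dataclass
class EvaluationReport:
    """Test-set performance of one fitted model.

    ``confusion`` rows are true classes, columns predicted classes, both in
    the model's class order; row sums equal the per-class test counts and
    ``accuracy`` is trace/total. ``accuracy_ci90`` is a binomial (Wilson) 90%
    confidence interval on the accuracy. The threshold sweep reports, per
    running point t in [0.1, 0.9], the one-vs-rest accuracy of calling each
    class positive when its probability is >= t.
    """

    confusion: pd.DataFrame
    accuracy: float
    accuracy_ci90: tuple[float, float]
    per_class_recall: dict[str, float]
    per_class_auc: dict[str, float]
    macro_auc: float
    threshold_sweep: pd.DataFrame
    roc_curves: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.to_dict(),
            "accuracy": self.accuracy,
            "accuracy_ci90": list(self.accuracy_ci90),
            "per_class_recall": self.per_class_recall,
            "per_class_auc": self.per_class_auc,
            "macro_auc": self.macro_auc,
            "threshold_sweep": self.threshold_sweep.to_dict(orient="list"),
        }


@dataclass
class ImportanceReport:
    """Bootstrap feature-selection outcome.

    ``table`` has one row per feature: ``selection_count`` over the B models,
    ``selection_fraction``, ``mean_drop`` (mean permutation accuracy drop) and
    ``mean_rank`` (1 = largest drop). ``selected_features`` are those with
    selection_fraction > the frequency threshold and mean rank <= k_top.
    """

    table: pd.DataFrame
    selected_features: list[str]
    b: int
    k_top: int
    freq_threshold: float


class InteractionForest:
    """Random-forest model specification bound to a training dataset."""

    def __init__(
        self,
        train: GIDataset,
        features: list[str] | None = None,
        n_trees: int = 500,
        seed: int = 0,
    ):
        if train.n == 0:
            raise DataError("empty training dataset")
        if features is not None:
            train = train.select_features(features)
        classes = [c for c in CLASS_ORDER if train.class_counts[c] > 0]
        if len(classes) < 2:
            raise DataError("training requires at least two classes")
        if train.features.isna().any().any():
            raise DataError("training features contain missing values")
        self.data = train
        self.feature_names = list(train.feature_names)
        self.class_labels = classes
        self.n_trees = int(n_trees)
        self.seed = int(seed)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        features: list[str] | None = None,
        n_trees: int = 500,
        seed: int = 0,
    ) -> "InteractionForest":
        """Build from a raw (gene_a, gene_b, label, features...) DataFrame."""
        return cls(GIDataset(df.copy()), features=features, n_trees=n_trees, seed=seed)

    def fit(self) -> "InteractionForestResults":
        est = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features="sqrt",
            oob_score=True,
            random_state=self.seed,
            n_jobs=1,
        )
        X = self.data.features.to_numpy(dtype=float)
        y = self.data.labels.to_numpy()
        est.fit(X, y)
        return InteractionForestResults(self, est)


class InteractionForestResults:
    """Fitted forest plus evaluation/diagnostic methods."""

    def __init__(self, model: InteractionForest, estimator: RandomForestClassifier):
        self.model = model
        self.estimator = estimator
        self.feature_names = model.feature_names
        self.class_labels = model.class_labels
        self.seed = model.seed
        self.oob_error_ = 1.0 - float(estimator.oob_score_)
        self.dataset_hash = model.data.content_hash()
        self.fitted_at = _dt.datetime.now().isoformat(timespec="seconds")
        # column permutation from sklearn's alphabetical order to CLASS_ORDER
        self._col_of = {c: i for i, c in enumerate(estimator.classes_)}

    # -- prediction ---------------------------------------------------------
    def _check_features(self, features: pd.DataFrame) -> pd.DataFrame:
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing:
            raise DataError(f"missing feature columns: {missing}")
        return features[self.feature_names]

    def predict_proba(self, features: pd.DataFrame) -> pd.DataFrame:
        """Per-row class probabilities, columns in SL < SV < NOT order."""
        X = self._check_features(features).to_numpy(dtype=float)
        if np.isnan(X).any():
            raise DataError("prediction features contain missing values")
        raw = self.estimator.predict_proba(X)
        cols = [c for c in CLASS_ORDER if c in self.class_labels]
        out = np.column_stack([raw[:, self._col_of[c]] for c in cols])
        return pd.DataFrame(out, columns=cols, index=features.index)

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        """Probabilities plus the argmax label (ties -> earliest class in order)."""
        proba = self.predict_proba(features)
        idx = proba.to_numpy().argmax(axis=1)  # first max wins = fixed tie-break
        out = proba.copy()
        out["label"] = [proba.columns[i] for i in idx]
        return out

    # -- evaluation ---------------------------------------------------------
    def evaluate(
        self, test: GIDataset, thresholds=DEFAULT_THRESHOLDS
    ) -> EvaluationReport:
        if test.n == 0:
            raise DataError("empty test dataset")
        counts = test.class_counts
        for c in self.class_labels:
            if counts.get(c, 0) == 0:
                raise DataError(f"class {c} absent from test set")
        pred = self.predict(test.features)
        y = test.labels.to_numpy()
        yhat = pred["label"].to_numpy()
        classes = [c for c in CLASS_ORDER if c in self.class_labels]
        conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
        for t, p in zip(y, yhat):
            conf.loc[t, p] += 1
        n = conf.to_numpy().sum()
        correct = int(np.trace(conf.to_numpy()))
        accuracy = correct / n
        ci = proportion_confint(correct, n, alpha=0.10, method="wilson")
        recall = {c: float(conf.loc[c, c] / conf.loc[c].sum()) for c in classes}
        aucs, curves = {}, {}
        for c in classes:
            r = roc_curve(pred[c].to_numpy(), (y == c).astype(int), positive_label=1)
            aucs[c] = r.auc
            curves[c] = r
        macro = float(np.mean(list(aucs.values())))
        rows = []
        for t in thresholds:
            row = {"threshold": float(t)}
            for c in classes:
                row[c] = float(np.mean((pred[c].to_numpy() >= t) == (y == c)))
            row["macro"] = float(np.mean([row[c] for c in classes]))
            rows.append(row)
        sweep = pd.DataFrame(rows)
        return EvaluationReport(
            confusion=conf,
            accuracy=float(accuracy),
            accuracy_ci90=(float(ci[0]), float(ci[1])),
            per_class_recall=recall,
            per_class_auc={c: float(a) for c, a in aucs.items()},
            macro_auc=macro,
            threshold_sweep=sweep,
            roc_curves=curves,
        )

    def permutation_importance(
        self, data: GIDataset, repeats: int = 5, seed: int = 0
    ) -> pd.Series:
        """Accuracy drop when each feature column is independently shuffled.

        drop(f) = baseline accuracy - mean accuracy over ``repeats`` runs with
        column f permuted; all other columns untouched.
        """
        if data.n == 0:
            raise DataError("empty dataset for permutation importance")
        X = self._check_features(data.features).to_numpy(dtype=float)
        y = data.labels.to_numpy()
        cols = list(self.feature_names)
        baseline = float(np.mean(self._predict_X(X) == y))
        rng = np.random.default_rng(seed)
        drops = np.zeros(len(cols))
        for j in range(len(cols)):
            accs = []
            for _ in range(repeats):
                Xp = X.copy()
                Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
                accs.append(np.mean(self._predict_X(Xp) == y))
            drops[j] = baseline - float(np.mean(accs))
        return pd.Series(drops, index=cols, name="accuracy_drop")

    def oob_permutation_importance(self, seed: int = 0) -> pd.Series:
        """Per-tree out-of-bag permutation importance (randomForest-style).

        For every tree, the feature column is permuted within that tree's
        out-of-bag rows and the drop in the tree's OOB accuracy is recorded;
        the importance is the drop averaged over all trees. Averaging over
        hundreds of trees makes this estimate far more stable than a single
        holdout permutation, and evaluating on OOB rows keeps features the
        forest merely overfits from scoring as informative.
        """
        if self.model is None:
            raise DataError("OOB importance needs the in-memory training data")
        X = self.model.data.features.to_numpy(dtype=float)
        y = self.model.data.labels.to_numpy()
        n, p = X.shape
        rng = np.random.default_rng(seed)
        classes = self.estimator.classes_
        drops = np.zeros(p)
        used = 0
        for tree, inbag in zip(self.estimator.estimators_, self.estimator.estimators_samples_):
            oob = np.setdiff1d(np.arange(n), inbag)
            if len(oob) < 5:
                continue
            Xo, yo = X[oob], y[oob]
            base = np.mean(classes[tree.predict_proba(Xo).argmax(axis=1)] == yo)
            for j in range(p):
                Xp = Xo.copy()
                Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
                acc = np.mean(classes[tree.predict_proba(Xp).argmax(axis=1)] == yo)
                drops[j] += base - acc
            used += 1
        if used == 0:
            raise DataError("no tree had enough out-of-bag rows")
        return pd.Series(drops / used, index=self.feature_names, name="accuracy_drop")

    def _predict_X(self, X: np.ndarray) -> np.ndarray:
        raw = self.estimator.predict_proba(X)
        cols = [c for c in CLASS_ORDER if c in self.class_labels]
        stacked = np.column_stack([raw[:, self._col_of[c]] for c in cols])
        return np.asarray(cols)[stacked.argmax(axis=1)]

    def summary(self) -> str:
        lines = [
            "Genetic-interaction random forest",
            "=" * 42,
            f"classes:        {', '.join(self.class_labels)}",
            f"features ({len(self.feature_names)}):  "
            + ", ".join(self.feature_names),
            f"trees:          {self.model.n_trees}",
            f"seed:           {self.seed}",
            f"training rows:  {self.model.data.n}",
            f"OOB error:      {self.oob_error_:.4f}",
            f"dataset hash:   {self.dataset_hash[:16]}…",
        ]
        return "\n".join(lines)


# -- thin functional surface ------------------------------------------------

def train(
    train_ds: GIDataset,
    n_trees: int = 500,
    seed: int = 0,
    features: list[str] | None = None,
) -> InteractionForestResults:
    return InteractionForest(train_ds, features=features, n_trees=n_trees, seed=seed).fit()


def predict(results: InteractionForestResults, features: pd.DataFrame) -> pd.DataFrame:
    return results.predict(features)


def evaluate(
    results: InteractionForestResults, test: GIDataset, thresholds=DEFAULT_THRESHOLDS
) -> EvaluationReport:
    return results.evaluate(test, thresholds=thresholds)


def permutation_importance(
    results: InteractionForestResults, data: GIDataset, repeats: int = 5, seed: int = 0
) -> pd.Series:
    return results.permutation_importance(data, repeats=repeats, seed=seed)


# -- bootstrap feature selection -------------------------------------------

def bootstrap_select(
    source: GIDataset,
    b: int = 1000,
    k_top: int = 5,
    freq_threshold: float = 0.90,
    seed: int = 0,
    *,
    not_pool: GIDataset | None = None,
    n_trees: int = 100,
    train_frac: float = 0.7,
    importance: str = "oob",
    perm_repeats: int = 2,
    max_b: int = 2000,
    force: bool = False,
) -> ImportanceReport:
    """Bootstrap permutation-importance feature selection.

    For each of ``b`` models: the NOT class is re-drawn (from ``not_pool`` if
    given, otherwise resampled with replacement from the source NOT rows), all
    classes are under-sampled to the smallest class count, and a forest is
    fitted. With ``importance="oob"`` (default, mirroring randomForest's
    variable importance) the model trains on the whole balanced draw and
    drops come from per-tree out-of-bag permutation; with
    ``importance="holdout"`` the draw is split ``train_frac``/rest and drops
    come from whole-model permutation on the held-out part. A feature is
    "selected by a model" when its accuracy drop ranks in that model's top
    ``k_top``. Features selected in more than ``freq_threshold`` of models
    *and* with mean rank <= ``k_top`` form ``selected_features``.

    ``b > max_b`` is refused unless ``force=True`` (runtime guardrail).
    """
    if importance not in ("oob", "holdout"):
        raise ConfigError(f"unknown importance mode: {importance!r}")
    if b < 1:
        raise ConfigError("b must be >= 1")
    if b > max_b and not force:
        raise GuardrailError(
            f"b={b} exceeds the guardrail of {max_b} models; pass force=True"
        )
    counts = source.class_counts
    if min(counts.values()) == 0:
        raise DataError("bootstrap selection needs all three classes present")
    feats = list(source.feature_names)
    sel = np.zeros(len(feats))
    drop_sum = np.zeros(len(feats))
    rank_sum = np.zeros(len(feats))
    rng = np.random.default_rng(seed)
    non_not = source.df[source.df["label"] != "NOT"]
    n_not = counts["NOT"]
    for i in range(b):
        it_seed = int(rng.integers(0, 2**31 - 1))
        it_rng = np.random.default_rng(it_seed)
        if not_pool is not None:
            take = it_rng.choice(not_pool.n, size=min(n_not, not_pool.n), replace=False)
            not_rows = not_pool.df.iloc[np.sort(take)]
        else:
            take = it_rng.integers(0, n_not, size=n_not)
            not_rows = source.df[source.df["label"] == "NOT"].iloc[take]
        ds = GIDataset.__new__(GIDataset)
        ds.df = pd.concat([non_not, not_rows], ignore_index=True)
        ds.feature_names = feats
        m = min(ds.class_counts.values())
        ds = balance(ds, "undersample", {c: m for c in CLASS_ORDER}, seed=it_seed)
        if importance == "oob":
            res = InteractionForest(ds, n_trees=n_trees, seed=it_seed).fit()
            drops = res.oob_permutation_importance(seed=it_seed)
        else:
            sp = split(ds, train_frac, seed=it_seed)
            res = InteractionForest(sp.train, n_trees=n_trees, seed=it_seed).fit()
            drops = res.permutation_importance(sp.test, repeats=perm_repeats, seed=it_seed)
        order = (-drops.to_numpy()).argsort(kind="stable")
        ranks = np.empty(len(feats))
        ranks[order] = np.arange(1, len(feats) + 1)
        sel[ranks <= k_top] += 1
        drop_sum += drops.to_numpy()
        rank_sum += ranks
    table = pd.DataFrame(
        {
            "selection_count": sel.astype(int),
            "selection_fraction": sel / b,
            "mean_drop": drop_sum / b,
            "mean_rank": rank_sum / b,
        },
        index=pd.Index(feats, name="feature"),
    ).sort_values("selection_fraction", ascending=False)
    selected = [
        f
        for f in feats
        if table.at[f, "selection_fraction"] > freq_threshold
        and table.at[f, "mean_rank"] <= k_top
    ]
    return ImportanceReport(table, selected, b, k_top, freq_threshold)


def error_vs_trees(
    train_ds: GIDataset, tree_grid: list[int], seed: int = 0
) -> pd.DataFrame:
    """Out-of-bag error at each forest size (grid sorted ascending first)."""
    grid = sorted(int(t) for t in tree_grid)
    rows = []
    for n in grid:
        res = InteractionForest(train_ds, n_trees=n, seed=seed).fit()
        rows.append({"n_trees": n, "oob_error": res.oob_error_})
    return pd.DataFrame(rows)


def correlation_screen(
    features: pd.DataFrame, threshold: float = 0.7
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Spearman correlations plus advisory high-|rho| flags.

    Zero-variance columns yield undefined (NaN) correlations, reported as
    missing. Flags are advisory only: correlated features are not dropped.
    """
    num = features.select_dtypes(include=[np.number])
    if num.shape[1] < 2 or num.shape[0] < 3:
        raise DataError("correlation screen needs >= 2 feature columns and >= 3 rows")
    cols = list(num.columns)
    k = len(cols)
    mat = np.full((k, k), np.nan)
    variant = [num[c].nunique() > 1 for c in cols]
    for i in range(k):
        if variant[i]:
            mat[i, i] = 1.0
        for j in range(i + 1, k):
            if variant[i] and variant[j]:
                rho = sps.spearmanr(num[cols[i]], num[cols[j]]).statistic
                mat[i, j] = mat[j, i] = rho
    corr = pd.DataFrame(mat, index=cols, columns=cols)
    flags = [
        (cols[i], cols[j], float(mat[i, j]))
        for i in range(k)
        for j in range(i + 1, k)
        if np.isfinite(mat[i, j]) and abs(mat[i, j]) >= threshold
    ]
    return corr, flags


# -- persistence ------------------------------------------------------------

def save_model(results: InteractionForestResults, path: str | Path) -> None:
    """Persist as a versioned archive (estimator + feature names + seed + hash)."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "estimator": results.estimator,
        "feature_names": results.feature_names,
        "class_labels": results.class_labels,
        "n_trees": results.model.n_trees,
        "seed": results.seed,
        "dataset_hash": results.dataset_hash,
        "fitted_at": results.fitted_at,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path, expected_features: list[str] | None = None):
    """Load a persisted model; refuse on version or feature-name mismatch."""
    payload = joblib.load(path)
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise DataError(f"unsupported model archive version: {payload.get('format_version')}")
    if expected_features is not None and list(expected_features) != payload["feature_names"]:
        raise DataError("model archive feature names do not match the expected features")
    results = InteractionForestResults.__new__(InteractionForestResults)
    results.model = None
    results.estimator = payload["estimator"]
    results.feature_names = payload["feature_names"]
    results.class_labels = payload["class_labels"]
    results.seed = payload["seed"]
    results.oob_error_ = 1.0 - float(payload["estimator"].oob_score_)
    results.dataset_hash = payload["dataset_hash"]
    results.fitted_at = payload["fitted_at"]
    results._col_of = {c: i for i, c in enumerate(payload["estimator"].classes_)}
    return results
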