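"""Labeled SL/SV/NOT datasets: NOT-set construction, balancing, splitting.

A :class:`GIDataset` is a pair table (gene_a, gene_b, label) joined with its
feature columns. The negative (NOT) class is built by exclusion sampling over
the unordered pair space of the network's genes; balancing supports random
under-sampling, random over-sampling, a hybrid of the two, and a SMOTE-style
hybrid that synthesizes minority rows by k-nearest-neighbor interpolation in
feature space.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigError, DataError, GuardrailError

__all__ = [
    "CLASS_ORDER",
    "PUBLISHED_BALANCE_TARGETS",
    "GIDataset",
    "SplitResult",
    "read_labeled_pairs",
    "write_labeled_pairs",
    "read_pair_list",
    "pair_key",
    "build_not_set",
    "balance",
    "split",
]

#: Fixed class order used everywhere (probability columns, tie-breaks).
CLASS_ORDER = ["SL", "SV", "NOT"]

#: Published balanced class sizes (SL / SV / NOT), usable as a preset.
PUBLISHED_BALANCE_TARGETS = {"SL": 11238, "SV": 11601, "NOT": 4230}

_KEY_COLS = ["gene_a", "gene_b"]


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) key of an unordered gene pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class GIDataset:
    """Labeled pair table with features.

    ``df`` columns: gene_a, gene_b, label, then feature columns. All rows are
    mapped (features non-missing); pair keys are stored sorted and unique.
    """

    df: pd.DataFrame
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = _KEY_COLS + ["label"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise DataError(f"dataset missing columns: {missing}")
        if not self.feature_names:
            self.feature_names = [
                c for c in self.df.columns if c not in required and c != "mapped"
            ]
        bad = set(self.df["label"]) - set(CLASS_ORDER)
        if bad:
            raise DataError(f"unknown labels: {sorted(bad)}")
        if self.df[self.feature_names].isna().any().any():
            raise DataError("dataset contains missing feature values")
        keys = list(map(tuple, self.df[_KEY_COLS].to_numpy()))
        if len(set(keys)) != len(keys):
            raise DataError("duplicate pair keys in dataset")
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def from_features(cls, labeled: pd.DataFrame, features: pd.DataFrame) -> "GIDataset":
        """Join a (gene_a, gene_b, label) table with a pair-feature table.

        Unmapped pairs (``mapped == False``) are dropped with a warning.
        """
        lab = labeled.copy()
        lab[_KEY_COLS] = np.sort(lab[_KEY_COLS].to_numpy(), axis=1)
        merged = lab.merge(features, on=_KEY_COLS, how="left")
        if "mapped" in merged.columns:
            n_un = int((~merged["mapped"].fillna(False).astype(bool)).sum())
            if n_un:
                warnings.warn(f"dropping {n_un} unmapped pair(s)", stacklevel=2)
            merged = merged[merged["mapped"].fillna(False).astype(bool)]
            merged = merged.drop(columns="mapped")
        return cls(merged.reset_index(drop=True))

    @property
    def class_counts(self) -> dict[str, int]:
        counts = self.df["label"].value_counts()
        return {c: int(counts.get(c, 0)) for c in CLASS_ORDER}

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def features(self) -> pd.DataFrame:
        return self.df[self.feature_names]

    @property
    def labels(self) -> pd.Series:
        return self.df["label"]

    def keys(self) -> set[tuple[str, str]]:
        return set(map(tuple, self.df[_KEY_COLS].to_numpy()))

    def select_features(self, names: list[str]) -> "GIDataset":
        missing = [f for f in names if f not in self.feature_names]
        if missing:
            raise DataError(f"features not in dataset: {missing}")
        return GIDataset(self.df[_KEY_COLS + ["label"] + list(names)].copy(), list(names))

    def subset(self, index) -> "GIDataset":
        return GIDataset(self.df.loc[index].reset_index(drop=True), list(self.feature_names))

    def content_hash(self) -> str:
        """Order-insensitive sha256 of rows; identifies the dataset in manifests."""
        canon = self.df.sort_values(_KEY_COLS + ["label"]).reset_index(drop=True)
        h = hashlib.sha256()
        h.update(pd.util.hash_pandas_object(canon, index=False).to_numpy().tobytes())
        return h.hexdigest()


@dataclass
class SplitResult:
    train: GIDataset
    test: GIDataset
    seed: int


def read_labeled_pairs(path: str | Path) -> pd.DataFrame:
    """Read a 3-column TSV (geneA, geneB, label in {SL, SV, NOT}).

    Self-pairs are rejected; exact duplicate (pair, label) rows are collapsed;
    pairs appearing under two different labels are dropped entirely with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"labeled pair file not found: {path}")
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene_a", "gene_b", "label"], dtype=str)
    if df.isna().any().any():
        raise DataError(f"{path}: rows must have 3 columns (geneA, geneB, label)")
    bad = set(df["label"]) - set(CLASS_ORDER)
    if bad:
        raise DataError(f"{path}: unknown labels {sorted(bad)}")
    if (df["gene_a"] == df["gene_b"]).any():
        raise DataError(f"{path}: self-paired genes are not allowed")
    df[_KEY_COLS] = np.sort(df[_KEY_COLS].to_numpy(), axis=1)
    df = df.drop_duplicates()
    multi = df.groupby(_KEY_COLS)["label"].nunique()
    conflicted = multi[multi > 1].index
    if len(conflicted):
        warnings.warn(
            f"dropping {len(conflicted)} pair(s) labeled with more than one class",
            stacklevel=2,
        )
        df = df.set_index(_KEY_COLS).drop(index=conflicted).reset_index()
    return df.reset_index(drop=True)


def write_labeled_pairs(df: pd.DataFrame, path: str | Path) -> None:
    df[_KEY_COLS + ["label"]].to_csv(path, sep="\t", index=False, header=False)


def read_pair_list(path: str | Path) -> set[tuple[str, str]]:
    """Read a 2-column TSV into a set of canonical pair keys (exclusion lists)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"pair list not found: {path}")
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1], names=_KEY_COLS, dtype=str)
    return {pair_key(a, b) for a, b in df.to_numpy()}


def build_not_set(
    net_nodes,
    excluded_pairs: set[tuple[str, str]],
    n: int,
    seed: int,
    *,
    max_draw_factor: int = 200,
) -> pd.DataFrame:
    """Sample ``n`` unique NOT pairs uniformly from the admissible pair space.

    The admissible space is all unordered pairs of distinct genes not in
    ``excluded_pairs``; it is never materialized — pairs are rejection-sampled
    with a retry cap of ``max_draw_factor * n + 1000`` draws, which a uniform
    sample only exceeds when the admissible space is nearly exhausted.

    Returns a (gene_a, gene_b, label=NOT) DataFrame, reproducible under seed.
    """
    nodes = sorted(net_nodes)
    if len(nodes) < 2:
        raise DataError("need at least two genes to sample NOT pairs")
    excluded = {pair_key(a, b) for a, b in excluded_pairs}
    total = len(nodes) * (len(nodes) - 1) // 2
    applicable = sum(
        1 for k in excluded if k[0] in net_nodes and k[1] in net_nodes and k[0] != k[1]
    )
    admissible = total - applicable
    if n > admissible:
        raise DataError(
            f"requested {n} NOT pairs but only {admissible} admissible pairs exist"
        )
    rng = np.random.default_rng(seed)
    chosen: set[tuple[str, str]] = set()
    cap = max_draw_factor * n + 1000
    draws = 0
    while len(chosen) < n:
        if draws >= cap:
            raise GuardrailError(
                f"NOT sampling exceeded the retry cap of {cap} draws "
                f"({len(chosen)}/{n} sampled)"
            )
        i, j = rng.integers(0, len(nodes), size=2)
        draws += 1
        if i == j:
            continue
        key = pair_key(nodes[i], nodes[j])
        if key in excluded or key in chosen:
            continue
        chosen.add(key)
    out = pd.DataFrame(sorted(chosen), columns=_KEY_COLS)
    out["label"] = "NOT"
    return out


def _smote_rows(block: pd.DataFrame, feature_names: list[str], n_new: int,
                rng: np.random.Generator, k: int = 5) -> pd.DataFrame:
    """Synthesize rows by interpolating toward one of the k nearest same-class rows."""
    X = block[feature_names].to_numpy(dtype=float)
    k_eff = min(k, len(block) - 1)
    if k_eff < 1:  # single row: fall back to duplication
        idx = rng.integers(0, len(block), size=n_new)
        return block.iloc[idx].copy()
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X)
    _, neigh = nn.kneighbors(X)
    base = rng.integers(0, len(block), size=n_new)
    pick = rng.integers(1, k_eff + 1, size=n_new)
    u = rng.random(size=(n_new, 1))
    Xnew = X[base] + u * (X[neigh[base, pick]] - X[base])
    out = block.iloc[base].copy()
    out[feature_names] = Xnew
    return out


def balance(
    ds: GIDataset,
    strategy: str,
    targets: dict[str, int],
    seed: int,
) -> GIDataset:
    """Resample the dataset so that class counts equal ``targets``.

    Strategies: ``undersample`` (each target must not exceed the current
    count; rows are dropped at random, none duplicated), ``oversample``
    (targets at least the current counts; rows duplicated at random),
    ``hybrid`` (under- or over-sample per class as needed, duplication only)
    and ``hybrid-smote`` (as hybrid, but oversampled rows are synthesized by
    k=5 nearest-neighbor interpolation in feature space). Deterministic under
    seed. Resampled/synthetic rows do not count as duplicate pair keys.
    """
    if strategy not in ("undersample", "oversample", "hybrid", "hybrid-smote"):
        raise ConfigError(f"unknown balancing strategy: {strategy!r}")
    counts = ds.class_counts
    unknown = set(targets) - set(CLASS_ORDER)
    if unknown:
        raise ConfigError(f"targets for unknown classes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    parts = []
    for label in CLASS_ORDER:
        have = counts[label]
        block = ds.df[ds.df["label"] == label]
        if label not in targets:  # untargeted classes pass through unchanged
            if have:
                parts.append(block)
            continue
        want = targets[label]
        if have == 0:
            raise DataError(f"class {label} absent from dataset")
        if want == have:
            parts.append(block)
        elif want < have:
            if strategy == "oversample":
                raise ConfigError(
                    f"oversample cannot reduce class {label}: {have} -> {want}"
                )
            keep = rng.choice(have, size=want, replace=False)
            parts.append(block.iloc[np.sort(keep)])
        else:
            if strategy == "undersample":
                raise ConfigError(
                    f"undersample cannot grow class {label}: {have} -> {want}"
                )
            parts.append(block)
            extra = want - have
            if strategy == "hybrid-smote":
                parts.append(_smote_rows(block, ds.feature_names, extra, rng))
            else:
                idx = rng.integers(0, have, size=extra)
                parts.append(block.iloc[idx])
    out = pd.concat(parts, ignore_index=True)
    result = GIDataset.__new__(GIDataset)  # duplicates are intentional here
    result.df = out.reset_index(drop=True)
    result.feature_names = list(ds.feature_names)
    return result


def split(ds: GIDataset, train_frac: float, seed: int) -> SplitResult:
    """Stratified train/test split.

    Per class, floor(train_frac * count) rows go to train; the remaining
    whole-row budget up to floor(train_frac * total) is assigned one row at a
    time to the classes with the largest fractional remainders (ties broken in
    SL < SV < NOT order), so |train| = floor(train_frac * total) exactly.
    """
    if not 0 < train_frac < 1:
        raise ConfigError(f"train_frac must be in (0, 1), got {train_frac}")
    counts = ds.class_counts
    for label, c in counts.items():
        if 0 < c < 2:
            raise DataError(f"class {label} has fewer than 2 members")
    total_train = int(np.floor(train_frac * ds.n))
    floors = {}
    fracs = {}
    for label in CLASS_ORDER:
        exact = train_frac * counts[label]
        floors[label] = int(np.floor(exact))
        fracs[label] = exact - floors[label]
    remainder = total_train - sum(floors.values())
    order = sorted(CLASS_ORDER, key=lambda l: (-fracs[l], CLASS_ORDER.index(l)))
    for label in order[:remainder]:
        floors[label] += 1

    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for label in CLASS_ORDER:
        idx = ds.df.index[ds.df["label"] == label].to_numpy()
        if len(idx) == 0:
            continue
        perm = rng.permutation(idx)
        train_idx.append(np.sort(perm[: floors[label]]))
        test_idx.append(np.sort(perm[floors[label]:]))
    tr = np.concatenate(train_idx) if train_idx else np.array([], dtype=int)
    te = np.concatenate(test_idx) if test_idx else np.array([], dtype=int)

    def _take(ix: np.ndarray) -> GIDataset:
        out = GIDataset.__new__(GIDataset)
        out.df = ds.df.loc[ix].reset_index(drop=True)
        out.feature_names = list(ds.feature_names)
        return out

    return SplitResult(train=_take(tr), test=_take(te), seed=seed)
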