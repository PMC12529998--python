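"""End-to-end pipeline: network -> features -> dataset -> model -> reports.

A :class:`RunConfig` describes one run (input paths or a synthetic benchmark,
feature registry, balancing, split, forest and bootstrap parameters, global
seed). :func:`run_pipeline` executes the stages, logging each one, and writes
every output atomically (write to a temporary file, then rename) into the
output directory together with a manifest carrying the config hash and seed,
so a rerun with the same config and seed reproduces all non-plot outputs
byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classifier, dataset, netfeatures, plots, synthetic
from .errors import ConfigError, DataError
from .graph_io import Network, read_edge_list, network_summary

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("ginet.pipeline")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; CLI flags override file values."""

    outdir: str = "ginet-run"
    network: str | None = None  # None -> generate the synthetic benchmark
    benchmark: dict = field(default_factory=dict)  # BenchmarkConfig overrides
    pairs: str | None = None
    exclusions: list[str] = field(default_factory=list)
    annotations: str | None = None
    features: str = "all"  # all | core5 | comma-separated list
    aggregation: str = "average"
    community_objective: str = "CPM"
    resolution: float = 0.005
    not_size: int = 0  # 0 -> use NOT labels already present in `pairs`
    balance_strategy: str | None = None
    balance_targets: dict[str, int] = field(default_factory=dict)
    train_frac: float = 0.7
    n_trees: int = 500
    bootstrap_b: int = 0  # 0 -> skip bootstrap feature selection
    bootstrap_k_top: int = 5
    bootstrap_freq: float = 0.9
    thresholds: tuple = classifier.DEFAULT_THRESHOLDS
    seed: int = 1
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate(self) -> None:
        if self.network is not None and not Path(self.network).exists():
            raise ConfigError(f"config field 'network': path does not exist: {self.network}")
        if self.pairs is not None and not Path(self.pairs).exists():
            raise ConfigError(f"config field 'pairs': path does not exist: {self.pairs}")
        for p in self.exclusions:
            if not Path(p).exists():
                raise ConfigError(f"config field 'exclusions': path does not exist: {p}")
        if (self.network is None) != (self.pairs is None):
            raise ConfigError("fields 'network' and 'pairs' must be given together")
        if not 0 < self.train_frac < 1:
            raise ConfigError("config field 'train_frac' must be in (0, 1)")

    def feature_list(self) -> list[str] | None:
        if self.features == "all":
            return None
        if self.features == "core5":
            return list(netfeatures.CORE5)
        return [f.strip() for f in self.features.split(",") if f.strip()]

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage and return the output directory."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()

    # -- inputs -------------------------------------------------------------
    if cfg.network is None:
        _stage("simulate (synthetic benchmark)")
        bench_kwargs = dict(cfg.benchmark)
        bench_kwargs["seed"] = cfg.seed
        bench = synthetic.generate_benchmark(synthetic.BenchmarkConfig(**bench_kwargs))
        net, labeled = bench.network, bench.pairs
        bench.write(outdir / "benchmark")
    else:
        _stage("load network and pairs")
        net = read_edge_list(cfg.network)
        labeled = dataset.read_labeled_pairs(cfg.pairs)

    # -- optional NOT construction -----------------------------------------
    if cfg.not_size > 0:
        _stage("build NOT set")
        excluded = {dataset.pair_key(a, b) for a, b in labeled[["gene_a", "gene_b"]].to_numpy()}
        for path in cfg.exclusions:
            excluded |= dataset.read_pair_list(path)
        not_df = dataset.build_not_set(net.nodes, excluded, cfg.not_size, seed=cfg.seed)
        labeled = pd.concat([labeled[labeled["label"] != "NOT"], not_df], ignore_index=True)

    # -- features -----------------------------------------------------------
    _stage("compute pair features")
    feats = netfeatures.build_pair_features(
        net,
        list(map(tuple, labeled[["gene_a", "gene_b"]].to_numpy())),
        aggregation=cfg.aggregation,
        community_objective=cfg.community_objective,
        resolution=cfg.resolution,
        seed=cfg.seed,
    )
    _atomic_write(outdir / "features.tsv", feats.to_csv(sep="\t", index=False))
    ds = dataset.GIDataset.from_features(labeled, feats)
    sel = cfg.feature_list()
    if sel:
        ds = ds.select_features(sel)

    # -- balancing and split ------------------------------------------------
    if cfg.balance_strategy:
        _stage(f"balance ({cfg.balance_strategy})")
        targets = cfg.balance_targets or {
            c: min(ds.class_counts.values()) for c in dataset.CLASS_ORDER
        }
        ds = dataset.balance(ds, cfg.balance_strategy, targets, seed=cfg.seed)
    _stage("stratified split")
    sp = dataset.split(ds, cfg.train_frac, seed=cfg.seed)

    # -- training and evaluation -------------------------------------------
    _stage("train random forest")
    results = classifier.InteractionForest(sp.train, n_trees=cfg.n_trees, seed=cfg.seed).fit()
    classifier.save_model(results, outdir / "model.joblib")
    _stage("evaluate")
    report = results.evaluate(sp.test, thresholds=cfg.thresholds)
    _atomic_write(
        outdir / "evaluation.json",
        json.dumps(report.to_dict(), indent=2, sort_keys=True),
    )
    plots.plot_roc(report, outdir / "roc.png")
    plot_feats = [f for f in netfeatures.CORE5 if f in ds.feature_names] or ds.feature_names[:5]
    plots.plot_class_distributions(ds.df, plot_feats, outdir / "class_distributions.png")

    # -- bootstrap feature selection ---------------------------------------
    if cfg.bootstrap_b > 0:
        _stage(f"bootstrap feature selection (B={cfg.bootstrap_b})")
        imp = classifier.bootstrap_select(
            ds,
            b=cfg.bootstrap_b,
            k_top=cfg.bootstrap_k_top,
            freq_threshold=cfg.bootstrap_freq,
            seed=cfg.seed,
        )
        _atomic_write(
            outdir / "importance.tsv", imp.table.to_csv(sep="\t")
        )
        plots.plot_selection_frequencies(imp, outdir / "selection_frequencies.png")

    # -- manifest -----------------------------------------------------------
    summary = network_summary(net)
    manifest = {
        "config": dataclasses.asdict(cfg),
        "config_hash": chash,
        "seed": cfg.seed,
        "network": dataclasses.asdict(summary),
        "class_counts": ds.class_counts,
        "train_rows": sp.train.n,
        "test_rows": sp.test.n,
        "accuracy": report.accuracy,
        "macro_auc": report.macro_auc,
        "dataset_hash": results.dataset_hash,
    }
    _atomic_write(outdir / "manifest.json", json.dumps(manifest, indent=2, sort_keys=True, default=list))
    log.info("done: %s", outdir)
    return outdir
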