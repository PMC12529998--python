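"""Seeded synthetic benchmarks: network, planted pair classes, toy GO terms.

The generator emulates the statistical structure the classifier relies on,
at desk scale, so that every pipeline stage is testable without downloads:

* a sparse undirected network with community structure — a stochastic block
  model with dense intra-block wiring and very sparse inter-block wiring;
* planted SL pairs: endpoints in *different* blocks, drawn degree-weighted
  (hubs), so they sit far apart (long shortest paths, few edge-disjoint
  routes between them across the sparse inter-block cut) yet are individually
  central (high betweenness / triangles / 2-neighborhoods);
* planted SV pairs: endpoints in the *same* block, preferentially adjacent or
  at distance 2, so they are close, co-membered, and well multi-connected;
* planted NOT pairs: uniform random background, excluding planted pairs;
* toy GO annotations: SV pairs share a planted fraction of their terms, SL
  pairs almost none, and SL genes carry richer term sets.

Everything is reproducible from the config seed; the manifest records the
config and sha256 checksums of the three serialized tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .dataset import build_not_set, pair_key
from .errors import ConfigError, DataError
from .go_semantics import GOAnnotationMap
from .graph_io import Network, write_edge_list

__all__ = ["BenchmarkConfig", "Benchmark", "generate_benchmark", "generate_oracle_graphs"]


@dataclass(frozen=True)
class BenchmarkConfig:
    """Study conditions of the default benchmark.

    ``p_out`` is chosen so that a block's total capacity to the rest of the
    network (≈ ``block_size * (n_nodes - block_size) * p_out`` edges) sits
    *below* the typical hub degree: it is that inter-block bottleneck, not the
    endpoint degrees, that gives planted cross-block SL pairs their low
    adhesion while their degree-biased endpoints keep high centrality.
    """

    n_nodes: int = 600
    n_blocks: int = 12
    p_in: float = 0.12
    p_out: float = 0.00015
    n_per_class: int = 300
    sl_min_blocks_apart: int = 1
    sv_same_block: bool = True
    sv_adjacent_frac: float = 0.8
    hub_bias_sl: float = 3.0
    go_terms_per_gene: tuple[int, int] = (10, 40)
    go_universe: int = 4000
    sv_shared_go_frac: float = 0.5
    sl_shared_go_frac: float = 0.03
    sl_go_richness: float = 1.6
    seed: int = 1

    def validate(self) -> None:
        if not (0 < self.p_in <= 1 and 0 < self.p_out <= 1):
            raise ConfigError("edge probabilities must lie in (0, 1]")
        if self.n_per_class < 10:
            raise ConfigError("n_per_class must be >= 10")
        if self.n_blocks < 2 or self.n_nodes < 2 * self.n_blocks:
            raise ConfigError("need >= 2 blocks with >= 2 nodes each")
        lo, hi = self.go_terms_per_gene
        if not (0 < lo <= hi <= self.go_universe):
            raise ConfigError("invalid go_terms_per_gene range")
        if not 1 <= self.sl_min_blocks_apart <= self.n_blocks // 2:
            raise ConfigError("sl_min_blocks_apart out of range")


@dataclass
class Benchmark:
    network: Network
    pairs: pd.DataFrame  # gene_a, gene_b, label
    annotations: GOAnnotationMap
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_edge_list(self.network, outdir / "network.tsv")
        self.pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False, header=False)
        with open(outdir / "annotations.tsv", "w") as fh:
            fh.write(_annotations_text(self.annotations))
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _sha(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def _edges_text(net: Network) -> str:
    return "".join(f"{a}\t{b}\n" for a, b in sorted(net.edges()))


def _annotations_text(ann: GOAnnotationMap) -> str:
    lines = []
    for gene in sorted(ann.terms):
        for term in sorted(ann.terms[gene]):
            lines.append(f"{gene}\t{term}\tbiological_process\n")
    return "".join(lines)


def _sample_blocks_apart(rng, n_blocks: int, min_apart: int) -> tuple[int, int]:
    while True:
        i, j = rng.integers(0, n_blocks, size=2)
        d = abs(int(i) - int(j))
        if min(d, n_blocks - d) >= min_apart:
            return int(i), int(j)


def generate_benchmark(cfg: BenchmarkConfig | None = None) -> Benchmark:
    """Generate the full benchmark for one config (deterministic under seed)."""
    cfg = cfg or BenchmarkConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    width = len(str(cfg.n_nodes - 1))
    names = np.array([f"G{i:0{width}d}" for i in range(cfg.n_nodes)])
    block_of = np.repeat(np.arange(cfg.n_blocks), -(-cfg.n_nodes // cfg.n_blocks))[: cfg.n_nodes]
    members = [np.flatnonzero(block_of == b) for b in range(cfg.n_blocks)]

    # stochastic block model edges
    edges: list[tuple[int, int]] = []
    iu, ju = np.triu_indices(cfg.n_nodes, k=1)
    same = block_of[iu] == block_of[ju]
    p = np.where(same, cfg.p_in, cfg.p_out)
    keep = rng.random(len(iu)) < p
    edges = list(zip(iu[keep].tolist(), ju[keep].tolist()))
    g = nx.Graph()
    g.add_edges_from((names[a], names[b]) for a, b in edges)
    net = Network(g)
    present = net.nodes  # isolated vertices never make it into the network
    degree = {v: net.degree(v) for v in present}

    # planted SL pairs: cross-block, degree-weighted endpoints
    used: set[tuple[str, str]] = set()
    sl_rows: list[tuple[str, str]] = []
    block_nodes = []
    block_weights = []
    for b in range(cfg.n_blocks):
        nodes_b = [names[i] for i in members[b] if names[i] in present]
        if len(nodes_b) < 2:
            raise DataError(f"block {b} too small after dropping isolated nodes")
        w = np.array([degree[v] ** cfg.hub_bias_sl for v in nodes_b], dtype=float)
        block_nodes.append(nodes_b)
        block_weights.append(w / w.sum())
    tries = 0
    while len(sl_rows) < cfg.n_per_class:
        if tries > 200 * cfg.n_per_class:
            raise DataError("could not place the requested number of SL pairs")
        tries += 1
        bi, bj = _sample_blocks_apart(rng, cfg.n_blocks, cfg.sl_min_blocks_apart)
        a = rng.choice(block_nodes[bi], p=block_weights[bi])
        b = rng.choice(block_nodes[bj], p=block_weights[bj])
        key = pair_key(str(a), str(b))
        if key in used:
            continue
        used.add(key)
        sl_rows.append(key)

    # planted SV pairs: same block, adjacent or at distance <= 2
    intra_edges = [
        [
            (names[a], names[b])
            for a, b in edges
            if block_of[a] == bb and block_of[b] == bb
        ]
        for bb in range(cfg.n_blocks)
    ]
    if cfg.sv_same_block and any(len(e) == 0 for e in intra_edges):
        raise DataError("a block has no internal edges; cannot plant SV pairs")
    sv_rows: list[tuple[str, str]] = []
    tries = 0
    while len(sv_rows) < cfg.n_per_class:
        if tries > 200 * cfg.n_per_class:
            raise DataError("could not place the requested number of SV pairs")
        tries += 1
        bb = int(rng.integers(0, cfg.n_blocks))
        elist = intra_edges[bb]
        u, v = elist[int(rng.integers(0, len(elist)))]
        if rng.random() >= cfg.sv_adjacent_frac:
            # step once more inside the block: a distance-<=2 partner
            nbrs = [
                w
                for w in net.neighbors(v)
                if w != u and block_of[int(w[1:])] == bb
            ]
            if nbrs:
                v = nbrs[int(rng.integers(0, len(nbrs)))]
        key = pair_key(str(u), str(v))
        if key in used or key[0] == key[1]:
            continue
        used.add(key)
        sv_rows.append(key)

    # NOT pairs: uniform background excluding everything planted
    not_df = build_not_set(
        present, used, cfg.n_per_class, seed=int(rng.integers(0, 2**31 - 1))
    )

    pairs = pd.concat(
        [
            pd.DataFrame(sl_rows, columns=["gene_a", "gene_b"]).assign(label="SL"),
            pd.DataFrame(sv_rows, columns=["gene_a", "gene_b"]).assign(label="SV"),
            not_df,
        ],
        ignore_index=True,
    )

    annotations = _plant_annotations(cfg, rng, sorted(present), sl_rows, sv_rows)

    pairs_text = pairs.to_csv(sep="\t", index=False, header=False)
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "seed": cfg.seed,
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "class_counts": pairs["label"].value_counts().to_dict(),
        "checksums": {
            "network": _sha(_edges_text(net)),
            "pairs": _sha(pairs_text),
            "annotations": _sha(_annotations_text(annotations)),
        },
    }
    return Benchmark(network=net, pairs=pairs, annotations=annotations, manifest=manifest)


def _plant_annotations(cfg, rng, genes, sl_rows, sv_rows) -> GOAnnotationMap:
    universe = np.array([f"GO:{i:07d}" for i in range(1, cfg.go_universe + 1)])
    lo, hi = cfg.go_terms_per_gene
    sl_genes = {g for p in sl_rows for g in p}
    terms: dict[str, set[str]] = {}
    for gene in genes:
        count = int(rng.integers(lo, hi + 1))
        if gene in sl_genes:  # SL genes are annotation-rich
            count = min(cfg.go_universe, int(round(count * cfg.sl_go_richness)))
        terms[gene] = set(rng.choice(universe, size=count, replace=False))

    def _share(a: str, b: str, frac: float) -> None:
        k = int(round(frac * min(len(terms[a]), len(terms[b]))))
        if k < 1:
            return
        core = set(rng.choice(universe, size=k, replace=False))
        for gene in (a, b):
            own = sorted(terms[gene] - core)
            drop = rng.choice(len(own), size=min(k, len(own)), replace=False)
            terms[gene] -= {own[i] for i in drop}
            terms[gene] |= core

    for a, b in sl_rows:
        _share(a, b, cfg.sl_shared_go_frac)
    for a, b in sv_rows:
        _share(a, b, cfg.sv_shared_go_frac)
    return GOAnnotationMap(
        {g: frozenset(t) for g, t in terms.items()}, namespace="biological_process"
    )


def generate_oracle_graphs(
    seed: int, n_graphs: int = 200, max_nodes: int = 12
) -> list[Network]:
    """Seeded Erdős–Rényi family of small graphs for brute-force oracle tests.

    Sizes and densities vary so the family spans connected and disconnected
    cases (isolated vertices included). ``max_nodes`` must stay <= 12 to keep
    exhaustive oracles cheap.
    """
    if max_nodes > 12:
        raise ConfigError("oracle graphs are capped at 12 nodes")
    rng = np.random.default_rng(seed)
    out = []
    n_lo = min(4, max_nodes)
    for _ in range(n_graphs):
        n = int(rng.integers(n_lo, max_nodes + 1))
        p = float(rng.uniform(0.1, 0.6))
        g = nx.Graph()
        g.add_nodes_from(f"N{i}" for i in range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    g.add_edge(f"N{i}", f"N{j}")
        out.append(Network(g))
    return out
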