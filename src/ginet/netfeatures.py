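"""Topological node and pair properties of the PPI network.

Node-wise properties (degree, betweenness, closeness, coreness, Burt's
constraint, reciprocal eccentricity, eigenvector centrality, hub score,
1/2/3-neighborhood sizes, triangle counts) are averaged over the two genes of
a pair — ``degree(ab) = (degree(a) + degree(b)) / 2`` and analogously for the
rest — and combined with genuinely pairwise properties: shortest path (with
infinite distances replaced by the network's finite diameter), cohesion
(local vertex connectivity), adhesion (local edge connectivity), common
neighbors, community co-membership and mean community size. The resulting
per-pair vector is the classifier's input row.

Conventions, where the standard definitions leave room:

* betweenness is unnormalized, each unordered pair counted once, geodesic
  ties split fractionally (Brandes);
* closeness on disconnected graphs is computed within the node's component
  and scaled by (reachable-1)/(n-1);
* eccentricity defaults to the *reciprocal* of the maximum finite geodesic
  from the node (``eccentricity_mode="raw"`` gives the plain maximum);
* coreness is the standard k-core index;
* eigenvector centrality and hub score are max-normalized to [0, 1];
* local vertex connectivity of an adjacent pair uses the kappa_{G-e}+1
  convention; both connectivities are 0 for pairs in different components;
* communities come from Leiden (CPM objective, resolution 0.005 by default),
  encoded per pair as ``same_community`` (0/1) and ``avg_community_size``.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .graph_io import Network

__all__ = [
    "NODE_PROPERTIES",
    "PAIR_PROPERTIES",
    "FEATURE_REGISTRY",
    "CORE5",
    "compute_node_profiles",
    "detect_communities",
    "pairwise_shortest_path",
    "pairwise_connectivity",
    "common_neighbors",
    "build_pair_features",
    "write_pair_features",
    "feature_columns",
]

#: Node-wise properties averaged (or otherwise aggregated) over the two genes.
NODE_PROPERTIES = [
    "degree",
    "betweenness",
    "closeness",
    "coreness",
    "constraint",
    "eccentricity",
    "eigen_centrality",
    "hub_score",
    "neighbor1",
    "neighbor2",
    "neighbor3",
    "triangle",
]

#: Pairwise properties computed directly on the pair.
PAIR_PROPERTIES = [
    "shortest_path",
    "cohesion",
    "adhesion",
    "common_neighbors",
    "same_community",
    "avg_community_size",
]

_AGG_PREFIX = {"average": "avg", "sum": "sum", "diff": "diff", "max": "max", "min": "min"}

#: Full default feature registry (18 features, averaging aggregation).
FEATURE_REGISTRY = [f"avg_{p}" for p in NODE_PROPERTIES] + PAIR_PROPERTIES

#: The five discriminatory features retained by bootstrap selection.
CORE5 = ["shortest_path", "avg_neighbor2", "avg_betweenness", "avg_triangle", "adhesion"]


def feature_columns(aggregation: str = "average") -> list[str]:
    """Feature-column names, in the stable documented order, for one aggregation."""
    try:
        prefix = _AGG_PREFIX[aggregation]
    except KeyError:
        raise ConfigError(f"unknown aggregation mode: {aggregation!r}") from None
    return [f"{prefix}_{p}" for p in NODE_PROPERTIES] + PAIR_PROPERTIES


def _to_igraph(net: Network) -> tuple[ig.Graph, dict[str, int]]:
    """Convert with a deterministic (sorted) vertex order."""
    names = sorted(net.nodes)
    index = {name: i for i, name in enumerate(names)}
    edges = [(index[a], index[b]) for a, b in net.edges()]
    g = ig.Graph(n=len(names), edges=edges, directed=False)
    g.vs["name"] = names
    return g, index


def detect_communities(
    net: Network,
    objective: str = "CPM",
    resolution: float = 0.005,
    seed: int = 0,
    n_iterations: int = 10,
) -> pd.Series:
    """Leiden community detection; returns gene -> integer community label.

    ``objective`` is ``"CPM"`` (constant Potts model; requires resolution > 0)
    or ``"modularity"`` (RB-configuration null with the same resolution
    parameter). Leiden guarantees connected communities; with a fixed seed the
    partition is reproducible.
    """
    if net.n_nodes == 0:
        raise DataError("cannot detect communities on an empty network")
    g, _ = _to_igraph(net)
    if objective == "CPM":
        if resolution <= 0:
            raise ConfigError(f"CPM resolution must be > 0, got {resolution}")
        part = leidenalg.find_partition(
            g,
            leidenalg.CPMVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=n_iterations,
        )
    elif objective == "modularity":
        if resolution <= 0:
            raise ConfigError(f"resolution must be > 0, got {resolution}")
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=n_iterations,
        )
    else:
        raise ConfigError(f"unknown community objective: {objective!r}")
    return pd.Series(part.membership, index=g.vs["name"], name="community_id")


def compute_node_profiles(
    net: Network,
    *,
    eccentricity_mode: str = "reciprocal",
    community_objective: str = "CPM",
    resolution: float = 0.005,
    seed: int = 0,
) -> pd.DataFrame:
    """Compute every node-wise property plus the community label.

    Returns a DataFrame indexed by gene symbol with columns
    ``NODE_PROPERTIES + ["community_id"]``. Isolated nodes get constraint 0
    and eccentricity 0 (the value 0 is reserved for them in reciprocal mode).
    """
    if net.n_nodes == 0:
        raise DataError("cannot profile an empty network")
    if eccentricity_mode not in ("reciprocal", "raw"):
        raise ConfigError(f"unknown eccentricity_mode: {eccentricity_mode!r}")

    g, _ = _to_igraph(net)
    names = g.vs["name"]
    n = len(names)
    G = net.graph

    degree = np.asarray(g.degree(), dtype=float)
    betweenness = np.asarray(g.betweenness(directed=False), dtype=float)
    coreness = np.asarray(g.coreness(), dtype=float)
    constraint = np.nan_to_num(np.asarray(g.constraint(), dtype=float), nan=0.0)
    if n == 1:
        eigen = np.ones(1)
        hub = np.ones(1)
    else:
        eigen = np.asarray(g.eigenvector_centrality(scale=True), dtype=float)
        hub = np.asarray(g.hub_score(scale=True), dtype=float)
    triangles = nx.triangles(G)

    closeness = np.zeros(n)
    eccentricity = np.zeros(n)
    nbr = np.zeros((n, 3))
    for i, v in enumerate(names):
        dists = nx.single_source_shortest_path_length(G, v)
        del dists[v]
        if dists:
            dvals = np.fromiter(dists.values(), dtype=float)
            r = len(dvals)
            closeness[i] = (r / dvals.sum()) * (r / (n - 1)) if n > 1 else 0.0
            emax = dvals.max()
            eccentricity[i] = 1.0 / emax if eccentricity_mode == "reciprocal" else emax
            nbr[i, 0] = np.count_nonzero(dvals <= 1)
            nbr[i, 1] = np.count_nonzero(dvals <= 2)
            nbr[i, 2] = np.count_nonzero(dvals <= 3)

    community = detect_communities(
        net, objective=community_objective, resolution=resolution, seed=seed
    )
    return pd.DataFrame(
        {
            "degree": degree,
            "betweenness": betweenness,
            "closeness": closeness,
            "coreness": coreness,
            "constraint": constraint,
            "eccentricity": eccentricity,
            "eigen_centrality": eigen,
            "hub_score": hub,
            "neighbor1": nbr[:, 0],
            "neighbor2": nbr[:, 1],
            "neighbor3": nbr[:, 2],
            "triangle": [float(triangles[v]) for v in names],
            "community_id": community.reindex(names).to_numpy(),
        },
        index=pd.Index(names, name="gene"),
    )


def _check_genes(net: Network, *genes: str) -> None:
    for gene in genes:
        if gene not in net:
            raise DataError(f"gene not in network: {gene!r}")


def pairwise_shortest_path(net: Network, a: str, b: str) -> int:
    """Geodesic length between two genes, diameter-substituted if disconnected."""
    _check_genes(net, a, b)
    if a == b:
        raise DataError("shortest path requires two distinct genes")
    try:
        return nx.shortest_path_length(net.graph, a, b)
    except nx.NetworkXNoPath:
        return net.diameter_finite


def _connectivity_on_igraph(g: ig.Graph, ia: int, ib: int) -> tuple[int, int]:
    adhesion = int(g.edge_connectivity(source=ia, target=ib))
    if adhesion == 0:  # different components: both defined as 0
        return 0, 0
    if g.are_adjacent(ia, ib):
        h = g.copy()
        h.delete_edges([(ia, ib)])
        if h.edge_connectivity(source=ia, target=ib) == 0:
            cohesion = 1
        else:
            cohesion = int(h.vertex_connectivity(source=ia, target=ib)) + 1
    else:
        cohesion = int(g.vertex_connectivity(source=ia, target=ib))
    return cohesion, adhesion


def pairwise_connectivity(net: Network, a: str, b: str) -> tuple[int, int]:
    """(cohesion, adhesion): local vertex and edge connectivity of the pair.

    Adhesion is the max-flow value with unit edge capacities (Menger); cohesion
    the minimum vertex cut, with adjacent pairs handled by deleting the direct
    edge and adding 1. Pairs in different components return (0, 0).
    """
    _check_genes(net, a, b)
    if a == b:
        raise DataError("pair connectivity requires two distinct genes")
    g, index = _to_igraph(net)
    return _connectivity_on_igraph(g, index[a], index[b])


def common_neighbors(net: Network, a: str, b: str) -> int:
    """Number of shared adjacent vertices, excluding the pair itself."""
    _check_genes(net, a, b)
    shared = net.neighbors(a) & net.neighbors(b)
    shared.discard(a)
    shared.discard(b)
    return len(shared)


def _aggregate(agg: str, xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    if agg == "average":
        return (xa + xb) / 2.0
    if agg == "sum":
        return xa + xb
    if agg == "diff":
        return np.abs(xa - xb)  # absolute, to keep pair symmetry
    if agg == "max":
        return np.maximum(xa, xb)
    if agg == "min":
        return np.minimum(xa, xb)
    raise ConfigError(f"unknown aggregation mode: {agg!r}")


def build_pair_features(
    net: Network,
    pairs: Iterable[tuple[str, str]],
    aggregation: str = "average",
    *,
    profiles: pd.DataFrame | None = None,
    eccentricity_mode: str = "reciprocal",
    community_objective: str = "CPM",
    resolution: float = 0.005,
    seed: int = 0,
) -> pd.DataFrame:
    """Assemble the per-pair feature table.

    One row per input pair, keyed by the lexicographically sorted symbol pair
    (``gene_a <= gene_b``). Pairs with either gene absent from the network are
    kept with ``mapped=False`` and NaN features so callers can report them;
    they must be excluded from training. Feature values are identical under
    swapping the two genes.

    Passing a precomputed ``profiles`` table (from
    :func:`compute_node_profiles`) skips the node-wise recomputation.
    """
    pair_list = [tuple(p) for p in pairs]
    if not pair_list:
        raise DataError("no pairs supplied")
    if profiles is None:
        profiles = compute_node_profiles(
            net,
            eccentricity_mode=eccentricity_mode,
            community_objective=community_objective,
            resolution=resolution,
            seed=seed,
        )
    cols = feature_columns(aggregation)
    comm_sizes = profiles["community_id"].value_counts()
    g, index = _to_igraph(net)
    diameter = net.diameter_finite

    # one BFS per unique mapped endpoint, reused across pairs
    endpoints = sorted(
        {x for a, b in pair_list for x in (a, b) if x in net}
    )
    dist_rows: dict[str, dict] = {}
    if endpoints:
        mat = g.distances(source=[index[e] for e in endpoints])
        for e, row in zip(endpoints, mat):
            dist_rows[e] = row

    prop_mat = profiles[NODE_PROPERTIES]
    records = []
    for a, b in pair_list:
        a, b = (a, b) if a <= b else (b, a)
        rec: dict = {"gene_a": a, "gene_b": b}
        mapped = a in net and b in net and a != b
        rec["mapped"] = mapped
        if not mapped:
            rec.update({c: np.nan for c in cols})
            records.append(rec)
            continue
        xa = prop_mat.loc[a].to_numpy(dtype=float)
        xb = prop_mat.loc[b].to_numpy(dtype=float)
        agg = _aggregate(aggregation, xa, xb)
        for name, val in zip(cols[: len(NODE_PROPERTIES)], agg):
            rec[name] = val
        d = dist_rows[a][index[b]]
        rec["shortest_path"] = int(d) if np.isfinite(d) else diameter
        cohesion, adhesion = _connectivity_on_igraph(g, index[a], index[b])
        rec["cohesion"] = cohesion
        rec["adhesion"] = adhesion
        rec["common_neighbors"] = common_neighbors(net, a, b)
        ca, cb = profiles.at[a, "community_id"], profiles.at[b, "community_id"]
        rec["same_community"] = int(ca == cb)
        rec["avg_community_size"] = (comm_sizes[ca] + comm_sizes[cb]) / 2.0
        records.append(rec)
    return pd.DataFrame.from_records(records, columns=["gene_a", "gene_b", "mapped"] + cols)


def write_pair_features(features: pd.DataFrame, path) -> None:
    """TSV writer with the stable documented column order."""
    features.to_csv(path, sep="\t", index=False)
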