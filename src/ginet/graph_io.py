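"""Reading, cleaning and summarizing protein–protein interaction networks.

The canonical in-memory container is :class:`Network`, a thin wrapper around an
undirected simple :class:`networkx.Graph` whose nodes are gene symbols. Input
edge lists are cleaned on read: self-loops and duplicate interactions are
discarded and only unique undirected interactions are kept. Gene-symbol case is
preserved as-is and no symbol aliasing is attempted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

from .errors import DataError

__all__ = [
    "Network",
    "NetworkSummary",
    "read_edge_list",
    "write_edge_list",
    "network_summary",
    "BIOGRID_TAB_DEFAULTS",
]

#: Default column layout for the ``biogrid_tab`` dialect: 0-based indices of the
#: two interactor-symbol columns and an optional (filter column, kept value)
#: pair. The defaults target BioGRID tab3 files (official symbols in columns
#: 7/8, "Experimental System Type" in column 12, physical interactions only).
BIOGRID_TAB_DEFAULTS = {
    "symbol_columns": (7, 8),
    "filter_column": 12,
    "filter_value": "physical",
}


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class Network:
    """Undirected simple graph of gene symbols.

    Invariants: no self-loops, no duplicate edges, every edge endpoint is a
    node. The longest *finite* geodesic (``diameter_finite``) is computed
    lazily and cached; on disconnected graphs it is the maximum over the
    diameters of the connected components, which is also the value substituted
    for infinite pairwise shortest paths downstream.
    """

    def __init__(self, graph: nx.Graph):
        g = nx.Graph()
        g.add_nodes_from(graph.nodes())
        g.add_edges_from((u, v) for u, v in graph.edges() if u != v)
        self._graph = g
        self._diameter_finite: int | None = None

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "Network":
        g = nx.Graph()
        g.add_edges_from((u, v) for u, v in edges if u != v)
        return cls(g)

    # -- container protocol -------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> set[str]:
        return set(self._graph.nodes())

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self._graph

    def __len__(self) -> int:
        return self.n_nodes

    def edges(self) -> Iterator[tuple[str, str]]:
        for u, v in self._graph.edges():
            yield _pair_key(u, v)

    def degree(self, gene: str) -> int:
        return self._graph.degree[gene]

    def neighbors(self, gene: str) -> set[str]:
        return set(self._graph.neighbors(gene))

    # -- derived quantities -------------------------------------------------
    @property
    def diameter_finite(self) -> int:
        """Longest finite geodesic; 0 for a single-node or empty graph."""
        if self._diameter_finite is None:
            best = 0
            for comp in nx.connected_components(self._graph):
                if len(comp) > 1:
                    sub = self._graph.subgraph(comp)
                    best = max(best, nx.diameter(sub))
            self._diameter_finite = best
        return self._diameter_finite

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.nodes == other.nodes and set(self.edges()) == set(other.edges())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_components: int
    diameter_finite: int


def _iter_symbol_rows(
    path: Path,
    dialect: str,
    symbol_columns: tuple[int, int],
    filter_column: int | None,
    filter_value: str | None,
) -> Iterator[tuple[str, str]]:
    ca, cb = symbol_columns
    need = max(ca, cb, filter_column if filter_column is not None else 0) + 1
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        first = dialect == "biogrid_tab"  # header row expected in this dialect
        for lineno, row in enumerate(reader, start=1):
            if not row or (row[0].startswith("#")):
                continue
            if first:
                first = False
                continue
            if len(row) < need:
                raise DataError(
                    f"{path}:{lineno}: expected at least {need} columns, got {len(row)}"
                )
            if filter_column is not None and row[filter_column].strip() != filter_value:
                continue
            a, b = row[ca].strip(), row[cb].strip()
            if not a or not b:
                raise DataError(f"{path}:{lineno}: empty gene symbol")
            yield a, b


def read_edge_list(
    path: str | Path,
    dialect: str = "simple2col",
    *,
    symbol_columns: tuple[int, int] | None = None,
    filter_column: int | None = None,
    filter_value: str | None = None,
) -> Network:
    """Read a TSV edge list into a cleaned :class:`Network`.

    Parameters
    ----------
    path
        Tab-separated file. Lines starting with ``#`` are comments.
    dialect
        ``simple2col`` — two columns, no header; ``biogrid_tab`` — header-bearing
        multi-column file with configurable symbol columns and an optional
        keep-row filter (defaults in :data:`BIOGRID_TAB_DEFAULTS`).

    Raises
    ------
    DataError
        Missing file, a row with too few columns, or no edges left after
        removing self-loops and duplicates.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"edge list not found: {path}")
    if dialect == "simple2col":
        cols = symbol_columns or (0, 1)
        fcol, fval = filter_column, filter_value
    elif dialect == "biogrid_tab":
        cols = symbol_columns or BIOGRID_TAB_DEFAULTS["symbol_columns"]
        fcol = BIOGRID_TAB_DEFAULTS["filter_column"] if filter_column is None else filter_column
        fval = BIOGRID_TAB_DEFAULTS["filter_value"] if filter_value is None else filter_value
    else:
        raise DataError(f"unknown edge-list dialect: {dialect!r}")

    net = Network.from_edges(_iter_symbol_rows(path, dialect, cols, fcol, fval))
    if net.n_edges == 0:
        raise DataError(f"no edges remain after cleaning {path} (self-loops/duplicates only)")
    return net


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write the canonical serialized form: sorted unique 2-column TSV."""
    with open(path, "w") as fh:
        for a, b in sorted(net.edges()):
            fh.write(f"{a}\t{b}\n")


def network_summary(net: Network) -> NetworkSummary:
    return NetworkSummary(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        n_components=nx.number_connected_components(net.graph),
        diameter_finite=net.diameter_finite,
    )
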