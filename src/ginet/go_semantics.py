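"""Gene Ontology pair statistics: average term count and Jaccard index.

Two per-pair quantities are computed from direct (non-propagated) GO
annotations, by default restricted to the biological_process namespace:

* ``Average(ab) = (|terms(a)| + |terms(b)|) / 2``
* ``JI(ab) = |terms(a) ∩ terms(b)| / |terms(a) ∪ terms(b)|``

Annotations load either from a flattened 2–3 column TSV (gene, GO ID
[, namespace]) or from a GAF 2.x file (symbol column 3, GO ID column 5,
aspect column 9; ``!`` comment lines). Term sets are deduplicated — distinct
term IDs are counted, not annotation lines — and no evidence-code filtering
is applied.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from .errors import DataError

__all__ = [
    "GOAnnotationMap",
    "load_annotations",
    "read_gaf",
    "pair_average_terms",
    "pair_jaccard",
]

log = logging.getLogger(__name__)

_GO_ID = re.compile(r"^GO:\d{7}$")

# accepted namespace spellings -> canonical
_NAMESPACES = {
    "biological_process": "biological_process",
    "bp": "biological_process",
    "p": "biological_process",
    "molecular_function": "molecular_function",
    "mf": "molecular_function",
    "f": "molecular_function",
    "cellular_component": "cellular_component",
    "cc": "cellular_component",
    "c": "cellular_component",
}


@dataclass
class GOAnnotationMap:
    """gene -> deduplicated set of GO term IDs, after namespace filtering."""

    terms: dict[str, frozenset[str]] = field(default_factory=dict)
    namespace: str = "all"

    def __contains__(self, gene: str) -> bool:
        return gene in self.terms

    def __getitem__(self, gene: str) -> frozenset[str]:
        return self.terms[gene]

    def get(self, gene: str) -> frozenset[str]:
        return self.terms.get(gene, frozenset())

    @property
    def n_genes(self) -> int:
        return len(self.terms)


def _build_map(rows, namespace: str, source: str) -> GOAnnotationMap:
    if namespace not in ("all", "biological_process", "molecular_function",
                         "cellular_component"):
        raise DataError(f"unknown namespace filter: {namespace!r}")
    terms: dict[str, set[str]] = {}
    dropped_ns = 0
    for gene, term, ns in rows:
        if not _GO_ID.match(term):
            raise DataError(f"{source}: malformed GO term ID {term!r}")
        if namespace != "all":
            canon = _NAMESPACES.get(ns.lower()) if ns else None
            if canon is None:
                dropped_ns += 1
                continue
            if canon != namespace:
                continue
        terms.setdefault(gene, set()).add(term)
    if dropped_ns:
        log.info("%s: dropped %d row(s) with unknown namespace", source, dropped_ns)
    if not terms:
        raise DataError(f"{source}: no annotations after filtering")
    return GOAnnotationMap(
        {g: frozenset(t) for g, t in terms.items()}, namespace=namespace
    )


def load_annotations(path: str | Path, namespace: str = "biological_process") -> GOAnnotationMap:
    """Read a flattened TSV: gene, GO ID and (optionally) a namespace column.

    With a namespace filter active, 2-column rows (no namespace) are dropped
    and counted, as are rows with an unrecognized namespace label.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"annotation file not found: {path}")

    def rows():
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise DataError(f"{path}:{lineno}: expected >= 2 columns")
                yield parts[0], parts[1], (parts[2] if len(parts) > 2 else None)

    return _build_map(rows(), namespace, str(path))


def read_gaf(path: str | Path, namespace: str = "biological_process") -> GOAnnotationMap:
    """Read a GAF 2.x association file (columns 3/5/9; '!' comments)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"GAF file not found: {path}")

    def rows():
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("!"):
                    continue
                parts = line.split("\t")
                if len(parts) < 9:
                    raise DataError(f"{path}:{lineno}: GAF row with < 9 columns")
                yield parts[2], parts[4], parts[8]

    return _build_map(rows(), namespace, str(path))


def pair_average_terms(ann: GOAnnotationMap, a: str, b: str) -> float:
    """Mean annotation richness of the pair; NaN if either gene is unannotated."""
    if a not in ann or b not in ann:
        log.info("pair (%s, %s): unannotated gene, average undefined", a, b)
        return float("nan")
    return (len(ann[a]) + len(ann[b])) / 2.0


def pair_jaccard(ann: GOAnnotationMap, a: str, b: str) -> float:
    """Intersection-over-union of the two term sets; NaN if the union is empty."""
    if a not in ann or b not in ann:
        log.info("pair (%s, %s): unannotated gene, Jaccard undefined", a, b)
        return float("nan")
    ta, tb = ann[a], ann[b]
    union = ta | tb
    if not union:
        log.info("pair (%s, %s): both term sets empty, Jaccard undefined", a, b)
        return float("nan")
    return len(ta & tb) / len(union)
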