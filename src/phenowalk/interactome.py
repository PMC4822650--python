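"""Protein-protein interaction network loading and context filtering.

The analysis universe is the giant connected component of a
confidence-filtered PPI network restricted to genes expressed in the
experiment under study.  Networks are undirected ``networkx.Graph`` objects
with a ``confidence`` attribute in (0, 1] on every edge; identifiers are
matched as upper-cased strings, and identifier namespace reconciliation is
the caller's responsibility.
"""

from __future__ import annotations

import logging

import networkx as nx

from .exceptions import ConfigurationError, SchemaError
from .expression import ExpressedSet
from .ontology import AnnotationTable

logger = logging.getLogger(__name__)

__all__ = [
    "load_ppi",
    "filter_confidence",
    "context_filter",
    "giant_component",
    "load_ortholog_map",
    "map_annotations",
]


def load_ppi(path, default_confidence: float | None = None) -> nx.Graph:
    """Read a tab-separated edge list (protein_a, protein_b, confidence).

    Duplicate pairs keep the maximum confidence; self-loops are dropped with
    a warning.  If the file has only two columns and ``default_confidence``
    is given, every edge gets that confidence (for interaction databases
    that publish unscored edges); otherwise a missing confidence column is a
    schema error.
    """
    net = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                if default_confidence is None:
                    raise SchemaError(
                        f"{path}:{lineno}: no confidence column and no default given"
                    )
                conf = default_confidence
            elif len(fields) >= 3:
                try:
                    conf = float(fields[2])
                except ValueError as exc:
                    raise SchemaError(
                        f"{path}:{lineno}: unparseable confidence {fields[2]!r}"
                    ) from exc
            else:
                raise SchemaError(f"{path}:{lineno}: expected >= 2 columns")
            if not 0.0 < conf <= 1.0:
                raise ValueError(
                    f"{path}:{lineno}: confidence must be in (0, 1], got {conf}"
                )
            a, b = fields[0].upper(), fields[1].upper()
            if a == b:
                n_self += 1
                continue
            if net.has_edge(a, b):
                net[a][b]["confidence"] = max(net[a][b]["confidence"], conf)
            else:
                net.add_edge(a, b, confidence=conf)
    if n_self:
        logger.warning("dropped %d self-loop rows from %s", n_self, path)
    return net


def filter_confidence(net: nx.Graph, min_conf: float = 0.7) -> nx.Graph:
    """Keep edges with confidence >= ``min_conf``; isolated nodes are dropped.

    The boundary is inclusive: an edge scored exactly at the cutoff is
    low-confidence only when strictly below it.
    """
    kept = nx.Graph()
    for a, b, data in net.edges(data=True):
        if data["confidence"] >= min_conf:
            kept.add_edge(a, b, **data)
    if net.number_of_edges() and not kept.number_of_edges():
        logger.warning("confidence filter at %.2f removed every edge", min_conf)
    return kept


def context_filter(net: nx.Graph, expressed: ExpressedSet) -> nx.Graph:
    """Induced subgraph on expressed genes (the context-specific network)."""
    keep = {n for n in net.nodes if n in expressed.genes}
    if not keep:
        raise ConfigurationError(
            "no network protein is in the expressed set; check identifier namespaces"
        )
    sub = net.subgraph(keep).copy()
    logger.info(
        "context filter: %d/%d proteins expressed, %d edges retained",
        sub.number_of_nodes(), net.number_of_nodes(), sub.number_of_edges(),
    )
    return sub


def giant_component(net: nx.Graph) -> nx.Graph:
    """Largest connected component by node count.

    Ties are broken by the component containing the lexicographically
    smallest node identifier, so the result is deterministic.
    """
    if net.number_of_edges() == 0:
        raise ConfigurationError("network has no edges; no giant component")
    components = list(nx.connected_components(net))
    biggest = max(len(c) for c in components)
    tied = [c for c in components if len(c) == biggest]
    best = min(tied, key=min)
    return net.subgraph(best).copy()


def load_ortholog_map(path) -> dict[str, set[str]]:
    """Two-column TSV (source gene, target gene); one source may map to many."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise SchemaError(f"{path}:{lineno}: expected two columns")
            mapping.setdefault(fields[0].upper(), set()).add(fields[1].upper())
    return mapping


def map_annotations(
    annotations: AnnotationTable, orthologs: dict[str, set[str]]
) -> AnnotationTable:
    """Translate gene-phenotype pairs through an ortholog map.

    Each (gene, term) pair becomes (ortholog, term) for every mapped target;
    pairs for unmapped genes are dropped and counted in the log.
    """
    mapped: set[tuple[str, str]] = set()
    dropped_genes: set[str] = set()
    for gene, term in annotations.pairs:
        targets = orthologs.get(gene.upper())
        if not targets:
            dropped_genes.add(gene)
            continue
        for target in targets:
            mapped.add((target, term))
    if dropped_genes:
        logger.info(
            "ortholog mapping dropped %d genes with no target", len(dropped_genes)
        )
    if not mapped:
        raise ConfigurationError("ortholog mapping produced no annotation pairs")
    return AnnotationTable(frozenset(mapped))
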