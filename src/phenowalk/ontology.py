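"""Phenotype ontology handling: term DAG, information content, Resnik similarity.

The phenome side of the heterogeneous network is built from a phenotype
ontology (e.g. a cross-species phenotype ontology spanning human, mouse and
zebrafish terms) together with gene-to-phenotype annotations.  Terms are
compared by Resnik semantic similarity -- the information content (IC) of
their most informative common ancestor -- and term pairs above a similarity
threshold become weighted edges of the phenome network.

Only ``is_a`` relationships are traversed; the term graph must be acyclic.
IC uses the natural logarithm: ``IC(t) = -ln(n_t / N)`` where ``n_t`` counts
distinct genes annotated to ``t`` or any of its descendants and ``N`` is the
number of genes annotated anywhere in the ontology.  The similarity
threshold (default 3.0) is therefore on the natural-log scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .exceptions import ConfigurationError, SchemaError, StructuralError

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyGraph",
    "AnnotationTable",
    "load_ontology",
    "load_annotations",
    "information_content",
    "resnik_similarity",
    "build_phenome_network",
]


@dataclass(frozen=True)
class OntologyGraph:
    """A phenotype term DAG with ``is_a`` parent links.

    Parameters
    ----------
    terms
        All term identifiers (e.g. ``"HP:0005086"``).
    parents
        Mapping from each term to its set of ``is_a`` parents.  Roots map to
        the empty set.
    """

    terms: frozenset[str]
    parents: dict[str, frozenset[str]]
    _children: dict[str, set[str]] = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        unknown = {p for ps in self.parents.values() for p in ps} - self.terms
        if unknown:
            raise StructuralError(f"parent terms not in term set: {sorted(unknown)}")
        cycle = _find_cycle(self.parents)
        if cycle:
            raise StructuralError(
                "ontology is_a graph contains a cycle: " + " -> ".join(cycle)
            )
        children: dict[str, set[str]] = {t: set() for t in self.terms}
        for term, ps in self.parents.items():
            for p in ps:
                children[p].add(term)
        object.__setattr__(self, "_children", children)

    @classmethod
    def from_parents(cls, parents: Mapping[str, Iterable[str]]) -> "OntologyGraph":
        """Build from a ``term -> parents`` mapping; parents are added as terms."""
        full = {t: frozenset(ps) for t, ps in parents.items()}
        terms = set(full) | {p for ps in full.values() for p in ps}
        for t in terms:
            full.setdefault(t, frozenset())
        return cls(terms=frozenset(terms), parents=full)

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self.terms if not self.parents[t])

    def children(self, term: str) -> frozenset[str]:
        self._check(term)
        return frozenset(self._children[term])

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable via parent links, including ``term`` itself.

        The reflexive closure is deliberate: a term is its own subsumer, so
        ``resnik_similarity(t, t)`` equals ``IC(t)``.
        """
        self._check(term)
        seen = {term}
        stack = [term]
        while stack:
            for p in self.parents[stack.pop()]:
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return frozenset(seen)

    def descendants(self, term: str) -> frozenset[str]:
        """All terms that reach ``term`` via parent links, including itself."""
        self._check(term)
        seen = {term}
        stack = [term]
        while stack:
            for c in self._children[stack.pop()]:
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return frozenset(seen)

    def _check(self, term: str) -> None:
        if term not in self.terms:
            raise KeyError(f"unknown ontology term: {term!r}")

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)


def _find_cycle(parents: Mapping[str, Iterable[str]]) -> list[str] | None:
    """Return one cycle through parent links as a node list, or None."""
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {t: WHITE for t in parents}
    for start in parents:
        if colour[start] != WHITE:
            continue
        path: list[str] = []
        stack: list[tuple[str, iter]] = [(start, iter(parents.get(start, ())))]
        colour[start] = GREY
        path.append(start)
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if colour.get(nxt, BLACK) == GREY:
                    return path[path.index(nxt):] + [nxt]
                if colour.get(nxt, BLACK) == WHITE:
                    colour[nxt] = GREY
                    path.append(nxt)
                    stack.append((nxt, iter(parents.get(nxt, ()))))
                    advanced = True
                    break
            if not advanced:
                colour[node] = BLACK
                path.pop()
                stack.pop()
    return None


@dataclass(frozen=True)
class AnnotationTable:
    """Gene-to-phenotype annotation pairs.

    ``pairs`` holds direct annotations only; propagation to ancestors happens
    inside :func:`information_content` (the true-path rule: a gene annotated
    to a term is implicitly annotated to every ancestor of that term).
    """

    pairs: frozenset[tuple[str, str]]

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.pairs)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(t for _, t in self.pairs)

    def genes_for(self, term: str) -> frozenset[str]:
        return frozenset(g for g, t in self.pairs if t == term)

    def restrict_to_ontology(self, graph: OntologyGraph) -> "AnnotationTable":
        """Drop pairs whose term is not in the ontology, logging the count."""
        kept = frozenset(p for p in self.pairs if p[1] in graph)
        dropped = len(self.pairs) - len(kept)
        if dropped:
            logger.warning("dropped %d annotation pairs with unknown terms", dropped)
        return AnnotationTable(kept)

    def __len__(self) -> int:
        return len(self.pairs)


def load_ontology(path) -> OntologyGraph:
    """Parse an OBO file into an :class:`OntologyGraph`.

    Only ``is_a`` edges are kept; ``part_of`` and other relationship types
    are ignored, as are obsolete terms.  Raises :class:`SchemaError` on a
    file that does not parse as OBO and :class:`StructuralError` if the
    ``is_a`` graph contains a cycle.
    """
    try:
        multigraph = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # obonet raises ValueError with line context
        raise SchemaError(f"could not parse OBO file {path}: {exc}") from exc
    parents: dict[str, frozenset[str]] = {}
    for term in multigraph.nodes:
        isa = {
            v for _, v, key in multigraph.out_edges(term, keys=True) if key == "is_a"
        }
        parents[term] = frozenset(isa)
    return OntologyGraph(terms=frozenset(parents), parents=parents)


def load_annotations(path) -> AnnotationTable:
    """Read a two-column TSV (gene, term); ``#`` lines and blanks skipped."""
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise SchemaError(
                    f"{path}:{lineno}: expected two tab-separated columns (gene, term)"
                )
            pairs.add((fields[0], fields[1]))
    return AnnotationTable(frozenset(pairs))


def annotated_gene_sets(
    graph: OntologyGraph, annotations: AnnotationTable
) -> dict[str, frozenset[str]]:
    """Propagated annotation: term -> genes annotated to it or any descendant."""
    unknown = annotations.terms - graph.terms
    if unknown:
        raise StructuralError(
            f"annotations reference terms absent from the ontology: {sorted(unknown)[:5]}"
        )
    direct: dict[str, set[str]] = {t: set() for t in graph.terms}
    for gene, term in annotations.pairs:
        direct[term].add(gene)
    # accumulate upward in reverse topological order (children before parents)
    order = _topological_children_first(graph)
    acc: dict[str, set[str]] = {t: set(direct[t]) for t in graph.terms}
    for term in order:
        for parent in graph.parents[term]:
            acc[parent] |= acc[term]
    return {t: frozenset(gs) for t, gs in acc.items()}


def _topological_children_first(graph: OntologyGraph) -> list[str]:
    dg = nx.DiGraph()
    dg.add_nodes_from(graph.terms)
    for term, ps in graph.parents.items():
        for p in ps:
            dg.add_edge(term, p)  # child -> parent
    return list(nx.topological_sort(dg))


def information_content(
    graph: OntologyGraph, annotations: AnnotationTable
) -> dict[str, float]:
    """Annotation-frequency information content per term.

    ``IC(t) = -ln(n_t / N)`` with annotations propagated to ancestors first.
    Terms covering no annotated gene get no IC and are absent from the
    returned mapping (they cannot take part in similarity).
    """
    if not annotations.pairs:
        raise ConfigurationError("annotation table is empty; cannot compute IC")
    gene_sets = annotated_gene_sets(graph, annotations)
    total = len(annotations.genes)
    return {
        t: -math.log(len(gs) / total) for t, gs in gene_sets.items() if gs
    }


def resnik_similarity(
    graph: OntologyGraph, ic_map: Mapping[str, float], t1: str, t2: str
) -> float:
    """Resnik similarity: highest IC over the common ancestors of two terms.

    Ancestor sets are reflexive, so ``resnik(t, t) == IC(t)``.  Term pairs
    with no common ancestor (possible in a multi-rooted ontology) get 0.
    """
    for t in (t1, t2):
        if t not in ic_map:
            raise KeyError(f"term {t!r} has no information content (no annotated gene)")
    common = graph.ancestors(t1) & graph.ancestors(t2)
    ics = [ic_map[a] for a in common if a in ic_map]
    return max(ics, default=0.0)


def build_phenome_network(
    graph: OntologyGraph,
    ic_map: Mapping[str, float],
    threshold: float = 3.0,
    annotations: AnnotationTable | None = None,
) -> nx.Graph:
    """All-pairs Resnik similarity, thresholded, as an undirected weighted graph.

    Every unordered pair of IC-bearing terms with similarity >= ``threshold``
    becomes an edge with the similarity as its ``weight``.  Terms with no
    retained edge are kept as isolated nodes only if they carry a gene
    annotation (they can still anchor a bipartite link); otherwise they are
    dropped.
    """
    if threshold < 0:
        raise ConfigurationError(f"similarity threshold must be >= 0, got {threshold}")
    net = nx.Graph()
    # sim(t1, t2) <= min(IC(t1), IC(t2)) because IC never increases towards
    # the root, so terms below the threshold themselves can be skipped.
    candidates = sorted(t for t, ic in ic_map.items() if ic >= threshold)
    anc = {t: graph.ancestors(t) for t in candidates}
    for i, t1 in enumerate(candidates):
        for t2 in candidates[i + 1:]:
            common = anc[t1] & anc[t2]
            if not common:
                continue
            sim = max((ic_map[a] for a in common if a in ic_map), default=0.0)
            if sim >= threshold:
                net.add_edge(t1, t2, weight=sim)
    if annotations is not None:
        for term in annotations.terms:
            if term in graph and term not in net:
                net.add_node(term)
    return net
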