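"""Synthetic fixtures: ontologies, annotations, PPI networks and expression
tables with a known planted disease module.

The generator emulates the *structure* of the real inputs -- a phenotype
ontology with gene annotations, a confidence-weighted interactome and a
differential-expression table -- at desk scale, so that every pipeline
stage can be exercised and the planted ground truth recovered.  A bundle
consists of:

* an ontology with one "disease branch" whose terms are annotated to the
  planted module genes only, so those terms are specific (high information
  content) and similar to each other but not to other branches;
* a connected small-world background interactome with the module wired in
  as a clique, edge confidences in [0.7, 1);
* expression scores where module genes carry a fixed strong fold change and
  small adjusted p-value while background genes carry centred noise.

Setting ``planted_module_size = 0`` produces a null bundle (i.i.d. scores,
no planted structure) used to check the calibration of empirical p-values.
All draws are deterministic functions of ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .expression import ExpressedSet, ExpressionScores
from .ontology import AnnotationTable, OntologyGraph

__all__ = ["FixtureSpec", "FixtureBundle", "make_ontology", "make_ppi",
           "make_expression", "make_case"]

ROOT = "FP:0000000"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic test case.

    Defaults give a 200-gene, ~55-term case with an 8-gene planted module
    that runs the full pipeline in seconds.  ``annotation_density`` is the
    probability that a background gene is annotated at all.
    """

    n_genes: int = 200
    n_branches: int = 6            # 1 disease branch + (n_branches - 1) background
    leaves_per_subbranch: int = 3  # background branches; disease branch uses 2
    ppi_neighbours: int = 6        # small-world ring degree
    ppi_rewire: float = 0.1        # small-world rewiring probability
    planted_module_size: int = 8
    planted_log2fc: float = 2.0
    planted_adj_p: float = 1e-4
    background_log2fc_sd: float = 0.5
    seed_terms: int = 2
    annotation_density: float = 1.0
    expressed_fraction: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.planted_module_size <= self.n_genes:
            raise ConfigurationError("planted_module_size must be within n_genes")
        for name in ("annotation_density", "expressed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.annotation_density == 0.0:
            raise ConfigurationError("annotation_density must be > 0")
        if self.n_branches < 2:
            raise ConfigurationError("need at least one background branch")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(f"G{i:04d}" for i in range(self.n_genes))

    def module_genes(self) -> tuple[str, ...]:
        """The planted module gene identifiers (deterministic in rng_seed)."""
        if self.planted_module_size == 0:
            return ()
        rng = np.random.default_rng([self.rng_seed, 11])
        picked = rng.choice(
            self.n_genes, size=self.planted_module_size, replace=False
        )
        genes = self.genes
        return tuple(sorted(genes[i] for i in picked))


def make_ontology(spec: FixtureSpec) -> tuple[OntologyGraph, AnnotationTable]:
    """Ontology with a disease branch specific to the planted module.

    Branch 1 (terms ``FP:01...``) is the disease branch: a root with two
    sub-parents, each carrying two leaves, annotated exclusively to module
    genes.  Background branches carry ``leaves_per_subbranch`` leaves per
    sub-parent and soak up the background genes, keeping their terms'
    pairwise similarity low (their subsumers cover many genes).
    """
    rng = np.random.default_rng([spec.rng_seed, 23])
    parents: dict[str, set[str]] = {ROOT: set()}

    # disease branch: FP:0100 root, FP:01k0 sub-parents, FP:01k3 leaves
    d_root = "FP:0100000"
    parents[d_root] = {ROOT}
    disease_leaves: list[str] = []
    for k in range(2):
        sub = f"FP:01{k:02d}0"
        parents[sub] = {d_root}
        for j in range(2):
            leaf = f"FP:01{k:02d}{j + 1}"
            parents[leaf] = {sub}
            disease_leaves.append(leaf)

    background_leaves: list[str] = []
    for b in range(2, spec.n_branches + 1):
        b_root = f"FP:{b:02d}00000"
        parents[b_root] = {ROOT}
        for k in range(2):
            sub = f"FP:{b:02d}{k:02d}0"
            parents[sub] = {b_root}
            for j in range(spec.leaves_per_subbranch):
                leaf = f"FP:{b:02d}{k:02d}{j + 1}"
                parents[leaf] = {sub}
                background_leaves.append(leaf)

    graph = OntologyGraph.from_parents(parents)

    module = set(spec.module_genes())
    background = [g for g in spec.genes if g not in module]
    pairs: set[tuple[str, str]] = set()
    if module:
        # two module genes per disease leaf, cycling if the module is larger
        ordered = sorted(module)
        for i, gene in enumerate(ordered):
            pairs.add((gene, disease_leaves[(i // 2) % len(disease_leaves)]))
    else:
        # null bundle: disease leaves get a couple of background genes each
        picks = rng.choice(len(background), size=2 * len(disease_leaves), replace=False)
        for i, leaf in enumerate(disease_leaves):
            for j in picks[2 * i: 2 * i + 2]:
                pairs.add((background[j], leaf))
    for gene in background:
        if rng.random() >= spec.annotation_density:
            continue
        n_annot = 1 + int(rng.random() < 0.3)  # some genes get two annotations
        for idx in rng.choice(len(background_leaves), size=n_annot, replace=False):
            pairs.add((gene, background_leaves[idx]))
    annotations = AnnotationTable(frozenset(pairs))
    if not annotations.pairs:
        raise ConfigurationError("fixture produced an empty annotation table")
    return graph, annotations


def make_ppi(spec: FixtureSpec) -> nx.Graph:
    """Connected small-world background with the module wired as a clique.

    Edge confidences are drawn uniformly in [0.7, 1), so the fixture passes
    a 0.7 confidence filter unchanged and its giant component is the whole
    graph.
    """
    rng = np.random.default_rng([spec.rng_seed, 37])
    background = nx.connected_watts_strogatz_graph(
        spec.n_genes, spec.ppi_neighbours, spec.ppi_rewire,
        seed=int(rng.integers(2**31)),
    )
    genes = spec.genes
    net = nx.Graph()
    net.add_nodes_from(genes)
    for u, v in background.edges:
        net.add_edge(genes[u], genes[v], confidence=float(rng.uniform(0.7, 1.0)))
    for i, a in enumerate(spec.module_genes()):
        for b in spec.module_genes()[i + 1:]:
            net.add_edge(a, b, confidence=float(rng.uniform(0.7, 1.0)))
    return net


def make_expression(spec: FixtureSpec) -> tuple[ExpressionScores, ExpressedSet]:
    """Planted module genes get the fixed strong (log2fc, adj_p); background
    genes get centred Gaussian fold changes and uniform adjusted p-values."""
    rng = np.random.default_rng([spec.rng_seed, 53])
    module = set(spec.module_genes())
    rows = []
    for gene in spec.genes:
        if gene in module:
            rows.append((gene, spec.planted_log2fc, spec.planted_adj_p))
        else:
            fc = float(rng.normal(0.0, spec.background_log2fc_sd))
            adj_p = float(rng.uniform(1e-6, 1.0))
            rows.append((gene, fc, adj_p))
    scores = ExpressionScores.from_table(
        pd.DataFrame(rows, columns=["gene", "log2fc", "adj_p"])
    )
    expressed = set(spec.genes)
    if spec.expressed_fraction < 1.0:
        background = [g for g in spec.genes if g not in module]
        n_drop = int(round((1.0 - spec.expressed_fraction) * len(background)))
        for idx in rng.choice(len(background), size=n_drop, replace=False):
            expressed.discard(background[idx])
    return scores, ExpressedSet(
        genes=frozenset(expressed),
        rule=f"fixture: expressed_fraction={spec.expressed_fraction}",
    )


@dataclass(frozen=True)
class FixtureBundle:
    """A complete synthetic input set plus its ground truth."""

    spec: FixtureSpec
    ontology: OntologyGraph
    annotations: AnnotationTable
    ppi: nx.Graph
    scores: ExpressionScores
    expressed: ExpressedSet
    seeds: tuple[str, ...]
    module_genes: tuple[str, ...]

    def write(self, directory) -> dict[str, str]:
        """Write the bundle in the file formats the CLI reads; returns the
        mapping of logical input name to path."""
        from . import io as pio
        import os

        os.makedirs(directory, exist_ok=True)
        paths = {
            "obo": os.path.join(directory, "ontology.obo"),
            "annotations": os.path.join(directory, "annotations.tsv"),
            "ppi": os.path.join(directory, "ppi.tsv"),
            "de_table": os.path.join(directory, "de_table.tsv"),
            "expressed": os.path.join(directory, "expressed.txt"),
            "seeds": os.path.join(directory, "seeds.txt"),
            "truth": os.path.join(directory, "module_genes.txt"),
        }
        pio.write_obo(self.ontology, paths["obo"])
        pio.write_annotations(self.annotations, paths["annotations"])
        pio.write_ppi(self.ppi, paths["ppi"])
        pio.write_de_table(self.scores, paths["de_table"])
        pio.write_gene_list(sorted(self.expressed.genes), paths["expressed"])
        pio.write_gene_list(self.seeds, paths["seeds"])
        pio.write_gene_list(self.module_genes, paths["truth"])
        return paths


def make_case(spec: FixtureSpec = FixtureSpec()) -> FixtureBundle:
    """Full input bundle: ontology + annotations + PPI + expression + seeds.

    Module genes are annotated to the disease branch, so expression and
    phenotype evidence point at the same planted module.  Seed phenotypes
    are disease-branch leaves, one per sub-parent first.
    """
    ontology, annotations = make_ontology(spec)
    ppi = make_ppi(spec)
    scores, expressed = make_expression(spec)
    leaves = ["FP:01001", "FP:01011", "FP:01002", "FP:01012"]
    if not 1 <= spec.seed_terms <= len(leaves):
        raise ConfigurationError(
            f"seed_terms must be in [1, {len(leaves)}], got {spec.seed_terms}"
        )
    return FixtureBundle(
        spec=spec, ontology=ontology, annotations=annotations, ppi=ppi,
        scores=scores, expressed=expressed,
        seeds=tuple(leaves[: spec.seed_terms]),
        module_genes=spec.module_genes(),
    )
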