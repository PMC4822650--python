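"""The `PhenomeWalk` model and its results object.

`PhenomeWalk` bundles the inputs of a phenotype-guided sub-network analysis
-- a weighted PPI network, a phenotype ontology with gene annotations, a
differential-expression table and a set of seed phenotype terms -- together
with the tunable parameters, and `fit()` runs the two-stage procedure:

1. *Scoring*: assemble the heterogeneous phenome-interactome network and
   score every protein by random walk with restart over the whole
   (alpha, eta, lambda) parameter grid, yielding one ranked list per
   combination (196 with the default grid).
2. *Extraction*: run seeded (GIGA-style) expansion on each ranked list,
   intersect the per-run results into complete-co-occurrence consensus
   sub-networks, assign empirical p-values by random connected sub-network
   sampling and filter at a Benjamini-Hochberg FDR level.

The returned :class:`PhenomeWalkResults` carries the ranked lists, all
consensus sub-networks with their empirical p-values, the FDR-passing
subset, bookkeeping counts, and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from . import interactome as pin
from . import io as pio
from . import ontology as ponto
from . import subnetworks as psub
from .exceptions import ConfigurationError
from .expression import ExpressedSet, ExpressionScores, load_de_table
from .heterogeneous import (
    HeterogeneousNetwork,
    RankedList,
    SweepParameters,
    assemble_network,
    parameter_sweep,
)
from .subnetworks import ConsensusSubnetwork, SamplingConfig, SubNetwork

logger = logging.getLogger(__name__)

__all__ = ["PhenomeWalk", "PhenomeWalkResults"]


class PhenomeWalk:
    """Phenotype-guided active sub-network model.

    Parameters
    ----------
    ppi
        Weighted PPI network (``confidence`` edge attribute in (0, 1]).
    ontology, annotations
        Phenotype term DAG and direct gene-to-term annotation pairs.
    scores
        Differential-expression scores (log2fc, adj_p, pi per gene).
    seeds
        Seed phenotype term identifiers carrying the phenome restart mass.
    expressed
        Optional expressed-gene set; when given, the PPI network is
        restricted to it (context-specific network) before analysis.
    orthologs
        Optional gene -> ortholog mapping applied to the annotation pairs
        before they connect the two layers (e.g. human annotations onto a
        mouse interactome).
    similarity_threshold
        Minimum Resnik similarity (natural-log scale) for a phenome edge.
    min_confidence
        Interactions with confidence strictly below this are discarded.
    max_size
        Maximum size of an initially extracted sub-network.
    min_consensus_size
        Consensus components smaller than this are discarded.
    grid, sampling
        Parameter sweep grid and empirical-p sampling / FDR configuration.
    use_confidence_weights
        If False, PPI edges are treated as unweighted in the walk.
    """

    def __init__(
        self,
        ppi: nx.Graph,
        ontology: ponto.OntologyGraph,
        annotations: ponto.AnnotationTable,
        scores: ExpressionScores,
        seeds: Iterable[str],
        expressed: ExpressedSet | None = None,
        orthologs: Mapping[str, set[str]] | None = None,
        similarity_threshold: float = 3.0,
        min_confidence: float = 0.7,
        max_size: int = 15,
        min_consensus_size: int = 5,
        grid: SweepParameters = SweepParameters(),
        sampling: SamplingConfig = SamplingConfig(),
        use_confidence_weights: bool = True,
    ) -> None:
        self.ppi = ppi
        self.ontology = ontology
        self.annotations = annotations.restrict_to_ontology(ontology)
        self.scores = scores
        self.seeds = tuple(seeds)
        if not self.seeds:
            raise ConfigurationError("at least one seed phenotype is required")
        self.expressed = expressed
        self.orthologs = dict(orthologs) if orthologs else None
        self.similarity_threshold = similarity_threshold
        self.min_confidence = min_confidence
        self.max_size = max_size
        self.min_consensus_size = min_consensus_size
        self.grid = grid
        self.sampling = sampling
        self.use_confidence_weights = use_confidence_weights
        self._input_paths: dict[str, str] = {}

    @classmethod
    def from_files(
        cls,
        ppi_path,
        obo_path,
        annotation_path,
        de_table_path,
        seeds_path,
        expressed_path=None,
        ortholog_path=None,
        default_confidence: float | None = None,
        **kwargs,
    ) -> "PhenomeWalk":
        """Build the model from the flat-file formats the CLI consumes."""
        ppi = pin.load_ppi(ppi_path, default_confidence=default_confidence)
        ontology = ponto.load_ontology(obo_path)
        annotations = ponto.load_annotations(annotation_path)
        scores = load_de_table(de_table_path)
        seeds = pio.read_seed_file(seeds_path)
        expressed = None
        if expressed_path is not None:
            genes = frozenset(pio.read_seed_file(expressed_path))
            expressed = ExpressedSet(genes=genes, rule=f"file: {expressed_path}")
        orthologs = (
            pin.load_ortholog_map(ortholog_path) if ortholog_path else None
        )
        model = cls(
            ppi, ontology, annotations, scores, seeds,
            expressed=expressed, orthologs=orthologs, **kwargs,
        )
        model._input_paths = {
            "ppi": str(ppi_path), "obo": str(obo_path),
            "annotations": str(annotation_path), "de_table": str(de_table_path),
            "seeds": str(seeds_path),
        }
        if expressed_path:
            model._input_paths["expressed"] = str(expressed_path)
        if ortholog_path:
            model._input_paths["orthologs"] = str(ortholog_path)
        return model

    # -- pipeline stages -------------------------------------------------

    def build_phenome(self) -> tuple[dict[str, float], nx.Graph]:
        """Information content and the thresholded phenome network."""
        ic = ponto.information_content(self.ontology, self.annotations)
        phenome = ponto.build_phenome_network(
            self.ontology, ic, threshold=self.similarity_threshold,
            annotations=self._bipartite_annotations(),
        )
        return ic, phenome

    def _bipartite_annotations(self) -> ponto.AnnotationTable:
        if self.orthologs is not None:
            return pin.map_annotations(self.annotations, self.orthologs)
        return self.annotations

    def build_context_network(self) -> nx.Graph:
        """Confidence filter, expressed-gene restriction, giant component."""
        net = pin.filter_confidence(self.ppi, self.min_confidence)
        if self.expressed is not None:
            net = pin.context_filter(net, self.expressed)
        return pin.giant_component(net)

    def assemble(self) -> HeterogeneousNetwork:
        _, phenome = self.build_phenome()
        return assemble_network(
            self.build_context_network(), phenome, self._bipartite_annotations(),
            use_confidence_weights=self.use_confidence_weights,
        )

    def score(self) -> tuple[HeterogeneousNetwork, list[RankedList]]:
        """Stage one only: the full RWR parameter sweep."""
        net = self.assemble()
        missing = set(self.seeds) - set(net.terms)
        if missing:
            logger.warning("seed terms not in assembled network: %s", sorted(missing))
        ranked = parameter_sweep(net, self.scores, self.seeds, self.grid)
        return net, ranked

    def fit(self, rng_seed: int | None = None) -> "PhenomeWalkResults":
        """Run both stages and return the results object.

        ``rng_seed`` overrides ``sampling.rng_seed`` for the empirical
        p-value sampling; everything else is deterministic.
        """
        net, ranked = self.score()
        per_run = psub.extract_all(net.ppi, ranked, self.max_size)
        merged = psub.consensus(per_run, net.ppi, min_size=self.min_consensus_size)
        seed_used = self.sampling.rng_seed if rng_seed is None else rng_seed
        rng = np.random.default_rng(seed_used)
        with_p = []
        for sub in merged:
            p, r, n = psub.empirical_pvalue(
                sub.members, self.scores, net.ppi, self.sampling, rng=rng
            )
            with_p.append(
                ConsensusSubnetwork(members=sub.members, empirical_p=p, r=r, n=n)
            )
        passing = psub.fdr_filter(with_p, level=self.sampling.fdr_level)
        passing_members = {frozenset(s.members) for s in passing}
        annotated = [
            ConsensusSubnetwork(
                members=s.members, empirical_p=s.empirical_p, r=s.r, n=s.n,
                fdr_pass=frozenset(s.members) in passing_members,
            )
            for s in with_p
        ]
        provenance = self._provenance(net, ranked, annotated, seed_used)
        return PhenomeWalkResults(
            model=self, network=net, ranked_lists=ranked, per_run=per_run,
            consensus=annotated, significant=passing, provenance=provenance,
        )

    def _provenance(self, net, ranked, consensus_subs, rng_seed) -> dict:
        record = {
            "parameters": {
                "alpha_grid": list(self.grid.alpha_grid),
                "eta_grid": list(self.grid.eta_grid),
                "lambda_grid": list(self.grid.lambda_grid),
                "tolerance": self.grid.tolerance,
                "similarity_threshold": self.similarity_threshold,
                "min_confidence": self.min_confidence,
                "max_size": self.max_size,
                "min_consensus_size": self.min_consensus_size,
                "n_samples": self.sampling.n_samples,
                "fdr_level": self.sampling.fdr_level,
                "rng_seed": rng_seed,
                "use_confidence_weights": self.use_confidence_weights,
            },
            "seeds": list(self.seeds),
            "counts": {
                "input_ppi_nodes": self.ppi.number_of_nodes(),
                "input_ppi_edges": self.ppi.number_of_edges(),
                "network_genes": net.n_genes,
                "network_phenotypes": net.n_terms,
                "bipartite_links": len(net.bipartite),
                "runs": len(ranked),
                "consensus_subnetworks": len(consensus_subs),
                "significant_subnetworks": sum(
                    1 for s in consensus_subs if s.fdr_pass
                ),
            },
        }
        if self._input_paths:
            record["inputs"] = {
                name: {"path": path, "sha256": pio.file_sha256(path)}
                for name, path in self._input_paths.items()
            }
        return record


@dataclass(frozen=True)
class PhenomeWalkResults:
    """Fit output: ranked lists, consensus sub-networks and diagnostics."""

    model: PhenomeWalk = field(repr=False)
    network: HeterogeneousNetwork = field(repr=False)
    ranked_lists: list[RankedList] = field(repr=False)
    per_run: dict[int, list[SubNetwork]] = field(repr=False)
    consensus: list[ConsensusSubnetwork]
    significant: list[ConsensusSubnetwork]
    provenance: dict = field(repr=False)

    def summary(self) -> pd.DataFrame:
        """One row per consensus sub-network: size, empirical p, FDR flag."""
        rows = [
            {
                "network": i + 1,
                "n_nodes": sub.size,
                "empirical_p": sub.empirical_p,
                "exceedances": sub.r,
                "n_samples": sub.n,
                "fdr_pass": sub.fdr_pass,
            }
            for i, sub in enumerate(self.consensus)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "network", "n_nodes", "empirical_p", "exceedances",
                "n_samples", "fdr_pass",
            ],
        )

    @property
    def seed_annotated_genes(self) -> frozenset[str]:
        """Network genes directly annotated to a seed phenotype."""
        seeds = set(self.model.seeds)
        return frozenset(
            g for g, t in self.network.bipartite if t in seeds
        )

    def export(self, directory) -> dict[str, object]:
        """Write ranked lists, GraphML/SIF sub-networks, summary TSV and the
        provenance JSON into ``directory``; returns the paths written."""
        import os

        os.makedirs(directory, exist_ok=True)
        paths: dict[str, object] = {}
        ranked_path = os.path.join(directory, "ranked_lists.tsv")
        pio.write_ranked_lists(self.ranked_lists, ranked_path)
        paths["ranked_lists"] = ranked_path
        summary_path = os.path.join(directory, "summary.tsv")
        pio.write_summary(self.consensus, summary_path)
        paths["summary"] = summary_path
        ranks = self.ranked_lists[0].rank_of() if self.ranked_lists else None
        paths["graphml"] = pio.write_consensus_graphml(
            self.consensus, self.network.ppi,
            os.path.join(directory, "subnetwork_{i}.graphml"),
            scores=self.model.scores,
            seed_annotated=self.seed_annotated_genes,
            ranks=ranks,
        )
        sif_path = os.path.join(directory, "subnetworks.sif")
        pio.write_consensus_sif(self.consensus, self.network.ppi, sif_path)
        paths["sif"] = sif_path
        prov_path = os.path.join(directory, "provenance.json")
        pio.write_provenance(self.provenance, prov_path)
        paths["provenance"] = prov_path
        return paths
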