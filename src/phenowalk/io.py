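"""Readers and writers for the flat-file formats around the pipeline.

Inputs are plain TSV/OBO text (see the module functions); outputs are
ranked-list TSVs, consensus sub-networks as GraphML and SIF, a summary TSV
and a JSON provenance record.
"""

from __future__ import annotations

import hashlib
import json
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .expression import ExpressionScores
from .heterogeneous import RankedList
from .ontology import AnnotationTable, OntologyGraph
from .subnetworks import ConsensusSubnetwork

__all__ = [
    "read_seed_file",
    "write_obo",
    "write_annotations",
    "write_ppi",
    "write_de_table",
    "write_gene_list",
    "write_ranked_lists",
    "read_ranked_lists",
    "write_summary",
    "write_consensus_graphml",
    "write_consensus_sif",
    "write_provenance",
    "file_sha256",
]


def read_seed_file(path) -> tuple[str, ...]:
    """One phenotype term id per line; ``#`` comments and blanks ignored."""
    seeds = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                seeds.append(line)
    return tuple(seeds)


def write_obo(graph: OntologyGraph, path) -> None:
    """Minimal OBO 1.2 serialisation (id, name, is_a stanza lines)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for term in sorted(graph.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {term}\n")
            for parent in sorted(graph.parents[term]):
                fh.write(f"is_a: {parent}\n")
            fh.write("\n")


def write_annotations(annotations: AnnotationTable, path) -> None:
    with open(path, "w") as fh:
        for gene, term in sorted(annotations.pairs):
            fh.write(f"{gene}\t{term}\n")


def write_ppi(net: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{b}\t{net[a][b]['confidence']!r}\n")


def write_de_table(scores: ExpressionScores, path) -> None:
    frame = scores.frame.reset_index()
    frame.columns = ["gene", "log2fc", "adj_p", "pi"]
    frame[["gene", "log2fc", "adj_p"]].to_csv(path, sep="\t", index=False)


def write_gene_list(items: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for item in items:
            fh.write(f"{item}\n")


def write_ranked_lists(ranked_lists: Sequence[RankedList], path) -> None:
    """Long-format TSV: one row per (run, gene) with the parameter triple."""
    rows = []
    for run, rl in enumerate(ranked_lists):
        for rank, (gene, prob) in enumerate(zip(rl.genes, rl.probabilities), 1):
            rows.append((run, gene, rank, prob, rl.alpha, rl.eta, rl.lambda_))
    pd.DataFrame(
        rows, columns=["run", "gene", "rank", "probability", "alpha", "eta", "lambda"]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ranked_lists(path) -> list[RankedList]:
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str})
    out = []
    for _, grp in frame.groupby("run", sort=True):
        grp = grp.sort_values("rank")
        out.append(
            RankedList(
                genes=tuple(grp["gene"]),
                probabilities=tuple(grp["probability"]),
                alpha=float(grp["alpha"].iloc[0]),
                eta=float(grp["eta"].iloc[0]),
                lambda_=float(grp["lambda"].iloc[0]),
            )
        )
    return out


def write_summary(subnetworks: Sequence[ConsensusSubnetwork], path) -> None:
    """Summary TSV: network id, node count, empirical p, FDR status."""
    rows = [
        (i + 1, sub.size, sub.empirical_p, sub.r, sub.n, sub.fdr_pass)
        for i, sub in enumerate(subnetworks)
    ]
    pd.DataFrame(
        rows, columns=["network", "n_nodes", "empirical_p", "r", "n_samples", "fdr_pass"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _consensus_graph(
    sub: ConsensusSubnetwork,
    net: nx.Graph,
    scores: ExpressionScores | None = None,
    seed_annotated: frozenset[str] = frozenset(),
    ranks: Mapping[str, int] | None = None,
) -> nx.Graph:
    g = net.subgraph(sub.members).copy()
    for node in g.nodes:
        if scores is not None:
            g.nodes[node]["log2fc"] = float(
                scores.frame.at[node, "log2fc"]
            ) if node in scores.frame.index else 0.0
            g.nodes[node]["pi"] = scores.pi(node)
        if ranks is not None:
            g.nodes[node]["rank"] = int(ranks.get(node, 0))
        g.nodes[node]["seed_phenotype_associated"] = node in seed_annotated
    return g


def write_consensus_graphml(
    subnetworks: Sequence[ConsensusSubnetwork],
    net: nx.Graph,
    path_template: str,
    scores: ExpressionScores | None = None,
    seed_annotated: frozenset[str] = frozenset(),
    ranks: Mapping[str, int] | None = None,
) -> list[str]:
    """One GraphML file per consensus sub-network.

    ``path_template`` must contain ``{i}`` (1-based network number).  Node
    attributes carry log2fc, pi, rank and a seed-phenotype flag; edges keep
    their confidence.
    """
    paths = []
    for i, sub in enumerate(subnetworks, 1):
        g = _consensus_graph(sub, net, scores, seed_annotated, ranks)
        path = path_template.format(i=i)
        nx.write_graphml(g, path)
        paths.append(path)
    return paths


def write_consensus_sif(
    subnetworks: Sequence[ConsensusSubnetwork], net: nx.Graph, path
) -> None:
    """All consensus sub-networks in one SIF file (interaction type ``pp``)."""
    with open(path, "w") as fh:
        for sub in subnetworks:
            for a, b in sorted(
                tuple(sorted(e)) for e in net.subgraph(sub.members).edges
            ):
                fh.write(f"{a}\tpp\t{b}\n")


def file_sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_provenance(record: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
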