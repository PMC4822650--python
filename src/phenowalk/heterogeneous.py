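"""Heterogeneous network assembly and random walk with restart (RWR).

The two layers -- a context-specific PPI network and a phenome
(phenotype-similarity) network -- are joined by bipartite gene-phenotype
associations ``B`` and walked as one Markov chain.  The transition matrix

    M = [[M_G,  M_GP],
         [M_PG, M_P ]]

is row-stochastic with rows as source nodes.  ``lambda`` is the probability
of moving from the phenome layer to the PPI layer at a phenotype with gene
associations, and ``1 - lambda`` the probability of moving from the PPI
layer to the phenome at an associated gene; nodes without cross links keep
all their mass within their own layer.  Within a layer, movement follows
edge weights (interaction confidence or semantic similarity) normalised per
row.

Restart mass is split by ``eta``: genes share ``eta`` proportionally to
their pi-values and the selected seed phenotypes share ``1 - eta``
uniformly.  The walk iterates

    p_{s+1} = (1 - alpha) * M^T p_s + alpha * p0

until the L1 change drops below the tolerance; the steady state restricted
to gene nodes gives the ranked protein list for one (alpha, eta, lambda)
combination, and the whole parameter grid yields one ranked list per
combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .exceptions import ConfigurationError, ConvergenceError, StructuralError
from .expression import ExpressionScores
from .ontology import AnnotationTable

logger = logging.getLogger(__name__)

__all__ = [
    "HeterogeneousNetwork",
    "TransitionMatrix",
    "RestartVector",
    "SweepParameters",
    "RankedList",
    "assemble_network",
    "build_transition_matrix",
    "build_restart_vector",
    "random_walk",
    "rank_genes",
    "parameter_sweep",
]

#: row sums of M must match 1 to this absolute tolerance
ROW_SUM_TOL = 1e-12
#: steady-state probability mass must match 1 to this absolute tolerance
MASS_TOL = 1e-9


@dataclass(frozen=True)
class HeterogeneousNetwork:
    """PPI layer + phenome layer + bipartite associations, with a fixed
    node ordering (genes first, then phenotype terms, each lexicographic)
    so that runs are reproducible down to floating point."""

    ppi: nx.Graph
    phenome: nx.Graph
    bipartite: frozenset[tuple[str, str]]
    genes: tuple[str, ...]
    terms: tuple[str, ...]
    a_g: sp.csr_array = field(repr=False, compare=False)
    a_p: sp.csr_array = field(repr=False, compare=False)
    b: sp.csr_array = field(repr=False, compare=False)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.genes + self.terms

    def gene_index(self, gene: str) -> int:
        return self.genes.index(gene)


def assemble_network(
    ppi: nx.Graph,
    phenome: nx.Graph,
    annotations: AnnotationTable,
    use_confidence_weights: bool = True,
) -> HeterogeneousNetwork:
    """Join the layers, restricting to nodes that can carry the walk.

    The PPI network must be connected (apply :func:`~phenowalk.interactome.
    giant_component` first); if it is not, the giant component is taken here
    with a warning.  Bipartite pairs are restricted to genes present in the
    PPI layer and terms present in the phenome layer, and phenotype terms
    with neither a phenome edge nor a surviving association are dropped
    (they would be unreachable dead ends).
    """
    if ppi.number_of_nodes() == 0:
        raise ConfigurationError("PPI network is empty")
    if not nx.is_connected(ppi):
        from .interactome import giant_component

        logger.warning("PPI network not connected; using its giant component")
        ppi = giant_component(ppi)
    gene_set = {str(n) for n in ppi.nodes}
    term_universe = {str(n) for n in phenome.nodes}
    pairs = frozenset(
        (g, t) for g, t in annotations.pairs if g in gene_set and t in term_universe
    )
    linked_terms = {t for _, t in pairs}
    kept_terms = {
        t for t in term_universe if phenome.degree(t) > 0 or t in linked_terms
    }
    genes = tuple(sorted(gene_set))
    terms = tuple(sorted(kept_terms))
    phenome_sub = phenome.subgraph(kept_terms)
    a_g = sp.csr_array(
        nx.to_scipy_sparse_array(
            ppi, nodelist=genes,
            weight="confidence" if use_confidence_weights else None,
        ).astype(float)
    )
    if terms:
        a_p = sp.csr_array(
            nx.to_scipy_sparse_array(phenome_sub, nodelist=terms, weight="weight")
            .astype(float)
        )
    else:
        a_p = sp.csr_array((0, 0), dtype=float)
    gene_pos = {g: i for i, g in enumerate(genes)}
    term_pos = {t: j for j, t in enumerate(terms)}
    rows = [gene_pos[g] for g, t in pairs]
    cols = [term_pos[t] for g, t in pairs]
    b = sp.csr_array(
        sp.coo_array(
            (np.ones(len(rows)), (rows, cols)), shape=(len(genes), len(terms))
        )
    )
    logger.info(
        "assembled heterogeneous network: %d genes, %d phenotype terms, "
        "%d associations", len(genes), len(terms), len(pairs),
    )
    return HeterogeneousNetwork(
        ppi=ppi, phenome=phenome_sub, bipartite=pairs,
        genes=genes, terms=terms, a_g=a_g, a_p=a_p, b=b,
    )


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition matrix of the heterogeneous chain."""

    m: sp.csr_array = field(repr=False)
    mt: sp.csr_array = field(repr=False, compare=False)
    lambda_: float
    n_genes: int
    n_terms: int

    @property
    def m_g(self) -> sp.csr_array:
        return self.m[: self.n_genes, : self.n_genes]

    @property
    def m_p(self) -> sp.csr_array:
        return self.m[self.n_genes:, self.n_genes:]

    @property
    def m_gp(self) -> sp.csr_array:
        return self.m[: self.n_genes, self.n_genes:]

    @property
    def m_pg(self) -> sp.csr_array:
        return self.m[self.n_genes:, : self.n_genes]


def _scale_rows(mat: sp.sparray, factors: np.ndarray) -> sp.csr_array:
    return sp.csr_array(sp.diags_array(factors) @ mat)


def build_transition_matrix(
    net: HeterogeneousNetwork, lambda_: float
) -> TransitionMatrix:
    """Assemble M for a given cross-layer coupling ``lambda_`` in [0, 1].

    ``lambda_`` is the probability of crossing from the phenome layer to the
    PPI layer at a phenotype with gene associations; ``1 - lambda_`` is the
    probability of crossing from the PPI layer to the phenome at an
    associated gene.  Nodes without cross links keep all their mass within
    their own layer.
    """
    if not 0.0 <= lambda_ <= 1.0:
        raise ConfigurationError(f"lambda must be in [0, 1], got {lambda_}")
    a_g, a_p, b = net.a_g, net.a_p, net.b
    ag_rs = np.asarray(a_g.sum(axis=1)).ravel()
    ap_rs = np.asarray(a_p.sum(axis=1)).ravel()
    b_rs = np.asarray(b.sum(axis=1)).ravel()
    bt_rs = np.asarray(b.sum(axis=0)).ravel()
    if np.any(ag_rs == 0):
        raise StructuralError("gene with no PPI edge survived assembly")
    dangling = (ap_rs == 0) & (bt_rs == 0)
    if np.any(dangling):
        raise StructuralError(
            "phenotype node with no phenome edge and no association survived assembly"
        )
    gene_linked = b_rs > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        sg = np.where(gene_linked, lambda_, 1.0) / ag_rs
        sgp = np.where(gene_linked, (1.0 - lambda_) / np.where(b_rs > 0, b_rs, 1.0), 0.0)
        term_linked = bt_rs > 0
        has_phenome = ap_rs > 0
        sp_ = np.where(
            has_phenome,
            np.where(term_linked, 1.0 - lambda_, 1.0) / np.where(has_phenome, ap_rs, 1.0),
            0.0,
        )
        spg = np.where(
            term_linked,
            np.where(has_phenome, lambda_, 1.0) / np.where(term_linked, bt_rs, 1.0),
            0.0,
        )
    blocks = [
        [_scale_rows(a_g, sg), _scale_rows(b, sgp)],
        [_scale_rows(b.T, spg), _scale_rows(a_p, sp_)],
    ]
    if net.n_terms == 0:
        m = _scale_rows(a_g, 1.0 / ag_rs)
    else:
        m = sp.csr_array(sp.block_array(blocks, format="csr"))
    row_sums = np.asarray(m.sum(axis=1)).ravel()
    if not np.allclose(row_sums, 1.0, atol=ROW_SUM_TOL, rtol=0.0):
        worst = float(np.abs(row_sums - 1.0).max())
        raise StructuralError(
            f"transition matrix rows deviate from stochasticity by {worst:.2e}"
        )
    return TransitionMatrix(
        m=m, mt=sp.csr_array(m.T), lambda_=lambda_,
        n_genes=net.n_genes, n_terms=net.n_terms,
    )


@dataclass(frozen=True)
class RestartVector:
    """Restart (teleportation) distribution over all nodes."""

    p0: np.ndarray = field(repr=False)
    eta: float
    seeds: frozenset[str]


def build_restart_vector(
    scores: ExpressionScores,
    seeds: Iterable[str],
    eta: float,
    net: HeterogeneousNetwork,
) -> RestartVector:
    """Gene entries proportional to pi (total ``eta``); seed phenotype
    entries uniform (total ``1 - eta``); everything else zero."""
    if not 0.0 <= eta <= 1.0:
        raise ConfigurationError(f"eta must be in [0, 1], got {eta}")
    seeds = frozenset(seeds)
    if not seeds:
        raise ConfigurationError("at least one seed phenotype is required")
    present = seeds & set(net.terms)
    missing = seeds - present
    if not present:
        raise ConfigurationError(
            f"no seed phenotype is present in the network: missing {sorted(missing)}"
        )
    if missing:
        logger.warning("seed phenotypes absent from network: %s", sorted(missing))
    pi = scores.pi_vector(net.genes)
    total_pi = pi.sum()
    if total_pi <= 0:
        raise ConfigurationError("all pi-values are zero on the network genes")
    p0 = np.zeros(net.n_genes + net.n_terms)
    p0[: net.n_genes] = eta * pi / total_pi
    seed_mass = (1.0 - eta) / len(present)
    for term in present:
        p0[net.n_genes + net.terms.index(term)] = seed_mass
    return RestartVector(p0=p0, eta=eta, seeds=present)


def random_walk(
    matrix: TransitionMatrix,
    restart: RestartVector,
    alpha: float,
    tolerance: float = 1e-6,
    max_iter: int = 10000,
) -> np.ndarray:
    """Power-iterate ``p <- (1 - alpha) M^T p + alpha p0`` to the steady state.

    Iteration starts at ``p0`` and stops when the L1 change between
    successive vectors falls below ``tolerance``.  The returned vector sums
    to 1 within ``MASS_TOL``; failure to converge raises
    :class:`ConvergenceError` with the final residual.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    mt = matrix.mt
    p0 = restart.p0
    p = p0.copy()
    residual = np.inf
    for _ in range(max_iter):
        p_next = (1.0 - alpha) * (mt @ p) + alpha * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tolerance:
            mass = float(p.sum())
            if abs(mass - 1.0) > MASS_TOL:
                raise StructuralError(
                    f"steady-state mass {mass} deviates from 1 beyond {MASS_TOL}"
                )
            return p
    raise ConvergenceError(
        f"random walk did not converge in {max_iter} iterations "
        f"(final L1 residual {residual:.3e} >= {tolerance})"
    )


@dataclass(frozen=True)
class RankedList:
    """Gene ordering from one (alpha, eta, lambda) run; rank 1 is best."""

    genes: tuple[str, ...]
    probabilities: tuple[float, ...]
    alpha: float
    eta: float
    lambda_: float

    def rank_of(self) -> dict[str, int]:
        return {g: i + 1 for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)


def rank_genes(
    p_s: np.ndarray,
    net: HeterogeneousNetwork,
    alpha: float = float("nan"),
    eta: float = float("nan"),
    lambda_: float = float("nan"),
) -> RankedList:
    """Order gene nodes by descending steady-state probability.

    Exact ties are broken lexicographically by gene identifier so the
    ranking is a deterministic permutation of the gene set.
    """
    probs = p_s[: net.n_genes]
    order = sorted(range(net.n_genes), key=lambda i: (-probs[i], net.genes[i]))
    return RankedList(
        genes=tuple(net.genes[i] for i in order),
        probabilities=tuple(float(probs[i]) for i in order),
        alpha=alpha, eta=eta, lambda_=lambda_,
    )


def _grid(start: float, stop: float, step: float) -> tuple[float, ...]:
    n = int(round((stop - start) / step)) + 1
    return tuple(round(start + i * step, 10) for i in range(n))


@dataclass(frozen=True)
class SweepParameters:
    """The (alpha, eta, lambda) grid for the scoring stage.

    The default grid spans alpha 0.2-0.8 and eta 0.2-0.8 in steps of 0.1
    (seven values each) and lambda 0.5-0.8 in steps of 0.1 (four values),
    i.e. 7 x 7 x 4 = 196 combinations.  lambda is kept at or above 0.5 to
    promote movement between the two layers.
    """

    alpha_grid: tuple[float, ...] = _grid(0.2, 0.8, 0.1)
    eta_grid: tuple[float, ...] = _grid(0.2, 0.8, 0.1)
    lambda_grid: tuple[float, ...] = _grid(0.5, 0.8, 0.1)
    tolerance: float = 1e-6
    max_iter: int = 10000

    def __post_init__(self) -> None:
        for name, grid in (
            ("alpha", self.alpha_grid), ("eta", self.eta_grid),
            ("lambda", self.lambda_grid),
        ):
            if not grid:
                raise ConfigurationError(f"{name} grid is empty")
            if any(not 0.0 <= v <= 1.0 for v in grid):
                raise ConfigurationError(f"{name} grid values must be in [0, 1]")
        if any(not 0.0 < a < 1.0 for a in self.alpha_grid):
            raise ConfigurationError("alpha values must be strictly inside (0, 1)")

    @property
    def n_combinations(self) -> int:
        return len(self.alpha_grid) * len(self.eta_grid) * len(self.lambda_grid)


def parameter_sweep(
    net: HeterogeneousNetwork,
    scores: ExpressionScores,
    seeds: Iterable[str],
    grid: SweepParameters = SweepParameters(),
) -> list[RankedList]:
    """One ranked list per (alpha, eta, lambda) combination.

    The transition matrix is rebuilt once per distinct lambda and reused
    across the alpha and eta loops; restart vectors are cached per eta.
    Results are ordered by (lambda, eta, alpha) iteration order.
    """
    seeds = frozenset(seeds)
    restarts = {
        eta: build_restart_vector(scores, seeds, eta, net) for eta in grid.eta_grid
    }
    results: list[RankedList] = []
    for lambda_ in grid.lambda_grid:
        matrix = build_transition_matrix(net, lambda_)
        for eta in grid.eta_grid:
            restart = restarts[eta]
            for alpha in grid.alpha_grid:
                try:
                    p_s = random_walk(
                        matrix, restart, alpha,
                        tolerance=grid.tolerance, max_iter=grid.max_iter,
                    )
                except ConvergenceError as exc:
                    raise ConvergenceError(
                        f"(alpha={alpha}, eta={eta}, lambda={lambda_}): {exc}"
                    ) from exc
                results.append(rank_genes(p_s, net, alpha, eta, lambda_))
    return results
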