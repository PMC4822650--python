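import itertools
import math

import networkx as nx
import pytest

from phenowalk.exceptions import ConfigurationError
from phenowalk.expression import ExpressionScores
from phenowalk.subnetworks import (
    ConsensusSubnetwork,
    SamplingConfig,
    consensus,
    empirical_pvalue,
    fdr_filter,
    find_local_minima,
    giga_expand,
    giga_significance,
    sample_random_subnetwork,
)


def _scores(pi_by_gene):
    import pandas as pd

    rows = [(g, pi, 0.1) for g, pi in pi_by_gene.items()]
    return ExpressionScores.from_table(
        pd.DataFrame(rows, columns=["gene", "log2fc", "adj_p"])
    )


def exhaustive_min_p(net, rank, seed, max_size):
    """Oracle: smallest achievable significance over all connected subgraphs
    containing ``seed`` of size <= max_size, by brute-force enumeration."""
    total = len(rank)
    best = math.inf
    nodes = sorted(net.nodes)
    for size in range(1, max_size + 1):
        for comb in itertools.combinations(nodes, size):
            if seed not in comb:
                continue
            if not nx.is_connected(net.subgraph(comb)):
                continue
            p = giga_significance(size, max(rank[v] for v in comb), total)
            best = min(best, p)
    return best


class TestGigaSignificance:
    @pytest.mark.parametrize(
        "n, r_max, total, expected",
        [
            (1, 1, 100, 0.01),
            (10, 10, 10, 1.0),
            (4, 4, 8, 1 / 70),  # C(4,4)/C(8,4)
        ],
    )
    def test_closed_forms(self, n, r_max, total, expected):
        assert giga_significance(n, r_max, total) == pytest.approx(expected)

    def test_equals_binomial_ratio(self):
        for n, r_max, total in [(3, 5, 20), (2, 9, 30), (5, 12, 40)]:
            assert giga_significance(n, r_max, total) == pytest.approx(
                math.comb(r_max, n) / math.comb(total, n)
            )

    def test_matches_monte_carlo(self, rng):
        """Frequency of 'all 3 drawn ranks <= 5' over 10^6 draws from 20."""
        n, r_max, total, draws = 3, 5, 20, 10**6
        hits = 0
        chunk = 200_000
        for _ in range(draws // chunk):
            perms = rng.random((chunk, total)).argsort(axis=1)[:, :n] + 1
            hits += int((perms.max(axis=1) <= r_max).sum())
        p_hat = hits / draws
        p = giga_significance(n, r_max, total)
        se = math.sqrt(p * (1 - p) / draws)
        assert abs(p_hat - p) < 3 * se

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            giga_significance(0, 1, 10)
        with pytest.raises(ValueError):
            giga_significance(3, 2, 10)
        with pytest.raises(ValueError):
            giga_significance(3, 11, 10)


class TestLocalMinima:
    def test_path_has_single_valley(self):
        net = nx.path_graph(["g1", "g2", "g3"])
        assert find_local_minima(net, {"g1": 1, "g2": 2, "g3": 3}) == {"g1"}

    def test_two_valleys(self):
        net = nx.path_graph(["a", "b", "c", "d", "e"])
        rank = {"a": 1, "b": 4, "c": 5, "d": 3, "e": 2}
        assert find_local_minima(net, rank) == {"a", "e"}

    def test_star_centre(self):
        net = nx.star_graph(["hub", "s1", "s2", "s3"])
        rank = {"hub": 1, "s1": 2, "s2": 3, "s3": 4}
        assert find_local_minima(net, rank) == {"hub"}

    def test_global_best_is_always_a_minimum(self, rng):
        for _ in range(10):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(2**31)))
            rank = {n: r + 1 for r, n in enumerate(rng.permutation(list(g.nodes)))}
            minima = find_local_minima(g, rank)
            assert minima  # at least the globally best-ranked node
            best = min(g.nodes, key=rank.get)
            assert best in minima


class TestGigaExpand:
    def test_isolated_seed_stays_singleton(self):
        net = nx.Graph()
        net.add_node("g1")
        net.add_edge("g2", "g3")
        sub = giga_expand(net, {"g1": 1, "g2": 2, "g3": 3}, "g1", max_size=4)
        assert sub.members == {"g1"}

    def test_worsening_neighbourhood_stays_singleton(self):
        # star: centre rank 1, many badly-ranked satellites -> adding any
        # satellite multiplies p by (r_max - 1)/(N - 1) >> keeps p larger
        net = nx.star_graph(["hub", "s1", "s2", "s3"])
        rank = {"hub": 1, "s1": 8, "s2": 9, "s3": 10}
        rank.update({f"x{i}": i + 2 for i in range(6)})  # pad universe to N=10
        sub = giga_expand(net, rank, "hub", max_size=4)
        assert sub.members == {"hub"}
        assert sub.score_p == pytest.approx(1 / 10)

    def test_planted_clique_recovered_exactly(self):
        """An 8-node graph with a top-ranked 4-clique yields that clique,
        p = C(4,4)/C(8,4) = 1/70."""
        net = nx.Graph()
        clique = ["c1", "c2", "c3", "c4"]
        for a, b in itertools.combinations(clique, 2):
            net.add_edge(a, b)
        net.add_edge("c4", "b1")
        for a, b in [("b1", "b2"), ("b2", "b3"), ("b3", "b4"), ("b4", "b1")]:
            net.add_edge(a, b)
        rank = {"c1": 1, "c2": 2, "c3": 3, "c4": 4,
                "b1": 5, "b2": 6, "b3": 7, "b4": 8}
        sub = giga_expand(net, rank, "c1", max_size=4)
        assert sub.members == set(clique)
        assert sub.score_p == pytest.approx(1 / 70)

    def test_max_size_cap(self):
        net = nx.path_graph(["g1", "g2", "g3", "g4"])
        rank = {"g1": 1, "g2": 2, "g3": 3, "g4": 4}
        sub = giga_expand(net, rank, "g1", max_size=2)
        assert len(sub.members) <= 2

    def test_invalid_max_size(self):
        net = nx.path_graph(["g1", "g2"])
        with pytest.raises(ConfigurationError):
            giga_expand(net, {"g1": 1, "g2": 2}, "g1", max_size=0)

    def test_matches_exhaustive_search(self, rng):
        """Greedy expansion attains the exhaustive minimal significance on
        random graphs <= 10 nodes with max_size <= 4."""
        checked = 0
        for _ in range(25):
            n = int(rng.integers(5, 11))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(2**31)))
            net = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            for _ in range(5):
                perm = rng.permutation(sorted(net.nodes))
                rank = {node: r + 1 for r, node in enumerate(perm)}
                max_size = int(rng.integers(2, 5))
                for seed in sorted(find_local_minima(net, rank)):
                    greedy = giga_expand(net, rank, seed, max_size)
                    oracle = exhaustive_min_p(net, rank, seed, max_size)
                    assert greedy.score_p == pytest.approx(oracle, rel=1e-12)
                    checked += 1
        assert checked >= 100


class TestConsensus:
    def _run(self, members_lists):
        return [
            type("S", (), {"members": frozenset(m)})() for m in members_lists
        ]

    def test_complete_co_occurrence_required(self):
        net = nx.path_graph([f"g{i}" for i in range(8)])
        member_set = {f"g{i}" for i in range(6)}
        per_run = {0: self._run([member_set]), 1: self._run([member_set - {"g5"}])}
        out = consensus(per_run, net, min_size=5)
        assert out[0].members == member_set - {"g5"}

    def test_identical_runs_give_components_of_union(self):
        net = nx.Graph()
        nx.add_path(net, ["a", "b", "c", "d", "e"])
        nx.add_path(net, ["x", "y", "z", "w", "v"])
        subs = self._run([{"a", "b", "c", "d", "e"}, {"x", "y", "z", "w", "v"}])
        out = consensus({0: subs, 1: subs}, net, min_size=5)
        assert {frozenset(s.members) for s in out} == {
            frozenset("abcde"), frozenset({"x", "y", "z", "w", "v"})
        }

    def test_small_components_discarded(self):
        net = nx.Graph()
        nx.add_path(net, ["a", "b", "c", "d", "e", "f"])
        nx.add_path(net, ["x", "y", "z"])
        subs = self._run([{"a", "b", "c", "d", "e", "f"}, {"x", "y", "z"}])
        out = consensus({0: subs}, net, min_size=5)
        assert len(out) == 1
        assert out[0].members == frozenset("abcdef")

    def test_empty_intersection_gives_empty_list(self):
        net = nx.path_graph(["a", "b", "c"])
        per_run = {0: self._run([{"a"}]), 1: self._run([{"b"}])}
        assert consensus(per_run, net) == []


class TestSampling:
    def test_size_one_is_uniform(self, rng):
        """Chi-square uniformity over 10^4 single-node draws, 10-node net."""
        from scipy.stats import chisquare

        net = nx.cycle_graph([f"n{i}" for i in range(10)])
        counts = {n: 0 for n in net.nodes}
        for _ in range(10_000):
            (node,) = sample_random_subnetwork(net, 1, rng)
            counts[node] += 1
        stat, p = chisquare(list(counts.values()))
        assert p > 0.001

    def test_full_size_returns_everything(self, rng):
        net = nx.cycle_graph([f"n{i}" for i in range(6)])
        assert sample_random_subnetwork(net, 6, rng) == set(net.nodes)

    def test_samples_are_connected(self, bundle, rng):
        for _ in range(50):
            members = sample_random_subnetwork(bundle.ppi, 8, rng)
            assert len(members) == 8
            assert nx.is_connected(bundle.ppi.subgraph(members))

    def test_oversized_request_rejected(self, rng):
        net = nx.path_graph(["a", "b"])
        with pytest.raises(ValueError):
            sample_random_subnetwork(net, 3, rng)


class TestEmpiricalP:
    def test_unbeatable_subnetwork_gets_1e4(self, bundle):
        """A sub-network whose summed pi exceeds every one of 10000 random
        samples receives exactly p = 1.0e-4 (r = 0)."""
        p, r, n = empirical_pvalue(
            set(bundle.module_genes), bundle.scores, bundle.ppi,
            SamplingConfig(n_samples=10000, rng_seed=5),
        )
        assert r == 0
        assert n == 10000
        assert p == pytest.approx(1.0e-4)

    def test_never_exceeded_by_clamp(self, null_bundle, rng):
        members = sample_random_subnetwork(null_bundle.ppi, 6, rng)
        p, r, n = empirical_pvalue(
            members, null_bundle.scores, null_bundle.ppi,
            SamplingConfig(n_samples=200, rng_seed=3),
        )
        assert p <= 1.0
        assert p == min((r + 1) / n, 1.0)

    def test_constant_pi_gives_p_one(self):
        net = nx.cycle_graph([f"G{i}" for i in range(12)])
        scores = _scores({f"G{i}": 1.0 for i in range(12)})
        p, r, n = empirical_pvalue(
            {"G0", "G1", "G2"}, scores, net, SamplingConfig(n_samples=500, rng_seed=2)
        )
        assert p == 1.0
        assert r == n


def _bh_oracle(pvals, level):
    """Independent Benjamini-Hochberg: reject the first k ordered p-values
    where k is the largest index with p_(k) <= k/m * level."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    k_max = 0
    for k, idx in enumerate(order, start=1):
        if pvals[idx] <= k / m * level:
            k_max = k
    reject = [False] * m
    for idx in order[:k_max]:
        reject[idx] = True
    return reject


class TestFdrFilter:
    def _subs(self, pvals):
        return [
            ConsensusSubnetwork(members=frozenset({f"a{i}", f"b{i}"}), empirical_p=p)
            for i, p in enumerate(pvals)
        ]

    def test_single_small_p_passes(self):
        out = fdr_filter(self._subs([0.01]), level=0.05)
        assert len(out) == 1 and out[0].fdr_pass

    def test_mixed_pvalues(self):
        out = fdr_filter(self._subs([0.001, 0.9]), level=0.05)
        assert [s.empirical_p for s in out] == [0.001]

    def test_matches_independent_bh_oracle(self, rng):
        for _ in range(20):
            pvals = list(rng.uniform(0, 1, size=int(rng.integers(1, 15))))
            out = fdr_filter(self._subs(pvals), level=0.05)
            expected = _bh_oracle(pvals, 0.05)
            passing = {tuple(sorted(s.members)) for s in out}
            for i, rej in enumerate(expected):
                key = tuple(sorted({f"a{i}", f"b{i}"}))
                assert (key in passing) == rej

    def test_requires_assigned_p(self):
        with pytest.raises(ConfigurationError):
            fdr_filter([ConsensusSubnetwork(members=frozenset({"a"}))])
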