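"""Module detection, parcellation and consensus stability."""

import itertools

import networkx as nx
import numpy as np
import pytest

from annaceti.modularity import (
    ModulePartition,
    consensus_modules,
    detect_modules,
    merge_pairs,
    parcellation,
    parcellation_from_sizes,
)
from annaceti.synthetic_data import SkullGenConfig, fixture_table1, generate_skull_network

from conftest import net_from_edges, oracle_parcellation


def _planted_net(n_comms=4, size=8, p_in=0.9, p_out=0.05, seed=7):
    rng = np.random.default_rng(seed)
    names = [f"c{c}_n{i}" for c in range(n_comms) for i in range(size)]
    comm = {n: int(n[1]) for n in names}
    while True:
        edges = []
        for a, b in itertools.combinations(names, 2):
            p = p_in if comm[a] == comm[b] else p_out
            if rng.random() < p:
                edges.append((a, b))
        g = nx.Graph(edges)
        if len(g) == len(names) and nx.is_connected(g):
            return net_from_edges(edges, "planted"), comm


class TestDetectModules:
    def test_two_cliques(self):
        edges = [(f"a{i}", f"a{j}") for i in range(5) for j in range(i + 1, 5)]
        edges += [(f"b{i}", f"b{j}") for i in range(5) for j in range(i + 1, 5)]
        edges += [("a0", "b0")]
        part = detect_modules(net_from_edges(edges), n_restarts=10, seed=1)
        assert part.fingerprint() == (
            tuple(f"a{i}" for i in range(5)), tuple(f"b{i}" for i in range(5)))

    def test_complete_graph_single_block(self):
        edges = [(f"n{i}", f"n{j}") for i in range(6) for j in range(i + 1, 6)]
        part = detect_modules(net_from_edges(edges), n_restarts=10, seed=1)
        assert part.n_blocks == 1

    def test_planted_four_communities_recovered(self):
        net, comm = _planted_net(seed=7)
        part = detect_modules(net, n_restarts=20, seed=7)
        assert part.n_blocks == 4
        planted = {frozenset(n for n in net.bones if comm[n] == c) for c in range(4)}
        assert set(part.blocks) == planted

    def test_seeded_reproducibility(self):
        net = generate_skull_network(SkullGenConfig(seed=5, target_links=95))
        p1 = detect_modules(net, n_restarts=25, seed=42)
        p2 = detect_modules(net, n_restarts=25, seed=42)
        assert p1.fingerprint() == p2.fingerprint() and p1.Q == p2.Q

    def test_restarts_validated(self, triangle):
        with pytest.raises(ValueError):
            detect_modules(triangle, n_restarts=0, seed=1)

    def test_q_within_bounds(self):
        net = generate_skull_network(SkullGenConfig(seed=9, target_links=85))
        part = detect_modules(net, n_restarts=10, seed=3)
        assert -0.5 <= part.Q <= 1.0


class TestParcellation:
    def test_single_block_zero(self):
        part = ModulePartition("t", [frozenset("abc")], Q=0.0, method_seed=0,
                               n_restarts=1)
        assert parcellation(part) == 0.0

    def test_two_equal_blocks(self):
        assert parcellation_from_sizes([5, 5]) == pytest.approx(0.5)

    def test_all_singletons(self):
        assert parcellation_from_sizes([1] * 20) == pytest.approx(0.95)

    def test_oracle_agreement_random_partitions(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            sizes = list(rng.integers(1, 12, size=int(rng.integers(1, 7))))
            assert parcellation_from_sizes(sizes) == pytest.approx(
                oracle_parcellation(sizes))

    def test_merging_blocks_never_increases_P(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            sizes = list(rng.integers(1, 10, size=int(rng.integers(2, 7))))
            before = parcellation_from_sizes(sizes)
            i, j = rng.choice(len(sizes), size=2, replace=False)
            merged = [s for k, s in enumerate(sizes) if k not in (i, j)]
            merged.append(sizes[i] + sizes[j])
            assert parcellation_from_sizes(merged) < before

    def test_published_P_range_attainable_with_few_blocks(self):
        """Every published P value (0.666-0.797, N 34-35) is attainable by
        some 3-5-block partition at that node count, to within 0.005."""
        tab = fixture_table1()
        for _, row in tab.iterrows():
            n = int(row.N)
            attained = []
            for k in (3, 4, 5):
                for sizes in _compositions(n, k):
                    attained.append(parcellation_from_sizes(list(sizes)))
            assert min(abs(a - row.P) for a in attained) <= 0.005, row.taxon

    def test_merge_pairs_unites_mirror_blocks(self):
        net = generate_skull_network(SkullGenConfig(seed=2, target_links=90))
        left = frozenset(n for n, b in net.bones.items() if b.laterality == "left")
        right = frozenset(n for n, b in net.bones.items() if b.laterality == "right")
        mid = frozenset(n for n, b in net.bones.items() if b.laterality == "midline")
        part = ModulePartition(net.taxon, [left, right, mid], Q=0.0,
                               method_seed=0, n_restarts=1)
        merged = merge_pairs(part, net)
        assert merged.n_blocks == 2
        assert left | right in merged.blocks


class TestParcellationProperties:
    """Hypothesis property tests for the parcellation index."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    sizes_st = st.lists(st.integers(min_value=1, max_value=25),
                        min_size=2, max_size=9)

    @given(sizes=sizes_st)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_formula_matches_oracle(self, sizes):
        assert parcellation_from_sizes(sizes) == pytest.approx(
            oracle_parcellation(sizes))

    @given(sizes=sizes_st, data=st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounds_and_merge_monotonicity(self, sizes, data):
        p = parcellation_from_sizes(sizes)
        n = sum(sizes)
        assert 0.0 <= p <= 1.0 - 1.0 / n + 1e-12
        i = data.draw(self.st.integers(0, len(sizes) - 1))
        j = data.draw(self.st.integers(0, len(sizes) - 1).filter(lambda x: x != i))
        merged = [s for k, s in enumerate(sizes) if k not in (i, j)]
        merged.append(sizes[i] + sizes[j])
        assert parcellation_from_sizes(merged) < p


def _compositions(total, k):
    """Non-increasing k-part integer compositions of total."""
    if k == 1:
        yield (total,)
        return
    for first in range((total + k - 1) // k, total - k + 2):
        for rest in _compositions(total - first, k - 1):
            if rest[0] <= first:
                yield (first,) + rest


class TestConsensus:
    def test_planted_structure_fully_stable(self):
        net, _ = _planted_net(seed=7)
        cons = consensus_modules(net, n_runs=20, seed=7)
        assert all(s == pytest.approx(1.0) for s in cons.stability.values())

    def test_random_graph_less_stable_than_planted(self):
        rng = np.random.default_rng(3)
        from conftest import random_connected_edges

        edges = random_connected_edges(35, 0.15, rng)
        er = net_from_edges(edges, "er")
        cons_er = consensus_modules(er, n_runs=50, seed=3)
        net, _ = _planted_net(seed=7)
        cons_pl = consensus_modules(net, n_runs=50, seed=7)
        assert np.mean(list(cons_er.stability.values())) < \
            np.mean(list(cons_pl.stability.values()))

    def test_determinism(self):
        net = generate_skull_network(SkullGenConfig(seed=4, target_links=92))
        c1 = consensus_modules(net, n_runs=15, seed=9)
        c2 = consensus_modules(net, n_runs=15, seed=9)
        assert c1.fingerprint() == c2.fingerprint()
        assert c1.stability == c2.stability

    def test_run_count_validated(self, triangle):
        with pytest.raises(ValueError):
            consensus_modules(triangle, n_runs=1, seed=0)
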