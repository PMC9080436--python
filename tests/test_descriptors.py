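"""Whole-network descriptors against hand computations and brute-force oracles."""

import math

import numpy as np
import pytest

from annaceti.descriptors import (
    UndefinedDescriptorError,
    average_clustering,
    average_path_length,
    density,
    descriptor_table,
    heterogeneity,
    unpaired_bone_ratio,
)
from annaceti.modularity import detect_modules
from annaceti.network_model import AnatomicalNetwork, Bone
from annaceti.synthetic_data import SkullGenConfig, fixture_table1, generate_skull_network

from conftest import (
    all_connected_graphs,
    net_from_edges,
    oracle_average_path_length,
    oracle_local_clustering,
    random_connected_edges,
)


class TestDensity:
    @pytest.mark.parametrize("n,k,expected", [
        (35, 99, 0.166),   # Pakicetus
        (34, 103, 0.184),  # Physeter
        (35, 78, 0.131),   # Aetiocetus
        (35, 105, 0.176),  # Notocetus
    ])
    def test_published_rows_to_3dp(self, n, k, expected):
        d = 2 * k / (n * (n - 1))
        assert round(d, 3) == expected

    def test_complete_graph_density_one(self):
        net = net_from_edges([(f"n{i}", f"n{j}") for i in range(4)
                              for j in range(i + 1, 4)])
        assert density(net) == 1.0

    def test_density_recovers_k_exactly(self):
        net = generate_skull_network(SkullGenConfig(seed=3, target_links=88))
        n = net.n_bones
        assert round(density(net) * n * (n - 1) / 2) == net.n_links

    def test_undefined_below_two_nodes(self):
        net = net_from_edges([("a", "b")])
        del net.bones["b"]  # force N=1
        with pytest.raises(UndefinedDescriptorError):
            density(net)


class TestHeterogeneity:
    def test_regular_graph_zero(self):
        ring = net_from_edges([(f"n{i}", f"n{(i + 1) % 6}") for i in range(6)])
        assert heterogeneity(ring) == 0.0

    def test_star_sample_sd(self, star5):
        # degrees (4,1,1,1,1): sample sd 1.3416..., mean 1.6
        expected = np.std([4, 1, 1, 1, 1], ddof=1) / 1.6
        assert heterogeneity(star5) == pytest.approx(expected)
        assert heterogeneity(star5) == pytest.approx(0.8385, abs=1e-4)

    def test_star_population_sd(self, star5):
        assert heterogeneity(star5, population_sd=True) == pytest.approx(1.2 / 1.6)


class TestClustering:
    def test_triangle_is_one(self, triangle):
        assert average_clustering(triangle) == 1.0

    def test_star_is_zero(self, star5):
        assert average_clustering(star5) == 0.0

    def test_k4_minus_edge_matches_triangle_oracle(self):
        edges = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d")]
        net = net_from_edges(edges)
        oracle = oracle_local_clustering(sorted(net.bones), edges)
        assert average_clustering(net) == pytest.approx(np.mean(list(oracle.values())))

    def test_exclusion_flag(self, path3):
        # degrees (1, 2, 1): included mean 0; excluded mean is over 'b' only
        assert average_clustering(path3) == 0.0
        assert average_clustering(path3, exclude_low_degree=True) == 0.0


class TestPathLength:
    def test_triangle(self, triangle):
        assert average_path_length(triangle) == 1.0

    def test_star(self, star5):
        assert average_path_length(star5) == pytest.approx(1.6)

    def test_path3(self, path3):
        assert average_path_length(path3) == pytest.approx(4 / 3)

    def test_disconnected_errors_naming_components(self):
        net = net_from_edges([("a", "b"), ("c", "d")])
        with pytest.raises(UndefinedDescriptorError, match="2 components"):
            average_path_length(net)

    def test_largest_component_fallback(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("d", "e")])
        assert average_path_length(net, largest_component=True) == pytest.approx(4 / 3)


class TestUBR:
    def test_seven_midline_of_35(self):
        net = generate_skull_network(SkullGenConfig(seed=1, target_links=90))
        assert unpaired_bone_ratio(net) == pytest.approx(0.2)

    def test_all_midline(self, triangle):
        assert unpaired_bone_ratio(triangle) == 1.0

    def test_six_midline_of_35_rounds_to_017(self):
        net = generate_skull_network(
            SkullGenConfig(n_unpaired=7, n_pairs=14, seed=1, target_links=90))
        # re-declare one midline bone as a singleton pair member
        bones = [b for b in net.bones.values() if b.name != "Mesethmoid"]
        bones.append(Bone("Mesethmoid_L", "left", "Mesethmoid"))
        relabel = lambda n: "Mesethmoid_L" if n == "Mesethmoid" else n
        links = [tuple(relabel(x) for x in sorted(l)) for l in net.links]
        net2 = AnatomicalNetwork("t", bones, links)
        assert round(unpaired_bone_ratio(net2), 2) == 0.17


class TestOracleAgreement:
    def test_exhaustive_small_graphs(self):
        """L and C equal Floyd-Warshall / triangle-count oracles on all
        connected graphs with <= 4 nodes and a sample of 5-node graphs."""
        for n in (2, 3, 4):
            for edges in all_connected_graphs(n):
                net = net_from_edges(edges)
                names = sorted(net.bones)
                assert average_path_length(net) == pytest.approx(
                    oracle_average_path_length(names, edges))
                assert average_clustering(net) == pytest.approx(
                    np.mean(list(oracle_local_clustering(names, edges).values())))

    def test_random_medium_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(6, 13))
            edges = random_connected_edges(n, 0.35, rng)
            net = net_from_edges(edges)
            names = sorted(net.bones)
            assert average_path_length(net) == pytest.approx(
                oracle_average_path_length(names, edges))
            assert average_clustering(net) == pytest.approx(
                np.mean(list(oracle_local_clustering(names, edges).values())))


class TestMonotonicity:
    def test_adding_link_never_increases_L_or_decreases_D(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(5, 10))
            edges = random_connected_edges(n, 0.4, rng)
            net = net_from_edges(edges)
            names = sorted(net.bones)
            free = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]
                    if frozenset((a, b)) not in net.links]
            if not free:
                continue
            extra = free[int(rng.integers(len(free)))]
            bigger = net_from_edges(edges + [extra])
            assert average_path_length(bigger) <= average_path_length(net) + 1e-12
            assert density(bigger) > density(net)


class TestDescriptorTable:
    def test_empty_input(self):
        table = descriptor_table([])
        assert table.empty and list(table.columns)[0] == "taxon"

    def test_gexf_roundtrip_row_identical(self, tmp_path):
        from annaceti.network_model import load_gexf, write_gexf

        net = generate_skull_network(SkullGenConfig(seed=6, target_links=95))
        p = tmp_path / "net.gexf"
        write_gexf(net, p)
        copy = load_gexf(p, taxon=net.taxon)
        parts = [detect_modules(x, n_restarts=10, seed=1) for x in (net, copy)]
        table = descriptor_table([net, copy], parts)
        assert table.iloc[0].equals(table.iloc[1])

    def test_synthetic_cohort_invariants(self):
        nets = [generate_skull_network(SkullGenConfig(seed=s, target_links=78 + s),
                                       taxon=f"s{s}") for s in range(8)]
        parts = [detect_modules(n, n_restarts=10, seed=2) for n in nets]
        table = descriptor_table(nets, parts)
        assert len(table) == 8
        assert ((table.D > 0) & (table.D <= 1)).all()
        assert (table.H >= 0).all()
        assert ((table.C >= 0) & (table.C <= 1)).all()
        assert (table.L >= 1).all()
        # UBR * N is the midline-bone count, an integer
        prod = table.UBR * table.N
        assert np.allclose(prod, np.round(prod))

    def test_fixture_density_consistency(self):
        # the published table is self-consistent (D = 2K/N(N-1) at 3 dp)
        # except in the B. borealis row, where K=87 is printed next to the
        # D value of an 89-link network
        tab = fixture_table1()
        recomputed = np.round(2 * tab.K / (tab.N * (tab.N - 1)), 3)
        mismatch = tab.taxon[recomputed != tab.D].tolist()
        assert mismatch == ["Balaenoptera borealis"]
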