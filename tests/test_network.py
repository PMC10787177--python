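"""Network assembly, power-law fit, paths, centrality, recovery, alignment."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from altppi import network
from altppi.catalog import ProteinCatalog

from tests.conftest import make_record
from tests.oracles import dominant_eigenvector, floyd_warshall, nw_affine_oracle


@pytest.fixture
def net_catalog() -> ProteinCatalog:
    cat = ProteinCatalog()
    for g in ("GA", "GB", "GC", "GD"):
        cat.add(make_record(f"P_{g}", g))
    cat.add(make_record("IP_1", "GA", category="altProt", biotype="ncRNA"))
    cat.add(make_record("IP_2", "PSEUDO0", category="altProt", biotype="pseudogene",
                        parent="GB", sequence="ACDEFGHKMNPQRSTVWY"))
    return cat


def classified_frame(rows):
    return pd.DataFrame([{"bait_id": a, "prey": b, "hcip": h} for a, b, h in rows])


class TestAssembly:
    def test_reciprocal_detections_merge(self, net_catalog):
        g = network.assemble(
            classified_frame([("GA", "GB", True), ("GB", "GA", True)]), net_catalog
        )
        assert g.number_of_edges() == 1
        assert sorted(g.edges["GA", "GB"]["provenance"]) == ["GA", "GB"]

    def test_altprot_on_same_gene_is_a_distinct_node(self, net_catalog):
        g = network.assemble(classified_frame([("GA", "IP_1", True)]), net_catalog)
        assert set(g) == {"GA", "IP_1"}
        assert g.nodes["IP_1"]["kind"] == "altprot"
        assert g.nodes["GA"]["bait"] and g.nodes["IP_1"]["prey"]

    def test_self_pairs_are_skipped(self, net_catalog):
        g = network.assemble(classified_frame([("GA", "GA", True)]), net_catalog)
        assert g.number_of_edges() == 0

    def test_non_hcip_rows_are_ignored(self, net_catalog):
        g = network.assemble(classified_frame([("GA", "GB", False)]), net_catalog)
        assert len(g) == 0

    def test_unknown_entity_raises(self, net_catalog):
        with pytest.raises(ValueError, match="unknown entity"):
            network.assemble(classified_frame([("GA", "NOPE", True)]), net_catalog)


class TestPowerLaw:
    def test_recovers_known_exponent(self):
        rng = np.random.default_rng(42)
        x = network.sample_discrete_power_law(5000, 2.5, 1, rng)
        fit = network.fit_power_law(x, xmin=1)
        assert abs(fit.alpha - 2.5) < 0.1

    def test_duplicated_sample_gives_same_alpha(self):
        rng = np.random.default_rng(43)
        x = list(network.sample_discrete_power_law(500, 2.2, 1, rng))
        a = network.fit_power_law(x, xmin=1).alpha
        b = network.fit_power_law(x + x, xmin=1).alpha
        assert a == pytest.approx(b, abs=1e-12)

    def test_ks_xmin_selection_prefers_clean_tail(self):
        rng = np.random.default_rng(44)
        tail = network.sample_discrete_power_law(3000, 2.5, 5, rng)
        noise = rng.integers(1, 5, size=1000)
        fit = network.fit_power_law(np.concatenate([tail, noise]))
        assert fit.xmin >= 2
        assert abs(fit.alpha - 2.5) < 0.25

    def test_too_few_observations_raise(self):
        with pytest.raises(ValueError, match="at least"):
            network.fit_power_law([3] * 10 + [4] * 10)

    def test_degenerate_distribution_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            network.fit_power_law([2] * 100)

    def test_two_valued_fit_is_flagged_low_confidence(self):
        fit = network.fit_power_law([1] * 80 + [2] * 20, xmin=1)
        assert np.isfinite(fit.alpha) and fit.low_confidence


class TestPaths:
    def test_path_graph_histogram(self):
        g = nx.path_graph(["a", "b", "c"])
        hist, mean, unreachable = network.path_length_distribution(g)
        assert hist == {1: 2, 2: 1}
        assert mean == pytest.approx(4 / 3)
        assert unreachable == 0

    def test_complete_graph_all_distance_one(self):
        hist, mean, _ = network.path_length_distribution(nx.complete_graph(5))
        assert hist == {1: 10} and mean == 1.0

    def test_disconnected_pairs_are_counted_not_averaged(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        hist, mean, unreachable = network.path_length_distribution(g)
        assert hist == {1: 2} and mean == 1.0 and unreachable == 4

    def test_pair_separation_fallback_chain(self):
        primary = nx.Graph([("a", "b")])
        fallback = nx.Graph([("a", "c"), ("c", "d")])
        assert network.pair_separation(primary, ("a", "b")) == (1, "primary")
        assert network.pair_separation(primary, ("a", "d"), [fallback]) == (2, "fallback0")
        assert network.pair_separation(primary, ("a", "zz"), [fallback]) == (None, None)


class TestCentrality:
    def test_complete_graph_is_uniform(self):
        evc = network.eigenvector_centrality(nx.complete_graph(6))
        assert all(v == pytest.approx(1.0) for v in evc.values())

    def test_star_graph_closed_form(self):
        n = 8  # leaves
        g = nx.star_graph(n)
        evc = network.eigenvector_centrality(g)
        assert evc[0] == pytest.approx(1.0)
        for leaf in range(1, n + 1):
            assert evc[leaf] == pytest.approx(1 / math.sqrt(n), abs=1e-8)

    def test_each_component_is_normalized_separately(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.path_graph(3))
        g.add_node(99)  # isolated
        evc = network.eigenvector_centrality(g)
        assert evc[99] == 1.0
        assert max(evc[i] for i in range(4)) == pytest.approx(1.0)
        assert max(evc[i] for i in range(4, 7)) == pytest.approx(1.0)

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(7)
        g = nx.gnp_random_graph(30, 0.15, seed=3)
        evc = network.eigenvector_centrality(g)
        for comp in nx.connected_components(g):
            nodes = sorted(comp)
            if len(nodes) < 2:
                continue
            adj = nx.to_numpy_array(g, nodelist=nodes)
            expected = dominant_eigenvector(adj + np.eye(len(nodes)))
            got = np.array([evc[n] for n in nodes])
            assert np.allclose(got, expected, atol=1e-6)

    def test_second_neighborhood_radius_two(self):
        g = nx.path_graph(["a", "b", "c", "d", "e"])
        sub = network.second_neighborhood(g, "a")
        assert set(sub) == {"a", "b", "c"}
        assert set(map(frozenset, sub.edges())) == {frozenset(("a", "b")), frozenset(("b", "c"))}
        with pytest.raises(KeyError):
            network.second_neighborhood(g, "zz")

    def test_evc_delta_with_and_without_altprots(self):
        g = nx.Graph()
        for n, kind in [("GA", "gene"), ("GB", "gene"), ("GC", "gene"), ("IP_1", "altprot")]:
            g.add_node(n, kind=kind)
        # IP_1 makes GB the hub of a star; without it GA-GB-GC is a path
        g.add_edges_from([("GA", "GB"), ("GB", "GC"), ("GB", "IP_1")])
        with_alt, without_alt = network.evc_delta(g, "GB")
        assert with_alt == pytest.approx(1.0) and without_alt == pytest.approx(1.0)
        leaf_with, leaf_without = network.evc_delta(g, "GA")
        assert leaf_with < leaf_without  # extra leaf dilutes GA's relative score
        with pytest.raises(ValueError):
            network.evc_delta(g, "IP_1")

    def test_evc_delta_unchanged_by_disconnected_altprot(self):
        g = nx.Graph()
        for n, kind in [("GA", "gene"), ("GB", "gene"), ("IP_9", "altprot")]:
            g.add_node(n, kind=kind)
        g.add_edge("GA", "GB")
        with_alt, without_alt = network.evc_delta(g, "GA")
        assert with_alt == without_alt


class TestComplexRecovery:
    def build(self):
        g = nx.Graph()
        for n in ("a", "b", "c", "e"):
            g.add_node(n, kind="gene")
        g.add_node("ip", kind="altprot")
        g.add_edges_from([("a", "b"), ("a", "c"), ("a", "ip")])
        return g

    def test_hand_fixture_recovers_three_quarters(self):
        g = self.build()
        out = network.corum_recovery(g, {"cx": {"a", "b", "c", "d"}}, bait_set={"a", "b"})
        assert len(out) == 1
        row = out.iloc[0]
        assert row["recovery"] == 0.75 and row["n_recovered"] == 3
        assert row["altprot_neighbors"] == "ip"

    def test_single_baited_subunit_is_excluded(self):
        g = self.build()
        out = network.corum_recovery(g, {"cx": {"a", "e", "x", "y"}}, bait_set={"a"})
        assert out.empty

    def test_fully_recovered_clique(self):
        g = nx.complete_graph(["a", "b", "c"])
        nx.set_node_attributes(g, "gene", "kind")
        out = network.corum_recovery(g, {"cx": {"a", "b", "c"}}, bait_set={"a", "b"})
        assert out.iloc[0]["recovery"] == 1.0


class TestAlignment:
    def test_peptide_self_alignment_blosum62(self):
        assert network.nw_align("PEPTIDE", "PEPTIDE") == 39.0

    def test_symmetry(self):
        assert network.nw_align("ACDK", "AMDKW") == network.nw_align("AMDKW", "ACDK")

    def test_empty_sequence_costs_one_gap(self):
        assert network.nw_align("A", "") == -12.0
        assert network.nw_align("", "ACD") == -14.0
        with pytest.raises(ValueError):
            network.nw_align("", "")

    def test_invalid_residue_raises(self):
        with pytest.raises(ValueError, match="invalid residues"):
            network.nw_align("ACDB", "ACD")

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(11)
        blosum = substitution_matrices.load("BLOSUM62")
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(30):
            a = "".join(rng.choice(aas, size=rng.integers(1, 10)))
            b = "".join(rng.choice(aas, size=rng.integers(1, 10)))
            assert network.nw_align(a, b) == pytest.approx(nw_affine_oracle(a, b, blosum))

    def test_pseudogene_parent_table(self, net_catalog):
        g = nx.Graph()
        for n, kind in [("GB", "gene"), ("IP_2", "altprot")]:
            g.add_node(n, kind=kind)
        g.add_edge("GB", "IP_2")
        results = network.pseudogene_parent_table(g, net_catalog)
        assert len(results) == 1
        r = results[0]
        assert (r.altprot, r.parent_gene) == ("IP_2", "GB")
        assert r.separation == 1 and r.separation_source == "primary"
        assert r.nw_score == network.nw_align(
            net_catalog["IP_2"].sequence, net_catalog["P_GB"].sequence
        )
        frame = network.alignment_frame(results)
        assert list(frame["altprot"]) == ["IP_2"]


def test_bfs_distances_match_floyd_warshall():
    g = nx.gnp_random_graph(25, 0.12, seed=5)
    hist, mean, unreachable = network.path_length_distribution(g)
    d = floyd_warshall(nx.to_numpy_array(g))
    expected_hist: dict[int, int] = {}
    expected_unreachable = 0
    n = len(g)
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(d[i, j]):
                expected_hist[int(d[i, j])] = expected_hist.get(int(d[i, j]), 0) + 1
            else:
                expected_unreachable += 1
    assert hist == expected_hist and unreachable == expected_unreachable
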