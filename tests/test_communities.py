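"""MCL clustering and the hypergeometric + BH enrichment engine."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from altppi.communities import (
    ClusterSet,
    bh_fdr,
    cluster_link_enrichment,
    disease_association,
    disease_class_summary,
    enrichment_frame,
    go_enrichment,
    hypergeom_sf,
    mcl,
    propagate_annotations,
    read_ontology_tsv,
)

from tests.oracles import bh_stepup, hypergeom_sf_enumeration


# ------------------------------------------------------------------ MCL


def planted_partition(n_blocks, block_size, p_in, p_out, seed):
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    labels = {}
    nodes = [f"n{i:03d}" for i in range(n_blocks * block_size)]
    for i, n in enumerate(nodes):
        g.add_node(n)
        labels[n] = i // block_size
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            p = p_in if labels[nodes[i]] == labels[nodes[j]] else p_out
            if rng.random() < p:
                g.add_edge(nodes[i], nodes[j])
    return g, labels


def test_two_disjoint_triangles_are_two_clusters():
    g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")])
    cs = mcl(g)
    assert sorted(map(sorted, cs.clusters.values())) == [["a", "b", "c"], ["x", "y", "z"]]
    assert cs.discarded == []


def test_small_clusters_are_discarded():
    g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("x", "y")])
    cs = mcl(g)
    assert sorted(map(sorted, cs.clusters.values())) == [["a", "b", "c"]]
    assert sorted(map(sorted, cs.discarded)) == [["x", "y"]]


def test_clusters_partition_the_nodes():
    g, _ = planted_partition(3, 6, 0.85, 0.03, seed=2)
    cs = mcl(g)
    covered = [m for members in cs.clusters.values() for m in members]
    covered += [m for members in cs.discarded for m in members]
    assert sorted(covered) == sorted(g)


def test_planted_partition_recovery():
    g, labels = planted_partition(4, 10, 0.9, 0.02, seed=1)
    cs = mcl(g)
    membership = cs.membership()
    common = [n for n in g if n in membership]
    assert len(common) >= 0.9 * len(g)
    ari = adjusted_rand_score([labels[n] for n in common], [membership[n] for n in common])
    assert ari >= 0.9


def test_mcl_is_deterministic():
    g, _ = planted_partition(3, 5, 0.9, 0.05, seed=4)
    a, b = mcl(g), mcl(g)
    assert a.clusters == b.clusters and a.discarded == b.discarded


def test_empty_graph_raises():
    with pytest.raises(ValueError):
        mcl(nx.Graph())


# ------------------------------------------------------------------ urn


def test_hypergeom_sf_edge_cases():
    assert hypergeom_sf(0, 5, 4, 20) == 1.0
    assert hypergeom_sf(5, 5, 5, 5) == pytest.approx(1.0)
    assert hypergeom_sf(6, 5, 4, 20) == 0.0
    with pytest.raises(ValueError):
        hypergeom_sf(1, 10, 4, 5)


def test_hypergeom_sf_matches_combinatorial_enumeration():
    assert hypergeom_sf(3, 5, 4, 20) == pytest.approx(
        hypergeom_sf_enumeration(3, 5, 4, 20), rel=1e-12
    )
    rng = np.random.default_rng(0)
    for _ in range(200):
        N = int(rng.integers(1, 60))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        k = int(rng.integers(0, min(K, n) + 2))
        assert hypergeom_sf(k, K, n, N) == pytest.approx(
            hypergeom_sf_enumeration(k, K, n, N), abs=1e-12
        )


def test_bh_hand_example():
    q, reject = bh_fdr([0.001, 0.008, 0.039, 0.041], q_level=0.05)
    # step-up: p_(4)=0.041 <= 4/4 * 0.05, so all four are rejected
    assert reject.all()
    q2, reject2 = bh_fdr([0.001, 0.008, 0.039, 0.26], q_level=0.05)
    assert list(reject2) == [True, True, False, False]


def test_bh_extremes():
    _, none = bh_fdr([1.0, 1.0, 1.0], q_level=0.05)
    assert not none.any()
    _, single = bh_fdr([0.005], q_level=0.01)
    assert single.all()
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


def test_bh_matches_reference_stepup_on_random_vectors():
    rng = np.random.default_rng(1)
    for _ in range(50):
        p = rng.random(rng.integers(1, 40))
        q, reject = bh_fdr(p, q_level=0.05)
        q_ref, reject_ref = bh_stepup(p, 0.05)
        assert np.allclose(q, q_ref)
        assert np.array_equal(reject, reject_ref)


# ------------------------------------------------------------------ links


def two_cluster_graph():
    g = nx.Graph()
    a = ["a1", "a2", "a3"]
    b = ["b1", "b2", "b3"]
    for grp in (a, b):
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                g.add_edge(grp[i], grp[j])
    return g, ClusterSet({0: set(a), 1: set(b)}, [], inflation=2.0)


def test_unlinked_clusters_are_not_tested():
    g, cs = two_cluster_graph()
    assert cluster_link_enrichment(g, cs) == []


def test_fully_linked_clusters_match_enumeration_oracle():
    g, cs = two_cluster_graph()
    for u in cs.clusters[0]:
        for v in cs.clusters[1]:
            g.add_edge(u, v)
    # unclustered background nodes so the urn is not saturated
    nx.add_path(g, [f"x{i}" for i in range(6)])
    results = cluster_link_enrichment(g, cs, alpha=0.05, fdr=0.05)
    assert len(results) == 1
    r = results[0]
    assert (r.k, r.K, r.n, r.N) == (9, 9, 20, 66)
    assert r.p_value == pytest.approx(hypergeom_sf_enumeration(9, 9, 20, 66))
    assert r.significant


def test_overlapping_clusters_raise():
    g, cs = two_cluster_graph()
    cs.clusters[1].add("a1")
    with pytest.raises(ValueError, match="overlap"):
        cluster_link_enrichment(g, cs)


def test_single_cluster_yields_no_tests():
    g, cs = two_cluster_graph()
    solo = ClusterSet({0: cs.clusters[0]}, [], inflation=2.0)
    assert cluster_link_enrichment(g, solo) == []


# ------------------------------------------------------------------ disease


def test_universal_disease_is_not_significant():
    universe = {f"g{i}" for i in range(30)}
    cs = ClusterSet({0: {"g0", "g1", "g2", "g3"}}, [], inflation=2.0)
    dg = pd.DataFrame(
        [{"disease_id": "D1", "disease_name": "everything", "disease_class": "c", "gene": g}
         for g in universe]
    )
    results = disease_association(cs, dg, universe=universe)
    assert len(results) == 1
    assert results[0].p_value == pytest.approx(1.0)
    assert not results[0].significant


def test_exclusive_disease_matches_enumeration_and_flags_altprot():
    universe = {f"g{i}" for i in range(40)}
    members = {"g0", "g1", "g2", "g3"}
    cs = ClusterSet({0: members | {"IP_7"}}, [], inflation=2.0)
    dg = pd.DataFrame(
        [{"disease_id": "D2", "disease_name": "rare", "disease_class": "cls", "gene": g}
         for g in members]
    )
    results = disease_association(cs, dg, universe=universe, altprot_nodes={"IP_7"})
    r = results[0]
    assert (r.k, r.K, r.n, r.N) == (4, 4, 4, 40)
    assert r.p_value == pytest.approx(hypergeom_sf_enumeration(4, 4, 4, 40))
    assert r.significant and r.extra["has_altprot"]
    summary = disease_class_summary(results)
    assert summary.iloc[0]["with_altprot"] == 1 and summary.iloc[0]["without_altprot"] == 0


def test_altprot_only_cluster_is_skipped():
    universe = {"g0", "g1"}
    cs = ClusterSet({0: {"IP_1", "IP_2", "IP_3"}}, [], inflation=2.0)
    dg = pd.DataFrame([{"disease_id": "D", "disease_name": "d", "disease_class": "c", "gene": "g0"}])
    assert disease_association(cs, dg, universe=universe, altprot_nodes={"IP_1", "IP_2", "IP_3"}) == []


def test_empty_universe_raises():
    cs = ClusterSet({0: {"g0"}}, [], inflation=2.0)
    with pytest.raises(ValueError):
        disease_association(cs, pd.DataFrame(columns=["disease_id", "disease_name", "disease_class", "gene"]), universe=set())


# ------------------------------------------------------------------ ontology


def toy_ontology():
    dag = nx.DiGraph()
    dag.add_edge("leaf", "mid")
    dag.add_edge("mid", "root")
    dag.add_edge("leaf2", "root")
    return dag


def test_propagation_adds_all_ancestors():
    dag = toy_ontology()
    out = propagate_annotations({"g1": {"leaf"}, "g2": {"leaf2"}}, dag)
    assert out["g1"] == {"leaf", "mid", "root"}
    assert out["g2"] == {"leaf2", "root"}


def test_cyclic_ontology_raises():
    dag = toy_ontology()
    dag.add_edge("root", "leaf")
    with pytest.raises(ValueError, match="cycle"):
        propagate_annotations({"g1": {"leaf"}}, dag)


def test_root_term_annotating_everything_scores_one():
    dag = toy_ontology()
    background = {f"g{i}" for i in range(10)}
    gene2term = {g: {"leaf"} for g in background}
    results = go_enrichment({0: {"g0", "g1", "g2"}}, dag, gene2term, background)
    by_term = {r.unit[1]: r for r in results}
    assert by_term["root"].p_value == pytest.approx(1.0)
    assert not by_term["root"].significant


def test_leaf_enrichment_matches_oracle_and_ancestors_are_weaker():
    dag = toy_ontology()
    background = {f"g{i}" for i in range(20)}
    gene2term = {f"g{i}": {"leaf"} for i in range(4)}
    gene2term.update({f"g{i}": {"leaf2"} for i in range(4, 12)})
    cluster = {0: {"g0", "g1", "g2", "g3"}}
    results = go_enrichment(cluster, dag, gene2term, background, alpha=0.05, fdr=0.05)
    by_term = {r.unit[1]: r for r in results}
    leaf = by_term["leaf"]
    assert (leaf.k, leaf.K, leaf.n, leaf.N) == (4, 4, 4, 20)
    assert leaf.p_value == pytest.approx(hypergeom_sf_enumeration(4, 4, 4, 20))
    assert leaf.significant
    # root is annotated by leaf + leaf2 genes -> weaker enrichment
    assert by_term["root"].p_value >= leaf.p_value


def test_read_ontology_tsv(tmp_path):
    path = tmp_path / "ont.tsv"
    path.write_text("child\tparent\nleaf\tmid\nmid\troot\n")
    dag = read_ontology_tsv(path)
    assert set(dag.edges()) == {("leaf", "mid"), ("mid", "root")}


def test_enrichment_frame_has_columns_even_when_empty():
    frame = enrichment_frame([])
    assert list(frame.columns) == ["unit", "k", "K", "n", "N", "p_value", "q_value", "significant"]
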