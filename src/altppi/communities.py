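"""Markov clustering and the shared hypergeometric + BH enrichment engine.

MCL partitions the interactome into protein communities by alternating
expansion (matrix squaring) and inflation (elementwise power, here 2.0 by
default) on a column-stochastic flow matrix until the flow stops changing.
Communities smaller than three members are discarded.

All enrichment analyses (links between cluster pairs, disease-gene
associations per cluster, GO terms with ancestor propagation) share one urn:
``p = P(X >= k)`` for a hypergeometric draw of ``n`` from a population of
``N`` containing ``K`` successes, Benjamini-Hochberg corrected; a unit is
significant when the raw p-value passes the stated alpha AND the BH-adjusted
q-value passes the stated FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

# ------------------------------------------------------------------ MCL


@dataclass
class ClusterSet:
    clusters: dict[int, set[str]]  # retained clusters (size >= retained_min_size)
    discarded: list[set[str]]  # clusters below the size threshold
    inflation: float
    retained_min_size: int = 3

    def membership(self) -> dict[str, int]:
        return {m: cid for cid, members in self.clusters.items() for m in members}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cluster_id": cid, "member": m}
            for cid, members in self.clusters.items()
            for m in sorted(members)
        ]
        return pd.DataFrame(rows, columns=["cluster_id", "member"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def mcl(
    graph: nx.Graph,
    inflation: float = 2.0,
    retained_min_size: int = 3,
    prune_threshold: float = 1e-5,
    convergence_tol: float = 1e-8,
    max_iterations: int = 200,
) -> ClusterSet:
    """Markov clustering of an undirected graph.

    Self-loops of weight 1 are added before column normalization; iteration
    alternates expansion (M @ M) and inflation (elementwise power followed by
    pruning of entries below ``prune_threshold`` and renormalization) until
    the largest column change drops below ``convergence_tol``. Clusters are
    read from the attractor rows of the converged flow matrix; a node whose
    assignment is ambiguous goes to the cluster receiving its largest flow,
    ties broken toward the smaller cluster id.
    """
    if len(graph) == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph)
    m = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    np.fill_diagonal(m, m.diagonal() + 1.0)
    m /= m.sum(axis=0, keepdims=True)

    for _ in range(max_iterations):
        expanded = m @ m
        inflated = expanded**inflation
        inflated[inflated < prune_threshold] = 0.0
        sums = inflated.sum(axis=0, keepdims=True)
        sums[sums == 0] = 1.0
        inflated /= sums
        change = float(np.max(np.abs(inflated - m)))
        m = inflated
        if change < convergence_tol:
            break
    else:
        raise RuntimeError(
            f"MCL did not converge in {max_iterations} iterations (last change {change:.2e})"
        )

    # attractors are rows with flow on the diagonal
    attractors = [i for i in range(len(nodes)) if m[i, i] > prune_threshold]
    members = {i: set(np.flatnonzero(m[i] > 0.0)) for i in attractors}

    # merge attractor rows that overlap into one cluster (union-find)
    parent = {i: i for i in attractors}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in attractors:
        for j in attractors:
            if i < j and members[i] & members[j]:
                parent[find(j)] = find(i)
    systems: dict[int, list[int]] = {}
    for i in attractors:
        systems.setdefault(find(i), []).append(i)
    system_ids = sorted(systems)

    assignment: dict[int, int] = {}
    for col in range(len(nodes)):
        best_sid, best_flow = None, 0.0
        for sid in system_ids:
            flow = max(m[i, col] for i in systems[sid])
            if flow > best_flow:
                best_sid, best_flow = sid, flow
        if best_sid is None:
            best_sid = col  # isolated node: its own singleton cluster
            systems.setdefault(col, [])
        assignment[col] = best_sid

    raw: dict[int, set[str]] = {}
    for col, sid in assignment.items():
        raw.setdefault(sid, set()).add(nodes[col])
    retained, discarded = {}, []
    next_id = 0
    for sid in sorted(raw):
        if len(raw[sid]) >= retained_min_size:
            retained[next_id] = raw[sid]
            next_id += 1
        else:
            discarded.append(raw[sid])
    return ClusterSet(retained, discarded, inflation, retained_min_size)


# ------------------------------------------------------------------ urn


def hypergeom_sf(k: int, K: int, n: int, N: int) -> float:
    """Exact ``P(X >= k)`` for a hypergeometric(N, K, n) draw."""
    if not (0 <= K <= N and 0 <= n <= N and k >= 0):
        raise ValueError(f"invalid hypergeometric parameters k={k} K={K} n={n} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values, q_level: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q_values, significance flags at q_level)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, reject


@dataclass
class EnrichmentResult:
    unit: tuple
    k: int
    K: int
    n: int
    N: int
    p_value: float
    q_value: float = float("nan")
    significant: bool = False
    extra: dict = field(default_factory=dict)


def _finalize(results: list[EnrichmentResult], alpha: float, fdr: float) -> list[EnrichmentResult]:
    if not results:
        return results
    q, reject = bh_fdr([r.p_value for r in results], q_level=fdr)
    for r, qv, rej in zip(results, q, reject):
        r.q_value = float(qv)
        r.significant = bool(rej and r.p_value < alpha)
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "unit": "|".join(str(u) for u in r.unit),
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "significant": r.significant,
        }
        row.update(r.extra)
        rows.append(row)
    cols = ["unit", "k", "K", "n", "N", "p_value", "q_value", "significant"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ analyses


def cluster_link_enrichment(
    graph: nx.Graph, clusters: ClusterSet, alpha: float = 0.05, fdr: float = 0.01
) -> list[EnrichmentResult]:
    """Cluster pairs connected by more edges than expected by chance.

    Urn: the graph's ``n`` edges are draws from the ``N = C(|V|, 2)`` possible
    node pairs, of which ``K = |A| * |B|`` straddle the two clusters; ``k`` is
    the observed inter-cluster edge count. Only pairs with ``k >= 1`` are
    tested.
    """
    ids = sorted(clusters.clusters)
    for i in ids:
        for j in ids:
            if i < j and clusters.clusters[i] & clusters.clusters[j]:
                raise ValueError(f"clusters {i} and {j} overlap")
    n_edges = graph.number_of_edges()
    n_nodes = len(graph)
    N = n_nodes * (n_nodes - 1) // 2
    results = []
    for a_idx in range(len(ids)):
        for b_idx in range(a_idx + 1, len(ids)):
            a, b = clusters.clusters[ids[a_idx]], clusters.clusters[ids[b_idx]]
            k = sum(1 for u in a for v in b if graph.has_edge(u, v))
            if k == 0:
                continue
            K = len(a) * len(b)
            p = hypergeom_sf(k, K, n_edges, N)
            results.append(EnrichmentResult((ids[a_idx], ids[b_idx]), k, K, n_edges, N, p))
    return _finalize(results, alpha, fdr)


def disease_association(
    clusters: ClusterSet,
    disease_genes: pd.DataFrame,
    universe: set[str],
    alpha: float = 0.01,
    fdr: float = 0.01,
    altprot_nodes: Optional[set[str]] = None,
) -> list[EnrichmentResult]:
    """Disease-cluster associations by hypergeometric enrichment.

    ``disease_genes`` columns: disease_id, disease_name, disease_class, gene.
    altProt members carry no disease annotations: they are excluded from the
    counts but clusters containing them are flagged (``has_altprot``).
    """
    if not universe:
        raise ValueError("empty universe")
    altprot_nodes = altprot_nodes or set()
    dg = disease_genes[disease_genes["gene"].isin(universe)]
    by_disease = dg.groupby("disease_id")["gene"].agg(set)
    meta = disease_genes.drop_duplicates("disease_id").set_index("disease_id")
    N = len(universe)
    results = []
    for cid in sorted(clusters.clusters):
        members = clusters.clusters[cid]
        genes = (members & universe) - altprot_nodes
        if not genes:
            continue
        has_alt = bool(members & altprot_nodes)
        for did, dgenes in by_disease.items():
            k = len(genes & dgenes)
            if k == 0:
                continue
            p = hypergeom_sf(k, len(dgenes), len(genes), N)
            results.append(
                EnrichmentResult(
                    (cid, did),
                    k,
                    len(dgenes),
                    len(genes),
                    N,
                    p,
                    extra={
                        "has_altprot": has_alt,
                        "disease_name": meta.loc[did, "disease_name"],
                        "disease_class": meta.loc[did, "disease_class"],
                    },
                )
            )
    return _finalize(results, alpha, fdr)


def disease_class_summary(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Significant disease-cluster associations tallied per disease class,
    split by whether the cluster contains an altProt."""
    rows = [
        {"disease_class": r.extra["disease_class"], "has_altprot": r.extra["has_altprot"]}
        for r in results
        if r.significant
    ]
    if not rows:
        return pd.DataFrame(columns=["disease_class", "with_altprot", "without_altprot"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["disease_class", "has_altprot"]).size().unstack(fill_value=0)
        .rename(columns={True: "with_altprot", False: "without_altprot"})
        .reset_index()
    )
    for col in ("with_altprot", "without_altprot"):
        if col not in out:
            out[col] = 0
    return out[["disease_class", "with_altprot", "without_altprot"]]


# ------------------------------------------------------------------ ontology


def read_obo(path: str | Path) -> nx.DiGraph:
    """Minimal OBO loader keeping only id/name and is_a edges (child -> parent)."""
    import obonet

    multi = obonet.read_obo(path)
    dag = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        dag.add_node(node, name=data.get("name", ""))
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent)
    return dag


def read_ontology_tsv(path: str | Path) -> nx.DiGraph:
    """Child-parent edge list dialect (columns: child, parent)."""
    df = pd.read_csv(path, sep="\t")
    dag = nx.DiGraph()
    dag.add_edges_from(zip(df["child"], df["parent"]))
    return dag


def propagate_annotations(
    gene2term: dict[str, set[str]], ontology: nx.DiGraph
) -> dict[str, set[str]]:
    """Extend each gene's term set with all ancestors of its terms."""
    if not nx.is_directed_acyclic_graph(ontology):
        raise ValueError("ontology contains a cycle")
    ancestors = {t: nx.descendants(ontology, t) for t in ontology}  # child->parent edges
    out = {}
    for gene, terms in gene2term.items():
        full = set(terms)
        for t in terms:
            full.update(ancestors.get(t, ()))
        out[gene] = full
    return out


def go_enrichment(
    node_sets: dict,
    ontology: nx.DiGraph,
    gene2term: dict[str, set[str]],
    background: set[str],
    alpha: float = 0.05,
    fdr: float = 0.01,
) -> list[EnrichmentResult]:
    """Term enrichment per node set with ancestor propagation.

    Annotations are propagated to all parental terms before counting; the
    population is the background (by default the network's nodes); BH runs
    across the tested terms of each set separately.
    """
    annotated = propagate_annotations(gene2term, ontology)
    term_to_bg: dict[str, set[str]] = {}
    for gene in background:
        for t in annotated.get(gene, ()):
            term_to_bg.setdefault(t, set()).add(gene)
    N = len(background)
    all_results: list[EnrichmentResult] = []
    for set_id in sorted(node_sets):
        members = set(node_sets[set_id]) & background
        if not members:
            continue
        results = []
        for term, bg_genes in sorted(term_to_bg.items()):
            k = len(members & bg_genes)
            if k == 0:
                continue
            p = hypergeom_sf(k, len(bg_genes), len(members), N)
            results.append(
                EnrichmentResult(
                    (set_id, term),
                    k,
                    len(bg_genes),
                    len(members),
                    N,
                    p,
                    extra={
                        "term_name": ontology.nodes[term].get("name", "") if term in ontology else ""
                    },
                )
            )
        all_results.extend(_finalize(results, alpha, fdr))
    return all_results
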