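"""Interactome assembly and structural analyses.

The interactome is an undirected simple graph whose nodes are genes (for
refProts, which are collapsed by gene) and accessions (for altProts, which
stay separate because many share a gene with a refProt). Edges carry bait
provenance; reciprocal detections merge into one edge; self-loops are dropped.

Structural analyses: discrete power-law MLE of the degree distribution
(Clauset-style, with KS-minimizing lower cutoff), shortest-path length
distributions, per-component eigenvector centrality normalized to max 1,
second neighborhoods and the with/without-altProt centrality contrast, known
complex (CORUM-style) subunit recovery, and Needleman-Wunsch global alignment
of pseudogene-derived altProts against their parental refProts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.special import zeta

from altppi.catalog import AMINO_ACIDS, ProteinCatalog

# ------------------------------------------------------------------ assembly


def assemble(hcip: pd.DataFrame, catalog: ProteinCatalog) -> nx.Graph:
    """Build the interactome from classified bait-prey pairs.

    ``hcip`` needs columns bait_id, prey, hcip (boolean). Reciprocal
    detections merge into a single edge whose ``provenance`` lists every bait
    experiment supporting it.
    """
    g = nx.Graph()
    genes = catalog.genes()
    alt_accs = {r.accession for r in catalog.by_category("altProt")}
    for row in hcip[hcip["hcip"]].itertuples(index=False):
        bait, prey = row.bait_id, row.prey
        for ent in (bait, prey):
            if ent not in genes and ent not in alt_accs:
                raise ValueError(f"unknown entity {ent!r}")
        if bait == prey:
            continue
        for ent, is_bait in ((bait, True), (prey, False)):
            kind = "altprot" if ent in alt_accs else "gene"
            if ent not in g:
                g.add_node(ent, kind=kind, bait=False, prey=False)
            g.nodes[ent]["bait" if is_bait else "prey"] = True
        if g.has_edge(bait, prey):
            g.edges[bait, prey]["provenance"].append(bait)
        else:
            g.add_edge(bait, prey, provenance=[bait])
    return g


def write_graph(g: nx.Graph, edges_path: str | Path, nodes_path: str | Path) -> None:
    edges = pd.DataFrame(
        [
            {"node_a": a, "node_b": b, "provenance": ";".join(d["provenance"])}
            for a, b, d in g.edges(data=True)
        ]
    )
    nodes = pd.DataFrame(
        [
            {"node": n, "kind": d["kind"], "bait": d["bait"], "prey": d["prey"]}
            for n, d in g.nodes(data=True)
        ]
    )
    edges.to_csv(edges_path, sep="\t", index=False)
    nodes.to_csv(nodes_path, sep="\t", index=False)


# ------------------------------------------------------------------ power law


@dataclass
class PowerLawFit:
    alpha: float
    xmin: int
    n_tail: int
    ks_distance: float
    low_confidence: bool = False


def _alpha_hat(x: np.ndarray, xmin: int) -> float:
    """Exact discrete MLE of the power-law exponent over the tail x >= xmin.

    Maximizes ``-n ln zeta(alpha, xmin) - alpha * sum(ln x)`` numerically.
    The popular closed form ``1 + n / sum(ln(x / (xmin - 1/2)))`` is only an
    approximation of this likelihood and is visibly biased for small cutoffs
    (at xmin = 1 it underestimates a true alpha of 2.5 by ~0.45), so it is not
    used here.
    """
    n = len(x)
    slog = float(np.sum(np.log(x)))

    def nll(alpha: float) -> float:
        return n * math.log(zeta(alpha, xmin)) + alpha * slog

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(nll, bounds=(1.0001, 25.0), method="bounded",
                          options={"xatol": 1e-9})
    if not res.success:
        raise RuntimeError(f"power-law MLE failed to converge: {res.message}")
    return float(res.x)


def _ks_distance(x: np.ndarray, alpha: float, xmin: int) -> float:
    xs = np.arange(xmin, x.max() + 1)
    pmf = xs ** (-alpha) / zeta(alpha, xmin)
    model_cdf = np.cumsum(pmf)
    emp_cdf = np.searchsorted(np.sort(x), xs, side="right") / len(x)
    return float(np.max(np.abs(emp_cdf - model_cdf)))


def fit_power_law(
    degrees: Sequence[int], xmin: Optional[int] = None, min_observations: int = 50
) -> PowerLawFit:
    """Discrete maximum-likelihood power-law fit of a degree distribution.

    The exponent is the exact discrete MLE over the tail ``x >= xmin``
    (numerical maximization of the Hurwitz-zeta likelihood). With
    ``xmin=None`` the cutoff is chosen to minimize the KS distance between the
    empirical tail and the fitted model; pass ``xmin=1`` for the fixed-cutoff
    variant.
    """
    x = np.asarray([d for d in degrees if d >= 1], dtype=float)
    if len(x) < min_observations:
        raise ValueError(f"need at least {min_observations} positive degrees")
    if np.all(x == x[0]):
        raise ValueError("degenerate degree distribution (all degrees equal)")
    if xmin is not None:
        tail = x[x >= xmin]
        alpha = _alpha_hat(tail, xmin)
        return PowerLawFit(alpha, xmin, len(tail), _ks_distance(tail, alpha, xmin), len(np.unique(tail)) < 3)
    best: Optional[PowerLawFit] = None
    for cand in np.unique(x.astype(int))[:-1]:
        tail = x[x >= cand]
        if len(tail) < 2 or np.all(tail == tail[0]):
            continue
        alpha = _alpha_hat(tail, int(cand))
        ks = _ks_distance(tail, alpha, int(cand))
        if best is None or ks < best.ks_distance:
            best = PowerLawFit(alpha, int(cand), len(tail), ks, len(np.unique(tail)) < 3)
    if best is None:
        raise ValueError("no admissible xmin candidate")
    return best


def sample_discrete_power_law(
    n: int, alpha: float, xmin: int, rng: np.random.Generator, xmax: int = 100_000
) -> np.ndarray:
    """Exact inverse-CDF sampler for a truncated discrete power law (test oracle)."""
    xs = np.arange(xmin, xmax + 1)
    pmf = xs.astype(float) ** (-alpha)
    pmf /= pmf.sum()
    return rng.choice(xs, size=n, p=pmf)


# ------------------------------------------------------------------ paths


def path_length_distribution(
    g: nx.Graph, pair_set: Optional[Iterable[tuple[str, str]]] = None
) -> tuple[dict[int, int], float, int]:
    """Shortest-path histogram over unordered pairs.

    Returns ``(histogram, mean, n_unreachable)``. Unreachable pairs are
    excluded from the mean and counted separately.
    """
    if len(g) == 0:
        raise ValueError("empty graph")
    hist: dict[int, int] = {}
    unreachable = 0
    if pair_set is None:
        nodes = list(g)
        order = {n: i for i, n in enumerate(nodes)}
        n_pairs = len(nodes) * (len(nodes) - 1) // 2
        reached = 0
        for src, dists in nx.all_pairs_shortest_path_length(g):
            for dst, d in dists.items():
                if order[dst] > order[src]:
                    hist[d] = hist.get(d, 0) + 1
                    reached += 1
        unreachable = n_pairs - reached
    else:
        for a, b in pair_set:
            if a in g and b in g and nx.has_path(g, a, b):
                d = nx.shortest_path_length(g, a, b)
                hist[d] = hist.get(d, 0) + 1
            else:
                unreachable += 1
    total = sum(hist.values())
    mean = sum(d * c for d, c in hist.items()) / total if total else float("nan")
    return hist, mean, unreachable


def pair_separation(
    g: nx.Graph, pair: tuple[str, str], fallback_graphs: Sequence[nx.Graph] = ()
) -> tuple[Optional[int], Optional[str]]:
    """Shortest-path separation of a pair, falling back to reference networks.

    Returns ``(distance, source)`` where source is ``primary``, ``fallback<i>``
    or ``(None, None)`` when unreachable everywhere.
    """
    a, b = pair
    for name, graph in [("primary", g)] + [
        (f"fallback{i}", fg) for i, fg in enumerate(fallback_graphs)
    ]:
        if a in graph and b in graph and nx.has_path(graph, a, b):
            return nx.shortest_path_length(graph, a, b), name
    return None, None


# ------------------------------------------------------------------ centrality


def eigenvector_centrality(
    g: nx.Graph, tol: float = 1e-10, max_iter: int = 1000
) -> dict[str, float]:
    """Per-component eigenvector centrality, max-normalized to 1.

    Power iteration runs on A + I (same dominant eigenvector as A on a
    connected component, but aperiodic, so bipartite-like components such as
    stars converge too). Each component's scores are divided by their maximum
    so the most central node of every component scores 1.0.
    """
    scores: dict[str, float] = {}
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        if len(nodes) == 1:
            scores[nodes[0]] = 1.0
            continue
        a = nx.to_numpy_array(g, nodelist=nodes) + np.eye(len(nodes))
        v = np.full(len(nodes), 1.0 / math.sqrt(len(nodes)))
        for it in range(max_iter):
            w = a @ v
            w /= np.linalg.norm(w)
            if np.linalg.norm(w - v) < tol:
                v = w
                break
            v = w
        else:
            raise RuntimeError(
                f"eigenvector centrality did not converge in {max_iter} iterations "
                f"(component size {len(nodes)}, residual {np.linalg.norm(a @ v / np.linalg.norm(a @ v) - v):.2e})"
            )
        v = np.abs(v)
        v /= v.max()
        scores.update(zip(nodes, v.tolist()))
    return scores


def second_neighborhood(g: nx.Graph, node: str) -> nx.Graph:
    """Induced subgraph on all nodes within shortest-path distance 2."""
    if node not in g:
        raise KeyError(node)
    reach = {node} | set(g[node])
    for nb in list(g[node]):
        reach.update(g[nb])
    return g.subgraph(reach).copy()


def evc_delta(g: nx.Graph, refprot_node: str) -> tuple[float, float]:
    """Eigenvector centrality of a gene node in its second neighborhood,
    with altProts included versus with all altProt nodes removed first."""
    if g.nodes[refprot_node].get("kind") != "gene":
        raise ValueError(f"{refprot_node!r} is not a gene node")

    def _evc_in_neighborhood(graph: nx.Graph) -> float:
        if refprot_node not in graph:
            return 1.0
        sub = second_neighborhood(graph, refprot_node)
        if len(sub) < 2:
            import warnings

            warnings.warn(f"second neighborhood of {refprot_node} is a singleton; EVC = 1.0")
            return 1.0
        return eigenvector_centrality(sub)[refprot_node]

    without_alt = g.subgraph(
        [n for n, d in g.nodes(data=True) if d.get("kind") != "altprot"]
    )
    return _evc_in_neighborhood(g), _evc_in_neighborhood(without_alt)


# ------------------------------------------------------------------ CORUM


def corum_recovery(
    g: nx.Graph, complexes: dict[str, set[str]], bait_set: set[str]
) -> pd.DataFrame:
    """Subunit recovery of known complexes around their baited subunits.

    Only complexes with >=2 subunits among the network's baits are scored;
    recovery is the fraction of subunits found in the union of the baited
    subunits' direct neighborhoods (baited subunits included). altProt nodes
    adjacent to baited subunits are reported alongside.
    """
    rows = []
    for cid, subunits in complexes.items():
        baited = sorted(s for s in subunits if s in bait_set and s in g)
        if len(baited) < 2:
            continue
        reach = set(baited)
        alt_neighbors: set[str] = set()
        for b in baited:
            for nb in g[b]:
                reach.add(nb)
                if g.nodes[nb].get("kind") == "altprot":
                    alt_neighbors.add(nb)
        recovered = subunits & reach
        rows.append(
            {
                "complex_id": cid,
                "n_subunits": len(subunits),
                "n_baited": len(baited),
                "n_recovered": len(recovered),
                "recovery": len(recovered) / len(subunits),
                "altprot_neighbors": ";".join(sorted(alt_neighbors)),
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ alignment

GAP_OPEN = 11
GAP_EXTEND = 1


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.mode = "global"
    # a gap of length L costs GAP_OPEN + GAP_EXTEND * L; end gaps are penalized
    a.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    a.extend_gap_score = -GAP_EXTEND
    return a


def nw_align(seq_a: str, seq_b: str) -> float:
    """Needleman-Wunsch global alignment score (BLOSUM62, affine gaps 11/1)."""
    for seq in (seq_a, seq_b):
        if set(seq) - set(AMINO_ACIDS):
            raise ValueError(f"invalid residues in {seq!r}")
    if not seq_a and not seq_b:
        raise ValueError("both sequences empty")
    if not seq_a or not seq_b:
        return -(GAP_OPEN + GAP_EXTEND * max(len(seq_a), len(seq_b)))
    return float(_aligner().score(seq_a, seq_b))


@dataclass
class AlignmentResult:
    altprot: str
    parent_gene: str
    nw_score: Optional[float]
    separation: Optional[int]
    separation_source: Optional[str]
    skipped: bool = False


def pseudogene_parent_table(
    g: nx.Graph,
    catalog: ProteinCatalog,
    fallback_graphs: Sequence[nx.Graph] = (),
) -> list[AlignmentResult]:
    """Alignment score and network separation for every pseudogene-derived
    altProt against its parental refProt."""
    results = []
    by_gene = {r.gene_id: r for r in catalog.by_category("refProt")}
    for rec in catalog.by_category("altProt"):
        if rec.parent_gene is None:
            continue
        parent = by_gene.get(rec.parent_gene)
        if parent is None or not parent.sequence:
            results.append(AlignmentResult(rec.accession, rec.parent_gene, None, None, None, skipped=True))
            continue
        score = nw_align(rec.sequence, parent.sequence)
        sep, source = pair_separation(g, (rec.accession, rec.parent_gene), fallback_graphs)
        results.append(AlignmentResult(rec.accession, rec.parent_gene, score, sep, source))
    return results


def alignment_frame(results: list[AlignmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
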