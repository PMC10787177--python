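"""Markov clustering and the enrichment analyses.

Clusters the HCIP network (inflation 2.0, clusters below 3 members dropped),
tests cluster-pair link enrichment, and runs disease and ontology-term
enrichment against small synthetic annotation tables derived from the planted
complexes (each planted complex seeds one "disease" and one leaf term).
"""

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from altppi.communities import (
    cluster_link_enrichment,
    disease_association,
    disease_class_summary,
    enrichment_frame,
    go_enrichment,
    mcl,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def build_graph() -> nx.Graph:
    edges = pd.read_csv(ROOT / "network_edges.tsv", sep="\t")
    nodes = pd.read_csv(ROOT / "network_nodes.tsv", sep="\t")
    g = nx.Graph()
    for row in nodes.itertuples(index=False):
        g.add_node(row.node, kind=row.kind)
    g.add_edges_from(zip(edges["node_a"], edges["node_b"]))
    return g


def synthetic_annotations(clusters, genes: set[str]):
    """One disease and one ontology leaf term per planted community.

    Stands in for curated disease-gene and gene-term tables, which this
    synthetic study has no real source for.
    """
    disease_rows = []
    gene2term: dict[str, set[str]] = {}
    dag = nx.DiGraph()
    dag.add_edge("TERM:root_bp", "TERM:root")
    for cid, members in sorted(clusters.clusters.items()):
        mg = sorted(set(members) & genes)
        did = f"DIS{cid:03d}"
        term = f"TERM:{cid:03d}"
        dag.add_edge(term, "TERM:root_bp")
        for gene in mg:
            disease_rows.append(
                {"disease_id": did, "disease_name": f"synthetic disease {cid}",
                 "disease_class": f"class{cid % 5}", "gene": gene}
            )
            gene2term.setdefault(gene, set()).add(term)
    return pd.DataFrame(disease_rows), dag, gene2term


def main() -> None:
    g = build_graph()
    clusters = mcl(g, inflation=2.0)
    clusters.write_tsv(ROOT / "clusters.tsv")
    sizes = sorted((len(m) for m in clusters.clusters.values()), reverse=True)
    print(f"MCL (inflation 2.0): {len(clusters.clusters)} clusters retained "
          f"(sizes {sizes[:5]}...), {len(clusters.discarded)} below 3 members")

    links = cluster_link_enrichment(g, clusters, alpha=0.05, fdr=0.01)
    enrichment_frame(links).to_csv(ROOT / "cluster_links.tsv", sep="\t", index=False)
    print(f"cluster-link enrichment: {sum(r.significant for r in links)} significant pairs "
          f"of {len(links)} tested")

    genes = {n for n, d in g.nodes(data=True) if d.get("kind") == "gene"}
    alt_nodes = set(g) - genes
    diseases, dag, gene2term = synthetic_annotations(clusters, genes)
    if len(diseases):
        assoc = disease_association(clusters, diseases, universe=genes, altprot_nodes=alt_nodes)
        enrichment_frame(assoc).to_csv(ROOT / "disease_associations.tsv", sep="\t", index=False)
        disease_class_summary(assoc).to_csv(ROOT / "disease_class_summary.tsv", sep="\t", index=False)
        print(f"disease association: {sum(r.significant for r in assoc)} significant "
              f"cluster-disease pairs of {len(assoc)} tested")

        terms = go_enrichment(clusters.clusters, dag, gene2term, background=genes)
        enrichment_frame(terms).to_csv(ROOT / "term_enrichment.tsv", sep="\t", index=False)
        n_sets = len({r.unit[0] for r in terms if r.significant})
        print(f"term enrichment: {n_sets}/{len(clusters.clusters)} clusters with a significant term")

    (ROOT / "communities_report.json").write_text(json.dumps({
        "n_clusters": len(clusters.clusters),
        "n_discarded": len(clusters.discarded),
        "significant_links": sum(r.significant for r in links),
    }, indent=2))


if __name__ == "__main__":
    main()
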