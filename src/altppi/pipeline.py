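"""End-to-end driver: simulate -> count -> score -> classify -> network -> cluster -> enrich.

One config (a :class:`PipelineConfig`, optionally loaded from YAML) runs the
whole analysis on synthetic data and writes every stage's tables to an output
directory. The planted ground truth doubles as the reference interaction list
for classifier labels and threshold metrics, and as the oracle for the
precision/recall summary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from altppi import compass, counts, hcip, network
from altppi.communities import cluster_link_enrichment, enrichment_frame, mcl
from altppi.hcip import metrics_frame, normalize_pairs
from altppi.simulate import SimulationParams, simulate_study, write_outputs


@dataclass
class PipelineConfig:
    params: SimulationParams = field(default_factory=SimulationParams)
    threshold_policy: str = "f1"
    mcl_inflation: float = 2.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        params = SimulationParams(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.get("simulation", {}).items()
        })
        return cls(
            params=params,
            threshold_policy=raw.get("threshold_policy", "f1"),
            mcl_inflation=float(raw.get("mcl_inflation", 2.0)),
        )


@dataclass
class PipelineResult:
    graph: "object"
    summary: dict
    hcip_pairs: set
    true_pairs: set
    clusters: "object"


def evaluate_against_truth(hcip_pairs: set, true_pairs: set, baited_entities: set) -> dict:
    """Precision/recall of classified pairs against the planted edges.

    Recall is computed over planted edges with at least one baited endpoint
    (the only edges the bait-centric design can observe).
    """
    observable = {e for e in true_pairs if e & baited_entities}
    tp = len(hcip_pairs & true_pairs)
    precision = tp / len(hcip_pairs) if hcip_pairs else 0.0
    recall = len(hcip_pairs & observable) / len(observable) if observable else 0.0
    return {
        "n_hcip": len(hcip_pairs),
        "n_true_observable": len(observable),
        "precision": precision,
        "recall": recall,
    }


def run_pipeline(config: PipelineConfig, outdir: Optional[str | Path] = None) -> PipelineResult:
    params = config.params
    catalog, truth, evidence, design = simulate_study(params)

    matrix = counts.count_matrix(evidence, catalog, design)
    stats = compass.compute_stats(matrix)
    features = compass.build_features(stats, matrix, design)

    reference = normalize_pairs(
        tuple(e) for e in truth.true_entity_edges(catalog)
    )
    posteriors = hcip.train_classifier(features, reference)
    curves = hcip.threshold_metrics(posteriors, reference)
    threshold = hcip.select_threshold(curves, policy=config.threshold_policy)
    classified, dropped_baits = hcip.classify(posteriors, threshold)

    graph = network.assemble(classified, catalog)
    hcip_pairs = {
        frozenset((r.bait_id, r.prey))
        for r in classified[classified["hcip"]].itertuples(index=False)
        if r.bait_id != r.prey
    }
    baits = set(design["bait_id"])
    summary = evaluate_against_truth(hcip_pairs, reference, baits)
    summary.update(
        {
            "threshold": threshold,
            "n_candidate_pairs": len(posteriors),
            "n_dropped_baits": len(dropped_baits),
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "n_altprot_nodes": sum(1 for _, d in graph.nodes(data=True) if d["kind"] == "altprot"),
        }
    )

    clusters = None
    links = []
    if graph.number_of_nodes() > 0:
        clusters = mcl(graph, inflation=config.mcl_inflation)
        summary["n_clusters"] = len(clusters.clusters)
        links = cluster_link_enrichment(graph, clusters)
        summary["n_significant_cluster_links"] = sum(1 for r in links if r.significant)
        if graph.number_of_nodes() >= 2:
            _, mean_sep, n_unreach = network.path_length_distribution(graph)
            summary["mean_separation"] = mean_sep
            summary["n_unreachable_pairs"] = n_unreach
        degrees = [d for _, d in graph.degree()]
        if len(degrees) >= 50 and len(set(degrees)) > 1:
            fit = network.fit_power_law(degrees, xmin=1)
            summary["powerlaw_alpha_xmin1"] = fit.alpha

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_outputs(outdir, catalog, truth, evidence, design)
        matrix.write_tsv(outdir / "counts.tsv")
        stats.to_csv(outdir / "compass_stats.tsv", sep="\t", index=False)
        features.to_csv(outdir / "features.tsv", sep="\t", index=False)
        posteriors.to_csv(outdir / "posteriors.tsv", sep="\t", index=False)
        metrics_frame(curves).to_csv(outdir / "threshold_curves.tsv", sep="\t", index=False)
        (outdir / "threshold.json").write_text(
            json.dumps({"threshold": threshold, "policy": config.threshold_policy,
                        "dropped_baits": dropped_baits}, indent=2)
        )
        network.write_graph(graph, outdir / "network_edges.tsv", outdir / "network_nodes.tsv")
        if clusters is not None:
            clusters.write_tsv(outdir / "clusters.tsv")
            enrichment_frame(links).to_csv(outdir / "cluster_links.tsv", sep="\t", index=False)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))

    return PipelineResult(graph, summary, hcip_pairs, reference, clusters)


# ------------------------------------------------------------------ schemas

OUTPUT_SCHEMAS = {
    "evidence.tsv": ["run_id", "bait_id", "plate_id", "replicate_index", "peptide", "psm_count", "matched_accessions"],
    "design.tsv": ["run_id", "bait_id", "plate_id", "replicate_index"],
    "catalog.tsv": ["accession", "gene_id", "category", "biotype", "transcript_id",
                    "orf_start", "orf_end", "cds_start", "cds_end", "parent_gene", "sequence"],
    "truth_edges.tsv": ["accession_a", "accession_b"],
    "counts.tsv": ["bait_id", "entity", "entity_kind", "replicate_index", "psm_count", "unique_peptides"],
    "compass_stats.tsv": ["bait_id", "prey", "prey_kind", "x_avg", "z", "wd", "entropy", "f", "p_rep", "k"],
    "features.tsv": ["bait_id", "prey", "prey_kind", "plate_id"] + compass.FEATURE_COLUMNS,
    "posteriors.tsv": ["bait_id", "prey", "posterior", "label"],
    "threshold_curves.tsv": ["threshold", "n_predicted", "jaccard", "precision", "recall", "f1"],
    "network_edges.tsv": ["node_a", "node_b", "provenance"],
    "network_nodes.tsv": ["node", "kind", "bait", "prey"],
    "clusters.tsv": ["cluster_id", "member"],
    "cluster_links.tsv": ["unit", "k", "K", "n", "N", "p_value", "q_value", "significant"],
}


def validate_outputs(outdir: str | Path) -> list[str]:
    """Check that every declared pipeline output exists with its columns.

    Returns a list of problems (empty when the layout is valid).
    """
    outdir = Path(outdir)
    problems = []
    for fname, columns in OUTPUT_SCHEMAS.items():
        path = outdir / fname
        if not path.exists():
            problems.append(f"missing output {fname}")
            continue
        try:
            df = pd.read_csv(path, sep="\t", nrows=5)
        except pd.errors.EmptyDataError:
            problems.append(f"unreadable output {fname}")
            continue
        missing = [c for c in columns if c not in df.columns]
        if missing:
            problems.append(f"{fname} lacks columns {missing}")
    for fname in ("threshold.json", "summary.json"):
        path = outdir / fname
        if not path.exists():
            problems.append(f"missing output {fname}")
        else:
            try:
                json.loads(path.read_text())
            except json.JSONDecodeError:
                problems.append(f"invalid JSON in {fname}")
    return problems
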