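"""Peptide-to-protein assignment rules, detection filters and gene aggregation.

The assignment rules reflect the asymmetry between annotated (refProt) and
alternative (altProt) proteins: spectra shared among refProts are counted for
each of them; spectra matching only altProts are counted for each altProt;
spectra shared between an altProt and at least one refProt are given to the
refProt(s) only. refProt counts are combined by gene; altProts stay separate
accession-level entities because many are encoded by genes that already
contain a refProt.

Peptides are compared after I/L normalization (isobaric in MS), and a peptide
is "unique" when it credits exactly one entity of its credited class (one gene
for refProts, one altProt accession otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from altppi.catalog import ProteinCatalog
from altppi.peptides import il_normalize


@dataclass
class SpectralCountMatrix:
    """Per (bait experiment, prey entity, replicate) PSM and unique-peptide counts."""

    entries: pd.DataFrame  # bait_id, entity, entity_kind, replicate_index, psm_count, unique_peptides
    design: pd.DataFrame  # run_id, bait_id, plate_id, replicate_index

    def baits(self) -> list[str]:
        return sorted(self.design["bait_id"].unique())

    def replicate_count(self) -> int:
        return int(self.design.groupby("bait_id")["replicate_index"].nunique().max())

    def write_tsv(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


def assign_spectra(evidence: pd.DataFrame, catalog: ProteinCatalog) -> pd.DataFrame:
    """Credit PSM counts to entities per run following the sharing rules.

    Returns a peptide-level table with one row per (run, peptide, credited
    entity): columns run_id, bait_id, plate_id, replicate_index, peptide,
    entity, entity_kind, psm_count, is_unique. Evidence rows whose peptides
    coincide after I/L normalization are merged first (counts summed, matched
    sets unioned).
    """
    if evidence.empty:
        return pd.DataFrame(
            columns=[
                "run_id", "bait_id", "plate_id", "replicate_index",
                "peptide", "entity", "entity_kind", "psm_count", "is_unique",
            ]
        )
    known = set(catalog.records)
    ev = evidence.copy()
    ev["peptide"] = ev["peptide"].map(il_normalize)

    merged: dict[tuple, dict] = {}
    for row in ev.itertuples(index=False):
        accs = tuple(row.matched_accessions.split(";")) if isinstance(row.matched_accessions, str) else tuple(row.matched_accessions)
        unknown = set(accs) - known
        if unknown:
            raise ValueError(f"unknown accessions in evidence: {sorted(unknown)}")
        key = (row.run_id, row.peptide)
        slot = merged.setdefault(
            key,
            {
                "bait_id": row.bait_id,
                "plate_id": row.plate_id,
                "replicate_index": row.replicate_index,
                "psm": 0,
                "accs": set(),
            },
        )
        slot["psm"] += int(row.psm_count)
        slot["accs"].update(accs)

    out = []
    for (run_id, peptide), slot in merged.items():
        ref_entities = sorted(
            {catalog[a].gene_id for a in slot["accs"] if catalog[a].category != "altProt"}
        )
        alt_entities = sorted(a for a in slot["accs"] if catalog[a].category == "altProt")
        if ref_entities:
            credited, kind = ref_entities, "gene"
        else:
            credited, kind = alt_entities, "altprot"
        unique = len(credited) == 1
        for ent in credited:
            out.append(
                {
                    "run_id": run_id,
                    "bait_id": slot["bait_id"],
                    "plate_id": slot["plate_id"],
                    "replicate_index": slot["replicate_index"],
                    "peptide": peptide,
                    "entity": ent,
                    "entity_kind": kind,
                    "psm_count": slot["psm"],
                    "is_unique": unique,
                }
            )
    return pd.DataFrame(out).sort_values(["run_id", "peptide", "entity"]).reset_index(drop=True)


def apply_detection_filters(credited: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Keep entities passing the per-bait-experiment detection thresholds.

    An altProt is detected when at least one of its unique peptides is seen in
    >=2 technical replicates of the same bait experiment. A refProt gene is
    detected when >=2 distinct unique peptides are seen (each in >=1
    replicate) and the gene is present in >=2 replicates. Bait experiments
    with fewer than two replicates are excluded with a warning.
    """
    reps_per_bait = design.groupby("bait_id")["replicate_index"].nunique()
    bad_baits = set(reps_per_bait[reps_per_bait < 2].index)
    if bad_baits:
        warnings.warn(f"excluding bait experiments with <2 replicates: {sorted(bad_baits)}")
    if credited.empty:
        return credited
    df = credited[~credited["bait_id"].isin(bad_baits)]

    keep_keys: set[tuple[str, str]] = set()
    for (bait, entity), grp in df.groupby(["bait_id", "entity"], sort=False):
        kind = grp["entity_kind"].iloc[0]
        uniq = grp[grp["is_unique"]]
        if kind == "altprot":
            reps_per_pep = uniq.groupby("peptide")["replicate_index"].nunique()
            if (reps_per_pep >= 2).any():
                keep_keys.add((bait, entity))
        else:
            n_unique_peps = uniq["peptide"].nunique()
            reps_present = grp["replicate_index"].nunique()
            if n_unique_peps >= 2 and reps_present >= 2:
                keep_keys.add((bait, entity))
    mask = [
        (b, e) in keep_keys
        for b, e in zip(df["bait_id"], df["entity"])
    ]
    return df[mask].reset_index(drop=True)


def aggregate_by_gene(credited: pd.DataFrame, design: pd.DataFrame) -> SpectralCountMatrix:
    """Collapse credited peptide rows to the (bait, entity, replicate) matrix.

    refProt/novel-isoform credits were already expressed at gene level by the
    assignment step, so aggregation sums peptide PSMs per entity per replicate
    and tallies distinct unique peptides.
    """
    cols = ["bait_id", "entity", "entity_kind", "replicate_index", "psm_count", "unique_peptides"]
    if credited.empty:
        return SpectralCountMatrix(entries=pd.DataFrame(columns=cols), design=design)
    keys = ["bait_id", "entity", "entity_kind", "replicate_index"]
    grouped = credited.groupby(keys, sort=True)["psm_count"].sum().reset_index()
    uniq = (
        credited[credited["is_unique"]]
        .groupby(keys, sort=True)["peptide"]
        .nunique()
        .rename("unique_peptides")
        .reset_index()
    )
    merged = grouped.merge(uniq, on=keys, how="left")
    merged["unique_peptides"] = merged["unique_peptides"].fillna(0).astype(int)
    return SpectralCountMatrix(entries=merged[cols], design=design)


def count_matrix(
    evidence: pd.DataFrame, catalog: ProteinCatalog, design: pd.DataFrame
) -> SpectralCountMatrix:
    """Full counting stage: assignment, detection filtering, gene aggregation."""
    credited = assign_spectra(evidence, catalog)
    detected = apply_detection_filters(credited, design)
    return aggregate_by_gene(detected, design)
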