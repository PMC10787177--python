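"""Shared fixtures: tiny catalogs, evidence fixtures and matrix builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from altppi.catalog import ProteinCatalog, ProteinRecord
from altppi.counts import SpectralCountMatrix

SEQ = "ACDEFGHKMNPQRSTVWYACDEFGHKMNPQRSTVWY"


def make_record(accession, gene, category="refProt", biotype="protein_coding",
                sequence=SEQ, parent=None):
    return ProteinRecord(
        accession=accession,
        gene_id=gene,
        category=category,
        biotype=biotype,
        sequence=sequence,
        transcript_id=f"T_{gene}",
        orf_interval=(0, 3 * (len(sequence) + 1)),
        cds_interval=(0, 3 * (len(sequence) + 1)) if category == "refProt" else None,
        parent_gene=parent,
    )


@pytest.fixture
def tiny_catalog() -> ProteinCatalog:
    """Two refProt genes and two altProts, enough for the sharing rules."""
    cat = ProteinCatalog()
    cat.add(make_record("P_GA", "GA"))
    cat.add(make_record("P_GB", "GB"))
    cat.add(make_record("IP_X", "AGX", category="altProt", biotype="ncRNA"))
    cat.add(make_record("IP_Y", "AGY", category="altProt", biotype="ncRNA"))
    return cat


@pytest.fixture
def shared_peptide_evidence() -> tuple[pd.DataFrame, pd.DataFrame]:
    """12 evidence rows covering all three sharing cases for one bait (GA).

    Cases: refProt-only (unique and shared between two genes), altProt-only
    (unique and shared between two altProts), mixed refProt+altProt, and an
    I/L-isobaric peptide pair that must merge within a run.
    """
    rows = [
        # run, rep, peptide, psm, matched
        ("GA_r1", 1, "AAAAAAAK", 3, "P_GA"),
        ("GA_r1", 1, "CCCCCCCK", 1, "P_GA"),
        ("GA_r1", 1, "DDDDDDDK", 4, "P_GA;P_GB"),
        ("GA_r1", 1, "EEEEEEEK", 5, "IP_X"),
        ("GA_r1", 1, "FFFFFFFK", 2, "IP_X;IP_Y"),
        ("GA_r1", 1, "GGGGGGGK", 6, "IP_X;P_GB"),
        ("GA_r1", 1, "HHHHHHIK", 1, "P_GB"),
        ("GA_r1", 1, "HHHHHHLK", 2, "P_GB"),
        ("GA_r2", 2, "AAAAAAAK", 2, "P_GA"),
        ("GA_r2", 2, "CCCCCCCK", 1, "P_GA"),
        ("GA_r2", 2, "EEEEEEEK", 3, "IP_X"),
        ("GA_r2", 2, "GGGGGGGK", 4, "IP_X;P_GB"),
    ]
    evidence = pd.DataFrame(
        [
            {
                "run_id": run,
                "bait_id": "GA",
                "plate_id": "plate00",
                "replicate_index": rep,
                "peptide": pep,
                "psm_count": psm,
                "matched_accessions": acc,
            }
            for run, rep, pep, psm, acc in rows
        ]
    )
    design = pd.DataFrame(
        [
            {"run_id": "GA_r1", "bait_id": "GA", "plate_id": "plate00", "replicate_index": 1},
            {"run_id": "GA_r2", "bait_id": "GA", "plate_id": "plate00", "replicate_index": 2},
        ]
    )
    return evidence, design


def matrix_from_counts(counts: np.ndarray) -> SpectralCountMatrix:
    """Build a SpectralCountMatrix straight from a (baits, preys, reps) array."""
    n_baits, n_preys, n_reps = counts.shape
    baits = [f"b{i:02d}" for i in range(n_baits)]
    preys = [f"prey{j:02d}" for j in range(n_preys)]
    entries = []
    for i, bait in enumerate(baits):
        for j, prey in enumerate(preys):
            for r in range(n_reps):
                c = int(counts[i, j, r])
                if c > 0:
                    entries.append(
                        {
                            "bait_id": bait,
                            "entity": prey,
                            "entity_kind": "gene",
                            "replicate_index": r + 1,
                            "psm_count": c,
                            "unique_peptides": 1,
                        }
                    )
    design = pd.DataFrame(
        [
            {
                "run_id": f"{bait}_r{r + 1}",
                "bait_id": bait,
                "plate_id": f"plate{i // 4}",
                "replicate_index": r + 1,
            }
            for i, bait in enumerate(baits)
            for r in range(n_reps)
        ]
    )
    return SpectralCountMatrix(entries=pd.DataFrame(entries), design=design)
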