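"""Protein catalog: refProt/altProt records, biotypes and ORF-interval logic.

Intervals are 0-based half-open throughout: ``(start, end)`` covers positions
``start .. end-1`` in transcript coordinates, so touching intervals such as
``(10, 100)`` and ``(100, 200)`` do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

CATEGORIES = ("refProt", "altProt", "novel_isoform")
BIOTYPES = ("protein_coding", "pseudogene", "ncRNA")


def _check_interval(iv: tuple[int, int], name: str = "interval") -> None:
    start, end = iv
    if start >= end:
        raise ValueError(f"malformed {name}: start={start} >= end={end}")
    if start < 0:
        raise ValueError(f"malformed {name}: negative start {start}")


def classify_coding_structure(orf_a: tuple[int, int], orf_b: tuple[int, int]) -> str:
    """Classify a transcript carrying two ORFs as ``dual_coding`` or ``bicistronic``.

    Two ORFs on the same transcript that share at least one nucleotide make the
    transcript dual coding; sequential (disjoint) ORFs make it bicistronic.
    """
    _check_interval(orf_a, "orf_a")
    _check_interval(orf_b, "orf_b")
    overlap = min(orf_a[1], orf_b[1]) - max(orf_a[0], orf_b[0])
    return "dual_coding" if overlap > 0 else "bicistronic"


def classify_altorf_location(
    cds: Optional[tuple[int, int]], altorf: tuple[int, int]
) -> str:
    """Locate an altORF relative to the canonical CDS of its transcript.

    Returns ``ncrna`` when the transcript has no annotated CDS, ``cds_overlap``
    when the altORF shares nucleotides with the CDS, ``5utr`` when it ends
    before the CDS starts and ``3utr`` when it starts after the CDS ends.
    """
    _check_interval(altorf, "altorf")
    if cds is None:
        return "ncrna"
    _check_interval(cds, "cds")
    overlap = min(cds[1], altorf[1]) - max(cds[0], altorf[0])
    if overlap > 0:
        return "cds_overlap"
    return "5utr" if altorf[1] <= cds[0] else "3utr"


@dataclass
class ProteinRecord:
    accession: str
    gene_id: str
    category: str  # refProt | altProt | novel_isoform
    biotype: str  # protein_coding | pseudogene | ncRNA
    sequence: str
    transcript_id: str
    orf_interval: tuple[int, int]
    cds_interval: Optional[tuple[int, int]] = None
    parent_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if not self.sequence or set(self.sequence) - set(AMINO_ACIDS):
            raise ValueError(f"invalid sequence for {self.accession}")
        if self.parent_gene is not None and self.biotype != "pseudogene":
            raise ValueError("parent_gene is only meaningful for pseudogene biotype")


@dataclass
class ProteinCatalog:
    """Accession-keyed protein records with refProt/altProt semantics."""

    records: dict[str, ProteinRecord] = field(default_factory=dict)

    def add(self, record: ProteinRecord) -> None:
        if record.accession in self.records:
            raise ValueError(f"duplicate accession {record.accession}")
        self.records[record.accession] = record

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, accession: str) -> bool:
        return accession in self.records

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self.records[accession]

    def accessions(self) -> list[str]:
        return list(self.records)

    def by_category(self, category: str) -> list[ProteinRecord]:
        return [r for r in self.records.values() if r.category == category]

    def gene_of(self, accession: str) -> str:
        return self.records[accession].gene_id

    def entity_of(self, accession: str) -> str:
        """Network entity id: gene for refProts/isoforms, accession for altProts."""
        rec = self.records[accession]
        return rec.accession if rec.category == "altProt" else rec.gene_id

    def entity_kind(self, entity: str) -> str:
        if entity in self.records and self.records[entity].category == "altProt":
            return "altprot"
        return "gene"

    def genes(self) -> set[str]:
        return {r.gene_id for r in self.records.values()}

    # ---------------------------------------------------------------- I/O

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records.values():
            rows.append(
                {
                    "accession": r.accession,
                    "gene_id": r.gene_id,
                    "category": r.category,
                    "biotype": r.biotype,
                    "transcript_id": r.transcript_id,
                    "orf_start": r.orf_interval[0],
                    "orf_end": r.orf_interval[1],
                    "cds_start": r.cds_interval[0] if r.cds_interval else -1,
                    "cds_end": r.cds_interval[1] if r.cds_interval else -1,
                    "parent_gene": r.parent_gene or "",
                    "sequence": r.sequence,
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records.values():
                fh.write(f">{r.accession} gene={r.gene_id} category={r.category}\n")
                seq = r.sequence
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProteinCatalog":
        cat = cls()
        for row in df.itertuples(index=False):
            cds = None
            if row.cds_start >= 0:
                cds = (int(row.cds_start), int(row.cds_end))
            parent = row.parent_gene if isinstance(row.parent_gene, str) and row.parent_gene else None
            cat.add(
                ProteinRecord(
                    accession=row.accession,
                    gene_id=row.gene_id,
                    category=row.category,
                    biotype=row.biotype,
                    sequence=row.sequence,
                    transcript_id=row.transcript_id,
                    orf_interval=(int(row.orf_start), int(row.orf_end)),
                    cds_interval=cds,
                    parent_gene=parent,
                )
            )
        return cat

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ProteinCatalog":
        return cls.from_frame(pd.read_csv(path, sep="\t", keep_default_na=False))
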