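"""Synthetic AP-MS study generator.

Emulates the statistical structure of a BioPlex-style AP-MS screen searched
against a catalog that contains both annotated proteins (refProts) and
unannotated alternative proteins (altProts):

- planted multi-protein complexes probed by baits in >=2 technical replicates
  arranged on plates;
- overdispersed (negative binomial) PSM counts for true interactors, with the
  bait itself the most abundant protein in its own runs;
- frequency-weighted "sticky" contaminants with per-run detection
  probabilities and low background counts;
- tryptic peptides shared between pseudogene-derived altProts and their
  parental refProts (mutated-and-truncated copies of the parental sequence),
  which is what drives the downstream spectrum-assignment rules;
- altProt annotation structure: pseudogene-derived, dual-coding/bicistronic
  partners on refProt transcripts, and ncRNA-derived.

Random streams are split per subcomponent (catalog / ground truth / design /
counts) so that changing one parameter does not reshuffle unrelated draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from altppi.catalog import AMINO_ACIDS, ProteinCatalog, ProteinRecord
from altppi.peptides import digest

# ------------------------------------------------------------------ params


@dataclass
class SimulationParams:
    """Knobs of the synthetic study; defaults define the default scenario."""

    n_genes: int = 300
    n_baits: int = 100
    n_complexes: int = 20
    complex_size_range: tuple[int, int] = (4, 8)
    replicate_count: int = 2
    plate_size: int = 96
    frac_pseudogene_altprots: float = 0.08
    frac_dualcoding_altprots: float = 0.05
    frac_ncrna_altprots: float = 0.04
    negbin_mean_true: float = 30.0
    negbin_dispersion: float = 3.0
    contaminant_pool_size: int = 50
    contaminant_stickiness_distribution: tuple = ("lognormal", -2.2, 1.0)
    pseudogene_mutation_rate: float = 0.1
    altprot_complex_prob: float = 0.5
    refprot_length_range: tuple[int, int] = (200, 800)
    altprot_length_range: tuple[int, int] = (30, 150)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_baits", "n_complexes", "plate_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        fracs = (
            self.frac_pseudogene_altprots,
            self.frac_dualcoding_altprots,
            self.frac_ncrna_altprots,
        )
        if any(f < 0 for f in fracs) or sum(fracs) > 1:
            raise ValueError("altProt fractions must be >=0 and sum to <=1")
        if self.replicate_count < 2:
            raise ValueError("replicate_count must be >=2 (detection rules need two technical replicates)")
        if self.contaminant_pool_size < 0:
            raise ValueError("contaminant_pool_size must be >=0")
        if not 0 <= self.pseudogene_mutation_rate <= 1:
            raise ValueError("pseudogene_mutation_rate must be in [0,1]")

    def _streams(self) -> dict[str, np.random.Generator]:
        kids = np.random.SeedSequence(self.seed).spawn(4)
        names = ("catalog", "truth", "design", "counts")
        return {n: np.random.default_rng(k) for n, k in zip(names, kids)}


# ------------------------------------------------------------------ catalog


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0:
        return seq
    out = list(seq)
    hits = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hits):
        out[i] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
    return "".join(out)


def generate_catalog(params: SimulationParams) -> ProteinCatalog:
    """Generate a protein catalog with refProts and structured altProts.

    One refProt per gene (lengths drawn from ``refprot_length_range``);
    altProts are much shorter (``altprot_length_range``) and partitioned into
    pseudogene-derived (mutated, truncated copies of a parental refProt),
    dual-coding/bicistronic partners hosted on refProt transcripts, and
    ncRNA-derived proteins.
    """
    params.validate()
    rng = params._streams()["catalog"]
    cat = ProteinCatalog()

    genes = [f"GENE{i:04d}" for i in range(params.n_genes)]
    utr5 = 100  # nt of 5'UTR before each canonical CDS
    for g in genes:
        length = int(rng.integers(*params.refprot_length_range))
        cds = (utr5, utr5 + 3 * (length + 1))
        cat.add(
            ProteinRecord(
                accession=f"P_{g}",
                gene_id=g,
                category="refProt",
                biotype="protein_coding",
                sequence=_random_sequence(rng, length),
                transcript_id=f"T_{g}",
                orf_interval=cds,
                cds_interval=cds,
            )
        )

    n_pseudo = round(params.frac_pseudogene_altprots * params.n_genes)
    n_dual = round(params.frac_dualcoding_altprots * params.n_genes)
    n_ncrna = round(params.frac_ncrna_altprots * params.n_genes)
    ip_counter = 100000

    # pseudogene-derived: mutate the parental sequence, then truncate to an
    # altProt-like window, so tryptic peptides are shared with the parent
    parents = rng.choice(genes, size=n_pseudo, replace=False) if n_pseudo else []
    for k, parent in enumerate(parents):
        parent_seq = cat[f"P_{parent}"].sequence
        alt_len = int(rng.integers(*params.altprot_length_range))
        alt_len = min(alt_len, len(parent_seq))
        mutated = _mutate(rng, parent_seq, params.pseudogene_mutation_rate)
        start = int(rng.integers(0, len(mutated) - alt_len + 1))
        gene = f"PSEUDO{k:04d}"
        cat.add(
            ProteinRecord(
                accession=f"IP_{ip_counter}",
                gene_id=gene,
                category="altProt",
                biotype="pseudogene",
                sequence=mutated[start : start + alt_len],
                transcript_id=f"T_{gene}",
                orf_interval=(0, 3 * (alt_len + 1)),
                parent_gene=parent,
            )
        )
        ip_counter += 1

    # dual-coding / bicistronic partners on refProt transcripts
    remaining = [g for g in genes if g not in set(parents)]
    hosts = rng.choice(remaining, size=n_dual, replace=False) if n_dual else []
    for host in hosts:
        ref = cat[f"P_{host}"]
        cds = ref.cds_interval
        alt_len = int(rng.integers(*params.altprot_length_range))
        alt_nt = 3 * (alt_len + 1)
        if rng.random() < 0.5:  # dual coding: altORF overlaps the CDS
            start = int(rng.integers(cds[0] + 1, cds[1] - 1))
        else:  # bicistronic: altORF downstream in the 3'UTR
            start = cds[1] + int(rng.integers(1, 50))
        cat.add(
            ProteinRecord(
                accession=f"IP_{ip_counter}",
                gene_id=host,
                category="altProt",
                biotype="protein_coding",
                sequence=_random_sequence(rng, alt_len),
                transcript_id=ref.transcript_id,
                orf_interval=(start, start + alt_nt),
                cds_interval=cds,
            )
        )
        ip_counter += 1

    for k in range(n_ncrna):
        alt_len = int(rng.integers(*params.altprot_length_range))
        gene = f"NCGENE{k:04d}"
        cat.add(
            ProteinRecord(
                accession=f"IP_{ip_counter}",
                gene_id=gene,
                category="altProt",
                biotype="ncRNA",
                sequence=_random_sequence(rng, alt_len),
                transcript_id=f"T_{gene}",
                orf_interval=(10, 10 + 3 * (alt_len + 1)),
            )
        )
        ip_counter += 1

    return cat


# ------------------------------------------------------------------ truth


@dataclass
class GroundTruth:
    """Planted interactome and background model behind a simulated study."""

    complexes: list[set[str]]
    true_edges: set[frozenset[str]]
    contaminant_profile: dict[str, tuple[float, float]]  # acc -> (detect prob, mean bg PSM)
    abundance: dict[str, float]
    params: SimulationParams
    seed: int

    def validate(self, catalog: ProteinCatalog) -> None:
        for cx in self.complexes:
            missing = cx - set(catalog.records)
            if missing:
                raise ValueError(f"complex members missing from catalog: {missing}")
        for _, (p, _m) in self.contaminant_profile.items():
            if not 0 <= p <= 1:
                raise ValueError("contaminant detection probability outside [0,1]")

    def true_entity_edges(self, catalog: ProteinCatalog) -> set[frozenset[str]]:
        """Planted edges mapped to network entities (genes / altProt accessions)."""
        out = set()
        for e in self.true_edges:
            a, b = tuple(e)
            ea, eb = catalog.entity_of(a), catalog.entity_of(b)
            if ea != eb:
                out.add(frozenset((ea, eb)))
        return out


def generate_ground_truth(catalog: ProteinCatalog, params: SimulationParams) -> GroundTruth:
    """Plant complexes (clique-expanded to true edges) and a contaminant pool."""
    params.validate()
    rng = params._streams()["truth"]

    ref_accs = sorted(r.accession for r in catalog.by_category("refProt"))
    pseudo_alts: dict[str, list[str]] = {}
    for r in catalog.by_category("altProt"):
        if r.parent_gene is not None:
            pseudo_alts.setdefault(r.parent_gene, []).append(r.accession)

    lo, hi = params.complex_size_range
    sizes = rng.integers(lo, hi + 1, size=params.n_complexes)
    if sizes.sum() > len(ref_accs):
        raise ValueError("not enough genes for the requested complexes")
    pool = list(rng.permutation(ref_accs))
    complexes: list[set[str]] = []
    for s in sizes:
        members = {pool.pop() for _ in range(int(s))}
        # pseudogene-derived altProts may join their parent's complex
        for acc in sorted(members):
            parent = catalog[acc].gene_id
            for alt in sorted(pseudo_alts.get(parent, [])):
                if rng.random() < params.altprot_complex_prob:
                    members.add(alt)
        complexes.append(members)

    true_edges = {
        frozenset((a, b))
        for cx in complexes
        for a in cx
        for b in cx
        if a < b
    }

    in_complex = set().union(*complexes) if complexes else set()
    bg_candidates = [a for a in ref_accs if a not in in_complex] or ref_accs
    n_cont = min(params.contaminant_pool_size, len(bg_candidates))
    cont_accs = rng.choice(bg_candidates, size=n_cont, replace=False) if n_cont else []
    dist_name, *dist_args = params.contaminant_stickiness_distribution
    profile: dict[str, tuple[float, float]] = {}
    for acc in cont_accs:
        if dist_name == "lognormal":
            stick = float(np.clip(rng.lognormal(*dist_args), 0.0, 0.8))
        elif dist_name == "uniform":
            stick = float(rng.uniform(*dist_args))
        else:
            raise ValueError(f"unknown stickiness distribution {dist_name!r}")
        profile[str(acc)] = (stick, 1.0 + 6.0 * stick)

    abundance = {a: float(rng.lognormal(0.0, 0.5)) for a in sorted(catalog.records)}
    gt = GroundTruth(
        complexes=complexes,
        true_edges=true_edges,
        contaminant_profile=profile,
        abundance=abundance,
        params=params,
        seed=params.seed,
    )
    gt.validate(catalog)
    return gt


# ------------------------------------------------------------------ AP-MS


@dataclass
class PeptideEvidence:
    """One search-result row: a peptide observed in one run."""

    run_id: str
    bait_id: str  # bait gene
    plate_id: str
    replicate_index: int
    peptide: str
    psm_count: int
    matched_accessions: tuple[str, ...]


def build_peptide_index(catalog: ProteinCatalog) -> dict[str, tuple[str, ...]]:
    """Map every tryptic peptide in the catalog to ALL proteins containing it.

    Containment is plain substring containment, so peptides of a pseudogene
    product that survive inside the parental sequence (or vice versa) match
    both proteins even when flanking cleavage context differs.
    """
    peptides: set[str] = set()
    digests: dict[str, list[str]] = {}
    for acc, rec in catalog.records.items():
        peps = digest(rec.sequence)
        digests[acc] = peps
        peptides.update(peps)
    lengths = sorted({len(p) for p in peptides})
    matched: dict[str, set[str]] = {p: set() for p in peptides}
    for acc, rec in catalog.records.items():
        seq = rec.sequence
        n = len(seq)
        for i in range(n):
            for L in lengths:
                if i + L > n:
                    break
                sub = seq[i : i + L]
                if sub in matched:
                    matched[sub].add(acc)
    return {p: tuple(sorted(s)) for p, s in matched.items()}


def _negbin(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def make_design(params: SimulationParams, truth: GroundTruth, catalog: ProteinCatalog) -> pd.DataFrame:
    """Choose baits (complex-member genes) and assign them to plates/replicates."""
    rng = params._streams()["design"]
    member_genes = sorted(
        {catalog[a].gene_id for cx in truth.complexes for a in cx if catalog[a].category == "refProt"}
    )
    if not member_genes:
        raise ValueError("no complexes to draw baits from")
    if params.n_baits <= len(member_genes):
        baits = list(rng.choice(member_genes, size=params.n_baits, replace=False))
    else:
        extra_pool = sorted(set(f"GENE{i:04d}" for i in range(params.n_genes)) - set(member_genes))
        extra = list(rng.choice(extra_pool, size=params.n_baits - len(member_genes), replace=False))
        baits = member_genes + extra
    # distribute baits evenly (round-robin) over the minimum number of plates:
    # filling plates sequentially can leave a near-empty last plate, which
    # would make the plate-batch cross-validation folds degenerate (a fold's
    # training complement must remain a usable sample)
    n_plates = -(-len(baits) // params.plate_size)
    rows = []
    for i, bait in enumerate(baits):
        plate = f"plate{i % n_plates:02d}"
        for rep in range(1, params.replicate_count + 1):
            rows.append(
                {
                    "run_id": f"{bait}_r{rep}",
                    "bait_id": bait,
                    "plate_id": plate,
                    "replicate_index": rep,
                }
            )
    return pd.DataFrame(rows)


def simulate_apms(
    truth: GroundTruth,
    catalog: ProteinCatalog,
    design: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate peptide evidence for every run in the design.

    Per bait run: the bait protein and its planted complex co-members receive
    negative binomial PSM counts scaled by abundance; contaminants appear per
    their profile; each protein's total is spread multinomially over its
    tryptic peptides; a peptide row's matched accessions are all catalog
    proteins containing the peptide as a substring.

    Returns ``(evidence, design)`` data frames. Evidence columns: run_id,
    bait_id, plate_id, replicate_index, peptide, psm_count,
    matched_accessions (semicolon-joined).
    """
    params = truth.params
    truth.validate(catalog)
    if design is None:
        design = make_design(params, truth, catalog)
    bad = set(design["bait_id"]) - catalog.genes()
    if bad:
        raise ValueError(f"baits not in catalog: {sorted(bad)}")
    rng = params._streams()["counts"]
    index = build_peptide_index(catalog)
    digests = {acc: digest(rec.sequence) for acc, rec in catalog.records.items()}

    partners: dict[str, set[str]] = {}
    for cx in truth.complexes:
        for a in cx:
            partners.setdefault(a, set()).update(cx - {a})

    rows: list[dict] = []
    for run in design.itertuples(index=False):
        bait_acc = f"P_{run.bait_id}"
        protein_counts: dict[str, int] = {}
        mean_bait = 3.0 * params.negbin_mean_true * truth.abundance.get(bait_acc, 1.0)
        protein_counts[bait_acc] = max(1, _negbin(rng, mean_bait, params.negbin_dispersion))
        for prey in sorted(partners.get(bait_acc, ())):
            c = _negbin(rng, params.negbin_mean_true * truth.abundance[prey], params.negbin_dispersion)
            if c > 0:
                protein_counts[prey] = protein_counts.get(prey, 0) + c
        for acc, (p_detect, bg_mean) in sorted(truth.contaminant_profile.items()):
            if rng.random() < p_detect:
                c = max(1, _negbin(rng, bg_mean, params.negbin_dispersion))
                protein_counts[acc] = protein_counts.get(acc, 0) + c

        peptide_counts: dict[str, int] = {}
        for acc, total in protein_counts.items():
            peps = digests[acc]
            if not peps or total == 0:
                continue
            alloc = rng.multinomial(total, np.full(len(peps), 1.0 / len(peps)))
            for pep, c in zip(peps, alloc):
                if c > 0:
                    peptide_counts[pep] = peptide_counts.get(pep, 0) + int(c)

        for pep in sorted(peptide_counts):
            rows.append(
                {
                    "run_id": run.run_id,
                    "bait_id": run.bait_id,
                    "plate_id": run.plate_id,
                    "replicate_index": run.replicate_index,
                    "peptide": pep,
                    "psm_count": peptide_counts[pep],
                    "matched_accessions": ";".join(index[pep]),
                }
            )
    return pd.DataFrame(rows), design


def simulate_study(params: SimulationParams) -> tuple[ProteinCatalog, GroundTruth, pd.DataFrame, pd.DataFrame]:
    """Catalog + ground truth + evidence + design in one call (the default scenario)."""
    catalog = generate_catalog(params)
    truth = generate_ground_truth(catalog, params)
    evidence, design = simulate_apms(truth, catalog)
    return catalog, truth, evidence, design


# ------------------------------------------------------------------ I/O


def write_outputs(
    outdir: str | Path,
    catalog: ProteinCatalog,
    truth: GroundTruth,
    evidence: pd.DataFrame,
    design: pd.DataFrame,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog.write_tsv(outdir / "catalog.tsv")
    catalog.write_fasta(outdir / "catalog.fasta")
    evidence.to_csv(outdir / "evidence.tsv", sep="\t", index=False)
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    edges = pd.DataFrame(
        [sorted(e) for e in sorted(truth.true_edges, key=sorted)],
        columns=["accession_a", "accession_b"],
    )
    edges.to_csv(outdir / "truth_edges.tsv", sep="\t", index=False)


def read_evidence_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)
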