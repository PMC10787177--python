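"""Apply the spectrum-assignment rules and detection filters.

Reads results/study/, writes the (bait, entity, replicate) spectral-count
matrix to results/counts.tsv and reports how many entities survive the
detection thresholds.
"""

from pathlib import Path

import pandas as pd

from altppi.catalog import ProteinCatalog
from altppi.counts import count_matrix
from altppi.simulate import read_evidence_tsv

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    catalog = ProteinCatalog.read_tsv(ROOT / "study" / "catalog.tsv")
    evidence = read_evidence_tsv(ROOT / "study" / "evidence.tsv")
    design = pd.read_csv(ROOT / "study" / "design.tsv", sep="\t")
    matrix = count_matrix(evidence, catalog, design)
    matrix.write_tsv(ROOT / "counts.tsv")
    ents = matrix.entries
    n_gene = ents.loc[ents.entity_kind == "gene", "entity"].nunique()
    n_alt = ents.loc[ents.entity_kind == "altprot", "entity"].nunique()
    print(f"detected entities: {n_gene} genes, {n_alt} altProts "
          f"({len(ents)} matrix entries) -> {ROOT / 'counts.tsv'}")


if __name__ == "__main__":
    main()
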