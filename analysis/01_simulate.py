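"""Generate the default synthetic AP-MS study.

Writes the protein catalog (TSV + FASTA), the planted true-edge list, the
plate/replicate design and the peptide evidence table under results/study/.
"""

from pathlib import Path

from altppi.pipeline import PipelineConfig
from altppi.simulate import simulate_study, write_outputs

OUT = Path(__file__).resolve().parents[1] / "results" / "study"


def main(seed: int = 1) -> None:
    cfg = PipelineConfig()
    cfg.params.seed = seed
    catalog, truth, evidence, design = simulate_study(cfg.params)
    write_outputs(OUT, catalog, truth, evidence, design)
    n_alt = len(catalog.by_category("altProt"))
    print(f"catalog: {len(catalog)} proteins ({n_alt} altProts)")
    print(f"planted: {len(truth.complexes)} complexes, {len(truth.true_edges)} true edges")
    print(f"evidence: {len(evidence)} peptide rows across {design['run_id'].nunique()} runs -> {OUT}")


if __name__ == "__main__":
    main()
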