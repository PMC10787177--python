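"""In-silico tryptic digestion and peptide identity conventions.

Digestion mirrors common high-throughput search settings: cleavage C-terminal
to K/R except before proline, up to two missed cleavages, peptide length
restricted to 8-30 residues. Peptide identity treats isoleucine and leucine as
indistinguishable (isobaric in MS).
"""

from __future__ import annotations

from pyteomics import parser as _pyt_parser

MIN_PEPTIDE_LEN = 8
MAX_PEPTIDE_LEN = 30
MAX_MISSED_CLEAVAGES = 2


def digest(
    sequence: str,
    missed_cleavages: int = MAX_MISSED_CLEAVAGES,
    min_length: int = MIN_PEPTIDE_LEN,
    max_length: int = MAX_PEPTIDE_LEN,
) -> list[str]:
    """Tryptic peptides of ``sequence``, sorted, after the length filter."""
    if not sequence:
        raise ValueError("empty sequence")
    peps = _pyt_parser.cleave(sequence, "trypsin", missed_cleavages=missed_cleavages)
    return sorted(p for p in peps if min_length <= len(p) <= max_length)


def il_normalize(peptide: str) -> str:
    """Collapse I/L so isobaric peptides compare equal."""
    return peptide.replace("I", "L")
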