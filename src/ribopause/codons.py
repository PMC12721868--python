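"""Codon alphabets and translation helpers.

Sequences are handled in DNA form (T, not U) throughout the package; the 61
sense codons are ordered lexicographically over A < C < G < T so that matrix
axes are stable across modules.
"""

from __future__ import annotations

from itertools import product

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"

ALL_CODONS: tuple[str, ...] = tuple("".join(c) for c in product(BASES, repeat=3))
STOP_CODONS: tuple[str, ...] = tuple(sorted(standard_dna_table.stop_codons))
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
SENSE_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
START_CODON = "ATG"

GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(GENETIC_CODE.values())))


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon; '*' for a stop codon."""
    if codon in GENETIC_CODE:
        return GENETIC_CODE[codon]
    if codon in STOP_CODONS:
        return "*"
    raise KeyError(f"not a DNA codon: {codon!r}")


def is_sense(codon: str) -> bool:
    return codon in SENSE_INDEX
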