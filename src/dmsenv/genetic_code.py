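"""Standard genetic code (NCBI translation table 1) and degenerate-codon helpers."""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, stop codons mapped to ``*``
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: the 32 NNK codons (third base G or T)
NNK_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "GT"
)

STANDARD_AAS = "ACDEFGHIKLMNPQRSTVWY"


def translate_codon(codon: str) -> str:
    """Translate a single codon; ``X`` for codons containing ambiguous bases."""
    codon = codon.upper()
    if codon in CODON_TO_AA:
        return CODON_TO_AA[codon]
    if len(codon) != 3:
        raise ValueError(f"not a codon: {codon!r}")
    return "X"


def translate_cds(seq: str) -> str:
    if len(seq) % 3:
        raise ValueError("coding sequence length not divisible by 3")
    return "".join(translate_codon(seq[i : i + 3]) for i in range(0, len(seq), 3))
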