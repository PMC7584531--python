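"""Vertebrate mitochondrial genetic code (NCBI translation table 2).

The table is hard-coded: it differs from the standard code at TGA (Trp,
not stop), ATA (Met, not Ile) and AGA/AGG (stop, not Arg). Incomplete
stop codons completed by polyadenylation do not matter for single-base
substitution effect calls and are ignored throughout.
"""

from __future__ import annotations

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_BASES = "TCAG"

# Standard-code amino acids in TCAG codon order, then the mito overrides.
_STANDARD = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)

VERTEBRATE_MITO_CODE: dict[str, str] = {}
for _i, _aa in enumerate(_STANDARD):
    _codon = _BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]
    VERTEBRATE_MITO_CODE[_codon] = _aa
VERTEBRATE_MITO_CODE["TGA"] = "W"
VERTEBRATE_MITO_CODE["ATA"] = "M"
VERTEBRATE_MITO_CODE["AGA"] = "*"
VERTEBRATE_MITO_CODE["AGG"] = "*"

AA_THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}


def complement(base: str) -> str:
    try:
        return COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"not a DNA base: {base!r}") from None


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def translate_codon(codon: str) -> str:
    """One-letter amino acid (or ``*``) for a sense-strand codon."""
    codon = codon.upper()
    if codon not in VERTEBRATE_MITO_CODE:
        raise ValueError(f"not a valid codon: {codon!r}")
    return VERTEBRATE_MITO_CODE[codon]


def translate(seq: str) -> str:
    """Translate a sense-strand ORF, ignoring any trailing partial codon."""
    return "".join(
        translate_codon(seq[i : i + 3]) for i in range(0, len(seq) - 2, 3)
    )
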