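"""Builder for the packaged synthetic rCRS-like reference scaffold.

The packaged reference is **synthetic**: it is not the NC_012920 sequence.
It keeps the canonical NC_012920 gene coordinates (with three 1–3 bp
boundary simplifications so that only the two classic protein-coding
overlaps, MT-ATP8/MT-ATP6 and MT-ND4L/MT-ND4, remain) and pins the
reference base/codon at every position referenced by the packaged
haplogroup tree or by documented LHON-associated variants, so that
effect annotation of those variants yields the protein changes reported
for the real rCRS (e.g. m.9055G>A → p.Ala177Thr, m.14167C>T → p.Glu169=
on the light-strand MT-ND6). Everywhere else the sequence is a stop-free
filler: protein-coding genes carry a CTA(-Leu) repeat in their own
reading frame, other positions an ACGT cycle.

Regenerate the packaged data files with ``python -m mitovar.refdata``.
"""

from __future__ import annotations

from pathlib import Path

from .genetic_code import COMPLEMENT, translate

GENOME_LENGTH = 16569

#: locus, start, end (1-based inclusive), strand, product_class.
#: The control region wraps the origin and is listed as two segments.
GENES: list[tuple[str, int, int, str, str]] = [
    ("MT-CR", 16024, 16569, "heavy", "noncoding"),
    ("MT-CR", 1, 576, "heavy", "noncoding"),
    ("MT-TF", 577, 647, "heavy", "tRNA"),
    ("MT-RNR1", 648, 1601, "heavy", "rRNA"),
    ("MT-TV", 1602, 1670, "heavy", "tRNA"),
    ("MT-RNR2", 1671, 3229, "heavy", "rRNA"),
    ("MT-TL1", 3230, 3304, "heavy", "tRNA"),
    ("MT-ND1", 3307, 4262, "heavy", "complexI"),
    ("MT-TI", 4263, 4331, "heavy", "tRNA"),
    ("MT-TQ", 4332, 4400, "light", "tRNA"),
    ("MT-TM", 4402, 4469, "heavy", "tRNA"),
    ("MT-ND2", 4470, 5511, "heavy", "complexI"),
    ("MT-TW", 5512, 5579, "heavy", "tRNA"),
    ("MT-TA", 5587, 5655, "light", "tRNA"),
    ("MT-TN", 5657, 5729, "light", "tRNA"),
    ("MT-TC", 5761, 5826, "light", "tRNA"),
    ("MT-TY", 5827, 5891, "light", "tRNA"),
    ("MT-CO1", 5904, 7445, "heavy", "complexIV"),
    ("MT-TS1", 7446, 7514, "light", "tRNA"),
    ("MT-TD", 7518, 7585, "heavy", "tRNA"),
    ("MT-CO2", 7586, 8269, "heavy", "complexIV"),
    ("MT-TK", 8295, 8364, "heavy", "tRNA"),
    ("MT-ATP8", 8366, 8572, "heavy", "ATPsynthase"),
    ("MT-ATP6", 8527, 9206, "heavy", "ATPsynthase"),
    ("MT-CO3", 9207, 9990, "heavy", "complexIV"),
    ("MT-TG", 9991, 10058, "heavy", "tRNA"),
    ("MT-ND3", 10059, 10404, "heavy", "complexI"),
    ("MT-TR", 10405, 10469, "heavy", "tRNA"),
    ("MT-ND4L", 10470, 10766, "heavy", "complexI"),
    ("MT-ND4", 10760, 12137, "heavy", "complexI"),
    ("MT-TH", 12138, 12206, "heavy", "tRNA"),
    ("MT-TS2", 12207, 12265, "heavy", "tRNA"),
    ("MT-TL2", 12266, 12336, "heavy", "tRNA"),
    ("MT-ND5", 12337, 14148, "heavy", "complexI"),
    ("MT-ND6", 14149, 14673, "light", "complexI"),
    ("MT-TE", 14674, 14742, "light", "tRNA"),
    ("MT-CYB", 14747, 15887, "heavy", "complexIII"),
    ("MT-TT", 15888, 15953, "heavy", "tRNA"),
    ("MT-TP", 15956, 16023, "light", "tRNA"),
]

#: Sense-strand codons pinned so documented variant effects reproduce.
#: (locus, codon index, codon). MT-ND6 codons are light-strand sense.
PINNED_CODONS: list[tuple[str, int, str]] = [
    ("MT-ND1", 52, "GCC"),   # m.3460G>A -> p.Ala52Thr
    ("MT-ND1", 58, "AAA"),   # m.3480A>G -> p.Lys58=
    ("MT-ND1", 64, "GCC"),   # m.3497C>T -> p.Ala64Val
    ("MT-ND1", 304, "TTA"),  # m.4216T>C synonymous marker
    ("MT-ND2", 37, "CTG"),   # m.4580G>A synonymous marker
    ("MT-CO1", 106, "CTT"),  # m.6221T>C synonymous marker
    ("MT-ATP6", 59, "ATA"),  # m.8701A>G -> p.Met59Val
    ("MT-ATP6", 104, "ATA"),  # m.8836A>G -> p.Met104Val
    ("MT-ATP6", 177, "GCC"),  # m.9055G>A -> p.Ala177Thr
    ("MT-ND3", 114, "ATA"),  # m.10398A>G non-synonymous marker
    ("MT-ND4", 164, "CTA"),  # m.11251A>G synonymous marker
    ("MT-ND4", 180, "ACT"),  # m.11299T>C -> p.Thr180=
    ("MT-ND4", 236, "CTA"),  # m.11467A>G synonymous marker
    ("MT-ND4", 340, "CGC"),  # m.11778G>A -> p.Arg340His (primary mutation)
    ("MT-ND5", 12, "CTG"),   # m.12372G>A synonymous marker
    ("MT-ND5", 458, "GTA"),  # m.13708G>A -> p.Val458Met
    ("MT-ND6", 64, "ATA"),   # m.14484T>C -> p.Met64Val
    ("MT-ND6", 169, "GAG"),  # m.14167C>T -> p.Glu169=
    ("MT-CYB", 7, "CCT"),    # m.14766C>T -> p.Pro7Leu
    ("MT-CYB", 18, "TTA"),   # m.14798T>C synonymous marker
    ("MT-CYB", 29, "GCC"),   # m.14831G>A -> p.Ala29Thr
]

#: Non-coding / RNA positions pinned to the documented rCRS base.
PINNED_BASES: dict[int, str] = {
    72: "T", 73: "A", 153: "A", 204: "T", 263: "A", 295: "C",
    709: "G", 1243: "T", 1811: "A", 10034: "T", 12308: "A",
    16069: "C", 16129: "G", 16189: "T", 16217: "T", 16224: "T",
    16294: "C", 16311: "T", 16519: "T",
}

#: Reference-base assertions covering every variant position used by the
#: packaged tree, the documented associations, and the primary mutation.
EXPECTED_REF: dict[int, str] = {
    **PINNED_BASES,
    3460: "G", 3480: "A", 3497: "C", 4216: "T", 4580: "G", 6221: "T",
    8701: "A", 8836: "A", 9055: "G", 10398: "A", 11251: "A", 11299: "T",
    11467: "A", 11778: "G", 12372: "G", 13708: "G", 14167: "C",
    14484: "T", 14766: "C", 14798: "T", 14831: "G",
}

_BACKGROUND = "ACGT"
_FILLER = "CTA"


def _coding_features() -> list[tuple[str, int, int, str]]:
    return [
        (name, s, e, strand)
        for name, s, e, strand, pc in GENES
        if pc in {"complexI", "complexIII", "complexIV", "ATPsynthase"}
    ]


def build_sequence() -> str:
    """Assemble and validate the synthetic scaffold sequence."""
    seq = [_BACKGROUND[(p - 1) % 4] for p in range(1, GENOME_LENGTH + 1)]

    # Coding genes: CTA repeat in each gene's own frame. List order makes
    # the downstream member of each overlap (ATP6, ND4) win; any frame
    # rotation of a CTA repeat is stop-free, so the upstream frame stays
    # clean through the overlap.
    for name, start, end, strand in _coding_features():
        if strand == "heavy":
            for off in range(end - start + 1):
                seq[start - 1 + off] = _FILLER[off % 3]
        else:  # light strand: sense runs end -> start on the heavy axis
            for off in range(end - start + 1):
                seq[end - 1 - off] = COMPLEMENT[_FILLER[off % 3]]

    bounds = {name: (s, e, strand) for name, s, e, strand in _coding_features()}
    for name, codon_idx, codon in PINNED_CODONS:
        start, end, strand = bounds[name]
        if strand == "heavy":
            base0 = start + 3 * (codon_idx - 1)
            for k, b in enumerate(codon):
                seq[base0 - 1 + k] = b
        else:
            base0 = end - 3 * (codon_idx - 1)
            for k, b in enumerate(codon):
                seq[base0 - 1 - k] = COMPLEMENT[b]

    for pos, base in PINNED_BASES.items():
        seq[pos - 1] = base

    out = "".join(seq)
    _validate(out)
    return out


def _validate(seq: str) -> None:
    if len(seq) != GENOME_LENGTH:
        raise AssertionError("scaffold length mismatch")
    for pos, base in EXPECTED_REF.items():
        if seq[pos - 1] != base:
            raise AssertionError(
                f"scaffold base at {pos} is {seq[pos - 1]}, expected {base}"
            )
    for name, start, end, strand in _coding_features():
        if strand == "heavy":
            sense = seq[start - 1 : end]
        else:
            sense = "".join(COMPLEMENT[b] for b in reversed(seq[start - 1 : end]))
        aa = translate(sense)
        if "*" in aa:
            raise AssertionError(f"internal stop codon in {name}")


def write_fasta(path: Path | str) -> None:
    seq = build_sequence()
    lines = [">synthetic_rcrs_scaffold rCRS-like synthetic scaffold, not NC_012920"]
    lines += [seq[i : i + 70] for i in range(0, len(seq), 70)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_annotation(path: Path | str) -> None:
    rows = ["#locus\tstart\tend\tstrand\tproduct_class"]
    rows += ["\t".join(map(str, g)) for g in GENES]
    Path(path).write_text("\n".join(rows) + "\n")


def main() -> None:
    data = Path(__file__).parent / "data"
    write_fasta(data / "synthetic_rcrs_scaffold.fasta")
    write_annotation(data / "rcrs_genes.tsv")
    print("wrote packaged reference data files")


if __name__ == "__main__":
    main()
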