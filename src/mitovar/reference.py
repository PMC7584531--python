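"""rCRS gene model, the seven-region functional partition and effect calls.

The mitochondrial genome is partitioned into seven functional regions:
the complex I, III and IV coding regions, the ATP synthase coding
region, the rRNA and tRNA coding regions, and the non-coding region
(control region plus intergenic spacers). Every 1-based coordinate on
the 16,569-bp circle maps to exactly one region; the two classic gene
overlaps (MT-ATP8/MT-ATP6 and MT-ND4L/MT-ND4) lie within a single
region each, so the partition is unambiguous.

Substitution effects are called by translating the affected codon under
the vertebrate mitochondrial code, reverse-complementing for the one
light-strand protein gene (MT-ND6). Variants are expressed in heavy
strand ``m.<pos><ref>><alt>`` notation throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .genetic_code import AA_THREE_LETTER, COMPLEMENT, translate_codon

REGIONS = (
    "complexI",
    "complexIII",
    "complexIV",
    "ATPsynthase",
    "rRNA",
    "tRNA",
    "noncoding",
)

CODING_REGIONS = frozenset({"complexI", "complexIII", "complexIV", "ATPsynthase"})

#: Protein-coding overlaps accepted by the model validator.
KNOWN_OVERLAPS = frozenset({("MT-ATP8", "MT-ATP6"), ("MT-ND4L", "MT-ND4")})

TRANSITIONS = frozenset({frozenset("AG"), frozenset("CT")})


class ReferenceMismatchError(ValueError):
    """The stated reference allele disagrees with the model sequence."""


@dataclass(frozen=True)
class GeneFeature:
    name: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # "heavy" | "light"
    product_class: str  # one of REGIONS

    def __post_init__(self):
        if self.strand not in ("heavy", "light"):
            raise ValueError(f"{self.name}: missing/invalid strand {self.strand!r}")
        if self.product_class not in REGIONS:
            raise ValueError(f"{self.name}: unknown product class {self.product_class!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"{self.name}: bad coordinates {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_coding(self) -> bool:
        return self.product_class in CODING_REGIONS


@dataclass(frozen=True)
class EffectCall:
    """Predicted consequence of a single-nucleotide substitution.

    ``category`` is one of ``synonymous``, ``non-synonymous``,
    ``rna-change`` or ``non-coding-change``. ``protein_change`` carries
    HGVS-like p.-notation for coding calls (``p.Xaa<pos>=`` when
    synonymous) and is empty otherwise.
    """

    category: str
    protein_change: str = ""
    codon_index: int | None = None
    locus: str = ""

    def __post_init__(self):
        coding = self.category in ("synonymous", "non-synonymous")
        if coding != bool(self.protein_change):
            raise ValueError("protein_change must be set iff the call is coding")


@dataclass
class GeneModel:
    """An annotated mitochondrial reference.

    Maintains O(1) position -> (locus, region) lookup over the whole
    genome; positions not covered by a feature resolve to the
    ``intergenic`` locus in the non-coding region.
    """

    features: list[GeneFeature]
    sequence: str
    _locus_of: list[str] = field(repr=False, default_factory=list)
    _region_idx: np.ndarray | None = field(repr=False, default=None)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        self._validate()
        n = len(self.sequence)
        self._locus_of = ["intergenic"] * (n + 1)
        region_idx = np.full(n + 1, REGIONS.index("noncoding"), dtype=np.int8)
        # later (downstream) features win inside the known overlaps,
        # matching the conventional per-position primary assignment
        for f in self.features:
            for p in range(f.start, f.end + 1):
                self._locus_of[p] = f.name
                region_idx[p] = REGIONS.index(f.product_class)
        self._region_idx = region_idx

    # -- validation ---------------------------------------------------
    def _validate(self) -> None:
        n = len(self.sequence)
        if not self.features:
            raise ValueError("gene model has no features")
        top = max(f.end for f in self.features)
        if n != top:
            raise ValueError(f"sequence length {n} != annotation extent {top}")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("sequence contains non-ACGTN symbols")
        coding = sorted(
            (f for f in self.features if f.is_coding), key=lambda f: f.start
        )
        for a, b in zip(coding, coding[1:]):
            if b.start <= a.end and (a.name, b.name) not in KNOWN_OVERLAPS:
                raise ValueError(f"unexpected coding overlap: {a.name}/{b.name}")

    # -- queries ------------------------------------------------------
    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        self._check_position(position)
        return self.sequence[position - 1]

    def _check_position(self, position: int) -> None:
        if not 1 <= position <= self.length:
            raise ValueError(
                f"position {position} outside reference coordinates 1..{self.length}"
            )

    def locate(self, position: int) -> tuple[str, str]:
        """Primary (locus, region) for a coordinate."""
        self._check_position(position)
        return self._locus_of[position], REGIONS[self._region_idx[position]]

    def features_at(self, position: int) -> list[GeneFeature]:
        self._check_position(position)
        return [f for f in self.features if f.start <= position <= f.end]

    def coding_feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name and f.is_coding:
                return f
        raise KeyError(name)

    def gene_sense_sequence(self, name: str) -> str:
        """Sense-strand (reading) sequence of a protein-coding gene."""
        f = self.coding_feature(name)
        seg = self.sequence[f.start - 1 : f.end]
        if f.strand == "light":
            seg = "".join(COMPLEMENT[b] for b in reversed(seg))
        return seg


# -- construction -----------------------------------------------------

def load_gene_model(annotation_path: str | Path, fasta_path: str | Path) -> GeneModel:
    """Build a model from a BED-like TSV annotation and a FASTA reference.

    Annotation columns: locus, start, end, strand, product_class
    (1-based inclusive, strand ``heavy``/``light``). The FASTA must hold
    a single record spanning the annotation.
    """
    features = []
    for line in Path(annotation_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"malformed annotation line: {line!r}")
        name, start, end, strand, pc = parts
        features.append(GeneFeature(name, int(start), int(end), strand, pc))
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected a single FASTA record, found {len(records)}")
    return GeneModel(features=features, sequence=str(records[0].seq))


def default_gene_model() -> GeneModel:
    """The packaged model: canonical NC_012920 gene coordinates over the
    synthetic scaffold sequence (see :mod:`mitovar.refdata`)."""
    data = resources.files("mitovar") / "data"
    return load_gene_model(
        str(data / "rcrs_genes.tsv"), str(data / "synthetic_rcrs_scaffold.fasta")
    )


# -- classification ---------------------------------------------------

def classify_substitution(ref_allele: str, alt_allele: str) -> str:
    """``transition`` (purine<->purine / pyrimidine<->pyrimidine) or
    ``transversion``."""
    ref, alt = ref_allele.upper(), alt_allele.upper()
    if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"alleles must be single ACGT bases, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt alleles are identical: {ref!r}")
    return "transition" if frozenset((ref, alt)) in TRANSITIONS else "transversion"


def locate(position: int, model: GeneModel) -> tuple[str, str]:
    return model.locate(position)


def _codon_call(position: int, ref: str, alt: str, feature: GeneFeature,
                model: GeneModel) -> EffectCall:
    if feature.strand == "heavy":
        offset = position - feature.start
        codon_idx = offset // 3 + 1
        base0 = feature.start + 3 * (codon_idx - 1)
        if base0 + 2 > feature.end:  # trailing partial codon (incomplete stop)
            return EffectCall("non-coding-change", locus=feature.name)
        within = position - base0
        codon = model.sequence[base0 - 1 : base0 + 2]
        ref_s, alt_s = ref, alt
    else:
        offset = feature.end - position
        codon_idx = offset // 3 + 1
        base0 = feature.end - 3 * (codon_idx - 1)  # heavy coord of sense base 1
        if base0 - 2 < feature.start:
            return EffectCall("non-coding-change", locus=feature.name)
        within = base0 - position
        codon = "".join(
            COMPLEMENT[model.sequence[base0 - 1 - k]] for k in range(3)
        )
        ref_s, alt_s = COMPLEMENT[ref], COMPLEMENT[alt]
    if codon[within] != ref_s:
        raise ReferenceMismatchError(
            f"position {position}: sense codon carries {codon[within]}, "
            f"stated reference is {ref}"
        )
    alt_codon = codon[:within] + alt_s + codon[within + 1 :]
    aa_ref = AA_THREE_LETTER[translate_codon(codon)]
    aa_alt = AA_THREE_LETTER[translate_codon(alt_codon)]
    if aa_ref == aa_alt:
        return EffectCall(
            "synonymous", f"p.{aa_ref}{codon_idx}=", codon_idx, feature.name
        )
    return EffectCall(
        "non-synonymous", f"p.{aa_ref}{codon_idx}{aa_alt}", codon_idx, feature.name
    )


def annotate_effect(position: int, ref: str, alt: str, model: GeneModel,
                    all_frames: bool = False):
    """Effect call for a heavy-strand substitution.

    The reference allele must match the model sequence. At the two known
    gene overlaps the primary call reports the gene ``locate`` assigns
    the position to; pass ``all_frames=True`` for one call per
    overlapping reading frame.
    """
    ref, alt = ref.upper(), alt.upper()
    classify_substitution(ref, alt)  # validates the allele pair
    if model.base(position) != ref:
        raise ReferenceMismatchError(
            f"position {position}: reference base is {model.base(position)}, "
            f"stated reference is {ref}"
        )
    coding = [f for f in model.features_at(position) if f.is_coding]
    if coding:
        primary_locus, _ = model.locate(position)
        coding.sort(key=lambda f: f.name != primary_locus)
        calls = [_codon_call(position, ref, alt, f, model) for f in coding]
        return calls if all_frames else calls[0]
    locus, region = model.locate(position)
    if region in ("rRNA", "tRNA"):
        call = EffectCall("rna-change", locus=locus)
    else:
        call = EffectCall("non-coding-change", locus=locus)
    return [call] if all_frames else call
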