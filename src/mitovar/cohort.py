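"""Subjects, cohorts and population-frequency annotation.

A :class:`Variant` is one heavy-strand substitution carried by a
subject, keyed by ``(position, alt)`` and written ``m.<pos><ref>><alt>``.
Rarity is assigned from a population frequency table with an inclusive
cutoff (default ≤0.5% → rare); variants absent from the table are
classed ``unknown`` and excluded from rare/common tallies rather than
assumed rare, so table incompleteness cannot inflate rare-variant
counts. Heteroplasmy is the mutant-allele percentage in (0, 100]; calls
below the homoplasmy threshold (default 95%) are heteroplasmic.

Cohorts can be read from and written to a long-format TSV or a
multi-sample VCF (GT plus per-sample AF); the two readers produce
identical in-memory cohorts for equivalent content.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from .reference import EffectCall, GeneModel, annotate_effect

logger = logging.getLogger(__name__)

GROUPS = ("patient", "control")

PRIMARY_MUTATION = (11778, "A")  # m.11778G>A

_M_NOTATION = re.compile(r"^m\.(\d+)([ACGT])>([ACGT])$")


def parse_m_notation(label: str) -> tuple[int, str, str]:
    """``m.73A>G`` -> (73, 'A', 'G')."""
    m = _M_NOTATION.match(label.strip())
    if not m:
        raise ValueError(f"not m.<pos><ref>><alt> notation: {label!r}")
    return int(m.group(1)), m.group(2), m.group(3)


def format_m_notation(position: int, ref: str, alt: str) -> str:
    return f"m.{position}{ref}>{alt}"


@dataclass
class Variant:
    position: int
    ref: str
    alt: str
    heteroplasmy_fraction: float = 100.0  # percent in (0, 100]
    effect: EffectCall | None = None
    region: str | None = None  # one of the seven regions, set on annotation
    population_frequency: float | None = None  # percent, None = unknown
    rarity: str = "unknown"  # rare | common | unknown
    reported_association: str | None = None

    def __post_init__(self):
        if not 0 < self.heteroplasmy_fraction <= 100:
            raise ValueError(
                f"heteroplasmy fraction must be in (0,100], got "
                f"{self.heteroplasmy_fraction}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.position}")

    @property
    def key(self) -> tuple[int, str]:
        return (self.position, self.alt)

    @property
    def label(self) -> str:
        return format_m_notation(self.position, self.ref, self.alt)


@dataclass
class SubjectProfile:
    subject_id: str
    group: str  # patient | control
    variants: dict[tuple[int, str], Variant] = field(default_factory=dict)
    haplogroup: "object | None" = None  # HaplogroupCall, set by haplotree

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    def add(self, variant: Variant) -> None:
        if variant.key in self.variants:
            raise ValueError(
                f"duplicate variant {variant.label} for subject {self.subject_id}"
            )
        self.variants[variant.key] = variant

    def __iter__(self):
        return iter(self.variants.values())

    def __len__(self):
        return len(self.variants)


@dataclass
class Cohort:
    subjects: list[SubjectProfile] = field(default_factory=list)

    def __post_init__(self):
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids in cohort")

    def group(self, name: str) -> list[SubjectProfile]:
        if name not in GROUPS:
            raise ValueError(f"unknown group {name!r}")
        return [s for s in self.subjects if s.group == name]

    @property
    def n_patients(self) -> int:
        return len(self.group("patient"))

    @property
    def n_controls(self) -> int:
        return len(self.group("control"))

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self):
        return len(self.subjects)


class FrequencyTable:
    """Mapping (position, alt) -> population frequency in percent."""

    def __init__(self, entries: dict[tuple[int, str], float] | None = None):
        self._entries: dict[tuple[int, str], float] = {}
        for key, pct in (entries or {}).items():
            self[key] = pct

    def __setitem__(self, key: tuple[int, str], pct: float) -> None:
        if not 0 <= pct <= 100:
            raise ValueError(f"frequency out of [0,100]: {pct} for {key}")
        self._entries[key] = float(pct)

    def get(self, key: tuple[int, str]) -> float | None:
        return self._entries.get(key)

    def __contains__(self, key) -> bool:
        return key in self._entries

    def __len__(self):
        return len(self._entries)

    def items(self):
        return self._entries.items()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyTable":
        """Two/three-column TSV: ``m.<pos><ref>><alt>  percent  [note]``
        or ``position  alt  percent``."""
        table = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if _M_NOTATION.match(parts[0]):
                pos, _, alt = parse_m_notation(parts[0])
                pct = float(parts[1])
            else:
                pos, alt, pct = int(parts[0]), parts[1], float(parts[2])
            table[(pos, alt)] = pct
        return table

    def to_tsv(self, path: str | Path, model: GeneModel | None = None) -> None:
        lines = ["#variant\tfrequency_percent"]
        for (pos, alt), pct in sorted(self.items()):
            ref = model.base(pos) if model is not None else "N"
            lines.append(f"{format_m_notation(pos, ref, alt)}\t{pct:g}")
        Path(path).write_text("\n".join(lines) + "\n")


# -- annotation operations -------------------------------------------

def annotate_frequency(profile: SubjectProfile, freq: FrequencyTable,
                       cutoff: float = 0.5) -> SubjectProfile:
    """Set population frequency and rarity on every variant (in place).

    The cutoff comparison is inclusive: frequency ≤ cutoff → rare.
    Unknown variants are logged and classed ``unknown``. Idempotent.
    """
    if cutoff <= 0:
        raise ValueError(f"rarity cutoff must be positive, got {cutoff}")
    for v in profile:
        pct = freq.get(v.key)
        v.population_frequency = pct
        if pct is None:
            v.rarity = "unknown"
            logger.debug(
                "variant %s of subject %s absent from frequency table",
                v.label, profile.subject_id,
            )
        else:
            v.rarity = "rare" if pct <= cutoff else "common"
    return profile


def flag_reported(profile: SubjectProfile,
                  association_list: dict[tuple[int, str], str]) -> SubjectProfile:
    """Attach reported-association annotations to matching variants."""
    for v in profile:
        if v.key in association_list:
            v.reported_association = association_list[v.key]
    return profile


def load_association_list(path: str | Path) -> dict[tuple[int, str], str]:
    out: dict[tuple[int, str], str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        variant, annotation = line.split("\t")[:2]
        pos, _, alt = parse_m_notation(variant)
        out[(pos, alt)] = annotation
    return out


def heteroplasmy_status(variant: Variant | float,
                        homoplasmy_threshold: float = 95.0) -> str:
    """``homoplasmic`` or ``heteroplasmic`` for a variant or a percent."""
    frac = (
        variant.heteroplasmy_fraction if isinstance(variant, Variant) else variant
    )
    if not 0 < frac <= 100:
        raise ValueError(f"heteroplasmy fraction must be in (0,100], got {frac}")
    return "heteroplasmic" if frac < homoplasmy_threshold else "homoplasmic"


def annotate_effects(cohort: Cohort, model: GeneModel) -> Cohort:
    """Attach an :class:`EffectCall` to every variant in the cohort."""
    for subject in cohort:
        for v in subject:
            v.effect = annotate_effect(v.position, v.ref, v.alt, model)
            v.region = model.locate(v.position)[1]
    return cohort


def annotate_cohort(cohort: Cohort, model: GeneModel, freq: FrequencyTable,
                    cutoff: float = 0.5,
                    association_list: dict[tuple[int, str], str] | None = None
                    ) -> Cohort:
    """Full per-variant annotation: effects, rarity, reported flags."""
    annotate_effects(cohort, model)
    for subject in cohort:
        annotate_frequency(subject, freq, cutoff)
        if association_list:
            flag_reported(subject, association_list)
    return cohort


# -- cohort IO --------------------------------------------------------

_TSV_HEADER = "subject_id\tgroup\tposition\tref\talt\theteroplasmy_percent"


def write_cohort_tsv(cohort: Cohort, path: str | Path) -> None:
    lines = [_TSV_HEADER]
    for s in cohort:
        for v in sorted(s, key=lambda v: v.key):
            lines.append(
                f"{s.subject_id}\t{s.group}\t{v.position}\t{v.ref}\t{v.alt}"
                f"\t{v.heteroplasmy_fraction:g}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_cohort_tsv(path: str | Path) -> Cohort:
    subjects: dict[str, SubjectProfile] = {}
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].lstrip("#") != _TSV_HEADER:
        raise ValueError(f"unrecognized cohort TSV header in {path}")
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        sid, group, pos, ref, alt, het = line.split("\t")
        if sid not in subjects:
            subjects[sid] = SubjectProfile(sid, group)
        subjects[sid].add(Variant(int(pos), ref, alt, float(het)))
    return Cohort(list(subjects.values()))


def write_cohort_vcf(cohort: Cohort, path: str | Path,
                     model: GeneModel | None = None) -> None:
    """Multi-sample VCF 4.2: haploid GT plus per-sample AF (fraction of
    mutant molecules, i.e. heteroplasmy/100). Group membership is kept
    in ##SAMPLE header lines."""
    samples = [s.subject_id for s in cohort]
    by_id = {s.subject_id: s for s in cohort}
    keys: dict[tuple[int, str], str] = {}
    for s in cohort:
        for v in s:
            keys.setdefault(v.key, v.ref)
    length = model.length if model is not None else 16569
    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID=chrM,length={length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AF,Number=1,Type=Float,Description='
        '"Mutant allele fraction (heteroplasmy)">',
    ]
    header += [
        f"##SAMPLE=<ID={sid},Group={by_id[sid].group}>" for sid in samples
    ]
    header.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )
    body = []
    for (pos, alt), ref in sorted(keys.items()):
        calls = []
        for sid in samples:
            v = by_id[sid].variants.get((pos, alt))
            if v is None:
                calls.append("0:.")
            else:
                calls.append(f"1:{v.heteroplasmy_fraction / 100:.4f}")
        body.append(
            f"chrM\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AF\t"
            + "\t".join(calls)
        )
    Path(path).write_text("\n".join(header + body) + "\n")


def read_cohort_vcf(path: str | Path) -> Cohort:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    groups: dict[str, str] = {}
    for line in vcf.raw_header.splitlines():
        m = re.match(r"##SAMPLE=<ID=([^,>]+),Group=([^,>]+)>", line)
        if m:
            groups[m.group(1)] = m.group(2)
    missing = [sid for sid in vcf.samples if sid not in groups]
    if missing:
        raise ValueError(f"no ##SAMPLE group annotation for: {missing}")
    subjects = {
        sid: SubjectProfile(sid, groups[sid]) for sid in vcf.samples
    }
    for record in vcf:
        if len(record.REF) != 1 or any(len(a) != 1 for a in record.ALT):
            raise ValueError(
                f"only single-nucleotide variants supported, got "
                f"{record.REF}>{record.ALT} at {record.POS}"
            )
        af = record.format("AF")
        for i, sid in enumerate(vcf.samples):
            alleles = record.genotypes[i][:-1]
            called = [a for a in alleles if a is not None and a >= 0]
            if not called or all(a == 0 for a in called):
                continue
            alt = record.ALT[max(called) - 1]
            het = float(af[i][0]) * 100 if af is not None else 100.0
            subjects[sid].add(Variant(record.POS, record.REF, alt, het))
    return Cohort(list(subjects.values()))
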