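"""Pathogenicity-score variant loads.

The *total variant load* of a subject is the sum of pathogenicity
scores (in [0,1], e.g. MutPred) over its non-synonymous variants; the
*threshold load* sums only scores strictly above a threshold (default
0.5, the conventional likely-deleterious cutoff). The primary disease
mutation m.11778G>A is excluded from both loads, since every patient
carries it by ascertainment.

Scores enter via a :class:`ScoreTable` keyed by nucleotide change
``m.<pos><ref>><alt>`` or by protein change ``p.<Xaa><pos><Yaa>``; both
key forms are accepted. Non-synonymous variants missing from the table
are skipped with a warning by default (set ``missing='fail'`` to raise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .burden import CarrierPredicate, DEFAULT_EXCLUSIONS, carrier_table
from .cohort import Cohort, SubjectProfile, Variant, parse_m_notation
from .stats import AssociationResult, ContingencyTable2x2, associate, pooled_t_test

logger = logging.getLogger(__name__)


class ScoreTable:
    """Mapping of non-synonymous variants to pathogenicity scores in [0,1]."""

    def __init__(self, by_variant: dict[tuple[int, str], float] | None = None,
                 by_protein: dict[str, float] | None = None):
        self._by_variant: dict[tuple[int, str], float] = {}
        self._by_protein: dict[str, float] = {}
        for k, v in (by_variant or {}).items():
            self.set_variant(k, v)
        for k, v in (by_protein or {}).items():
            self.set_protein(k, v)

    @staticmethod
    def _check(score: float) -> float:
        if not 0 <= score <= 1:
            raise ValueError(f"pathogenicity score outside [0,1]: {score}")
        return float(score)

    def set_variant(self, key: tuple[int, str], score: float) -> None:
        self._by_variant[key] = self._check(score)

    def set_protein(self, key: str, score: float) -> None:
        self._by_protein[key] = self._check(score)

    def get(self, variant: Variant) -> float | None:
        """Score for a variant, trying the nucleotide key first, then
        the annotated protein change."""
        score = self._by_variant.get(variant.key)
        if score is None and variant.effect is not None:
            score = self._by_protein.get(variant.effect.protein_change)
        return score

    def __len__(self):
        return len(self._by_variant) + len(self._by_protein)

    def variant_items(self):
        return self._by_variant.items()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreTable":
        """Two-column TSV: m.-notation or p.-notation key, score."""
        table = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, score = line.split("\t")[:2]
            if key.startswith("p."):
                table.set_protein(key, float(score))
            else:
                pos, _, alt = parse_m_notation(key)
                table.set_variant((pos, alt), float(score))
        return table

    def to_tsv(self, path: str | Path, refs: dict[tuple[int, str], str] | None = None
               ) -> None:
        lines = ["#variant\tscore"]
        for (pos, alt), score in sorted(self._by_variant.items()):
            ref = (refs or {}).get((pos, alt), "N")
            lines.append(f"m.{pos}{ref}>{alt}\t{score:.4f}")
        for key, score in sorted(self._by_protein.items()):
            lines.append(f"{key}\t{score:.4f}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class LoadResult:
    subject_id: str
    total_load: float
    threshold_load: float
    n_ns: int  # scored non-synonymous variants

    def __post_init__(self):
        if not 0 <= self.threshold_load <= self.total_load <= self.n_ns:
            raise ValueError("inconsistent load aggregates")


def compute_loads(profile: SubjectProfile, scores: ScoreTable,
                  threshold: float = 0.5,
                  exclusions: frozenset[tuple[int, str]] = DEFAULT_EXCLUSIONS,
                  missing: str = "warn") -> LoadResult:
    """Per-subject loads over non-synonymous variants.

    The threshold comparison is strict (score > threshold).
    """
    if missing not in ("warn", "fail"):
        raise ValueError("missing policy must be 'warn' or 'fail'")
    total = 0.0
    thresholded = 0.0
    n_scored = 0
    for v in profile:
        if v.effect is None:
            raise ValueError(
                f"variant {v.label} of subject {profile.subject_id} "
                "is not effect-annotated"
            )
        if v.effect.category != "non-synonymous" or v.key in exclusions:
            continue
        score = scores.get(v)
        if score is None:
            msg = (f"no pathogenicity score for non-synonymous variant "
                   f"{v.label} ({v.effect.protein_change}) of subject "
                   f"{profile.subject_id}")
            if missing == "fail":
                raise KeyError(msg)
            logger.warning(msg)
            continue
        n_scored += 1
        total += score
        if score > threshold:
            thresholded += score
    return LoadResult(profile.subject_id, total, thresholded, n_scored)


@dataclass(frozen=True)
class LoadComparison:
    per_subject: tuple[LoadResult, ...]
    mean_total: dict[str, float]
    sd_total: dict[str, float]
    mean_threshold: dict[str, float]
    sd_threshold: dict[str, float]
    t_total: tuple[float, float, float]  # (t, df, p)
    t_threshold: tuple[float, float, float]
    carrier_2x2: ContingencyTable2x2
    carrier_association: AssociationResult


def compare_loads(cohort: Cohort, scores: ScoreTable, threshold: float = 0.5,
                  exclusions: frozenset[tuple[int, str]] = DEFAULT_EXCLUSIONS,
                  equal_var: bool = True, missing: str = "warn"
                  ) -> LoadComparison:
    """Group comparison of variant loads.

    Computes per-group mean ± SD of the total and thresholded loads,
    two-sample t-tests on each, and the carrier 2x2 (subjects with at
    least one variant scoring above the threshold) with its Fisher/OR
    association summary.
    """
    import numpy as np

    if cohort.n_patients < 2 or cohort.n_controls < 2:
        raise ValueError("need at least two subjects per group")
    results = {
        g: [compute_loads(s, scores, threshold, exclusions, missing)
            for s in cohort.group(g)]
        for g in ("patient", "control")
    }
    totals = {g: np.array([r.total_load for r in rs]) for g, rs in results.items()}
    thresh = {g: np.array([r.threshold_load for r in rs]) for g, rs in results.items()}

    def summary(values):
        return ({g: float(v.mean()) for g, v in values.items()},
                {g: float(v.std(ddof=1)) for g, v in values.items()})

    mean_t, sd_t = summary(totals)
    mean_h, sd_h = summary(thresh)

    def ttest(mean, sd):
        return pooled_t_test(
            mean["patient"], sd["patient"], cohort.n_patients,
            mean["control"], sd["control"], cohort.n_controls,
            equal_var=equal_var,
        )

    table = carrier_table(
        cohort, CarrierPredicate(score_threshold=threshold), scores, exclusions
    )
    return LoadComparison(
        per_subject=tuple(results["patient"] + results["control"]),
        mean_total=mean_t, sd_total=sd_t,
        mean_threshold=mean_h, sd_threshold=sd_h,
        t_total=ttest(mean_t, sd_t),
        t_threshold=ttest(mean_h, sd_h),
        carrier_2x2=table,
        carrier_association=associate(table),
    )
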