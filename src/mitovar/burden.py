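"""Regional variant burden tallies and group comparisons.

Tallies are computed per functional region and group in two modes:
*occurrence* counts every variant instance across subjects, *unique*
counts each distinct (position, alt) at most once per group. The
``overall`` category aggregates the whole genome; in unique mode it is
reported as ``overall_unique``.

To avoid the primary disease mutation dominating the complex I counts,
m.11778G>A is excluded by default from the complex I and overall
tallies (all six counters — the exclusion only materially affects the
transition, rare and non-synonymous counts, since the variant is a
transition, population-rare and non-synonymous).
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import Cohort, PRIMARY_MUTATION, Variant
from .reference import REGIONS, classify_substitution
from .stats import AssociationResult, ContingencyTable2x2, associate

TALLY_SCOPES = REGIONS + ("overall",)

#: scopes the default exclusion rule applies to
EXCLUSION_SCOPES = frozenset({"complexI", "overall"})

DEFAULT_EXCLUSIONS = frozenset({PRIMARY_MUTATION})

METRICS = {
    "ts_vs_tv": ("ts", "tv"),
    "rare_vs_common": ("rare", "common"),
    "ns_vs_s": ("ns", "s"),
}


@dataclass
class RegionBurden:
    region: str  # one of the seven regions, overall, or overall_unique
    group: str
    mode: str  # occurrence | unique
    ts: int = 0
    tv: int = 0
    rare: int = 0
    common: int = 0
    unknown_rarity: int = 0
    ns: int = 0
    s: int = 0

    @property
    def total(self) -> int:
        return self.ts + self.tv


@dataclass(frozen=True)
class CarrierPredicate:
    """A subject is a carrier iff ≥1 variant passes all active filters."""

    region: str | None = None
    rarity: str | None = None
    score_threshold: float | None = None


def _check_annotated(v: Variant, subject_id: str) -> None:
    if v.effect is None or v.region is None:
        raise ValueError(
            f"variant at position {v.position} of subject {subject_id} "
            "is not effect-annotated"
        )


def tally(cohort: Cohort, region: str, mode: str = "occurrence",
          exclusions: frozenset[tuple[int, str]] = DEFAULT_EXCLUSIONS,
          ) -> dict[str, RegionBurden]:
    """Per-group :class:`RegionBurden` for one region or ``overall``."""
    if region not in TALLY_SCOPES:
        raise ValueError(f"region must be one of {TALLY_SCOPES}, got {region!r}")
    if mode not in ("occurrence", "unique"):
        raise ValueError(f"mode must be occurrence|unique, got {mode!r}")
    label = region
    if region == "overall" and mode == "unique":
        label = "overall_unique"
    apply_exclusion = region in EXCLUSION_SCOPES
    out: dict[str, RegionBurden] = {}
    for group in ("patient", "control"):
        burden = RegionBurden(label, group, mode)
        seen: set[tuple[int, str]] = set()
        for subject in cohort.group(group):
            for v in subject:
                _check_annotated(v, subject.subject_id)
                if region != "overall" and v.region != region:
                    continue
                if apply_exclusion and v.key in exclusions:
                    continue
                if mode == "unique":
                    if v.key in seen:
                        continue
                    seen.add(v.key)
                if classify_substitution(v.ref, v.alt) == "transition":
                    burden.ts += 1
                else:
                    burden.tv += 1
                if v.rarity == "rare":
                    burden.rare += 1
                elif v.rarity == "common":
                    burden.common += 1
                else:
                    burden.unknown_rarity += 1
                if v.effect.category == "non-synonymous":
                    burden.ns += 1
                elif v.effect.category == "synonymous":
                    burden.s += 1
        out[group] = burden
    return out


def ts_tv_ratio(burden: RegionBurden) -> float | None:
    """ts/tv, or None (rendered "n/a") when no transversions."""
    if burden.tv == 0:
        return None
    return burden.ts / burden.tv


def compare_burden(group_a: RegionBurden, group_b: RegionBurden,
                   metric: str) -> AssociationResult:
    """Fisher/OR/CI on the 2x2 built from one metric's two counters,
    metric counts as rows, groups as columns."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {sorted(METRICS)}, got {metric!r}")
    if group_a.region != group_b.region or group_a.mode != group_b.mode:
        raise ValueError(
            f"burden mismatch: {group_a.region}/{group_a.mode} vs "
            f"{group_b.region}/{group_b.mode}"
        )
    hi, lo = METRICS[metric]
    table = ContingencyTable2x2(
        getattr(group_a, hi), getattr(group_a, lo),
        getattr(group_b, hi), getattr(group_b, lo),
    )
    return associate(table)


def carrier_table(cohort: Cohort, predicate: CarrierPredicate,
                  scores=None,
                  exclusions: frozenset[tuple[int, str]] = DEFAULT_EXCLUSIONS,
                  ) -> ContingencyTable2x2:
    """2x2 of carriers vs non-carriers by group.

    a = patient carriers, b = patient non-carriers,
    c = control carriers, d = control non-carriers.
    ``scores`` (a :class:`~mitovar.variant_load.ScoreTable`) is required
    when the predicate has an active score threshold.
    """
    if predicate.score_threshold is not None and scores is None:
        raise ValueError("score filter active but no score table supplied")

    def passes(v: Variant, subject_id: str) -> bool:
        _check_annotated(v, subject_id)
        if v.key in exclusions:
            return False
        if predicate.region is not None and v.region != predicate.region:
            return False
        if predicate.rarity is not None and v.rarity != predicate.rarity:
            return False
        if predicate.score_threshold is not None:
            score = scores.get(v)
            if score is None or score <= predicate.score_threshold:
                return False
        return True

    counts = {}
    for group in ("patient", "control"):
        carriers = sum(
            any(passes(v, s.subject_id) for v in s) for s in cohort.group(group)
        )
        counts[group] = (carriers, len(cohort.group(group)) - carriers)
    return ContingencyTable2x2(
        counts["patient"][0], counts["patient"][1],
        counts["control"][0], counts["control"][1],
    )


def rarity_spectrum(cohort: Cohort, region: str, mode: str = "occurrence",
                    exclusions: frozenset[tuple[int, str]] = DEFAULT_EXCLUSIONS,
                    ) -> dict[str, dict]:
    """Rare/common shares per group for one region.

    Shares are counts / (rare + common); unknown-rarity variants are
    reported separately and excluded from the denominator. A region
    with no classified variants yields ``defined=False``.
    """
    burdens = tally(cohort, region, mode, exclusions)
    out = {}
    for group, b in burdens.items():
        denom = b.rare + b.common
        out[group] = {
            "n_rare": b.rare,
            "n_common": b.common,
            "n_unknown": b.unknown_rarity,
            "rare_share": b.rare / denom if denom else None,
            "common_share": b.common / denom if denom else None,
            "defined": denom > 0,
        }
    return out
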