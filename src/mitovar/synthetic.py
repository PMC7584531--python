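"""Synthetic cohort generation and printed-table fixtures.

The generator emulates the statistical structure the analysis assumes:
two groups (47 LHON-like patients, 42 controls by default) of
homoplasmic-dominant variant profiles. Every patient carries the
primary mutation m.11778G>A (homoplasmic except a ~4/47 chance of
70–95% heteroplasmy). Each subject draws a haplogroup from per-group
frequency vectors modelled on the observed distribution and inherits
that haplogroup's cumulative defining variants; private filler variants
are then drawn per region at configurable rare/common Poisson rates,
with transition probability ~0.97 and a ~0.40 non-synonymous fraction
among coding changes, matching whole-mtDNA variation surveys. The
generator also fabricates the population-frequency table (rare ≤0.5%,
common >0.5%) and a Beta-distributed pathogenicity score table for
non-synonymous variants, so the full pipeline runs without downloads.

Filler positions are drawn uniformly within each region, excluding
positions already used by the subject, all tree-marker positions and
the primary-mutation site — so haplogroup recovery on marker-complete
cohorts is exact by construction.

:func:`paper_fixture` reconstructs the association tables whose printed
inputs (group sizes and frequencies) fully determine the 2x2 cells,
and validates each against its printed odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, FrequencyTable, PRIMARY_MUTATION, SubjectProfile, Variant
from .haplotree import HaploTree, default_tree
from .reference import GeneModel, REGIONS, default_gene_model
from .stats import ContingencyTable2x2, counts_from_percent, odds_ratio
from .variant_load import ScoreTable

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

#: observed haplogroup percentages per group (reporting-level labels)
_HG_PCT_PATIENT = {"B": 2, "H": 32, "HV": 2, "I": 4, "J": 11, "K": 11,
                   "N": 4, "T": 6, "U": 19, "V": 2, "W": 4, "X": 2}
_HG_PCT_CONTROL = {"B": 0, "H": 43, "HV": 2, "I": 2, "J": 17, "K": 0,
                   "N": 2, "T": 2, "U": 12, "V": 12, "W": 2, "X": 5}


def _normalised(pct: dict[str, float]) -> dict[str, float]:
    total = sum(pct.values())
    return {k: v / total for k, v in pct.items()}


def _default_region_rates() -> dict[str, dict[str, tuple[float, float]]]:
    """Per-subject Poisson means of (rare, common) filler variants per
    region and group; sized to the observed ~26 variants/subject, with
    the complex IV rare excess placed in controls."""
    base = {
        "complexI": (0.9, 5.0),
        "complexIII": (0.5, 2.4),
        "complexIV": (0.35, 1.5),
        "ATPsynthase": (0.3, 1.4),
        "rRNA": (0.6, 3.4),
        "tRNA": (0.15, 0.55),
        "noncoding": (1.4, 6.9),
    }
    control = dict(base)
    control["complexIV"] = (0.65, 1.5)
    return {"patient": base, "control": control}


@dataclass
class SimulationConfig:
    n_patients: int = 47
    n_controls: int = 42
    haplogroup_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "patient": _normalised(_HG_PCT_PATIENT),
            "control": _normalised(_HG_PCT_CONTROL),
        }
    )
    marker_fidelity: float = 1.0
    region_rates: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_region_rates
    )
    ts_prob: float = 0.97
    ns_prob: float = 0.40
    score_dist: tuple[float, float] = (2.0, 3.0)  # Beta(a, b)
    heteroplasmy_prob: float = 4 / 47
    heteroplasmy_range: tuple[float, float] = (70.0, 95.0)
    seed: int = 0

    def __post_init__(self):
        for group, freqs in self.haplogroup_freqs.items():
            total = sum(freqs.values())
            if freqs and not np.isclose(total, 1.0):
                raise ValueError(
                    f"haplogroup frequencies for {group} sum to {total}, not 1"
                )
            if any(p < 0 for p in freqs.values()):
                raise ValueError("negative haplogroup frequency")
        for group, rates in self.region_rates.items():
            for region, (rare, common) in rates.items():
                if region not in REGIONS:
                    raise ValueError(f"unknown region in rates: {region!r}")
                if rare < 0 or common < 0:
                    raise ValueError("region rates must be non-negative")

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Both groups share the patient-group generating process
        (identical haplogroup frequencies and region rates)."""
        cfg = cls(seed=seed, **overrides)
        cfg.haplogroup_freqs["control"] = dict(cfg.haplogroup_freqs["patient"])
        cfg.region_rates["control"] = dict(cfg.region_rates["patient"])
        return cfg


@dataclass
class SimulationTruth:
    """Generator-side bookkeeping, usable as an oracle in tests."""

    haplogroups: dict[str, str] = field(default_factory=dict)
    # (subject_id, group, region, position, ref, alt, rarity_class)
    variants: list[tuple] = field(default_factory=list)


@dataclass
class SimulationResult:
    cohort: Cohort
    frequency_table: FrequencyTable
    score_table: ScoreTable
    truth: SimulationTruth
    config: SimulationConfig


def _region_pools(model: GeneModel, excluded: set[int]) -> dict[str, np.ndarray]:
    pools: dict[str, list[int]] = {r: [] for r in REGIONS}
    for p in range(1, model.length + 1):
        if p in excluded:
            continue
        pools[model.locate(p)[1]].append(p)
    return {r: np.array(v) for r, v in pools.items()}


def simulate_cohort(config: SimulationConfig,
                    model: GeneModel | None = None,
                    tree: HaploTree | None = None) -> SimulationResult:
    """Draw a cohort, its frequency table and its score table.

    Reproducible: one pseudo-random stream seeded from the config,
    consumed subject by subject (patients first), so appending subjects
    never perturbs earlier ones. Within a subject the order is:
    haplogroup draw, marker variants, then per-region filler; each new
    variant draws its population frequency (and pathogenicity score if
    non-synonymous) when first seen cohort-wide, and its heteroplasmy
    at creation (only the primary mutation has a heteroplasmic
    component).
    """
    from .reference import annotate_effect

    if model is None:
        model = default_gene_model()
    if tree is None:
        tree = default_tree()
    rng = np.random.default_rng(config.seed)

    marker_positions = {pos for node in tree.nodes.values()
                        for pos, _ in node.cumulative}
    pools = _region_pools(model, marker_positions | {PRIMARY_MUTATION[0]})

    freq = FrequencyTable()
    scores = ScoreTable()
    truth = SimulationTruth()
    subjects: list[SubjectProfile] = []

    def effect_category(pos: int, ref: str, alt: str) -> str:
        return annotate_effect(pos, ref, alt, model).category

    def register(variant: Variant, rarity_class: str | None) -> None:
        """First-seen bookkeeping: population frequency and NS score."""
        if variant.key not in freq:
            if rarity_class == "rare":
                pct = float(rng.uniform(0.05, 0.5))
            elif rarity_class == "common":
                pct = float(rng.uniform(0.6, 30.0))
            else:  # haplogroup marker / primary mutation: fixed class
                pct = float(rng.uniform(2.0, 45.0))
            if variant.key == PRIMARY_MUTATION:
                pct = 0.2
            freq[variant.key] = pct
            cat = effect_category(variant.position, variant.ref, variant.alt)
            if cat == "non-synonymous":
                a, b = config.score_dist
                scores.set_variant(variant.key, float(rng.beta(a, b)))

    def make_subject(sid: str, group: str) -> SubjectProfile:
        profile = SubjectProfile(sid, group)
        freqs = config.haplogroup_freqs[group]
        labels = sorted(freqs)
        hg = str(rng.choice(labels, p=[freqs[l] for l in labels]))
        truth.haplogroups[sid] = hg

        markers = sorted(tree.nodes[hg].cumulative)
        if markers and rng.random() >= config.marker_fidelity:
            markers.pop(int(rng.integers(len(markers))))  # one dropped marker
        for pos, alt in markers:
            v = Variant(pos, model.base(pos), alt)
            profile.add(v)
            register(v, None)
            truth.variants.append(
                (sid, group, model.locate(pos)[1], pos, v.ref, alt, "marker")
            )

        if group == "patient":
            het = 100.0
            if rng.random() < config.heteroplasmy_prob:
                het = float(rng.uniform(*config.heteroplasmy_range))
            pos, alt = PRIMARY_MUTATION
            v = Variant(pos, model.base(pos), alt, heteroplasmy_fraction=het)
            profile.add(v)
            register(v, None)
            truth.variants.append(
                (sid, group, model.locate(pos)[1], pos, v.ref, alt, "primary")
            )

        used = {pos for pos, _ in profile.variants}
        for region in REGIONS:
            rare_rate, common_rate = config.region_rates[group].get(
                region, (0.0, 0.0)
            )
            for rarity_class, rate in (("rare", rare_rate),
                                       ("common", common_rate)):
                for _ in range(rng.poisson(rate)):
                    v = _draw_filler(
                        rng, pools[region], used, model, config, region
                    )
                    if v is None:
                        continue
                    used.add(v.position)
                    profile.add(v)
                    register(v, rarity_class)
                    truth.variants.append(
                        (sid, group, region, v.position, v.ref, v.alt,
                         rarity_class)
                    )
        return profile

    for i in range(config.n_patients):
        subjects.append(make_subject(f"P{i + 1:03d}", "patient"))
    for i in range(config.n_controls):
        subjects.append(make_subject(f"C{i + 1:03d}", "control"))

    return SimulationResult(Cohort(subjects), freq, scores, truth, config)


def _draw_filler(rng, pool, used, model, config, region,
                 max_tries: int = 60) -> Variant | None:
    """One private variant in a region: transition with probability
    ts_prob; in coding regions, rejection-sample toward a target
    synonymous/non-synonymous category (probability ns_prob of NS)."""
    from .reference import CODING_REGIONS, annotate_effect

    if len(pool) == 0:
        return None
    is_transition = rng.random() < config.ts_prob
    target = None
    if region in CODING_REGIONS:
        target = ("non-synonymous" if rng.random() < config.ns_prob
                  else "synonymous")
    last = None
    for _ in range(max_tries):
        pos = int(pool[rng.integers(len(pool))])
        if pos in used:
            continue
        ref = model.base(pos)
        alt = (_TRANSITION[ref] if is_transition
               else _TRANSVERSIONS[ref][rng.integers(2)])
        v = Variant(pos, ref, alt)
        if target is None:
            return v
        if annotate_effect(pos, ref, alt, model).category == target:
            return v
        last = v
    return last  # category target unmet after max_tries; accept anyway


# -- printed-table fixtures ------------------------------------------

@dataclass(frozen=True)
class FixtureEntry:
    table: ContingencyTable2x2
    expected: dict  # printed statistics: p, OR, ci_low, ci_high, corrected


@dataclass(frozen=True)
class PaperFixture:
    tables: dict[str, FixtureEntry]
    #: (mean, sd, n) per group for the two variant loads, plus printed p
    load_summaries: dict[str, dict]

    def __getitem__(self, name: str) -> FixtureEntry:
        return self.tables[name]

    def __len__(self):
        return len(self.tables)


_HAPLOGROUP_STATS = {
    # printed (p, OR, ci_low, ci_high, corrected)
    "B": (1.000, 2.742, 0.109, 69.144, True),
    "H": (0.380, 0.625, 0.263, 1.486, False),
    "HV": (1.000, 0.891, 0.054, 14.710, False),
    "I": (1.000, 1.822, 0.159, 20.854, False),
    "J": (0.537, 0.595, 0.174, 2.041, False),
    "K": (0.057, 11.000, 0.590, 205.205, True),
    "N": (1.000, 1.822, 0.159, 20.854, False),
    "T": (0.619, 2.795, 0.279, 27.961, False),
    "U": (0.396, 1.753, 0.537, 5.722, False),
    "V": (0.096, 0.161, 0.018, 1.438, False),
    "W": (1.000, 1.822, 0.159, 20.854, False),
    "X": (0.600, 0.435, 0.038, 4.976, False),
}

_SNV_STATS = {
    "m.73A>G": (66, 43, 0.035, 2.583, 1.095, 6.097, False),
    "m.3480A>G": (13, 0, 0.028, 13.313, 0.727, 243.917, True),
    "m.9055G>A": (13, 0, 0.028, 13.313, 0.727, 243.917, True),
    "m.11299T>C": (13, 0, 0.028, 13.313, 0.727, 243.917, True),
    "m.14167C>T": (13, 0, 0.028, 13.313, 0.727, 243.917, True),
}


def paper_fixture(n_patients: int = 47, n_controls: int = 42) -> PaperFixture:
    """2x2 tables reconstructed from printed group sizes and
    frequencies, each validated against its printed odds ratio."""
    tables: dict[str, FixtureEntry] = {}

    def add(name: str, a: int, c: int, p, or_, lo, hi, corrected) -> None:
        table = ContingencyTable2x2(a, n_patients - a, c, n_controls - c)
        got_or, got_corr = odds_ratio(table)
        if round(got_or, 3) != or_ or got_corr != corrected:
            raise AssertionError(
                f"fixture {name}: OR {got_or:.3f} (corrected={got_corr}) "
                f"does not reproduce printed {or_}"
            )
        tables[name] = FixtureEntry(
            table,
            {"p": p, "OR": or_, "ci_low": lo, "ci_high": hi,
             "corrected": corrected},
        )

    for hg, (p, or_, lo, hi, corr) in _HAPLOGROUP_STATS.items():
        pct_p = _HG_PCT_PATIENT[hg]
        pct_c = _HG_PCT_CONTROL[hg]
        add(f"haplogroup:{hg}", counts_from_percent(pct_p, n_patients),
            counts_from_percent(pct_c, n_controls), p, or_, lo, hi, corr)

    for snv, (pct_p, pct_c, p, or_, lo, hi, corr) in _SNV_STATS.items():
        add(f"snv:{snv}", counts_from_percent(pct_p, n_patients),
            counts_from_percent(pct_c, n_controls), p, or_, lo, hi, corr)

    add("carrier:score_gt_0.5",
        counts_from_percent(62, n_patients), counts_from_percent(43, n_controls),
        0.091, 2.148, 0.920, 5.017, False)
    add("carrier:rare_complexIV",
        counts_from_percent(30, n_patients), counts_from_percent(45, n_controls),
        0.187, 0.514, 0.215, 1.228, False)

    # count-based rows printed in full (transitions/transversions and
    # non-synonymous/synonymous per region)
    def add_counts(name, a, b, c, d, p, or_, lo, hi, corrected):
        table = ContingencyTable2x2(a, b, c, d)
        got_or, got_corr = odds_ratio(table)
        if round(got_or, 3) != or_ or got_corr != corrected:
            raise AssertionError(f"fixture {name}: OR mismatch ({got_or:.3f})")
        tables[name] = FixtureEntry(
            table, {"p": p, "OR": or_, "ci_low": lo, "ci_high": hi,
                    "corrected": corrected})

    add_counts("tstv:rRNA", 188, 0, 143, 1, 0.434, 3.941, 0.159, 97.450, True)
    add_counts("nss:complexIII", 113, 23, 88, 8, 0.077, 0.447, 0.191, 1.046,
               False)

    load_summaries = {
        "total": {"patient": (1.970, 0.901, n_patients),
                  "control": (1.762, 0.961, n_controls), "p": 0.295},
        "threshold": {"patient": (0.525, 0.501, n_patients),
                      "control": (0.452, 0.600, n_controls), "p": 0.531},
    }
    return PaperFixture(tables, load_summaries)
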