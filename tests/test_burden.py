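"""Regional burden tallies, exclusion rule and group comparisons."""

import math

import pytest

from mitovar.burden import (
    CarrierPredicate,
    RegionBurden,
    carrier_table,
    compare_burden,
    rarity_spectrum,
    tally,
    ts_tv_ratio,
)
from mitovar.cohort import (
    Cohort,
    FrequencyTable,
    PRIMARY_MUTATION,
    SubjectProfile,
    Variant,
    annotate_cohort,
)
from mitovar.reference import REGIONS
from mitovar.stats import associate

NO_EXCLUSIONS = frozenset()


def toy_cohort(model, spec):
    """spec: list of (sid, group, [(pos, alt, freq_pct), ...])."""
    subjects = []
    freq = FrequencyTable()
    for sid, group, variants in spec:
        s = SubjectProfile(sid, group)
        for pos, alt, pct in variants:
            s.add(Variant(pos, model.base(pos), alt))
            if pct is not None:
                freq[(pos, alt)] = pct
        subjects.append(s)
    cohort = Cohort(subjects)
    annotate_cohort(cohort, model, freq)
    return cohort


class TestTally:
    def test_empty_cohort_is_all_zero(self, model):
        cohort = toy_cohort(model, [("P1", "patient", []),
                                    ("C1", "control", [])])
        b = tally(cohort, "overall")
        for group in ("patient", "control"):
            assert b[group].total == 0
            assert b[group].ns == b[group].s == 0

    def test_shared_transition_occurrence_vs_unique(self, model):
        spec = [(f"P{i}", "patient", [(73, "G", 25.0)]) for i in range(3)]
        spec.append(("C1", "control", []))
        cohort = toy_cohort(model, spec)
        occ = tally(cohort, "noncoding", "occurrence")["patient"]
        uniq = tally(cohort, "noncoding", "unique")["patient"]
        assert (occ.ts, occ.tv) == (3, 0)
        assert (uniq.ts, uniq.tv) == (1, 0)

    def test_counts_match_generator_bookkeeping(self, sim_result):
        """Generator-side records are the oracle for per-region counts."""
        cohort, truth = sim_result.cohort, sim_result.truth
        freq = sim_result.frequency_table
        for region in REGIONS:
            expected = {"patient": [0, 0, 0, 0],  # ts, tv, rare, common
                        "control": [0, 0, 0, 0]}
            for sid, group, reg, pos, ref, alt, _cls in truth.variants:
                if reg != region:
                    continue
                if region == "complexI" and (pos, alt) == PRIMARY_MUTATION:
                    continue
                purines = {"A", "G"}
                is_ts = (ref in purines) == (alt in purines)
                expected[group][0 if is_ts else 1] += 1
                pct = freq.get((pos, alt))
                if pct is not None:
                    expected[group][2 if pct <= 0.5 else 3] += 1
            got = tally(sim_result.cohort, region)
            for group in ("patient", "control"):
                b = got[group]
                assert [b.ts, b.tv, b.rare, b.common] == expected[group], region

    def test_primary_mutation_exclusion_deltas(self, cohort):
        carriers = sum(
            PRIMARY_MUTATION in s.variants for s in cohort.group("patient"))
        assert carriers == cohort.n_patients  # every patient carries it
        with_excl = tally(cohort, "overall", "occurrence")["patient"]
        without = tally(cohort, "overall", "occurrence",
                        exclusions=NO_EXCLUSIONS)["patient"]
        assert without.ts - with_excl.ts == carriers
        u_with = tally(cohort, "overall", "unique")["patient"]
        u_without = tally(cohort, "overall", "unique",
                          exclusions=NO_EXCLUSIONS)["patient"]
        assert u_without.ts - u_with.ts == 1

    def test_region_tallies_sum_to_overall(self, cohort):
        for group in ("patient", "control"):
            total = [0, 0, 0, 0, 0]
            for region in REGIONS:
                b = tally(cohort, region)[group]
                for i, attr in enumerate(("ts", "tv", "rare", "common", "ns")):
                    total[i] += getattr(b, attr)
            overall = tally(cohort, "overall")[group]
            assert total == [overall.ts, overall.tv, overall.rare,
                             overall.common, overall.ns]

    def test_unique_never_exceeds_occurrence(self, cohort):
        for region in list(REGIONS) + ["overall"]:
            for group in ("patient", "control"):
                occ = tally(cohort, region, "occurrence")[group]
                uniq = tally(cohort, region, "unique")[group]
                for attr in ("ts", "tv", "rare", "common", "ns", "s"):
                    assert getattr(uniq, attr) <= getattr(occ, attr)

    def test_unannotated_variant_names_subject_and_position(self, model):
        s = SubjectProfile("P1", "patient")
        s.add(Variant(73, "A", "G"))
        with pytest.raises(ValueError, match="P1.*73|73.*P1"):
            tally(Cohort([s]), "overall")

    def test_invalid_region_or_mode_rejected(self, cohort):
        with pytest.raises(ValueError):
            tally(cohort, "complexV")
        with pytest.raises(ValueError):
            tally(cohort, "overall", "both")


class TestTsTvRatio:
    @pytest.mark.parametrize(
        ("ts", "tv", "expected"),
        [(1189, 34, 34.97), (298, 10, 29.80), (143, 1, 143.00)],
    )
    def test_published_ratio_arithmetic(self, ts, tv, expected):
        b = RegionBurden("overall", "patient", "occurrence", ts=ts, tv=tv)
        assert round(ts_tv_ratio(b), 2) == expected

    def test_no_transversions_is_undefined(self):
        b = RegionBurden("rRNA", "patient", "occurrence", ts=188, tv=0)
        assert ts_tv_ratio(b) is None


class TestCompareBurden:
    def test_rrna_tstv_comparison_matches_published(self):
        a = RegionBurden("rRNA", "patient", "occurrence", ts=188, tv=0)
        b = RegionBurden("rRNA", "control", "occurrence", ts=143, tv=1)
        res = compare_burden(a, b, "ts_vs_tv")
        assert round(res.odds_ratio, 3) == 3.941
        assert res.haldane_applied
        assert round(res.p_value, 3) == 0.434

    def test_complex3_nss_comparison_matches_published(self):
        a = RegionBurden("complexIII", "patient", "occurrence", ns=113, s=23)
        b = RegionBurden("complexIII", "control", "occurrence", ns=88, s=8)
        res = compare_burden(a, b, "ns_vs_s")
        assert round(res.odds_ratio, 3) == 0.447
        assert round(res.p_value, 3) == 0.077
        assert not res.haldane_applied

    def test_identical_burdens_are_null(self):
        a = RegionBurden("tRNA", "patient", "occurrence", rare=5, common=10)
        b = RegionBurden("tRNA", "control", "occurrence", rare=5, common=10)
        res = compare_burden(a, b, "rare_vs_common")
        assert res.odds_ratio == 1.0
        assert res.p_value == 1.0

    def test_agrees_with_direct_stats_call(self, cohort):
        b = tally(cohort, "complexI")
        res = compare_burden(b["patient"], b["control"], "ts_vs_tv")
        direct = associate((b["patient"].ts, b["patient"].tv,
                            b["control"].ts, b["control"].tv))
        assert res.p_value == direct.p_value
        assert res.odds_ratio == direct.odds_ratio

    def test_mode_mismatch_rejected(self):
        a = RegionBurden("tRNA", "patient", "occurrence", ts=1)
        b = RegionBurden("tRNA", "control", "unique", ts=1)
        with pytest.raises(ValueError, match="mismatch"):
            compare_burden(a, b, "ts_vs_tv")


class TestCarriers:
    def test_matching_nothing_gives_margin_counts(self, cohort):
        t = carrier_table(cohort, CarrierPredicate(region="tRNA",
                                                   rarity="unknown"))
        assert (t.a, t.c) == (0, 0)
        assert t.b == cohort.n_patients
        assert t.d == cohort.n_controls

    def test_score_filter_without_scores_rejected(self, cohort):
        with pytest.raises(ValueError, match="score"):
            carrier_table(cohort, CarrierPredicate(score_threshold=0.5))

    def test_primary_mutation_never_makes_carriers(self, model):
        spec = [("P1", "patient", [(11778, "A", 0.2)]),
                ("C1", "control", [])]
        cohort = toy_cohort(model, spec)
        t = carrier_table(cohort, CarrierPredicate(rarity="rare"))
        assert t.a == 0

    def test_rare_region_carriers(self, model):
        spec = [
            ("P1", "patient", [(7586, "A", 0.1)]),   # rare complexIV (CO2)
            ("P2", "patient", [(73, "G", 25.0)]),
            ("C1", "control", [(9207, "T", 0.3)]),   # rare complexIV (CO3)
            ("C2", "control", []),
        ]
        cohort = toy_cohort(model, spec)
        t = carrier_table(cohort,
                          CarrierPredicate(region="complexIV", rarity="rare"))
        assert t.cells == (1, 1, 1, 1)


class TestRaritySpectrum:
    def test_empty_region_flagged_undefined(self, model):
        cohort = toy_cohort(model, [("P1", "patient", []),
                                    ("C1", "control", [])])
        spec = rarity_spectrum(cohort, "tRNA")
        assert not spec["patient"]["defined"]
        assert spec["patient"]["rare_share"] is None

    def test_all_rare_cohort_has_unit_share(self, model):
        spec_in = [("P1", "patient", [(7586, "A", 0.1), (73, "G", 0.2)]),
                   ("C1", "control", [(9207, "T", 0.3)])]
        cohort = toy_cohort(model, spec_in)
        for region in ("complexIV", "noncoding"):
            out = rarity_spectrum(cohort, region)["patient"]
            if out["defined"]:
                assert out["rare_share"] == 1.0

    def test_unknown_rarity_excluded_from_denominator(self, model):
        spec_in = [("P1", "patient", [(7586, "A", 0.1), (7587, "A", None)]),
                   ("C1", "control", [])]
        cohort = toy_cohort(model, spec_in)
        out = rarity_spectrum(cohort, "complexIV")["patient"]
        assert out["n_unknown"] == 1
        assert out["rare_share"] == 1.0
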