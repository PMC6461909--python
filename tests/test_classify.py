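"""Dependence profiling, the seven-category classifier, and marker concordance."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cobamide_scout.catalog import AnnotationID
from cobamide_scout.classify import (CATEGORIES, CATEGORY_GROUP, PhenotypeCall,
                                     RuleError, RuleSet, classify_biosynthesis,
                                     classify_cohort, marker_concordance,
                                     profile_dependence,
                                     subtype_precursor_salvager)
from cobamide_scout.ingest import AnnotationProfile

from conftest import ALL_NLA, ALL_RING, NON_MARKER_RING, profile_from_groups


class TestDependence:
    def test_meth_and_mete_yield_both(self, catalog):
        p = AnnotationProfile("T", {AnnotationID("EC", "2.1.1.13"): 1,
                                    AnnotationID("EC", "2.1.1.14"): 1})
        dep = profile_dependence(p, catalog)
        assert "metH" in dep.families_present
        assert dep.process_status["methionine_synthesis"] == "both"

    def test_empty_profile(self, catalog):
        dep = profile_dependence(AnnotationProfile("T", {}), catalog)
        assert dep.n_families == 0 and not dep.uses_cobamides
        assert set(dep.process_status.values()) == {"neither"}

    def test_random_profiles_match_naive_family_count(self, catalog):
        """200 random profiles: n_families equals a brute-force loop over
        the catalog's dependent families."""
        rng = np.random.default_rng(8)
        universe = sorted(catalog.all_annotation_ids, key=str)
        for _ in range(200):
            k = int(rng.integers(0, 20))
            chosen = rng.choice(len(universe), size=k, replace=False)
            p = AnnotationProfile("R", {universe[int(i)]: 1 for i in chosen})
            naive = sum(
                1 for fam in catalog.families if fam.dependent
                and any(a in p.counts for a in fam.annotation_ids))
            assert profile_dependence(p, catalog).n_families == naive

    def test_propionate_caveat_attached(self, catalog):
        dep = profile_dependence(AnnotationProfile("T", {}), catalog)
        assert "propionate_metabolism" in dep.caveats


class TestClassifier:
    def test_complete_pathway_with_markers_is_very_likely(self, catalog, rules):
        p = profile_from_groups(catalog, ring=ALL_RING, nla=ALL_NLA)
        call = classify_biosynthesis(p, catalog, rules)
        assert call.category == "very_likely_producer"
        assert call.group == "complete_biosynthesis"

    def test_nucleotide_loop_only_is_cbi_salvager(self, catalog, rules):
        p = profile_from_groups(catalog, ring=(), nla=ALL_NLA)
        call = classify_biosynthesis(p, catalog, rules)
        assert call.category == "cbi_salvager"
        assert call.group == "partial_biosynthesis"

    def test_four_ring_groups_incomplete_loop_is_nonproducer(self, catalog, rules):
        p = profile_from_groups(catalog, ring=NON_MARKER_RING[:4],
                                nla=ALL_NLA[:2])
        call = classify_biosynthesis(p, catalog, rules)
        assert call.group == "no_biosynthesis"

    def test_empty_profile_is_very_likely_nonproducer(self, catalog, rules):
        call = classify_biosynthesis(AnnotationProfile("T", {}), catalog, rules)
        assert call.category == "very_likely_nonproducer"

    def test_missing_tetrapyrrole_prefix_flips_producer_to_salvager(
            self, catalog, rules):
        p = profile_from_groups(catalog, ring=ALL_RING, nla=ALL_NLA,
                                tp_steps=["hemB", "hemC", "hemD"])
        call = classify_biosynthesis(p, catalog, rules)
        assert call.category == "tetrapyrrole_precursor_salvager"
        assert call.salvager_subtype == "ALA"

    def test_noncontiguous_absence_stays_producer_with_note(self, catalog, rules):
        p = profile_from_groups(catalog, ring=ALL_RING, nla=ALL_NLA,
                                tp_steps=["hemL", "hemC", "hemD"])
        call = classify_biosynthesis(p, catalog, rules)
        assert call.category == "very_likely_producer"
        assert any("inconsistent" in n for n in call.notes)

    def test_every_genome_gets_exactly_one_category(self, catalog, rules,
                                                    noisy_cohort):
        calls = classify_cohort(noisy_cohort.profiles, catalog, rules)
        assert set(calls) == {p.genome_id for p in noisy_cohort.profiles}
        for call in calls.values():
            assert call.category in CATEGORIES
            assert call.group == CATEGORY_GROUP[call.category]

    def test_evidence_records_segment_counts(self, catalog, rules):
        p = profile_from_groups(catalog, ring=ALL_RING[:6], nla=ALL_NLA[:3])
        call = classify_biosynthesis(p, catalog, rules)
        assert call.evidence["corrin_ring"] == 6
        assert call.evidence["nucleotide_loop"] == 3
        assert call.evidence["tetrapyrrole_precursor"] == 5

    def test_inconsistent_thresholds_rejected(self):
        with pytest.raises(RuleError, match="floor"):
            RuleSet(cr_possible_min=2, cr_likely_nonproducer_min=3)

    def test_call_invariant_subtype_only_for_salvagers(self):
        with pytest.raises(RuleError):
            PhenotypeCall("T", "very_likely_producer", {}, salvager_subtype="ALA")

    def test_overrides_force_category(self, catalog, rules):
        p = profile_from_groups(catalog, ring=ALL_RING, nla=ALL_NLA)
        calls = classify_cohort([p], catalog, rules,
                                overrides={"T1": "possible_producer"})
        assert calls["T1"].category == "possible_producer"
        assert calls["T1"].overridden


class TestSubtype:
    def test_all_present_is_not_a_salvager(self, catalog):
        p = profile_from_groups(catalog)
        assert subtype_precursor_salvager(p, catalog) is None

    @pytest.mark.parametrize("present,expected", [
        (["hemL", "hemB", "hemC", "hemD"], "GSA"),
        (["hemB", "hemC", "hemD"], "ALA"),
        (["hemC", "hemD"], "PBG"),
        (["hemD"], "HMB"),
        ([], "UroIII"),
    ])
    def test_contiguous_prefix_maps_to_precursor(self, catalog, present, expected):
        p = profile_from_groups(catalog, tp_steps=present)
        assert subtype_precursor_salvager(p, catalog) == expected

    def test_noncontiguous_absence_returns_none(self, catalog):
        # hemA absent, hemL present, hemB absent: not simple auxotrophy
        p = profile_from_groups(catalog, tp_steps=["hemL", "hemC", "hemD"])
        assert subtype_precursor_salvager(p, catalog) is None


class TestMarkerConcordance:
    def test_all_producers_carry_all_markers(self, catalog, rules):
        profiles = {f"G{i}": profile_from_groups(catalog, f"G{i}",
                                                 ring=ALL_RING, nla=ALL_NLA)
                    for i in range(5)}
        calls = classify_cohort(profiles.values(), catalog, rules)
        table = marker_concordance(calls, profiles, catalog)
        for m in catalog.marker_set.markers:
            assert table.loc[m, "very_likely_producer"] == 100.0
        triple = " and ".join(catalog.marker_set.markers)
        assert table.loc[triple, "all_producers"] == 100.0

    def test_empty_category_is_undefined_not_zero(self, catalog, rules):
        profiles = {"G0": AnnotationProfile("G0", {})}
        calls = classify_cohort(profiles.values(), catalog, rules)
        table = marker_concordance(calls, profiles, catalog)
        assert math.isnan(table.loc[catalog.marker_set.markers[0],
                                    "likely_producer"])
        assert table.attrs["n"]["likely_producer"] == 0

    def test_random_cohort_matches_brute_force_tally(self, catalog, rules,
                                                     noisy_cohort):
        profiles = {p.genome_id: p for p in noisy_cohort.profiles}
        calls = classify_cohort(profiles.values(), catalog, rules)
        table = marker_concordance(calls, profiles, catalog)
        ring = catalog.ortholog_groups("corrin_ring", scored_only=False)
        for marker in catalog.marker_set.markers:
            for cat in CATEGORIES:
                members = [g for g, c in calls.items() if c.category == cat]
                if not members:
                    continue
                hits = 0
                for g in members:  # independent recount
                    anns = ring[marker]
                    if any(profiles[g].counts.get(a, 0) >= 1 for a in anns):
                        hits += 1
                assert table.loc[marker, cat] == pytest.approx(
                    100.0 * hits / len(members))
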