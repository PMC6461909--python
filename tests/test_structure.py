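"""Lower-ligand structure: tandem cobT detection, bza logic, determinants."""

from __future__ import annotations

import numpy as np
import pytest
import yaml

from cobamide_scout.catalog import AnnotationID
from cobamide_scout.ingest import AnnotationProfile, GeneRecord, HmmHit
from cobamide_scout.structure import (BzaComplement, ComboMapError,
                                      bza_complement, detect_arsAB,
                                      load_combo_map, predict_benzimidazole,
                                      predict_structure)

COBT = frozenset({AnnotationID("IMGTerm", "TERM:cobT")})


def gene(gid, genome, ordinal, length, cobt=True, scaffold="s1"):
    return GeneRecord(gid, genome, scaffold, ordinal, length,
                      COBT if cobt else frozenset())


def arsab_oracle(genes, cobt_ids):
    """Independent exhaustive scan over all adjacent gene pairs."""
    accepted = set()
    cobt = set(cobt_ids)
    pool = sorted((g for g in genes if g.annotations & cobt),
                  key=lambda g: (g.genome_id, g.scaffold, g.ordinal))
    for a in pool:
        for b in pool:
            if (a.genome_id == b.genome_id and a.scaffold == b.scaffold
                    and b.ordinal == a.ordinal + 1
                    and 300 <= a.protein_length_aa <= 800
                    and 300 <= b.protein_length_aa <= 800):
                accepted.add((a.genome_id, a.gene_id, b.gene_id))
    return accepted


def random_gene_table(rng, n_genomes=3):
    genes = []
    for g in range(n_genomes):
        genome = f"G{g}"
        ordinal = 1
        for _ in range(int(rng.integers(1, 8))):
            genes.append(gene(f"{genome}_g{ordinal}", genome, ordinal,
                              int(rng.integers(100, 1000)),
                              cobt=bool(rng.random() < 0.6)))
            if rng.random() < 0.3:   # leave gaps so adjacency actually varies
                ordinal += int(rng.integers(2, 4))
            else:
                ordinal += 1
    return genes


class TestDetectArsAB:
    def test_adjacent_pair_in_window_accepted(self):
        genes = [gene("a", "G1", 1, 350), gene("b", "G1", 2, 340)]
        calls = detect_arsAB(genes, COBT)
        assert len(calls) == 1 and calls[0].accepted
        assert calls[0].lengths_aa == (350, 340)

    def test_short_member_rejected(self):
        genes = [gene("a", "G1", 1, 250), gene("b", "G1", 2, 340)]
        calls = detect_arsAB(genes, COBT)
        assert len(calls) == 1 and not calls[0].accepted

    @pytest.mark.parametrize("lengths,ok", [
        ((300, 800), True), ((299, 400), False), ((400, 801), False)])
    def test_window_is_inclusive(self, lengths, ok):
        genes = [gene("a", "G1", 1, lengths[0]), gene("b", "G1", 2, lengths[1])]
        assert detect_arsAB(genes, COBT)[0].accepted is ok

    def test_isolated_cobt_makes_no_call(self):
        assert detect_arsAB([gene("a", "G1", 1, 350)], COBT) == []

    def test_different_scaffolds_not_tandem(self):
        genes = [gene("a", "G1", 1, 350, scaffold="s1"),
                 gene("b", "G1", 2, 340, scaffold="s2")]
        assert detect_arsAB(genes, COBT) == []

    def test_random_tables_match_exhaustive_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            genes = random_gene_table(rng)
            got = {(c.genome_id, *c.pair)
                   for c in detect_arsAB(genes, COBT) if c.accepted}
            assert got == arsab_oracle(genes, COBT)


class TestBzaLogic:
    def _c(self, genes):
        return BzaComplement("G1", frozenset(genes))

    @pytest.mark.parametrize("genes,compound", [
        (["bzaF"], "5-OHBza"),
        (["bzaA", "bzaB"], "5-OHBza"),
        (["bzaF", "bzaC"], "5-OMeBza"),
        (["bzaA", "bzaB", "bzaC", "bzaD"], "5-OMe-6-MeBza"),
        (["bzaF", "bzaC", "bzaD", "bzaE"], "DMB"),
        (["bzaA", "bzaB", "bzaC", "bzaD", "bzaE"], "DMB"),
    ])
    def test_known_complements(self, combo_map, genes, compound):
        assert predict_benzimidazole(self._c(genes), combo_map) == compound

    @pytest.mark.parametrize("genes", [[], ["bzaC"], ["bzaA"], ["bzaB"],
                                       ["bzaC", "bzaD", "bzaE"]])
    def test_first_step_missing_yields_no_call(self, combo_map, genes):
        assert predict_benzimidazole(self._c(genes), combo_map) is None

    @pytest.mark.parametrize("genes", [["bzaF", "bzaD"], ["bzaF", "bzaE"],
                                       ["bzaA", "bzaB", "bzaE"]])
    def test_capable_but_unmapped_is_unresolved(self, combo_map, genes):
        assert predict_benzimidazole(self._c(genes), combo_map) == "unresolved"

    def test_removing_first_step_always_yields_none(self, combo_map):
        rng = np.random.default_rng(3)
        genes = ["bzaA", "bzaB", "bzaC", "bzaD", "bzaE", "bzaF"]
        for _ in range(50):
            sub = {g for g in genes if rng.random() < 0.5}
            stripped = frozenset(sub - {"bzaF", "bzaA", "bzaB"})
            assert predict_benzimidazole(self._c(stripped), combo_map) is None

    def test_combo_lacking_first_step_is_config_error(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text(yaml.safe_dump(
            {"combos": [{"genes": ["bzaC", "bzaD"], "compound": "DMB"}]}))
        with pytest.raises(ComboMapError, match="first-step"):
            load_combo_map(p)

    def test_below_cutoff_hits_never_contribute(self):
        hits = [HmmHit("G1", "g1", "bzaF", 219.9, 220.0),
                HmmHit("G1", "g2", "bzaC", 180.0, 150.0)]
        assert bza_complement("G1", hits).genes_present == {"bzaC"}


class TestPredictStructure:
    def test_blub_alone_predicts_cobalamin(self, catalog, combo_map):
        p = AnnotationProfile("G1", {AnnotationID("TIGRFAM", "TIGR02476"): 1})
        pred = predict_structure(p, [], [], catalog, combo_map)
        assert (pred.determinant, pred.predicted_compound) == ("bluB", "DMB")

    def test_no_determinants(self, catalog, combo_map):
        pred = predict_structure(AnnotationProfile("G1", {}), [], [],
                                 catalog, combo_map)
        assert pred.determinant == "none"
        assert pred.predicted_compound is None

    def test_cbiz_only_sets_remodel_flag(self, catalog, combo_map):
        p = AnnotationProfile("G1", {AnnotationID("IMGTerm", "TERM:cbiZ"): 1})
        pred = predict_structure(p, [], [], catalog, combo_map)
        assert pred.can_remodel and pred.determinant == "none"

    def test_precedence_bza_over_blub_over_arsab(self, catalog, combo_map):
        p = AnnotationProfile("G1", {AnnotationID("TIGRFAM", "TIGR02476"): 1})
        genes = [gene("a", "G1", 1, 350), gene("b", "G1", 2, 340)]
        hits = [HmmHit("G1", "g9", "bzaF", 300.0, 220.0)]
        pred = predict_structure(p, genes, hits, catalog, combo_map)
        assert pred.determinant == "bza"
        assert pred.evidence["bluB_present"]
        assert pred.evidence["arsAB_pairs_accepted"] == 1
        no_bza = predict_structure(p, genes, [], catalog, combo_map)
        assert no_bza.determinant == "bluB"

    def test_unscreened_genome_flagged_and_bza_ignored(self, catalog, combo_map):
        hits = [HmmHit("G1", "g9", "bzaF", 300.0, 220.0)]
        pred = predict_structure(AnnotationProfile("G1", {}), [], hits,
                                 catalog, combo_map, screened=False)
        assert not pred.bza_screened
        assert pred.determinant == "none"

    def test_determinant_classes_partition_cohort(self, catalog, combo_map,
                                                  noisy_cohort):
        from cobamide_scout.structure import predict_structures
        profiles = {p.genome_id: p for p in noisy_cohort.profiles}
        preds = predict_structures(profiles, noisy_cohort.genes,
                                   noisy_cohort.hits, catalog, combo_map,
                                   screened=noisy_cohort.screened)
        assert set(preds) == set(profiles)
        for p in preds.values():
            assert p.determinant in ("bluB", "bza", "arsAB", "none")
            assert (p.predicted_compound is not None) == (p.determinant != "none")
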