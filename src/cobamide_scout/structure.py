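"""Lower-ligand structure prediction.

Three genetic determinants predict which lower ligand a cobamide producer
attaches: ``bluB`` (the aerobic DMB synthase, marking cobalamin), the
anaerobic benzimidazole biosynthesis genes ``bzaABCDEF`` (the gene
complement determines which benzimidazole is made), and tandem ``cobT``
homologs (``arsAB``, activating phenolic bases).  Independently of the
determinant, CblS (alpha-ribazole kinase) marks salvage of activated lower
ligands and CbiZ (nucleotide-loop amidohydrolase) marks corrinoid
remodeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .catalog import BZA_GENES, AnnotationID, CatalogError, FunctionCatalog
from .ingest import AnnotationProfile, GeneRecord, HmmHit

DETERMINANTS = ("bluB", "bza", "arsAB", "none")
COMPOUNDS = ("DMB", "5-OHBza", "5-OMeBza", "5-OMe-6-MeBza", "phenolic", "unresolved")

# inclusive protein-length window for plausible cobT homologs (CobT itself
# is ~350 AA; entries outside the window are annotation errors)
COBT_MIN_AA = 300
COBT_MAX_AA = 800


@dataclass(frozen=True)
class BzaComplement:
    """The set of trusted-cutoff-supported bza genes in one genome."""

    genome_id: str
    genes_present: frozenset[str]

    @property
    def first_step_present(self) -> bool:
        """The committed first step (AIR -> 5-OHBza): BzaF, or BzaA + BzaB."""
        g = self.genes_present
        return "bzaF" in g or {"bzaA", "bzaB"} <= g


@dataclass(frozen=True)
class TandemCobTCall:
    genome_id: str
    pair: tuple[str, str]
    lengths_aa: tuple[int, int]
    accepted: bool


@dataclass
class StructurePrediction:
    genome_id: str
    determinant: str                      # bluB | bza | arsAB | none
    predicted_compound: Optional[str]     # set iff determinant != none
    can_salvage_alpha_ribazole: bool      # CblS (kinase) present
    can_remodel: bool                     # CbiZ present
    cblt_present: bool = False            # transporter, reported separately
    bza_screened: bool = True
    evidence: dict = field(default_factory=dict)


class ComboMapError(CatalogError):
    pass


def load_combo_map(path: Optional[str | Path] = None) -> dict[frozenset[str], str]:
    """Load the bza complement -> compound table.

    Every combo row must itself satisfy the first-step requirement (contain
    ``bzaF``, or both ``bzaA`` and ``bzaB``); a row that does not is a
    configuration error.
    """
    if path is None:
        path = Path(str(resources.files("cobamide_scout.data") / "bza_combos.yaml"))
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    mapping: dict[frozenset[str], str] = {}
    for row in raw.get("combos") or []:
        genes = frozenset(row["genes"])
        unknown = genes - set(BZA_GENES)
        if unknown:
            raise ComboMapError(f"combo {sorted(genes)} names unknown genes {sorted(unknown)}")
        if not ("bzaF" in genes or {"bzaA", "bzaB"} <= genes):
            raise ComboMapError(
                f"combo {sorted(genes)} lacks the first-step genes "
                "(bzaF, or bzaA and bzaB)")
        compound = str(row["compound"])
        if compound not in COMPOUNDS:
            raise ComboMapError(f"combo {sorted(genes)}: unknown compound {compound!r}")
        mapping[genes] = compound
    if not mapping:
        raise ComboMapError("combo map defines no rows")
    return mapping


def bza_complement(genome_id: str, hits: Iterable[HmmHit]) -> BzaComplement:
    """Collapse trusted HMM hits into a genome's bza gene complement."""
    genes = {h.hmm_name for h in hits
             if h.genome_id == genome_id and h.hmm_name in BZA_GENES
             and h.bit_score >= h.trusted_cutoff}
    return BzaComplement(genome_id, frozenset(genes))


def predict_benzimidazole(complement: BzaComplement,
                          mapping: Optional[Mapping[frozenset[str], str]] = None
                          ) -> Optional[str]:
    """Predict the benzimidazole made by a bza complement.

    ``None`` when the first step is absent (no benzimidazole potential);
    ``"unresolved"`` for first-step-capable complements not in the mapping.
    """
    if not complement.first_step_present:
        return None
    mapping = mapping if mapping is not None else load_combo_map()
    return mapping.get(frozenset(complement.genes_present), "unresolved")


def detect_arsAB(genes: Sequence[GeneRecord],
                 cobt_ids: Iterable[AnnotationID]) -> list[TandemCobTCall]:
    """Find tandem cobT homolog pairs (putative arsAB).

    Tandem means consecutive ordinals on the same scaffold (strand is not
    considered).  A pair is accepted only when both members encode a
    protein within the inclusive [300, 800] AA window; every adjacent pair
    is evaluated and reported, accepted or not.  A genome is
    phenolic-capable iff it has at least one accepted pair.
    """
    cobt = frozenset(cobt_ids)
    calls: list[TandemCobTCall] = []
    by_scaffold: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        if g.annotations & cobt:
            by_scaffold.setdefault((g.genome_id, g.scaffold), []).append(g)
    for (genome_id, _), members in sorted(by_scaffold.items()):
        members = sorted(members, key=lambda g: g.ordinal)
        for a, b in zip(members, members[1:]):
            if b.ordinal != a.ordinal + 1:
                continue
            ok = all(COBT_MIN_AA <= g.protein_length_aa <= COBT_MAX_AA
                     for g in (a, b))
            calls.append(TandemCobTCall(
                genome_id, (a.gene_id, b.gene_id),
                (a.protein_length_aa, b.protein_length_aa), accepted=ok))
    return calls


def predict_structure(profile: AnnotationProfile,
                      genes: Sequence[GeneRecord],
                      hits: Sequence[HmmHit],
                      catalog: FunctionCatalog,
                      combo_map: Optional[Mapping[frozenset[str], str]] = None,
                      screened: bool = True) -> StructurePrediction:
    """Predict lower-ligand structure determinants for one genome.

    When several determinants co-occur the single reported label follows
    the precedence bza > bluB > arsAB (all raw flags are kept in
    ``evidence`` so no information is lost).  Genomes outside the HMM
    screen (``screened=False``) cannot contribute bza evidence and are
    flagged via ``bza_screened``.
    """
    gid = profile.genome_id
    complement = (bza_complement(gid, hits) if screened
                  else BzaComplement(gid, frozenset()))
    compound_bza = predict_benzimidazole(complement, combo_map) if screened else None

    blub_present = any(profile.counts.get(a, 0) >= 1
                       for a in catalog.ligand_annotations("bluB"))
    pairs = detect_arsAB([g for g in genes if g.genome_id == gid],
                         catalog.ligand_annotations("cobT"))
    arsab_present = any(p.accepted for p in pairs)

    if compound_bza is not None:
        determinant, compound = "bza", compound_bza
    elif blub_present:
        determinant, compound = "bluB", "DMB"
    elif arsab_present:
        determinant, compound = "arsAB", "phenolic"
    else:
        determinant, compound = "none", None

    def _has(name: str) -> bool:
        return any(profile.counts.get(a, 0) >= 1
                   for a in catalog.ligand_annotations(name))

    return StructurePrediction(
        genome_id=gid,
        determinant=determinant,
        predicted_compound=compound,
        can_salvage_alpha_ribazole=_has("cblS"),
        can_remodel=_has("cbiZ"),
        cblt_present=_has("cblT"),
        bza_screened=screened,
        evidence={
            "bluB_present": blub_present,
            "bza_genes": sorted(complement.genes_present),
            "arsAB_pairs_accepted": sum(p.accepted for p in pairs),
            "arsAB_pairs_rejected": sum(not p.accepted for p in pairs),
        },
    )


def predict_structures(profiles: Mapping[str, AnnotationProfile],
                       genes: Sequence[GeneRecord],
                       hits: Sequence[HmmHit],
                       catalog: FunctionCatalog,
                       combo_map: Optional[Mapping[frozenset[str], str]] = None,
                       screened: Optional[Iterable[str]] = None
                       ) -> dict[str, StructurePrediction]:
    """Vectorized convenience wrapper over :func:`predict_structure`."""
    combo_map = combo_map if combo_map is not None else load_combo_map()
    screened_set = set(screened) if screened is not None else set(profiles)
    genes_by_genome: dict[str, list[GeneRecord]] = {}
    for g in genes:
        genes_by_genome.setdefault(g.genome_id, []).append(g)
    hits_by_genome: dict[str, list[HmmHit]] = {}
    for h in hits:
        hits_by_genome.setdefault(h.genome_id, []).append(h)
    return {gid: predict_structure(p, genes_by_genome.get(gid, []),
                                   hits_by_genome.get(gid, []), catalog,
                                   combo_map, screened=gid in screened_set)
            for gid, p in profiles.items()}
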