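"""Synthetic genome-cohort generator with planted ground truth.

Every pipeline stage is testable without any database download: the
generator instantiates, per genome, the annotation content its planted
biosynthesis category requires (using the catalog's own step sets), then
degrades it with a simple noise model — independent Bernoulli dropout per
annotation (annotation false negatives) and Poisson-distributed spurious
additions drawn uniformly from the catalog (false positives).  Genomes
carrying planted lower-ligand determinants also receive the corresponding
gene-table rows (tandem cobT pairs) and HMM hit rows (bza genes, plus
below-cutoff decoys), and every genome gets a single-copy-gene block at a
chosen completeness level.

With both noise rates at zero the emitted profile satisfies its category's
classification rule exactly, so planted-truth recovery is 100% by
construction; recovery under noise is what the generator exists to measure.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .catalog import BZA_GENES, AnnotationID, FunctionCatalog, load_catalog
from .classify import CATEGORIES, PRODUCER_CATEGORIES
from .ingest import (AnnotationProfile, GeneRecord, GenomeMetadata, HmmHit,
                     PipelineState, assemble_state, write_gene_table,
                     write_hmmer_tbl, write_metadata, write_profile_matrix)
from .structure import load_combo_map

DEFAULT_PHYLUM_WEIGHTS = {
    "Proteobacteria": 0.40,
    "Firmicutes": 0.25,
    "Actinobacteria": 0.20,
    "Bacteroidetes": 0.15,
}
DEFAULT_ECOSYSTEM_WEIGHTS = {"host-associated": 0.20, "environmental": 0.28, None: 0.52}
DEFAULT_BZA_CUTOFFS = {"bzaA": 200.0, "bzaB": 180.0, "bzaC": 150.0,
                       "bzaD": 300.0, "bzaE": 280.0, "bzaF": 220.0}
SUBTYPES = ("GSA", "ALA", "PBG", "HMB", "UroIII")


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticTruth:
    genome_id: str
    planted_category: str
    planted_subtype: Optional[str]
    planted_determinant: Optional[str]    # bluB | bza | arsAB | none (producers)
    planted_bza_genes: frozenset[str]
    planted_families: frozenset[str]
    planted_cbls: bool
    planted_cblt: bool
    planted_cbiz: bool
    dropout_rate: float
    spurious_rate: float
    seed: int


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults are the noise-free conditions used for planted-truth recovery:
    ten genomes per category, no annotation dropout or spurious additions,
    and complete (55/55, copy 1) single-copy-gene blocks.
    """

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 10 for c in CATEGORIES})
    dropout_rate: float = 0.0
    spurious_rate: float = 0.0
    scg_unique: int = 55
    scg_dup_rate: float = 0.0
    phylum_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHYLUM_WEIGHTS))
    ecosystem_weights: dict[Optional[str], float] = field(
        default_factory=lambda: dict(DEFAULT_ECOSYSTEM_WEIGHTS))
    determinant_cycle: tuple[str, ...] = ("bluB", "bza", "arsAB", "none")
    subtype_cycle: tuple[str, ...] = SUBTYPES
    unscreened_fraction: float = 0.0
    family_prob_dependent: float = 0.55
    family_prob_independent: float = 0.30

    def validate(self, catalog: FunctionCatalog) -> None:
        bad = set(self.counts) - set(CATEGORIES)
        if bad:
            raise GenerationError(f"unknown categories in spec: {sorted(bad)}")
        if any(n < 0 for n in self.counts.values()):
            raise GenerationError("per-category counts must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise GenerationError("dropout_rate must be in [0, 1)")
        if self.spurious_rate < 0:
            raise GenerationError("spurious_rate must be >= 0")
        if not 0 <= self.scg_unique <= len(catalog.scg_annotations):
            raise GenerationError("scg_unique out of range")
        products = [s.product or s.step_name for s in catalog.tetrapyrrole_steps()]
        bad_sub = set(self.subtype_cycle) - set(products)
        if bad_sub:
            raise GenerationError(
                f"subtype_cycle names unknown precursors {sorted(bad_sub)}; "
                f"catalog provides {products}")


@dataclass
class Cohort:
    """In-memory synthetic cohort plus its planted truths."""

    profiles: list[AnnotationProfile]
    genes: list[GeneRecord]
    hits: list[HmmHit]                       # trusted (above-cutoff) hits only
    hit_rows: list[tuple[str, str, float]]   # raw tblout rows incl. decoys
    cutoffs: dict[str, float]
    metadata: list[GenomeMetadata]
    truths: list[SyntheticTruth]
    screened: set[str]

    def state(self) -> PipelineState:
        return assemble_state(self.profiles, self.genes, self.hits,
                              self.metadata, screened=self.screened)

    def truth_by_genome(self) -> dict[str, SyntheticTruth]:
        return {t.genome_id: t for t in self.truths}


def _epithet(i: int) -> str:
    letters = string.ascii_lowercase
    out = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        out = letters[r] + out
    return "synthetica" + out


def _pick(rng: np.random.Generator, items: Sequence) -> object:
    return items[int(rng.integers(len(items)))]


def _weighted(rng: np.random.Generator, weights: Mapping) -> object:
    keys = list(weights)
    p = np.asarray([weights[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


class _Builder:
    """Builds one genome's profile/genes/hits from its category template."""

    def __init__(self, catalog: FunctionCatalog, spec: CohortSpec,
                 rng: np.random.Generator):
        self.catalog = catalog
        self.spec = spec
        self.rng = rng
        ring = catalog.ortholog_groups("corrin_ring")
        order = {s.ortholog_group: s.order_index
                 for s in catalog.steps_in_segment("corrin_ring")}
        self.ring_groups = sorted(ring, key=lambda g: (order[g], g))
        self.markers = [m for m in catalog.marker_set.markers]
        self.nonmarker = [g for g in self.ring_groups if g not in self.markers]
        self.ring_anns = ring
        self.nla = catalog.ortholog_groups("nucleotide_loop")
        self.nla_core = [g for g in ("adoT", "cobU/cobP", "cobS/cobV", "cbiB")
                         if g in self.nla]
        self.tp_steps = catalog.tetrapyrrole_steps()
        self.scg = sorted(catalog.scg_annotations, key=str)
        self.combo_keys = sorted(load_combo_map(), key=lambda s: sorted(s))
        self.all_ids = sorted(catalog.all_annotation_ids, key=str)

    def group_annotation(self, groups: Mapping[str, frozenset[AnnotationID]],
                         group: str) -> AnnotationID:
        """One representative annotation for an ortholog group (random member,
        emulating that a genome encodes either the aerobic or the anaerobic
        ortholog)."""
        return _pick(self.rng, sorted(groups[group], key=str))

    # -- segment templates --------------------------------------------

    def ring_template(self, category: str) -> list[str]:
        rng = self.rng
        if category in ("very_likely_producer", "tetrapyrrole_precursor_salvager"):
            return list(self.ring_groups)
        if category == "likely_producer":
            keep_markers = self.markers[:2]
            others = list(self.nonmarker)
            drop = _pick(rng, others)
            return keep_markers + [g for g in others if g != drop]
        if category == "possible_producer":
            n_extra = 5
            extras = list(rng.choice(self.nonmarker, size=n_extra, replace=False))
            return [self.markers[0]] + [str(g) for g in extras]
        if category == "cbi_salvager":
            k = int(rng.integers(0, 3))
            return [str(g) for g in rng.choice(self.nonmarker, size=k, replace=False)]
        if category == "likely_nonproducer":
            k = int(rng.integers(3, 5))
            return [str(g) for g in rng.choice(self.nonmarker, size=k, replace=False)]
        k = int(rng.integers(0, 3))  # very_likely_nonproducer
        return [str(g) for g in rng.choice(self.nonmarker, size=k, replace=False)]

    def nla_template(self, category: str) -> list[str]:
        rng = self.rng
        full = list(self.nla_core)
        if category in ("very_likely_producer", "possible_producer",
                        "tetrapyrrole_precursor_salvager", "cbi_salvager"):
            return full
        if category == "likely_producer":
            drop = _pick(rng, full)
            return [g for g in full if g != drop]
        k = int(rng.integers(0, 2))  # non-producers: 0 or 1 core steps
        return [str(g) for g in rng.choice(full, size=k, replace=False)]

    def tp_template(self, category: str, subtype: Optional[str]) -> list:
        steps = self.tp_steps
        if category == "tetrapyrrole_precursor_salvager":
            products = [s.product or s.step_name for s in steps]
            if subtype not in products:
                raise GenerationError(f"unknown precursor subtype {subtype!r}")
            cut = products.index(subtype) + 1  # steps [0, cut) are absent
            if cut == 0:
                raise GenerationError(
                    "salvager template with full tetrapyrrole set is inconsistent")
            return steps[cut:]
        return list(steps)


def generate_cohort(spec: Optional[CohortSpec] = None, seed: int = 0,
                    catalog: Optional[FunctionCatalog] = None) -> Cohort:
    """Generate a cohort; deterministic given (spec, seed)."""
    spec = spec or CohortSpec()
    catalog = catalog or load_catalog()
    spec.validate(catalog)
    rng = np.random.default_rng(seed)
    b = _Builder(catalog, spec, rng)

    profiles: list[AnnotationProfile] = []
    genes: list[GeneRecord] = []
    hits: list[HmmHit] = []
    hit_rows: list[tuple[str, str, float]] = []
    metadata: list[GenomeMetadata] = []
    truths: list[SyntheticTruth] = []
    screened: set[str] = set()

    idx = 0
    producer_idx = 0
    salvager_idx = 0
    for category in CATEGORIES:
        for _ in range(spec.counts.get(category, 0)):
            gid = f"G{idx:05d}"
            counts: dict[AnnotationID, int] = {}

            subtype = None
            if category == "tetrapyrrole_precursor_salvager":
                subtype = spec.subtype_cycle[salvager_idx % len(spec.subtype_cycle)]
                salvager_idx += 1

            for step in b.tp_template(category, subtype):
                ann = _pick(rng, sorted(step.annotation_ids, key=str))
                counts[ann] = 1
            for group in b.ring_template(category):
                counts[b.group_annotation(b.ring_anns, group)] = 1
            for group in b.nla_template(category):
                counts[b.group_annotation(b.nla, group)] = 1

            # dependence families
            fams: set[str] = set()
            for fam in catalog.families:
                p = (spec.family_prob_dependent if fam.dependent
                     else spec.family_prob_independent)
                if rng.random() < p:
                    counts[_pick(rng, sorted(fam.annotation_ids, key=str))] = 1
                    if fam.dependent:
                        fams.add(fam.family_name)

            # lower-ligand determinant (producer categories only)
            determinant = None
            bza_genes: frozenset[str] = frozenset()
            if category in PRODUCER_CATEGORIES:
                determinant = spec.determinant_cycle[
                    producer_idx % len(spec.determinant_cycle)]
                producer_idx += 1
                if determinant == "bluB":
                    for a in catalog.ligand_annotations("bluB"):
                        counts[a] = 1
                elif determinant == "bza":
                    bza_genes = frozenset(_pick(rng, b.combo_keys))
                    for g in sorted(bza_genes):
                        for a in catalog.ligand_annotations(g):
                            counts[a] = 1

            # salvage / remodel flags (any category)
            cbls = rng.random() < 0.10
            cblt = rng.random() < 0.05
            cbiz = rng.random() < 0.15
            for flag, name in ((cbls, "cblS"), (cblt, "cblT"), (cbiz, "cbiZ")):
                if flag:
                    for a in catalog.ligand_annotations(name):
                        counts[a] = 1

            # noise: Bernoulli dropout then Poisson spurious additions
            if spec.dropout_rate > 0:
                counts = {a: n for a, n in counts.items()
                          if rng.random() >= spec.dropout_rate}
            n_spurious = (int(rng.poisson(spec.spurious_rate))
                          if spec.spurious_rate > 0 else 0)
            for _ in range(n_spurious):
                a = _pick(rng, b.all_ids)
                counts[a] = counts.get(a, 0) + 1

            # single-copy-gene block (not subject to annotation noise;
            # completeness is a controlled condition, not an outcome)
            scg_pick = rng.choice(len(b.scg), size=spec.scg_unique, replace=False)
            for j in sorted(int(x) for x in scg_pick):
                copy = 2 if rng.random() < spec.scg_dup_rate else 1
                counts[b.scg[j]] = copy

            # gene table: background genes plus cobT constructs
            scaffold = "s1"
            ordinal = 1
            for _ in range(int(rng.integers(3, 6))):
                genes.append(GeneRecord(f"{gid}_g{ordinal}", gid, scaffold,
                                        ordinal, int(rng.integers(150, 900)),
                                        frozenset()))
                ordinal += 1
            cobt = catalog.ligand_annotations("cobT")
            if determinant == "arsAB":
                for a in cobt:
                    counts[a] = counts.get(a, 0) + 2
                for length in (int(rng.integers(310, 420)),
                               int(rng.integers(310, 420))):
                    genes.append(GeneRecord(f"{gid}_g{ordinal}", gid, scaffold,
                                            ordinal, length, cobt))
                    ordinal += 1
            else:
                decoy = rng.random()
                if decoy < 0.3:   # isolated cobT homolog: never a pair
                    genes.append(GeneRecord(f"{gid}_g{ordinal}", gid, scaffold,
                                            ordinal, int(rng.integers(310, 420)),
                                            cobt))
                    ordinal += 1
                elif decoy < 0.5:  # adjacent pair failing the length filter
                    for length in (250, int(rng.integers(310, 420))):
                        genes.append(GeneRecord(f"{gid}_g{ordinal}", gid,
                                                scaffold, ordinal, length, cobt))
                        ordinal += 1

            # HMM screen membership and hit rows
            is_screened = rng.random() >= spec.unscreened_fraction
            if is_screened:
                screened.add(gid)
                for g in sorted(bza_genes):
                    cutoff = DEFAULT_BZA_CUTOFFS[g]
                    score = cutoff + float(rng.uniform(5, 100))
                    hit_rows.append((f"{gid}|{gid}_bza_{g}", g, score))
                    hits.append(HmmHit(gid, f"{gid}_bza_{g}", g, score, cutoff))
                if rng.random() < 0.25:  # below-cutoff decoy, must never count
                    g = str(_pick(rng, list(BZA_GENES)))
                    cutoff = DEFAULT_BZA_CUTOFFS[g]
                    hit_rows.append((f"{gid}|{gid}_decoy", g,
                                     cutoff - float(rng.uniform(5, 50))))

            profiles.append(AnnotationProfile(gid, counts))

            phylum = str(_weighted(rng, spec.phylum_weights))
            eco = _weighted(rng, spec.ecosystem_weights)
            status = "finished" if rng.random() < 0.2 else "permanent_draft"
            metadata.append(GenomeMetadata(
                gid, f"{phylum[:-1].capitalize()} {_epithet(idx)}",
                phylum, status, eco))

            truths.append(SyntheticTruth(
                gid, category, subtype, determinant, bza_genes,
                frozenset(fams), cbls, cblt, cbiz,
                spec.dropout_rate, spec.spurious_rate, seed))
            idx += 1

    return Cohort(profiles, genes, hits, hit_rows, dict(DEFAULT_BZA_CUTOFFS),
                  metadata, truths, screened)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Emit the cohort in the exact dialects :mod:`cobamide_scout.ingest`
    reads.  Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "profiles": outdir / "profiles.tsv",
        "genes": outdir / "genes.tsv",
        "hmm_hits": outdir / "bza_hits.tbl",
        "cutoffs": outdir / "bza_cutoffs.tsv",
        "metadata": outdir / "metadata.tsv",
        "truths": outdir / "truths.tsv",
        "screened": outdir / "screened.txt",
    }
    write_profile_matrix(cohort.profiles, paths["profiles"])
    write_gene_table(cohort.genes, paths["genes"])
    write_hmmer_tbl(cohort.hit_rows, paths["hmm_hits"])
    with open(paths["cutoffs"], "w") as fh:
        fh.write("hmm_name\ttrusted_cutoff\n")
        for name, cutoff in sorted(cohort.cutoffs.items()):
            fh.write(f"{name}\t{cutoff}\n")
    write_metadata(cohort.metadata, paths["metadata"])
    with open(paths["truths"], "w") as fh:
        fh.write("genome_id\tplanted_category\tplanted_subtype\t"
                 "planted_determinant\tplanted_bza_genes\tplanted_families\n")
        for t in cohort.truths:
            fh.write("\t".join([
                t.genome_id, t.planted_category, t.planted_subtype or "",
                t.planted_determinant or "",
                ";".join(sorted(t.planted_bza_genes)),
                ";".join(sorted(t.planted_families))]) + "\n")
    with open(paths["screened"], "w") as fh:
        for gid in sorted(cohort.screened):
            fh.write(gid + "\n")
    return paths


def perturb(profile: AnnotationProfile, op: str, annotation: AnnotationID,
            catalog: Optional[FunctionCatalog] = None) -> AnnotationProfile:
    """Single-annotation edit (used by monotonicity property tests).

    ``add`` increments the annotation's count; ``remove`` decrements it, and
    removing an absent annotation is a no-op (with a warning).
    """
    if catalog is not None and annotation not in catalog.all_annotation_ids \
            and annotation not in catalog.scg_annotations:
        raise GenerationError(f"annotation {annotation} not in catalog")
    out = profile.copy()
    if op == "add":
        out.counts[annotation] = out.counts.get(annotation, 0) + 1
    elif op == "remove":
        n = out.counts.get(annotation, 0)
        if n == 0:
            import logging
            logging.getLogger(__name__).warning(
                "%s: removing absent annotation %s is a no-op",
                profile.genome_id, annotation)
        elif n == 1:
            del out.counts[annotation]
        else:
            out.counts[annotation] = n - 1
    else:
        raise GenerationError(f"unknown perturbation op {op!r}")
    return out
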