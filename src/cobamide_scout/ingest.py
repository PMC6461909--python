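"""Readers and writers for the pipeline's input dialects.

Three tabular inputs drive the whole analysis: a genome x annotation
function-profile matrix (generic TSV or the IMG export dialect with
decoration lines), a gene-level table used for tandem-gene detection, and
HMMER3 per-target tabular output (``tblout``) for the six anaerobic
benzimidazole HMMs, filtered at per-HMM trusted cutoffs.  Genome metadata
(species binomial, phylum, sequencing status, ecosystem) rides alongside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SearchIO

from .catalog import BZA_GENES, AnnotationID, CatalogError, FunctionCatalog

logger = logging.getLogger(__name__)

GENOME_STATUSES = ("finished", "permanent_draft")


class IngestError(ValueError):
    """Raised on malformed input files."""


@dataclass
class AnnotationProfile:
    """Per-genome multiset of annotation identifiers — the unit of inference."""

    genome_id: str
    counts: dict[AnnotationID, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for aid, n in self.counts.items():
            if n < 0:
                raise IngestError(f"{self.genome_id}: negative count for {aid}")

    def has(self, annotation: AnnotationID) -> bool:
        return self.counts.get(annotation, 0) >= 1

    def copy(self) -> "AnnotationProfile":
        return AnnotationProfile(self.genome_id, dict(self.counts))


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    genome_id: str
    scaffold: str
    ordinal: int                # 1-based position in the scaffold's gene order
    protein_length_aa: int
    annotations: frozenset[AnnotationID]


@dataclass(frozen=True)
class HmmHit:
    genome_id: str
    gene_id: str
    hmm_name: str
    bit_score: float
    trusted_cutoff: float


@dataclass(frozen=True)
class GenomeMetadata:
    genome_id: str
    species_name: str
    phylum: str
    status: str = "permanent_draft"
    ecosystem: Optional[str] = None


# ---------------------------------------------------------------------------
# function-profile matrix
# ---------------------------------------------------------------------------

def read_profile_matrix(path: str | Path, dialect: str = "generic",
                        catalog: Optional[FunctionCatalog] = None
                        ) -> list[AnnotationProfile]:
    """Read a genome x annotation count matrix.

    The first column holds genome IDs; the header row holds
    ``namespace:identifier`` annotation tokens.  Empty cells are read as 0.
    The ``img`` dialect additionally tolerates the export tool's decoration
    lines (skipped by ``#`` prefix).  Annotation columns not present in
    ``catalog`` (when given) are retained but logged.
    """
    if dialect not in ("img", "generic"):
        raise IngestError(f"unknown profile dialect {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#" if dialect == "img" else None)
    if df.shape[1] < 1:
        raise IngestError(f"{path}: empty profile matrix")
    genome_col = df.columns[0]
    ann_cols = list(df.columns[1:])
    annotations = [AnnotationID.parse(c) for c in ann_cols]

    if catalog is not None:
        known = catalog.all_annotation_ids | catalog.scg_annotations
        unknown = [str(a) for a in annotations if a not in known]
        if unknown:
            logger.warning("%s: %d annotation columns not in catalog "
                           "(retained): %s", path, len(unknown),
                           ", ".join(unknown[:8]))

    profiles: list[AnnotationProfile] = []
    seen: set[str] = set()
    for row_idx, row in df.iterrows():
        gid = str(row[genome_col])
        if gid in seen:
            raise IngestError(f"{path}: duplicate genome row {gid!r}")
        seen.add(gid)
        counts: dict[AnnotationID, int] = {}
        for aid, col in zip(annotations, ann_cols):
            cell = row[col]
            if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
                continue
            try:
                n = int(cell)
            except (TypeError, ValueError):
                raise IngestError(
                    f"{path}: non-integer cell {cell!r} at row {row_idx + 1} "
                    f"(genome {gid}), column {col!r}") from None
            if n:
                counts[aid] = n
        profiles.append(AnnotationProfile(gid, counts))
    return profiles


def write_profile_matrix(profiles: Sequence[AnnotationProfile], path: str | Path) -> None:
    """Write profiles as a generic-dialect TSV matrix (column-sorted, stable)."""
    all_ids = sorted({a for p in profiles for a in p.counts}, key=str)
    header = ["genome_id"] + [str(a) for a in all_ids]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for p in profiles:
            cells = [str(p.counts.get(a, 0)) for a in all_ids]
            fh.write("\t".join([p.genome_id] + cells) + "\n")


# ---------------------------------------------------------------------------
# HMMER3 tblout
# ---------------------------------------------------------------------------

def read_hmmer_tbl(path: str | Path, cutoffs: Mapping[str, float],
                   gene_to_genome: Optional[Mapping[str, str]] = None
                   ) -> list[HmmHit]:
    """Read HMMER3 per-target tabular output, keeping trusted hits only.

    A hit is retained when its full-sequence bit score is at or above the
    trusted cutoff of its HMM; a score exactly equal to the cutoff is kept,
    matching HMMER's own trusted-cutoff (``--cut_tc``) semantics.  Target
    names of the form ``genome|gene`` are split; otherwise the genome is
    resolved through ``gene_to_genome``.
    """
    path = Path(path)
    hits: list[HmmHit] = []
    try:
        queries = list(SearchIO.parse(str(path), "hmmer3-tab"))
    except Exception as exc:  # SearchIO raises assorted ValueErrors
        raise IngestError(f"{path}: malformed HMMER3 tblout ({exc})") from exc
    for query in queries:
        hmm_name = query.id
        if hmm_name not in cutoffs:
            raise IngestError(
                f"{path}: no trusted cutoff supplied for HMM {hmm_name!r}")
        cutoff = float(cutoffs[hmm_name])
        for hit in query:
            target = hit.id
            if "|" in target:
                genome_id, gene_id = target.split("|", 1)
            elif gene_to_genome and target in gene_to_genome:
                genome_id, gene_id = gene_to_genome[target], target
            else:
                genome_id, gene_id = "", target
            score = float(hit.bitscore)
            if score >= cutoff:
                hits.append(HmmHit(genome_id, gene_id, hmm_name, score, cutoff))
    return hits


def read_cutoffs(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV of HMM name -> trusted bit-score cutoff."""
    df = pd.read_csv(path, sep="\t")
    if not {"hmm_name", "trusted_cutoff"} <= set(df.columns):
        raise IngestError(f"{path}: expected columns hmm_name, trusted_cutoff")
    return dict(zip(df["hmm_name"], df["trusted_cutoff"].astype(float)))


def write_hmmer_tbl(rows: Iterable[tuple[str, str, float]], path: str | Path) -> None:
    """Write minimal but valid tblout: rows of (target, hmm_name, score)."""
    with open(path, "w") as fh:
        fh.write("# target name\taccession\tquery name\taccession ...\n")
        fh.write("#" + "-" * 60 + "\n")
        for target, hmm, score in rows:
            evalue = 1e-30
            fields = [target, "-", hmm, "-", f"{evalue:.1e}", f"{score:.1f}", "0.0",
                      f"{evalue:.1e}", f"{score:.1f}", "0.0",
                      "1.0", "1", "0", "0", "1", "1", "1", "1", "synthetic"]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# gene table & metadata
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read the gene-level TSV (gene_id, genome_id, scaffold, ordinal,
    protein_length_aa, annotations as ``;``-separated tokens)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"gene_id", "genome_id", "scaffold", "ordinal", "protein_length_aa"}
    if not required <= set(df.columns):
        raise IngestError(f"{path}: gene table must have columns {sorted(required)}")
    records: list[GeneRecord] = []
    seen_genes: set[tuple[str, str]] = set()
    seen_ordinals: set[tuple[str, str, int]] = set()
    for _, row in df.iterrows():
        ordinal = int(row["ordinal"])
        length = int(row["protein_length_aa"])
        if ordinal < 1:
            raise IngestError(f"{path}: gene {row['gene_id']} has ordinal {ordinal} < 1")
        if length <= 0:
            raise IngestError(f"{path}: gene {row['gene_id']} has non-positive length")
        key = (row["genome_id"], row["gene_id"])
        if key in seen_genes:
            raise IngestError(f"{path}: duplicate gene {key}")
        seen_genes.add(key)
        okey = (row["genome_id"], row["scaffold"], ordinal)
        if okey in seen_ordinals:
            raise IngestError(f"{path}: duplicate ordinal {ordinal} on scaffold "
                              f"{row['scaffold']} of genome {row['genome_id']}")
        seen_ordinals.add(okey)
        tokens = [t for t in str(row.get("annotations", "")).split(";") if t]
        records.append(GeneRecord(
            gene_id=row["gene_id"], genome_id=row["genome_id"],
            scaffold=row["scaffold"], ordinal=ordinal, protein_length_aa=length,
            annotations=frozenset(AnnotationID.parse(t) for t in tokens)))
    return records


def write_gene_table(records: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgenome_id\tscaffold\tordinal\tprotein_length_aa\tannotations\n")
        for r in records:
            anns = ";".join(sorted(str(a) for a in r.annotations))
            fh.write(f"{r.gene_id}\t{r.genome_id}\t{r.scaffold}\t{r.ordinal}"
                     f"\t{r.protein_length_aa}\t{anns}\n")


def read_metadata(path: str | Path) -> list[GenomeMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"genome_id", "species_name", "phylum"}
    if not required <= set(df.columns):
        raise IngestError(f"{path}: metadata must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        if not row["species_name"]:
            raise IngestError(f"{path}: genome {row['genome_id']} has empty species name")
        status = row.get("status", "") or "permanent_draft"
        if status not in GENOME_STATUSES:
            raise IngestError(f"{path}: genome {row['genome_id']}: unknown status {status!r}")
        out.append(GenomeMetadata(
            genome_id=row["genome_id"], species_name=row["species_name"],
            phylum=row["phylum"], status=status,
            ecosystem=row.get("ecosystem", "") or None))
    return out


def write_metadata(records: Sequence[GenomeMetadata], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tspecies_name\tphylum\tstatus\tecosystem\n")
        for m in records:
            fh.write(f"{m.genome_id}\t{m.species_name}\t{m.phylum}\t{m.status}"
                     f"\t{m.ecosystem or ''}\n")


# ---------------------------------------------------------------------------
# assembled pipeline state
# ---------------------------------------------------------------------------

@dataclass
class PipelineState:
    """All ingested inputs for one run, keyed by genome.

    ``screened`` records which genomes were part of the HMM screen; genomes
    outside it get "not screened" structure calls rather than empty ones.
    """

    profiles: dict[str, AnnotationProfile] = field(default_factory=dict)
    genes: list[GeneRecord] = field(default_factory=list)
    hits: list[HmmHit] = field(default_factory=list)
    metadata: dict[str, GenomeMetadata] = field(default_factory=dict)
    screened: set[str] = field(default_factory=set)

    def check_integrity(self) -> list[str]:
        """Referential-integrity warnings (non-fatal), e.g. genes whose
        genome has no metadata row."""
        warnings: list[str] = []
        meta = set(self.metadata)
        orphan_genes = sorted({g.genome_id for g in self.genes} - meta)
        if orphan_genes:
            warnings.append("gene table references genomes without metadata: "
                            + ", ".join(orphan_genes))
        orphan_profiles = sorted(set(self.profiles) - meta)
        if orphan_profiles:
            warnings.append("profiles without metadata: " + ", ".join(orphan_profiles))
        for w in warnings:
            logger.warning(w)
        return warnings

    # -- JSON round trip ----------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "profiles": {g: {str(a): n for a, n in sorted(p.counts.items())}
                         for g, p in sorted(self.profiles.items())},
            "genes": [[r.gene_id, r.genome_id, r.scaffold, r.ordinal,
                       r.protein_length_aa, sorted(str(a) for a in r.annotations)]
                      for r in self.genes],
            "hits": [[h.genome_id, h.gene_id, h.hmm_name, h.bit_score,
                      h.trusted_cutoff] for h in self.hits],
            "metadata": [[m.genome_id, m.species_name, m.phylum, m.status,
                          m.ecosystem] for m in self.metadata.values()],
            "screened": sorted(self.screened),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineState":
        with open(path) as fh:
            doc = json.load(fh)
        state = cls()
        for gid, counts in doc.get("profiles", {}).items():
            state.profiles[gid] = AnnotationProfile(
                gid, {AnnotationID.parse(a): int(n) for a, n in counts.items()})
        for gene_id, genome_id, scaffold, ordinal, length, anns in doc.get("genes", []):
            state.genes.append(GeneRecord(
                gene_id, genome_id, scaffold, int(ordinal), int(length),
                frozenset(AnnotationID.parse(a) for a in anns)))
        for genome_id, gene_id, hmm, score, cutoff in doc.get("hits", []):
            state.hits.append(HmmHit(genome_id, gene_id, hmm, float(score),
                                     float(cutoff)))
        for genome_id, species, phylum, status, eco in doc.get("metadata", []):
            state.metadata[genome_id] = GenomeMetadata(
                genome_id, species, phylum, status, eco)
        state.screened = set(doc.get("screened", []))
        return state


def assemble_state(profiles: Sequence[AnnotationProfile],
                   genes: Sequence[GeneRecord] = (),
                   hits: Sequence[HmmHit] = (),
                   metadata: Sequence[GenomeMetadata] = (),
                   screened: Optional[Iterable[str]] = None) -> PipelineState:
    state = PipelineState(
        profiles={p.genome_id: p for p in profiles},
        genes=list(genes), hits=list(hits),
        metadata={m.genome_id: m for m in metadata},
        screened=set(screened) if screened is not None
        else {h.genome_id for h in hits if h.genome_id},
    )
    state.check_integrity()
    return state
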