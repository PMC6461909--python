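"""Genome completeness scoring and one-genome-per-species dereplication.

Completeness is proxied by 55 universal single-copy gene (SCG) annotations:
a genome's quality is measured first by how many of the 55 are detected at
all, and second by how close the mean copy number of the detected ones is
to 1.  Genomes detecting fewer than 45 of the 55 are dropped.  Species are
then collapsed by binomial name, keeping the highest-quality genome; exact
ties are broken by a seeded uniform draw so runs are reproducible.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import AnnotationID
from .ingest import AnnotationProfile, GenomeMetadata, IngestError

N_SCG = 55
DEFAULT_MIN_UNIQUE = 45

# tokens that mark a genus-only (unresolved species) name
_GENUS_ONLY_TOKENS = {"sp", "sp.", "spp", "spp.", "bacterium", "unclassified"}


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class CompletenessScore:
    genome_id: str
    unique_scg: int            # 0..55 distinct SCG annotations detected
    mean_scg_copy: float       # NaN when unique_scg == 0

    def sort_key(self) -> tuple[int, float]:
        """Lexicographic quality key: more unique SCGs, then mean copy
        number closest to 1 (absolute distance)."""
        dist = math.inf if math.isnan(self.mean_scg_copy) else abs(self.mean_scg_copy - 1.0)
        return (self.unique_scg, -dist)


@dataclass
class SpeciesGroup:
    species_key: str
    member_genomes: list[str]
    representative: str


def score_completeness(profile: AnnotationProfile,
                       scg_ids: Iterable[AnnotationID],
                       copy_mean_over_all: bool = False) -> CompletenessScore:
    """Score one genome against the 55 single-copy gene annotations.

    Parameters
    ----------
    copy_mean_over_all
        Average copy number over all 55 SCGs (undetected as 0) instead of
        the default average over detected SCGs only.
    """
    scg = frozenset(scg_ids)
    if len(scg) != N_SCG:
        raise QCError(f"expected {N_SCG} single-copy gene annotations, got {len(scg)}")
    counts = [profile.counts.get(a, 0) for a in scg]
    detected = [c for c in counts if c >= 1]
    unique = len(detected)
    if unique == 0:
        mean = float("nan")
    elif copy_mean_over_all:
        mean = float(np.mean(counts))
    else:
        mean = float(np.mean(detected))
    return CompletenessScore(profile.genome_id, unique, mean)


def filter_incomplete(scores: Sequence[CompletenessScore],
                      min_unique: int = DEFAULT_MIN_UNIQUE
                      ) -> tuple[list[CompletenessScore], list[CompletenessScore]]:
    """Partition into (kept, removed): kept genomes detect >= ``min_unique``
    unique SCGs ("fewer than ``min_unique``" are removed)."""
    kept = [s for s in scores if s.unique_scg >= min_unique]
    removed = [s for s in scores if s.unique_scg < min_unique]
    return kept, removed


def species_key(name: str, aliases: Optional[Mapping[str, str]] = None) -> Optional[str]:
    """Canonical species key from a raw species name.

    The key is the lowercased, whitespace-normalized binomial (genus +
    species epithet); strain suffixes beyond the epithet are dropped.
    Returns ``None`` for genus-only names (single token, or an epithet such
    as "sp."), which are each treated as their own species.  ``aliases``
    maps raw names to canonical keys ahead of the token rule, supporting
    manual curation of data-entry duplicates.
    """
    raw = " ".join(name.split())
    if aliases and raw in aliases:
        return aliases[raw]
    tokens = raw.split(" ")
    if len(tokens) < 2:
        return None
    epithet = tokens[1].lower().rstrip(".")
    if tokens[1].lower() in _GENUS_ONLY_TOKENS or epithet in {"sp", "spp"}:
        return None
    if not re.match(r"^[a-z][a-z-]*$", epithet):
        return None
    return f"{tokens[0].lower()} {epithet}"


def load_aliases(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"raw_name", "canonical_key"} <= set(df.columns):
        raise IngestError(f"{path}: alias file needs columns raw_name, canonical_key")
    return dict(zip(df["raw_name"], df["canonical_key"]))


def dereplicate(metadata: Sequence[GenomeMetadata],
                scores: Sequence[CompletenessScore],
                seed: int,
                aliases: Optional[Mapping[str, str]] = None) -> list[SpeciesGroup]:
    """Collapse genomes to one representative per species.

    The representative maximizes ``(unique_scg, -|mean_scg_copy - 1|)``
    lexicographically; exact ties are broken by a uniform draw from a
    generator seeded with ``seed`` so the choice is reproducible.  Genomes
    with genus-only names each form their own group.
    """
    score_by_genome = {s.genome_id: s for s in scores}
    missing = [m.genome_id for m in metadata if m.genome_id not in score_by_genome]
    if missing:
        raise QCError("no completeness score for genome(s): " + ", ".join(missing))

    groups: dict[str, list[str]] = {}
    for m in metadata:
        key = species_key(m.species_name, aliases)
        if key is None:
            key = f"__genusonly__::{m.genome_id}"
        groups.setdefault(key, []).append(m.genome_id)

    rng = np.random.default_rng(seed)
    out: list[SpeciesGroup] = []
    for key in sorted(groups):
        members = sorted(groups[key])
        best_key = max(score_by_genome[g].sort_key() for g in members)
        best = [g for g in members if score_by_genome[g].sort_key() == best_key]
        rep = best[0] if len(best) == 1 else best[int(rng.integers(len(best)))]
        out.append(SpeciesGroup(species_key=key, member_genomes=members,
                                representative=rep))
    return out
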