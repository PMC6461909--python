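"""Declarative model of the cobamide pathway and dependent enzyme families.

The catalog is the single source of truth for every downstream inference:
which annotation identifiers stand for which pathway step, how aerobic and
anaerobic orthologs merge into one scoreable group, which steps are excluded
from completeness scoring, which enzyme families mark cobamide dependence,
and which genes determine lower-ligand structure.  It ships as an editable
YAML file (``data/default_catalog.yaml``) so that annotation inventories can
be swapped without code changes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml

logger = logging.getLogger(__name__)

NAMESPACES = ("EC", "Pfam", "TIGRFAM", "COG", "IMGTerm", "BLASTQuery", "HMM")
SEGMENTS = (
    "tetrapyrrole_precursor",
    "corrin_ring",
    "nucleotide_loop",
    "salvage_remodel",
    "lower_ligand",
)
ROUTES = ("anaerobic", "aerobic", "shared")
BZA_GENES = ("bzaA", "bzaB", "bzaC", "bzaD", "bzaE", "bzaF")


class CatalogError(ValueError):
    """Raised when a catalog config is malformed or violates an invariant."""


@dataclass(frozen=True, order=True)
class AnnotationID:
    """A namespaced functional-annotation identifier, e.g. ``EC:2.1.1.13``."""

    namespace: str
    identifier: str

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise CatalogError(f"unknown annotation namespace {self.namespace!r}")
        if not self.identifier:
            raise CatalogError("annotation identifier must be non-empty")

    def __str__(self) -> str:
        return f"{self.namespace}:{self.identifier}"

    @classmethod
    def parse(cls, token: str) -> "AnnotationID":
        """Parse a ``namespace:identifier`` token (split on the first colon)."""
        ns, sep, ident = token.partition(":")
        if not sep:
            raise CatalogError(f"annotation token {token!r} lacks a namespace prefix")
        return cls(ns.strip(), ident.strip())


@dataclass(frozen=True)
class PathwayStep:
    """One gene-name-level step of the biosynthesis/salvage pathway.

    Steps whose aerobic and anaerobic forms catalyze the same reaction share
    an ``ortholog_group`` and are counted once during completeness scoring.
    """

    step_name: str
    segment: str
    route: str
    ortholog_group: str
    annotation_ids: frozenset[AnnotationID]
    order_index: int
    excluded_from_scoring: bool = False
    low_specificity: bool = False
    product: Optional[str] = None  # precursor produced (tetrapyrrole segment only)

    @property
    def scored(self) -> bool:
        return not (self.excluded_from_scoring or self.low_specificity)


@dataclass(frozen=True)
class EnzymeFamily:
    """A cobamide-dependent enzyme family or a cobamide-independent alternative."""

    family_name: str
    annotation_ids: frozenset[AnnotationID]
    dependent: bool
    process: Optional[str] = None


@dataclass(frozen=True)
class MarkerSet:
    markers: tuple[str, ...]
    legacy_marker: Optional[str] = None


@dataclass
class FunctionCatalog:
    """Validated catalog of pathway steps, enzyme families and ligand genes."""

    steps: list[PathwayStep]
    families: list[EnzymeFamily]
    marker_set: MarkerSet
    ligand_genes: dict[str, frozenset[AnnotationID]]
    scg_annotations: frozenset[AnnotationID]
    version: str = "unversioned"
    include_chelatases: bool = False

    # -- derived views -------------------------------------------------

    def steps_in_segment(self, segment: str) -> list[PathwayStep]:
        if segment not in SEGMENTS:
            raise CatalogError(f"unknown pathway segment {segment!r}")
        return [s for s in self.steps if s.segment == segment]

    def _step_scored(self, step: PathwayStep) -> bool:
        if step.excluded_from_scoring:
            return False
        if step.low_specificity and not self.include_chelatases:
            return False
        return True

    def ortholog_groups(self, segment: str, scored_only: bool = True
                        ) -> dict[str, frozenset[AnnotationID]]:
        """Map ortholog group -> union of its member steps' annotation IDs."""
        groups: dict[str, set[AnnotationID]] = {}
        for step in self.steps_in_segment(segment):
            if scored_only and not self._step_scored(step):
                continue
            groups.setdefault(step.ortholog_group, set()).update(step.annotation_ids)
        return {g: frozenset(a) for g, a in groups.items()}

    def tetrapyrrole_steps(self) -> list[PathwayStep]:
        """Tetrapyrrole precursor steps in pathway order (hemA..hemD)."""
        return sorted(self.steps_in_segment("tetrapyrrole_precursor"),
                      key=lambda s: s.order_index)

    @property
    def dependent_families(self) -> list[EnzymeFamily]:
        return [f for f in self.families if f.dependent]

    @property
    def independent_families(self) -> list[EnzymeFamily]:
        return [f for f in self.families if not f.dependent]

    @property
    def processes(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.families:
            if f.process is not None:
                seen.setdefault(f.process)
        return list(seen)

    @property
    def function_count(self) -> int:
        """Number of biosynthesis/modification/salvage functions (= steps)."""
        return len(self.steps)

    @property
    def all_annotation_ids(self) -> frozenset[AnnotationID]:
        ids: set[AnnotationID] = set()
        for step in self.steps:
            ids.update(step.annotation_ids)
        for fam in self.families:
            ids.update(fam.annotation_ids)
        return frozenset(ids)

    def family_by_name(self, name: str) -> EnzymeFamily:
        for fam in self.families:
            if fam.family_name == name:
                return fam
        raise KeyError(name)

    def ligand_annotations(self, name: str) -> frozenset[AnnotationID]:
        try:
            return self.ligand_genes[name]
        except KeyError:
            raise CatalogError(f"unknown ligand gene {name!r}") from None


# ---------------------------------------------------------------------------
# loading & validation
# ---------------------------------------------------------------------------

def default_catalog_path() -> Path:
    return Path(str(resources.files("cobamide_scout.data") / "default_catalog.yaml"))


def _parse_ids(tokens: Iterable[str]) -> frozenset[AnnotationID]:
    return frozenset(AnnotationID.parse(t) for t in tokens)


def load_catalog(path: Optional[str | Path] = None,
                 include_chelatases: bool = False) -> FunctionCatalog:
    """Load and validate a catalog config.

    Parameters
    ----------
    path
        YAML config file; ``None`` loads the packaged default.
    include_chelatases
        Re-include the low-specificity cobalt chelatase annotations
        (``cbiX``/``cbiK``, ``cobNST``) in corrin-ring completeness scoring.
        They are excluded by default because their annotations overlap other
        metal chelatases.
    """
    path = default_catalog_path() if path is None else Path(path)
    if not path.exists():
        raise CatalogError(f"catalog config not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise CatalogError(f"catalog config {path} did not parse to a mapping")

    steps = []
    for entry in raw.get("steps") or []:
        try:
            step = PathwayStep(
                step_name=str(entry["step"]),
                segment=str(entry["segment"]),
                route=str(entry.get("route", "shared")),
                ortholog_group=str(entry["group"]),
                annotation_ids=_parse_ids(entry["annotations"]),
                order_index=int(entry["order"]),
                excluded_from_scoring=bool(entry.get("excluded", False)),
                low_specificity=bool(entry.get("low_specificity", False)),
                product=entry.get("product"),
            )
        except KeyError as exc:
            raise CatalogError(f"step entry missing key {exc}: {entry!r}") from None
        if step.segment not in SEGMENTS:
            raise CatalogError(f"step {step.step_name}: unknown segment {step.segment!r}")
        if step.route not in ROUTES:
            raise CatalogError(f"step {step.step_name}: unknown route {step.route!r}")
        if not step.annotation_ids:
            raise CatalogError(f"step {step.step_name} has no annotation IDs")
        steps.append(step)
    if not steps:
        raise CatalogError("catalog defines zero pathway steps")

    families = []
    for entry in raw.get("families") or []:
        families.append(EnzymeFamily(
            family_name=str(entry["name"]),
            annotation_ids=_parse_ids(entry["annotations"]),
            dependent=bool(entry["dependent"]),
            process=entry.get("process"),
        ))

    ms = raw.get("marker_set") or {}
    marker_set = MarkerSet(markers=tuple(ms.get("markers") or ()),
                           legacy_marker=ms.get("legacy_marker"))

    step_by_name = {s.step_name: s for s in steps}
    ligand_genes: dict[str, frozenset[AnnotationID]] = {}
    for name in raw.get("ligand_genes") or []:
        if name not in step_by_name:
            raise CatalogError(f"ligand gene {name!r} does not match any pathway step")
        ligand_genes[name] = step_by_name[name].annotation_ids

    scg = _parse_ids(raw.get("scg_annotations") or [])

    catalog = FunctionCatalog(
        steps=steps, families=families, marker_set=marker_set,
        ligand_genes=ligand_genes, scg_annotations=scg,
        version=str(raw.get("version", "unversioned")),
        include_chelatases=include_chelatases,
    )
    validate_catalog(catalog)
    logger.info("loaded catalog %s: %d functions, %d families (%d dependent), "
                "%d ligand genes", catalog.version, catalog.function_count,
                len(catalog.families), len(catalog.dependent_families),
                len(catalog.ligand_genes))
    return catalog


def validate_catalog(catalog: FunctionCatalog) -> None:
    """Check structural invariants; raise :class:`CatalogError` on violation."""
    owner: dict[AnnotationID, str] = {}
    for step in catalog.steps:
        for aid in step.annotation_ids:
            if aid in owner and owner[aid] != step.step_name:
                raise CatalogError(
                    f"annotation {aid} is claimed by both steps "
                    f"{owner[aid]!r} and {step.step_name!r}")
            owner[aid] = step.step_name
    fam_owner: dict[AnnotationID, str] = {}
    for fam in catalog.families:
        for aid in fam.annotation_ids:
            if aid in owner:
                raise CatalogError(
                    f"annotation {aid} appears in both step {owner[aid]!r} "
                    f"and family {fam.family_name!r}")
            if aid in fam_owner and fam_owner[aid] != fam.family_name:
                raise CatalogError(
                    f"annotation {aid} is claimed by families "
                    f"{fam_owner[aid]!r} and {fam.family_name!r}")
            fam_owner[aid] = fam.family_name

    names = Counter(s.step_name for s in catalog.steps)
    dupes = [n for n, c in names.items() if c > 1]
    if dupes:
        raise CatalogError(f"duplicate step names: {dupes}")

    # every independent alternative must oppose >=1 dependent family
    dep_procs = {f.process for f in catalog.dependent_families if f.process}
    for fam in catalog.independent_families:
        if fam.process is None or fam.process not in dep_procs:
            raise CatalogError(
                f"independent family {fam.family_name!r} has process "
                f"{fam.process!r} with no dependent counterpart")

    tp = catalog.tetrapyrrole_steps()
    orders = [s.order_index for s in tp]
    if orders != sorted(orders) or len(set(orders)) != len(orders):
        raise CatalogError("tetrapyrrole steps must carry strictly increasing order_index")

    ring_groups = set(catalog.ortholog_groups("corrin_ring", scored_only=False))
    for marker in catalog.marker_set.markers:
        if marker not in ring_groups:
            raise CatalogError(f"marker {marker!r} is not a corrin-ring ortholog group")
    if (catalog.marker_set.legacy_marker
            and catalog.marker_set.legacy_marker not in ring_groups):
        raise CatalogError(
            f"legacy marker {catalog.marker_set.legacy_marker!r} "
            "is not a corrin-ring ortholog group")


# ---------------------------------------------------------------------------
# completeness scoring
# ---------------------------------------------------------------------------

def _counts_of(profile) -> Mapping[AnnotationID, int]:
    return profile.counts if hasattr(profile, "counts") else profile


def present_groups(catalog: FunctionCatalog, profile, segment: str) -> set[str]:
    """Ortholog groups of ``segment`` with at least one detected annotation.

    Presence is count >= 1; copy numbers are retained in profiles but
    binarized here.  Excluded and (by default) low-specificity steps do not
    contribute.
    """
    counts = _counts_of(profile)
    present: set[str] = set()
    for group, anns in catalog.ortholog_groups(segment, scored_only=True).items():
        if any(counts.get(a, 0) >= 1 for a in anns):
            present.add(group)
    return present


def merged_step_count(catalog: FunctionCatalog, profile, segment: str) -> int:
    """Number of distinct merged ortholog groups detected in a segment."""
    return len(present_groups(catalog, profile, segment))
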