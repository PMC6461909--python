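"""Cobamide dependence profiling and the seven-category biosynthesis classifier.

Each genome is scored for (i) which of the 15 cobamide-dependent enzyme
families it carries, and per process whether a cobamide-independent
alternative co-occurs; and (ii) one of seven biosynthesis phenotypes,
assigned from merged pathway-segment completeness:

================================  =====================
category                          group
================================  =====================
very_likely_producer              complete_biosynthesis
likely_producer                   complete_biosynthesis
possible_producer                 complete_biosynthesis
tetrapyrrole_precursor_salvager   partial_biosynthesis
cbi_salvager                      partial_biosynthesis
likely_nonproducer                no_biosynthesis
very_likely_nonproducer           no_biosynthesis
================================  =====================

The decision thresholds live in a :class:`RuleSet` loaded from YAML; the
shipped defaults honor the constraints that anchor the scheme — a
non-producer has fewer than five corrin-ring genes, producers carry the
three core ring markers at ~100%, and a Cbi salvager keeps nucleotide-loop
assembly while lacking all or most of the ring.  A genome that would call
as a confident producer but is missing a contiguous leading stretch of the
tetrapyrrole precursor steps is instead a tetrapyrrole precursor salvager,
subtyped by the precursor it must take up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .catalog import AnnotationID, FunctionCatalog, present_groups
from .ingest import AnnotationProfile

CATEGORIES = (
    "very_likely_producer",
    "likely_producer",
    "possible_producer",
    "tetrapyrrole_precursor_salvager",
    "cbi_salvager",
    "likely_nonproducer",
    "very_likely_nonproducer",
)
PRODUCER_CATEGORIES = CATEGORIES[:3]

CATEGORY_GROUP = {
    "very_likely_producer": "complete_biosynthesis",
    "likely_producer": "complete_biosynthesis",
    "possible_producer": "complete_biosynthesis",
    "tetrapyrrole_precursor_salvager": "partial_biosynthesis",
    "cbi_salvager": "partial_biosynthesis",
    "likely_nonproducer": "no_biosynthesis",
    "very_likely_nonproducer": "no_biosynthesis",
}

PROCESS_STATUSES = ("dependent_only", "independent_only", "both", "neither")

# fixed caveats attached to process-level dependence output
PROCESS_CAVEATS = {
    "propionate_metabolism":
        "dependent-side abundance is overestimated: the mutase annotation "
        "also matches mutases with no known independent counterpart",
    "ethanolamine_utilization":
        "independent-side abundance may be underestimated (identified from "
        "a limited number of query sequences)",
    "glycerol_propanediol":
        "independent-side abundance may be underestimated (identified from "
        "a limited number of query sequences)",
}


class RuleError(ValueError):
    pass


@dataclass
class RuleSet:
    """Named thresholds over merged segment counts and marker presence."""

    version: str = "default-0.1"
    cr_very_likely_min: int = 12
    cr_likely_min: int = 9
    cr_possible_min: int = 5
    cr_likely_nonproducer_min: int = 3
    nla_core_groups: tuple[str, ...] = ("adoT", "cobU/cobP", "cobS/cobV", "cbiB")
    nla_likely_min_fraction: float = 0.5
    markers_very_likely_min: int = 3
    markers_likely_min: int = 2
    core_groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.cr_very_likely_min >= self.cr_likely_min
                >= self.cr_possible_min > self.cr_likely_nonproducer_min >= 0):
            raise RuleError(
                "corrin-ring thresholds must satisfy very_likely >= likely >= "
                "possible (producer floor) > likely_nonproducer floor >= 0")
        if not 0 < self.nla_likely_min_fraction <= 1:
            raise RuleError("nla_likely_min_fraction must be in (0, 1]")
        if not self.nla_core_groups:
            raise RuleError("at least one core nucleotide-loop group required")

    @property
    def nla_likely_min(self) -> int:
        return math.ceil(len(self.nla_core_groups) * self.nla_likely_min_fraction)

    @classmethod
    def from_yaml(cls, path: Optional[str | Path] = None) -> "RuleSet":
        if path is None:
            path = Path(str(resources.files("cobamide_scout.data") / "default_rules.yaml"))
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cr = raw.get("corrin_ring", {})
        nla = raw.get("nucleotide_loop", {})
        mk = raw.get("markers", {})
        return cls(
            version=str(raw.get("version", "unversioned")),
            cr_very_likely_min=int(cr.get("very_likely_min", 12)),
            cr_likely_min=int(cr.get("likely_min", 9)),
            cr_possible_min=int(cr.get("possible_min", 5)),
            cr_likely_nonproducer_min=int(cr.get("likely_nonproducer_min", 3)),
            nla_core_groups=tuple(nla.get("core_groups",
                                          ("adoT", "cobU/cobP", "cobS/cobV", "cbiB"))),
            nla_likely_min_fraction=float(nla.get("likely_min_fraction", 0.5)),
            markers_very_likely_min=int(mk.get("very_likely_min", 3)),
            markers_likely_min=int(mk.get("likely_min", 2)),
            core_groups=tuple(raw.get("core_groups", ())),
        )


@dataclass
class DependenceProfile:
    genome_id: str
    families_present: frozenset[str]
    process_status: dict[str, str]
    caveats: dict[str, str] = field(default_factory=dict)

    @property
    def n_families(self) -> int:
        return len(self.families_present)

    @property
    def uses_cobamides(self) -> bool:
        return self.n_families >= 1


@dataclass
class PhenotypeCall:
    genome_id: str
    category: str
    evidence: dict[str, int]
    salvager_subtype: Optional[str] = None
    notes: tuple[str, ...] = ()
    overridden: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise RuleError(f"unknown category {self.category!r}")
        if (self.salvager_subtype is not None) != (
                self.category == "tetrapyrrole_precursor_salvager"):
            raise RuleError("salvager_subtype must be set exactly for "
                            "tetrapyrrole_precursor_salvager calls")

    @property
    def group(self) -> str:
        return CATEGORY_GROUP[self.category]


# ---------------------------------------------------------------------------
# dependence
# ---------------------------------------------------------------------------

def profile_dependence(profile: AnnotationProfile,
                       catalog: FunctionCatalog) -> DependenceProfile:
    """Which cobamide-dependent enzyme families a genome carries, and the
    per-process dependent/independent status."""
    present_dep: set[str] = set()
    present_indep: set[str] = set()
    for fam in catalog.families:
        if any(profile.counts.get(a, 0) >= 1 for a in fam.annotation_ids):
            (present_dep if fam.dependent else present_indep).add(fam.family_name)

    status: dict[str, str] = {}
    for process in catalog.processes:
        dep = any(f.family_name in present_dep
                  for f in catalog.dependent_families if f.process == process)
        indep = any(f.family_name in present_indep
                    for f in catalog.independent_families if f.process == process)
        status[process] = ("both" if dep and indep else
                           "dependent_only" if dep else
                           "independent_only" if indep else "neither")
    caveats = {p: PROCESS_CAVEATS[p] for p in status if p in PROCESS_CAVEATS}
    return DependenceProfile(profile.genome_id, frozenset(present_dep),
                             status, caveats)


# ---------------------------------------------------------------------------
# tetrapyrrole precursor subtyping
# ---------------------------------------------------------------------------

def subtype_precursor_salvager(profile: AnnotationProfile,
                               catalog: FunctionCatalog) -> Optional[str]:
    """Precursor a genome must salvage, from its tetrapyrrole absence pattern.

    Returns the product of the last step in the missing leading stretch when
    the absence pattern is a contiguous prefix of the segment (every step
    upstream of the precursor absent, every step downstream present), and
    ``None`` when nothing is missing or the pattern is non-contiguous —
    the latter is inconsistent with simple auxotrophy.
    """
    steps = catalog.tetrapyrrole_steps()
    present = [any(profile.counts.get(a, 0) >= 1 for a in s.annotation_ids)
               for s in steps]
    if all(present):
        return None
    n_absent_prefix = 0
    for p in present:
        if p:
            break
        n_absent_prefix += 1
    if any(not p for p in present[n_absent_prefix:]):
        return None  # non-contiguous absence
    last_missing = steps[n_absent_prefix - 1]
    return last_missing.product or last_missing.step_name


def tp_pattern_is_contiguous(profile: AnnotationProfile,
                             catalog: FunctionCatalog) -> bool:
    steps = catalog.tetrapyrrole_steps()
    present = [any(profile.counts.get(a, 0) >= 1 for a in s.annotation_ids)
               for s in steps]
    absent_idx = [i for i, p in enumerate(present) if not p]
    return absent_idx == list(range(len(absent_idx)))


# ---------------------------------------------------------------------------
# the seven-category classifier
# ---------------------------------------------------------------------------

def _producer_tier(cr: int, markers: int, nla: int, rules: RuleSet) -> Optional[str]:
    nla_total = len(rules.nla_core_groups)
    if (cr >= rules.cr_very_likely_min
            and markers >= rules.markers_very_likely_min and nla == nla_total):
        return "very_likely_producer"
    if (cr >= rules.cr_likely_min and markers >= rules.markers_likely_min
            and nla >= rules.nla_likely_min):
        return "likely_producer"
    if cr >= rules.cr_possible_min:
        return "possible_producer"
    return None


def classify_biosynthesis(profile: AnnotationProfile, catalog: FunctionCatalog,
                          rules: Optional[RuleSet] = None) -> PhenotypeCall:
    """Assign exactly one of the seven biosynthesis phenotypes.

    Precedence: the tetrapyrrole-salvager test applies only to genomes that
    would otherwise call as very likely / likely producers (they must have
    complete corrin-ring and nucleotide-loop pathways); then producer tiers,
    then Cbi salvager, then the non-producer tiers.
    """
    rules = rules or RuleSet()
    cr_groups = present_groups(catalog, profile, "corrin_ring")
    cr = len(cr_groups)
    markers = sum(1 for m in catalog.marker_set.markers if m in cr_groups)
    nla_groups = present_groups(catalog, profile, "nucleotide_loop")
    nla_core = sum(1 for g in rules.nla_core_groups if g in nla_groups)
    nla_complete = nla_core == len(rules.nla_core_groups)
    tp = len(present_groups(catalog, profile, "tetrapyrrole_precursor"))

    evidence = {
        "tetrapyrrole_precursor": tp,
        "corrin_ring": cr,
        "nucleotide_loop": nla_core,
        "markers": markers,
    }
    notes: list[str] = []

    tier = _producer_tier(cr, markers, nla_core, rules)
    if tier in ("very_likely_producer", "likely_producer"):
        subtype = subtype_precursor_salvager(profile, catalog)
        if subtype is not None:
            return PhenotypeCall(profile.genome_id,
                                 "tetrapyrrole_precursor_salvager",
                                 evidence, salvager_subtype=subtype)
        if not tp_pattern_is_contiguous(profile, catalog):
            notes.append("tetrapyrrole absence pattern inconsistent with "
                         "simple auxotrophy")
    if tier is not None:
        return PhenotypeCall(profile.genome_id, tier, evidence,
                             notes=tuple(notes))
    if nla_complete:  # cr < possible floor here
        return PhenotypeCall(profile.genome_id, "cbi_salvager", evidence)
    if cr >= rules.cr_likely_nonproducer_min:
        return PhenotypeCall(profile.genome_id, "likely_nonproducer", evidence)
    return PhenotypeCall(profile.genome_id, "very_likely_nonproducer", evidence)


def load_overrides(path: str | Path) -> dict[str, str]:
    """Per-genome forced categories (manual-curation analog): TSV with
    columns genome_id, category."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"genome_id", "category"} <= set(df.columns):
        raise RuleError(f"{path}: override file needs columns genome_id, category")
    bad = set(df["category"]) - set(CATEGORIES)
    if bad:
        raise RuleError(f"{path}: unknown override categories {sorted(bad)}")
    return dict(zip(df["genome_id"], df["category"]))


def classify_cohort(profiles: Iterable[AnnotationProfile],
                    catalog: FunctionCatalog,
                    rules: Optional[RuleSet] = None,
                    overrides: Optional[Mapping[str, str]] = None
                    ) -> dict[str, PhenotypeCall]:
    """Classify every profile; apply per-genome category overrides last."""
    rules = rules or RuleSet()
    calls: dict[str, PhenotypeCall] = {}
    for profile in profiles:
        call = classify_biosynthesis(profile, catalog, rules)
        if overrides and profile.genome_id in overrides:
            forced = overrides[profile.genome_id]
            subtype = call.salvager_subtype
            if forced == "tetrapyrrole_precursor_salvager":
                subtype = subtype or subtype_precursor_salvager(profile, catalog) \
                    or "unspecified"
            elif forced != call.category:
                subtype = None
            call = PhenotypeCall(profile.genome_id, forced, call.evidence,
                                 salvager_subtype=subtype,
                                 notes=call.notes + ("category forced by override",),
                                 overridden=True)
        calls[profile.genome_id] = call
    return calls


# ---------------------------------------------------------------------------
# marker concordance (per-category marker frequencies)
# ---------------------------------------------------------------------------

def marker_concordance(calls: Mapping[str, PhenotypeCall],
                       profiles: Mapping[str, AnnotationProfile],
                       catalog: FunctionCatalog) -> pd.DataFrame:
    """Percentage of genomes in each category carrying each corrin-ring
    marker, marker pair, the full triple, and the legacy marker.

    Rows are marker combinations, columns the seven categories plus the
    producer / non-producer aggregates.  Cells for empty categories are NaN
    (undefined), not 0.  Column denominators are stored in
    ``DataFrame.attrs["n"]``.
    """
    markers = list(catalog.marker_set.markers)
    combos: list[tuple[str, tuple[str, ...]]] = [(m, (m,)) for m in markers]
    for i in range(len(markers)):
        for j in range(i + 1, len(markers)):
            combos.append((f"{markers[i]} and {markers[j]}",
                           (markers[i], markers[j])))
    if len(markers) > 2:
        combos.append((" and ".join(markers), tuple(markers)))
    if catalog.marker_set.legacy_marker:
        combos.append((f"{catalog.marker_set.legacy_marker} (legacy)",
                       (catalog.marker_set.legacy_marker,)))

    ring = catalog.ortholog_groups("corrin_ring", scored_only=False)
    member_groups: dict[str, set[str]] = {}
    for gid, profile in profiles.items():
        member_groups[gid] = {g for g, anns in ring.items()
                              if any(profile.counts.get(a, 0) >= 1 for a in anns)}

    columns = list(CATEGORIES) + ["all_producers", "all_nonproducers"]
    genomes_in: dict[str, list[str]] = {c: [] for c in columns}
    for gid, call in calls.items():
        genomes_in[call.category].append(gid)
        if call.category in PRODUCER_CATEGORIES:
            genomes_in["all_producers"].append(gid)
        elif call.group == "no_biosynthesis":
            genomes_in["all_nonproducers"].append(gid)

    data: dict[str, list[float]] = {}
    for col in columns:
        members = genomes_in[col]
        vals = []
        for _, needed in combos:
            if not members:
                vals.append(float("nan"))
            else:
                k = sum(1 for g in members
                        if all(m in member_groups[g] for m in needed))
                vals.append(100.0 * k / len(members))
        data[col] = vals
    df = pd.DataFrame(data, index=[label for label, _ in combos])
    df.attrs["n"] = {c: len(genomes_in[c]) for c in columns}
    return df
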