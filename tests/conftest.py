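from __future__ import annotations

import pytest

from cobamide_scout.catalog import AnnotationID, FunctionCatalog, load_catalog
from cobamide_scout.classify import RuleSet
from cobamide_scout.ingest import AnnotationProfile
from cobamide_scout.structure import load_combo_map
from cobamide_scout.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def catalog() -> FunctionCatalog:
    return load_catalog()


@pytest.fixture(scope="session")
def rules() -> RuleSet:
    return RuleSet.from_yaml()


@pytest.fixture(scope="session")
def combo_map():
    return load_combo_map()


@pytest.fixture(scope="session")
def cohort0(catalog):
    """Noise-free default cohort: 10 genomes per category, seed 1."""
    return generate_cohort(CohortSpec(), seed=1, catalog=catalog)


@pytest.fixture(scope="session")
def noisy_cohort(catalog):
    """Cohort with realistic annotation noise for invariant tests."""
    spec = CohortSpec(dropout_rate=0.08, spurious_rate=1.5)
    return generate_cohort(spec, seed=5, catalog=catalog)


def profile_from_groups(catalog: FunctionCatalog, genome_id: str = "T1",
                        ring=(), nla=(), tp_steps=None, extra=()) -> AnnotationProfile:
    """Build a profile that detects exactly the given merged ortholog groups.

    ``tp_steps=None`` plants the full tetrapyrrole segment; pass a list of
    step names (e.g. ["hemB", "hemC", "hemD"]) to control the prefix.
    """
    counts: dict[AnnotationID, int] = {}
    ring_groups = catalog.ortholog_groups("corrin_ring")
    for g in ring:
        counts[min(ring_groups[g], key=str)] = 1
    nla_groups = catalog.ortholog_groups("nucleotide_loop")
    for g in nla:
        counts[min(nla_groups[g], key=str)] = 1
    steps = catalog.tetrapyrrole_steps()
    wanted = {s.step_name for s in steps} if tp_steps is None else set(tp_steps)
    for s in steps:
        if s.step_name in wanted:
            counts[min(s.annotation_ids, key=str)] = 1
    for a in extra:
        counts[a] = 1
    return AnnotationProfile(genome_id, counts)


ALL_RING = ("sumt", "cbiL/cobI", "cbiH/cobJ", "cbiF/cobM", "cbiG", "cbiD",
            "cobG", "cobF", "cbiJ/cobK", "cbiET/cobL", "cbiC/cobH", "cbiA/cobB")
ALL_NLA = ("adoT", "cobU/cobP", "cobS/cobV", "cbiB")
NON_MARKER_RING = tuple(g for g in ALL_RING
                        if g not in ("cbiL/cobI", "cbiF/cobM", "cbiC/cobH"))
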