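"""Cohort-level summary tables.

Aggregates per-genome calls into the analysis's standard summary surfaces:
the per-phylum histogram of cobamide-dependent enzyme families (with
mean/SD/median/mode inset), family rank abundance, per-process
dependent/independent/both tallies, seven-category phenotype proportions
overall and per phylum (with the "uses cobamides" fraction), lower-ligand
determinant and salvage/remodel proportions among predicted producers,
the marker-concordance table, and tetrapyrrole-salvager subtype counts.
All tables are plain DataFrames with explicit denominators; plotting is a
deliberately thin optional layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import FunctionCatalog
from .classify import (CATEGORIES, CATEGORY_GROUP, PRODUCER_CATEGORIES,
                       DependenceProfile, PhenotypeCall, marker_concordance)
from .ingest import AnnotationProfile, GenomeMetadata
from .structure import StructurePrediction


@dataclass
class SummaryTable:
    name: str
    table: pd.DataFrame
    denominators: dict[str, int]


def _histogram_stats(values: Sequence[int], n_max: int) -> dict[str, float]:
    arr = np.asarray(values)
    counts = np.bincount(arr, minlength=n_max + 1)
    mode = int(np.argmax(counts))
    return {"mean": float(arr.mean()), "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "median": float(np.median(arr)), "mode": float(mode)}


def summarize(calls: Mapping[str, PhenotypeCall],
              dependence: Mapping[str, DependenceProfile],
              structures: Mapping[str, StructurePrediction],
              metadata: Mapping[str, GenomeMetadata],
              profiles: Optional[Mapping[str, AnnotationProfile]] = None,
              catalog: Optional[FunctionCatalog] = None
              ) -> dict[str, SummaryTable]:
    """Build every summary table for a cohort of classified genomes."""
    genomes = sorted(calls)
    missing_meta = [g for g in genomes if g not in metadata]
    phylum = {g: metadata[g].phylum if g in metadata else "unknown" for g in genomes}
    phyla = sorted({phylum[g] for g in genomes})
    strata = ["all"] + phyla
    in_stratum = {s: [g for g in genomes if s == "all" or phylum[g] == s]
                  for s in strata}

    tables: dict[str, SummaryTable] = {}
    n_fam_max = max((len(catalog.dependent_families) if catalog else 15), 1)

    # 1. histogram of dependent-family counts, with inset stats
    rows = {}
    stats_rows = {}
    for s in strata:
        vals = [dependence[g].n_families for g in in_stratum[s]]
        counts = np.bincount(vals, minlength=n_fam_max + 1) if vals else \
            np.zeros(n_fam_max + 1, dtype=int)
        rows[s] = counts
        stats_rows[s] = _histogram_stats(vals, n_fam_max) if vals else {}
    hist = pd.DataFrame(rows, index=[str(i) for i in range(n_fam_max + 1)])
    hist.attrs["stats"] = stats_rows
    tables["dependence_histogram"] = SummaryTable(
        "dependence_histogram", hist, {s: len(in_stratum[s]) for s in strata})

    # 2. family rank abundance (percent of genomes carrying each family)
    fam_names = sorted({f for g in genomes for f in dependence[g].families_present})
    if catalog is not None:
        fam_names = sorted({f.family_name for f in catalog.dependent_families})
    rank = {}
    for s in strata:
        members = in_stratum[s]
        rank[s] = [100.0 * sum(f in dependence[g].families_present for g in members)
                   / len(members) if members else float("nan") for f in fam_names]
    rank_df = pd.DataFrame(rank, index=fam_names)
    rank_df = rank_df.sort_values("all", ascending=False)
    tables["family_rank_abundance"] = SummaryTable(
        "family_rank_abundance", rank_df, {s: len(in_stratum[s]) for s in strata})

    # 3. per-process dependent / independent / both / neither counts
    processes = sorted({p for g in genomes for p in dependence[g].process_status})
    proc_rows = []
    for p in processes:
        tally = {"dependent_only": 0, "independent_only": 0, "both": 0, "neither": 0}
        for g in genomes:
            tally[dependence[g].process_status[p]] += 1
        proc_rows.append({"process": p, **tally})
    tables["process_status"] = SummaryTable(
        "process_status", pd.DataFrame(proc_rows).set_index("process")
        if proc_rows else pd.DataFrame(), {"all": len(genomes)})

    # 4. seven-category proportions (and uses-cobamides) per stratum
    cat_rows = {}
    for s in strata:
        members = in_stratum[s]
        n = len(members)
        row = {}
        for c in CATEGORIES:
            row[c] = 100.0 * sum(calls[g].category == c for g in members) / n \
                if n else float("nan")
        for grp in ("complete_biosynthesis", "partial_biosynthesis", "no_biosynthesis"):
            row[grp] = 100.0 * sum(calls[g].group == grp for g in members) / n \
                if n else float("nan")
        row["uses_cobamides"] = 100.0 * sum(dependence[g].uses_cobamides
                                            for g in members) / n if n else float("nan")
        cat_rows[s] = row
    tables["phenotype_proportions"] = SummaryTable(
        "phenotype_proportions", pd.DataFrame(cat_rows),
        {s: len(in_stratum[s]) for s in strata})

    # 5. determinant / salvage / remodel proportions among predicted producers
    producers = [g for g in genomes if calls[g].category in PRODUCER_CATEGORIES]
    det_rows = {}
    for s in strata:
        members = [g for g in producers if s == "all" or phylum[g] == s]
        n = len(members)
        row = {}
        for d in ("bluB", "bza", "arsAB", "none"):
            row[d] = 100.0 * sum(structures[g].determinant == d for g in members) / n \
                if n else float("nan")
        row["alpha_ribazole_salvage"] = 100.0 * sum(
            structures[g].can_salvage_alpha_ribazole for g in members) / n \
            if n else float("nan")
        row["remodeling"] = 100.0 * sum(structures[g].can_remodel
                                        for g in members) / n if n else float("nan")
        det_rows[s] = row
        det_rows.setdefault("_n", {})[s] = n
    n_prod = det_rows.pop("_n")
    tables["structure_determinants"] = SummaryTable(
        "structure_determinants", pd.DataFrame(det_rows), n_prod)

    # 6. marker concordance
    if profiles is not None and catalog is not None:
        conc = marker_concordance(calls, profiles, catalog)
        tables["marker_concordance"] = SummaryTable(
            "marker_concordance", conc, dict(conc.attrs["n"]))

    # 7. tetrapyrrole-salvager subtype counts
    sub_counts: dict[str, int] = {}
    for g in genomes:
        if calls[g].salvager_subtype:
            sub_counts[calls[g].salvager_subtype] = \
                sub_counts.get(calls[g].salvager_subtype, 0) + 1
    tables["salvager_subtypes"] = SummaryTable(
        "salvager_subtypes",
        pd.DataFrame({"n_genomes": pd.Series(sub_counts, dtype=int)}),
        {"all": sum(sub_counts.values())})

    # integrity appendix: genomes in calls but absent from metadata
    tables["integrity"] = SummaryTable(
        "integrity", pd.DataFrame({"genomes_missing_metadata": missing_meta}),
        {"all": len(missing_meta)})
    return tables


def write_report(tables: Mapping[str, SummaryTable], outdir: str | Path) -> None:
    """Write every table as TSV plus a JSON bundle with denominators."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = {}
    for name, st in tables.items():
        st.table.to_csv(outdir / f"{name}.tsv", sep="\t")
        bundle[name] = {"denominators": st.denominators,
                        "table": json.loads(st.table.to_json(orient="index"))}
        if "stats" in st.table.attrs:
            bundle[name]["stats"] = st.table.attrs["stats"]
    with open(outdir / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=1, sort_keys=True)


def plot_report(tables: Mapping[str, SummaryTable], outdir: str | Path) -> None:
    """Optional stacked-bar renderings of the phenotype and determinant
    tables (shape-level figures, nothing pixel-matched)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("phenotype_proportions", "structure_determinants"):
        if name not in tables:
            continue
        df = tables[name].table
        rows = [r for r in df.index if r in CATEGORIES or r in
                ("bluB", "bza", "arsAB", "none")]
        fig, ax = plt.subplots(figsize=(8, 4))
        df.loc[rows].T.plot(kind="bar", stacked=True, ax=ax, width=0.8)
        ax.set_ylabel("% of genomes")
        ax.legend(fontsize=6, bbox_to_anchor=(1.02, 1), loc="upper left")
        fig.tight_layout()
        fig.savefig(outdir / f"{name}.png", dpi=120)
        plt.close(fig)
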