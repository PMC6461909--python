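# cobamide-scout

Rule-based prediction of cobamide (vitamin B12-family cofactor) biosynthesis,
dependence, and lower-ligand structure from per-genome functional-annotation
profiles.

Cobamides are corrinoid cofactors required by many bacterial metabolisms
(methionine synthesis via MetH, methylmalonyl-CoA mutase, B12-dependent
ribonucleotide reductases, reductive dehalogenation, ...), yet most bacteria
that use them cannot make them de novo. Whether a genome can produce a
cobamide, must salvage an intermediate such as cobinamide (Cbi) or an early
tetrapyrrole precursor (e.g. 5-aminolevulinic acid, ALA), or must import the
finished cofactor can be read off its annotated gene content — if the ~30-step
pathway, its aerobic/anaerobic ortholog pairs, and its known pitfalls
(promiscuous chelatase annotations, genes absent even in verified producers)
are modeled carefully. `cobamide-scout` is that model, packaged for
microbiologists and comparative genomicists working from IMG-style function
profiles or any genome × annotation count matrix.

## What it computes

Per genome, from an annotation profile (plus optional gene tables and HMMER3
hit files):

* **Dependence profile** — which of 15 cobamide-dependent enzyme families are
  present, and per metabolic process whether the cobamide-dependent enzyme,
  its cobamide-independent alternative, or both are encoded.
* **Biosynthesis phenotype** — one of seven categories: very likely / likely /
  possible cobamide producer (complete biosynthesis), tetrapyrrole precursor
  salvager or Cbi salvager (partial biosynthesis), likely / very likely
  non-producer (no biosynthesis). Scoring merges aerobic/anaerobic ortholog
  pairs (cbiL/cobI, cbiF/cobM, cbiC/cobH, ...) into single pathway steps and
  counts merged corrin-ring groups (CR), nucleotide-loop assembly steps, and
  the three core ring marker groups. The shipped default thresholds:

  | category | rule |
  |---|---|
  | very likely producer | CR ≥ 12 ∧ all 3 markers ∧ complete nucleotide loop |
  | likely producer | CR ≥ 9 ∧ ≥ 2 markers ∧ ≥ half the loop steps |
  | possible producer | CR ≥ 5 |
  | tetrapyrrole precursor salvager | would-be confident producer missing a contiguous leading stretch of hemA–hemD (subtyped GSA/ALA/PBG/HMB/UroIII) |
  | Cbi salvager | CR < 5 ∧ complete nucleotide loop |
  | likely non-producer | CR 3–4, loop incomplete |
  | very likely non-producer | CR ≤ 2, loop incomplete |

* **Lower-ligand structure** — `bluB` → cobalamin (DMB); `bza` gene complement
  (from trusted-cutoff-filtered HMM hits; BzaF or BzaA+BzaB is the committed
  first step) → 5-OHBza / 5-OMeBza / 5-OMe-6-MeBza / DMB; tandem cobT
  homologs (adjacent genes, both 300–800 AA) → phenolic cobamides; plus
  α-ribazole salvage (CblS/CblT) and corrinoid remodeling (CbiZ) flags.
* **QC** — genome completeness from 55 single-copy gene annotations (genomes
  with < 45/55 removed) and name-based, seeded-tie-break dereplication to one
  genome per species.
* **Synthetic cohorts** — genomes with planted phenotypes, noise
  (annotation dropout / spurious additions), gene-adjacency structure and HMM
  hit files, so the whole pipeline is testable end to end with known truth.

Everything is driven by an editable catalog
(`src/cobamide_scout/data/default_catalog.yaml`: 51 biosynthesis /
modification / salvage functions, 15 + 5 enzyme families) and a rules file,
so annotation inventories and thresholds can be swapped without code changes.

## Worked example

```bash
cobamide-scout simulate --seed 7 --outdir fixtures
cobamide-scout ingest --profiles fixtures/profiles.tsv --genes fixtures/genes.tsv \
    --hmm-hits fixtures/bza_hits.tbl --cutoffs fixtures/bza_cutoffs.tsv \
    --metadata fixtures/metadata.tsv --screened fixtures/screened.txt --out state.json
cobamide-scout classify --state state.json --out calls.tsv
cobamide-scout structure --state state.json --out structure.tsv
cobamide-scout report --state state.json --outdir report
```

which prints, along the way:

```
wrote 70 genomes to fixtures
state: 70 profiles, 358 genes, 23 trusted hits -> state.json
classified 70 genomes -> calls.tsv
predicted structure determinants for 70 genomes -> structure.tsv
wrote 8 summary tables -> report
```

`calls.tsv` then holds one row per genome with its category, group, salvager
subtype and evidence counts:

```
genome_id  category              group                  salvager_subtype  n_families  ...  n_corrin_ring  n_nucleotide_loop  n_markers
G00000     very_likely_producer  complete_biosynthesis                    8           ...  12             4                  3
```

(12 merged corrin-ring groups of 12, all 4 nucleotide-loop steps, all 3
markers → very likely producer carrying 8 of the 15 dependent families), and
`structure.tsv` the determinant calls, e.g. `G00001  bza  5-OMeBza ...
bza_genes=bzaC;bzaF` — BzaF makes 5-OHBza and BzaC methylates it to 5-OMeBza.
The `report/` directory collects the cohort summaries: dependence histogram
with mean/SD/median/mode, family rank abundance, per-process
dependent/independent/both tallies, phenotype proportions per phylum,
determinant proportions among producers, the marker-concordance table, and
salvager subtype counts.

The same API is available from Python (`cobamide_scout.generate_cohort`,
`classify_cohort`, `predict_structures`, `summarize`, ...).

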