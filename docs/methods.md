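# Methods

## The inference model

`cobamide-scout` treats a genome as a multiset of functional-annotation
identifiers (EC, Pfam, TIGRFAM, COG, IMG Term, BLAST-query and HMM
namespaces) and reduces every prediction to presence/absence logic over a
declarative pathway catalog. Copy numbers are retained in the data model but
binarized (count ≥ 1) for all classification; the only places copy number
matters are single-copy-gene completeness scoring and the tandem-gene test,
which works on gene coordinates rather than counts.

### Pathway model and ortholog merging

De novo cobamide biosynthesis is modeled as five segments: tetrapyrrole
precursor biosynthesis (hemA → hemL → hemB → hemC → hemD, glutamate to
uroporphyrinogen III), corrin ring biosynthesis (precorrin-2 to
adenosylcobinamide, with parallel aerobic/oxygen-sensitive routes),
nucleotide loop assembly, lower-ligand biosynthesis/activation, and
salvage/remodeling. Aerobic and anaerobic enzymes that catalyze the same
reaction (cbiL/cobI, cbiH/cobJ, cbiF/cobM, cbiJ/cobK, cbiE+cbiT/cobL,
cbiC/cobH, cbiA/cobB) share an *ortholog group* and count once toward
pathway completeness — the two routes cannot be distinguished from annotated
gene content, so completeness is scored route-agnostically. The shipped
catalog has 12 scoreable corrin-ring groups and 4 core nucleotide-loop
groups (adenosyltransferase, cobU/cobP, cobS/cobV, cbiB).

Two kinds of step are excluded from scoring. Hard exclusions (`excluded:
true`): cobR, pduX and cobD, which are absent from most experimentally
verified producers, and cobW, whose role is undetermined. Soft exclusions
(`low_specificity: true`): the cobalt chelatases (cbiK/cbiX, cobNST), whose
annotations overlap other metal chelatases; `load_catalog(...,
include_chelatases=True)` re-includes them. Exclusion lists, annotation IDs
and ortholog grouping are all config, not code.

Most annotation identifiers in the shipped catalog are editable placeholders
keyed by gene name (`IMGTerm:TERM:<gene>`); canonical accessions are used
only where unambiguous (hem genes, SUMT, cbiA/cobB, metH/metE, bluB,
cobW). Users with a curated annotation inventory are expected to replace
them in the YAML.

### The seven-category classifier

Let CR = number of merged corrin-ring groups detected, M = number of the
three core ring markers (cbiL/cobI, cbiF/cobM, cbiC/cobH) detected, NLA =
number of core nucleotide-loop groups detected (complete = 4/4). Default
rules, in precedence order:

1. compute the would-be producer tier:
   very likely (CR ≥ 12 ∧ M = 3 ∧ NLA complete),
   likely (CR ≥ 9 ∧ M ≥ 2 ∧ NLA ≥ ⌈4·0.5⌉), else
   possible (CR ≥ 5), else none;
2. a would-be very-likely/likely producer whose tetrapyrrole segment is
   missing a contiguous *leading* stretch (and nothing downstream) is a
   **tetrapyrrole precursor salvager**, subtyped by the product of the last
   missing step: hemA→GSA, hemL→ALA, hemB→PBG, hemC→HMB, hemD→UroIII.
   A non-contiguous absence pattern is inconsistent with simple auxotrophy:
   the genome stays in its producer tier and the call carries a note;
3. otherwise the producer tier stands;
4. below the producer floor (CR < 5), a complete nucleotide loop makes a
   **Cbi salvager**;
5. the remainder are non-producers: likely (CR 3–4) or very likely (CR ≤ 2).

The producer floor encodes the anchoring constraint that a non-producer has
fewer than five corrin-ring genes; "five genes" is interpreted as five
*merged ortholog groups*, consistent with the route-agnostic scoring above.
The very-likely/likely thresholds are this package's defaults, chosen to be
consistent with that floor, with near-100% marker frequency in confident
producers, and with the verbal category definitions; they are deliberately
config-overridable (`rules.yaml`) for users who maintain their own criteria
table, and a per-genome override file stands in for manual curation.
Category → group mapping is fixed: the three producer tiers are *complete
biosynthesis*, the two salvager classes *partial biosynthesis*, the two
non-producer tiers *no biosynthesis*.

Dependence profiling is independent of the pathway rules: a genome "uses
cobamides" when ≥ 1 of the 15 dependent enzyme families is detected, and
each of five processes with a cobamide-independent alternative (methionine
synthesis, ribonucleotide reduction, propionate, ethanolamine,
glycerol/propanediol) is labeled dependent-only / independent-only / both /
neither. Two fixed caveats are attached to output rather than modeled: the
mutase annotation overcounts the dependent side of propionate metabolism,
and the query-sequence-derived independent alternatives for ethanolamine and
glycerol/propanediol may undercount.

### Lower-ligand structure

Determinants are evaluated independently and reported with single-label
precedence bza > bluB > arsAB (raw flags always kept in evidence):

* **bza**: HMM hits are kept only at or above each HMM's trusted cutoff
  (a tie is kept, matching HMMER's `--cut_tc` semantics). A complement is
  benzimidazole-capable iff it contains bzaF or both bzaA and bzaB (the
  committed first step, AIR → 5-OHBza); the compound follows the shipped
  complement table (BzaC methylates to 5-OMeBza, BzaD to 5-OMe-6-MeBza,
  BzaE completes DMB), and capable-but-unmapped complements are
  "unresolved". Genomes outside the HMM screen are flagged `bza_screened =
  False` and contribute no bza evidence, rather than being scored as
  bza-negative observations.
* **bluB** implies DMB, i.e. cobalamin.
* **arsAB**: tandem cobT homologs — consecutive ordinals on one scaffold
  (strand ignored; gene order is what "sequential gene IDs" observably
  means), both members 300–800 AA inclusive — imply phenolic cobamides.
* CblS (α-ribazole kinase) sets the salvage flag; CblT (transporter) is
  reported separately rather than counted as salvage capability on its own;
  CbiZ sets the remodeling flag.

Purinyl cobamides and norcobamides have no known signature genes at this
resolution and are out of scope.

### QC and dereplication

Completeness = (number of the 55 single-copy-gene annotations detected,
mean copy number of the *detected* ones). Averaging over detected genes
only is the default reading of "average copy number of the annotation
hits"; `copy_mean_over_all=True` switches to the all-55 denominator.
Genomes with < 45/55 are removed (boundary: 45 is kept). Species are
binomial-name groups (lowercased genus + epithet, strain suffixes dropped,
optional alias file for data-entry duplicates); genus-only names are
singleton species. The representative maximizes (unique SCGs, −|mean − 1|)
lexicographically; exact ties are resolved by a uniform draw from a
generator seeded with a required user seed, so runs are reproducible.

## Synthetic cohorts: what they emulate and what they do not

The generator plants one of the seven categories per genome by
instantiating, from the catalog itself, an annotation set satisfying that
category's rule (choosing randomly between aerobic/anaerobic orthologs
within each group), then adds: a random subset of enzyme families; a
lower-ligand determinant for producer genomes (cycled bluB / bza / arsAB /
none, with bza complements drawn from the compound table and emitted as
tblout rows above the trusted cutoff, plus sub-cutoff decoy rows); decoy
cobT structures (isolated homologs, pairs failing the length filter) for
non-arsAB genomes; an SCG block at a chosen completeness level; and
metadata with phyla drawn from a four-phylum categorical (Proteobacteria
.40 / Firmicutes .25 / Actinobacteria .20 / Bacteroidetes .15) and an
ecosystem label for roughly half the genomes. Noise is independent
Bernoulli dropout per planted annotation plus Poisson-distributed spurious
annotations drawn uniformly from the catalog — the simplest model of the
annotation false negatives (poor annotation, non-homologous replacement)
and false positives the approach is known to face. Defaults are the
noise-free benchmark conditions (10 genomes per category, dropout =
spurious = 0, SCG 55/55); all rates are explicit arguments, and identical
(spec, seed) yields byte-identical output files.

Passing the planted-truth benchmark therefore shows that the classifier
implements its own rules exactly and degrades gracefully under independent
annotation noise (≈70% category recovery at 10% dropout + 1 spurious
annotation/genome in the acceptance run). It does **not** show that the
rules are biologically correct for real genomes: real annotation error is
correlated (whole-operon losses, shared HMM confusions), real pathways
include non-homologous replacements the catalog cannot see, and the
synthetic phylum labels carry no phylogenetic signal. Claims about real
cobamide ecology must come from running the pipeline on real profiles with
a curated catalog.

## Numerical and design choices

* Presence threshold is count ≥ 1 everywhere; there are no fractional
  scores, so there are no tolerance parameters in classification.
* "Closest to 1" in QC uses absolute distance |mean − 1|.
* Trusted-cutoff ties (score == cutoff) are retained.
* The tandem length window [300, 800] AA is inclusive at both ends.
* Tie-breaks that the rules leave open (equal-quality species
  representatives) are seeded-random and reproducible; everything else is
  deterministic.
* Degenerate inputs: an empty profile is a very likely non-producer with
  zero families; an empty category yields NaN (undefined), never 0, in the
  marker-concordance table; removing an absent annotation in `perturb` is a
  warning no-op.
* Problem sizes in the test-suite and acceptance runs (70-genome cohorts,
  100–1000 random oracle tables, 500 perturbations) were chosen as the
  smallest sizes at which every rule boundary and tie-break is actually
  exercised; all complete in seconds.

## Known limitations

* Archaeal cobamide biosynthesis differs in key steps and is explicitly not
  modeled.
* The shipped thresholds and placeholder annotation IDs are a documented
  starting point, not a curated inventory; results on real data are only as
  good as the catalog supplied.
* BLAST- and HMM-based searching is consumed as tabular input, not
  executed; the package never talks to external databases.
* Proportion tables are descriptive; no enrichment statistics are computed.
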