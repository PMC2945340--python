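# barcodeval

Evaluation of molecular species-identification markers: the mitochondrial
COI barcode against three nuclear rDNA expansion segments (18S V4, 18S V7,
28S D3), for multi-specimen, multi-species datasets such as ground-beetle
(Carabidae) surveys.

DNA barcoding identifies specimens by comparing a short standard marker —
usually the 5' ~658 bp of COI — against a reference library, relying on the
*barcoding gap*: intraspecific divergence staying well below interspecific
divergence. A single maternally inherited locus, however, can be misled by
introgression, incomplete lineage sorting, numts and endosymbiont sweeps.
Short nuclear rDNA expansion segments, invariant within species but
differing between close relatives by as little as one base, are candidate
supplements. This package implements the full comparative analysis for
that question:

* **Distances** — p-distance and the Kimura 2-parameter distance
  `d = -½·ln((1-2P-Q)·√(1-2Q))`, with P and Q the transition and
  transversion proportions under pairwise deletion; intra/interspecific
  summaries, A+T content, barcoding-gap report.
* **Resolution scoring** — a species is resolved by an rDNA marker when no
  heterospecific sequence is within one base change (substitution or indel
  event); by COI when every heterospecific specimen differs from every
  conspecific specimen by at least one substitution (diagnosability);
  combined-nuclear scoring sums differences over D3+V4+V7. An
  unresolved-pairs table collects the failing species pairs with per-marker
  evidence.
* **Trees** — neighbor-joining on distance matrices with nonparametric
  bootstrap support, Newick output.
* **Indicator vectors (Klee diagram)** — aligned sequences become 4L
  indicator vectors; one reference per species (M = 1); every remaining
  sequence is assigned to the species of maximal Pearson correlation, and
  the full correlation matrix is exported for heat-map display.
* **Statistical-parsimony haplotype networks** — TCS-style single-mutation
  networks with inferred intermediates up to a 95% parsimony connection
  limit, for sibling-species haplotype sharing.
* **Alignment** — an internal deterministic affine-gap pairwise aligner and
  progressive MSA (NJ guide tree); rDNA is aligned per genus because
  indel-rich expansion segments cannot be homologised across distant taxa.
* **Synthetic data** — a seeded generator that emulates the statistical
  structure of such a survey (75 species, 2–13 specimens each, AT-biased
  COI, within-species-invariant rDNA) including designed hard cases:
  a sibling pair sharing COI haplotypes and all rDNA sequences, a pair
  identical at all rDNA markers only, a cross-genus identical V4, and a
  deep-split species with two COI clusters. Every designed outcome is
  recorded as ground truth and re-verified by brute force.

## Worked example

```bash
barcodeval simulate --seed 4 --out simdata/
barcodeval resolve --dataset simdata --criterion coi
barcodeval klee --dataset simdata
barcodeval network --dataset simdata --species "Genus01 sp01" --species "Genus01 sp02"
```

prints

```
COI: 73/75 species resolved (97.3%)
  unresolved: Genus01 sp01 <-> Genus01 sp02
  unresolved: Genus01 sp02 <-> Genus01 sp01
298/300 test sequences (99.3%) assigned to their own species
3 haplotypes, limit 8 steps, 1 component(s)
```

Reading: of 75 simulated species, only the designed sibling pair that
shares COI haplotypes is unresolvable by COI (73/75 = 97.3%). Indicator-
vector classification misassigns only test sequences belonging to that
pair. Their joint haplotype network is a single component of three
haplotypes one mutational step apart — the signature of shared or
introgressed mitochondria. The full pipeline (`barcodeval run --simulate
--seed 1 --out out/`) additionally writes distance matrices and
histograms, the NJ tree with bootstrap, per-marker and combined-nuclear
resolution tables, the unresolved-pairs table, fragment-length and
within-genus boxplot statistics, the Klee correlation matrix, network edge
lists, and a provenance manifest.

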