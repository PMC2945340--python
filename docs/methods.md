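# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, the design of the synthetic data generator,
and what passing tests do and do not establish about real data.

## Distances

Pairwise distances operate under *pairwise deletion*: for each pair of
aligned rows, columns holding a gap or an IUPAC ambiguity code in either
row are excluded; `compared_sites + excluded_sites = alignment length`
holds per pair. Complete-deletion behaviour can be had by pre-filtering
columns. Substitutions are classed by purine/pyrimidine parity: A↔G and
C↔T are transitions (proportion P), all other differing pairs
transversions (Q).

* p-distance: `(transitions + transversions) / compared_sites`.
* K2P: `d = -½·ln((1-2P-Q)·√(1-2Q))`. When the logarithm's argument is
  non-positive (saturation) or no sites are comparable, the entry is NaN —
  flagged, logged, excluded from means, never imputed. K2P ≥ p always,
  with equality only at zero.

The interspecific "average" is the mean over all heterospecific specimen
pairs (species-pair min/max ranges are reported separately); percentages
in reports are fractions × 100. Histogram bin width defaults to 0.5% and
is presentation-only.

## Alignment

COI data are length-uniform in practice; equal-length input is stacked
without alignment, otherwise a global alignment is computed with a
warning. rDNA expansion segments are aligned **within genera only** —
their indels cannot be homologised across distant taxa — with each genus
aligned independently; cross-genus comparisons use exact string identity
(for resolution) or an on-demand pairwise alignment (for report cells).

The internal aligner is a Gotoh affine-gap global aligner (gap of length g
costs `open + g·extend`; defaults match 1, mismatch −1, open 4, extend 1 —
conservative gap placement appropriate for low-divergence rDNA).
Tie-breaking is fixed: match/mismatch preferred over gaps, then
gap-in-first-sequence, so output is deterministic. Groups are aligned
progressively along a neighbor-joining guide order computed from
pairwise-alignment p-distances; profiles are per-column base-frequency
vectors and ambiguity codes score zero against everything. Duplicate
sequences are collapsed before alignment and re-expanded afterwards.
Pre-aligned input rows pass through untouched after length validation.
The progressive heuristic is not guaranteed optimal for >2 sequences; the
invariants enforced are exact degap round-trip per row and pairwise
optimality (checked against exhaustive enumeration on small cases).

## Trees and bootstrap

Neighbor joining follows the Saitou–Nei agglomeration with a deterministic
tie-break on the Q criterion: row-major minimum over the current node
order, merged nodes appended last. Negative branch lengths are clamped to
zero (logged). Trees are unrooted clusterings, not phylogenies; Newick
output roots arbitrarily at the last internal node and quotes labels
containing metacharacters.

Bootstrap: alignment columns are resampled with replacement per replicate;
support for each non-trivial bipartition of the point-estimate tree is the
percentage of analysable replicate NJ trees containing it (support mapped
onto the point estimate, not a consensus). Replicates producing undefined
distances are skipped and counted. Full-scale analyses conventionally use
10³–10⁴ replicates; the shipped pipeline default is 200 and the
reproduction script uses 100, which stabilises support values to a few
percent — adequate for the ≥95 display convention.

## Resolution criteria

* **rDNA (single marker):** a species is unresolved iff some
  heterospecific sequence is within `min_differences` (default 1) base
  changes. A maximal run of gap columns in one row counts as one indel
  *event* by default (`column` counting available), since an insertion or
  deletion of several bases is one mutational change. With the default
  threshold this reduces to exact sequence identity, checked globally so
  that cross-genus identical sequences are caught without cross-genus
  alignment.
* **COI (diagnosability):** a species is resolved iff every conspecific
  specimen differs from every heterospecific specimen by at least
  `min_differences` substitutions. This deliberately treats species with
  deep intraspecific splits as resolved — cohesion is not required — and
  such species are flagged separately by a configurable maximum
  intraspecific distance threshold (default 2%, a common barcode
  heuristic above which distance-threshold delimitation would oversplit).
* **Combined nuclear:** difference counts summed over D3+V4+V7 per
  specimen pair (equivalently computed on the concatenation, fixed order
  D3, V4, V7); with threshold 1, a pair fails only when identical at all
  three markers. Combined p-distances are reported as summed differences
  over summed compared sites.

The unresolved-pairs table lists every species pair failing ≥1 marker,
with "identical sequences" or `p-distance/differences` cells per rDNA
marker and the K2P range for COI; a pair sharing any COI haplotype is
reported as identical there. Monotonicity (combined ⊇ each single marker;
raising the threshold never adds resolved species) is enforced by tests.

## Indicator-vector classification

Aligned sequences map to 4L vectors (slots A,C,G,T per column; gaps and
ambiguity codes give zero blocks by default, a fractional policy splits
ambiguity codes evenly). References are the per-species mean of M encoded
sequences, M = 1 by default, chosen as the lexicographically first
specimen id (a seeded random rule and a mean-accuracy-over-draws helper
exist to show insensitivity to the choice). Correlation is centred
Pearson (uncentred cosine available); assignment is argmax with
lexicographic tie-break, ties counted; all-undefined rows are unassigned
and scored incorrect.

## Statistical-parsimony network

Distinct haplotypes are connected agglomeratively in order of increasing
Hamming distance (ambiguous columns treated as missing); a pair k > 1
steps apart gains k−1 inferred intermediate nodes unless an existing path
of length ≤ k already joins it; pairs beyond the connection limit stay
separate, so reticulations are retained. The 95% connection limit is the
largest j with parsimony probability above the confidence level, where
the probability that j observed differences over m sites involve no
doubly-hit site is estimated from a per-site Poisson mutation model with
rate fitted by the Jukes–Cantor correction λ = −¾·ln(1 − 4j/3m):

    P(j, m) = a^j · b^(m−j),
    a = λe^{−λ} / (¾(1 − e^{−4λ/3}))     (one hit | site differs)
    b = e^{−λ} / (¼ + ¾e^{−4λ/3})        (no hit | site matches)

This estimate is monotone in both arguments (limit non-decreasing in m,
non-increasing in confidence) and gives a limit of 8 steps at 658 bp and
95% — conservative relative to some legacy software defaults; the limit
can be overridden explicitly. It is cross-checked in tests by an
independent 60-digit Decimal evaluation.

## Synthetic data generator

The generator's defaults encode the study conditions the pipeline is
meant for: 75 species in ~25–30 genera; specimens per species drawn from
a truncated geometric on 2–13 (decay 0.74, mean ≈ 4.6, ≈ 345 specimens).

**COI (658 bp).** One founder sequence with exact target composition
(A+T = 0.676; counts fixed, order shuffled — the whole dataset descends
from this founder, so its composition must not carry sampling noise).
Species founders apply a per-species substitution load drawn uniformly
from 1.7–10.5% of sites, giving interspecific distances of roughly 3–21%
with a mean near 12%; specimens add Bernoulli per-site noise (rate ≤
0.003), keeping intraspecific K2P below ~2%. Substitutions are HKY-like:
the replacement base is weighted by stationary frequency with the
transition partner up-weighted (realised ts:tv ≈ 2:1), which approximately
preserves composition; the realised dataset A+T is ≈ 66.3%, a small
downward drift of the jump chain from the 67.6% founder. Frame-0 stop
codons are repaired with same-composition leucine codons (TAA→TTA,
TAG→TTG) so the barcode behaves as numt-free coding sequence under
translation screening; an optional numt toggle adds frame-shifted copies
carrying a stop codon in every reading phase, solely to exercise the
screen.

**rDNA.** One random founder per genus per marker; lengths are drawn
truncated-exponential with means 198 (D3, 185–254), 384 (V4, 355–515) and
414 bp (V7, 388–504). Species are invariant within and differ between
congeners by disjoint private substitution sets — counts uniform on 1–11
(D3), 1–13 (V4), 2–17 (V7), calibrated to within-genus mean p-distances
of ~6%, ~3.5% and ~4.5% respectively — plus occasional 1–8 bp indels
(probability 0.3, geometric lengths) placed away from 10 bp conserved
flanks. Disjoint private sites guarantee ≥2 differences between any two
non-designed congeners, so resolution ground truth is exact by
construction.

**Designed pathologies.** A sibling pair sharing a COI haplotype pool and
all rDNA sequences (fails every marker); a pair identical at all three
rDNA markers but ~4.5% apart at COI (fails combined-nuclear only); a
cross-genus pair with identical V4; a deep-split species with two COI
clusters 3.8% of sites apart, optionally tracked by two V7 variants (the
one permitted within-species rDNA polymorphism). Additional per-marker
identity groups default, at 75 species, to totals of 14 (D3), 18 (V4,
including the cross-genus pair) and 10 (V7) unresolved species — i.e.
61/57/65 single-marker, 71 combined and 73 COI resolved. After
generation, `verify` re-checks every designed property by brute force
(exact identity structure, haplotype sharing confined to the designed
pair, minimum interspecific load, intraspecific caps, A+T within ±0.02)
and generation fails loudly on any mismatch.

**What the generator does not emulate:** phylogenetic correlation among
genera (genus founders are unrelated random sequences, so no global rDNA
alignment or cross-genus tree is meaningful and none is attempted),
coalescent population structure, selection, recombination, rate
heterogeneity along sequences, and rDNA base composition. Passing
parameter-recovery tests therefore demonstrates correctness of the
scoring machinery under the designed signal/noise structure, not
robustness to alignment ambiguity or population-genetic complications in
real data.

## Pipeline and reports

`run_pipeline` executes numt screen → COI alignment and distances →
NJ+bootstrap → per-genus rDNA alignments and distances → resolution and
unresolved-pairs table → barcoding gap and deep-split flags → indicator
vector classification → sibling-pair haplotype network, writing TSV /
JSON / Newick / FASTA plus a manifest recording config, seed and version;
reruns with the same seed are byte-identical. Box statistics for the
within-genus interspecific p-distance pools report mean (box midpoint by
the figure convention; median exported alongside), 25th/75th and
10th/90th percentiles using linear interpolation between order
statistics.

Problem sizes: the shipped tests use 20-species datasets (one at 75
species for scale checks) with 100-replicate bootstraps at most; the
reproduction script runs the full 75-species configuration with a
100-replicate bootstrap, completing in well under a minute of compute for
everything except the bootstrap and a few seconds per rDNA genus
alignment.

## Known limitations

* The progressive aligner is heuristic; pathological rDNA indel
  configurations could misplace gaps relative to an exact multiple
  aligner, slightly perturbing difference counts near the 1-difference
  threshold (not observable under the generator's disjoint-sites design).
* The parsimony connection limit uses the package's own documented
  probability estimate; networks built with other software may connect
  slightly more distant haplotypes.
* Bootstrap supports are mapped onto the point-estimate topology;
  majority-rule consensus supports would differ on poorly supported
  edges.
* Cross-genus rDNA evidence is exact identity only; a near-identical (1
  difference) cross-genus pair would be scored resolved without a
  cross-genus alignment, consistent with the per-genus alignment scope.
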