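# Methods

## Distance model

Pairwise divergence is the Kimura 2-parameter (K2P) distance. For a pair of
aligned sequences let *L* be the number of sites where both residues are in
{A,C,G,T}, *s* the transition differences (A↔G, C↔T) and *v* the transversion
differences; with P = s/L and Q = v/L,

    d = -(1/2) ln[(1 - 2P - Q) √(1 - 2Q)] .

The model assumes equal base frequencies, a single transition rate and a
single (per-channel) transversion rate, site independence and homogeneity.
Gaps and IUPAC ambiguity codes are treated as missing and removed
pair-by-pair (*pairwise deletion*), the default behaviour of the standard
distance software in this field; *complete deletion* (drop any column with a
gap/ambiguity anywhere) is a switch (`gap_mode="complete"`). Ambiguity codes
are never fractionally resolved — determinism is worth more than the handful
of half-informative sites. When 1−2P−Q ≤ 0 or 1−2Q ≤ 0 the distance has no
finite estimate ("saturation"); such pairs are flagged undefined (NaN),
excluded from all downstream summaries, and counted in a logged warning.
Substituting a large constant instead would silently distort gap histograms.

The uncorrected p-distance and percent identity (a plain similarity defined
as matches/compared sites) are provided as diagnostic companions. The K2P
correction always dominates the p-distance where defined.

## Barcoding-gap analysis

Defined distances are partitioned into intra-specific (same species) and
inter-specific pairs by the species map. The global verdict is strict:
**clear gap ⇔ min(inter) > max(intra)**; equality counts as overlap, matching
the visual notion of a gap between the two distributions. The signed margin
min(inter) − max(intra) is reported alongside.

Per-species summaries give max intra (undefined for singleton species), min
inter, and the species achieving it (ties broken lexicographically, so output
is stable). A singleton species' per-species gap verdict is min(inter) > 0 —
single-voucher species occur in real surveys and still need a score.
Singletons contribute nothing to the intra histogram.

Histograms bin both classes into half-open intervals [k·w, (k+1)·w). The bin
index is floor(d/w + 1e-9); the nudge keeps a distance lying exactly on a bin
boundary (e.g. 0.004 with w = 0.004) in the upper bin when floating-point
division lands infinitesimally below the integer. Conventional widths are
0.004 for slowly evolving regions and 0.008 for faster ones; the CLI keys
these defaults by region name (ITS/nLSU/mtSSU → 0.004, IGS/tef1 → 0.008) and
accepts an override.

## Neighbor-joining and bootstrap

NJ follows Saitou–Nei with the Studier–Keppler criterion
Q(i,j) = (m−2)·d(i,j) − R_i − R_j. Two numerical conventions matter:

* **Tie-breaking.** When several pairs minimise Q, the pair whose sorted
  cluster keys (the lexicographically smallest leaf label in each cluster)
  compare smallest is joined. Output is therefore deterministic and invariant
  under input-order permutation.
* **Exact symmetry.** R_i + R_j is computed as a grouped sum before
  subtraction; the naive left-to-right form (X − R_i) − R_j is not exactly
  symmetric in floating point and can make the Q-argmin's mirror entry differ
  by one ulp, breaking deterministic pair selection.

NJ recovers any additive (four-point) matrix's topology and branch lengths
exactly; this is tested against a brute-force path-metric oracle and
cross-checked against an independent implementation (scikit-bio). Negative
branch lengths on non-additive input are retained (they preserve additivity
accounting); Newick output can clamp them to 0 via a flag. Trees are dendropy
objects; Newick I/O, rooting and traversal are delegated to dendropy, with
supports carried as internal node labels and branch lengths written to six
decimals. Outgroup rooting splits the outgroup's terminal branch evenly.

Bootstrap supports use Felsenstein column resampling: replicate length equals
the original length, columns drawn uniformly with replacement. Internally
each replicate is a multinomial weight vector over the original columns, so
per-replicate transition/transversion/valid-site counts for all pairs are
three matrix products against precomputed per-pair column classifications —
this is what makes 100 × 200-replicate studies cheap. A replicate whose
distance matrix contains an undefined entry is dropped and counted; more than
10% dropped aborts with an error. Support = percentage of retained replicate
trees containing the reference bipartition, rounded half-up to an integer.
Replicate tree bipartitions are tracked as leaf bitmasks and compared in
canonical form (the side containing the lexicographically smallest label).

Monophyly: a species is monophyletic when some edge separates exactly its
samples from everything else. On a rooted tree this is the usual clade test;
an unrooted variant accepts either side of an edge, used when no outgroup is
supplied (rooting arbitrarily could otherwise split a species at the root).
Singleton species are monophyletic by convention, support n/a.

## Marker evaluation

Success rates are 100 × successes/total rounded half-up — the convention that
reproduces every percentage derivable from the bundled survey table (27/34 →
79, 24/34 → 71, 28/34 → 82, 21/34 → 62, 33/34 → 97, 32/34 → 94, 23/34 → 68).
Sequencing counts derive from accession presence/absence; PCR success counts
are lab bookkeeping and enter through the status table, not inference.
`evaluate_marker` composes rates, ungapped length range, gap verdict, and
monophyly with bootstrap supports into one report; `rank_markers` orders
candidates by (sequencing rate, gap margin) descending — a deliberate,
deterministic proxy for the qualitative ranking practitioners apply.

## Synthetic data generator

The generator emulates the structure of a small multi-locus barcoding survey:
by default 8 species with sample sizes (1, 3, 8, 6, 3, 6, 5, 2) — 34 samples,
matching a realistic skew from singleton vouchers up to a well-sampled
species — at 600 aligned bp, within the 400–1,000 bp range typical of
barcode loci.

A uniform-random root sequence evolves to each species ancestor for
`inter_depth` = 0.08 expected substitutions/site (star species tree), then to
each sample for `intra_depth` = 0.005, with κ = 2 (instantaneous transition
rate = κ × each transversion rate; rates normalized so one time unit is one
expected substitution/site). These defaults put true conspecific divergence
at 0.01 and heterospecific divergence at 0.17 substitutions/site — an
inter/intra ratio ≈ 17, the "inter ≫ intra" regime of a good barcode locus.
Substitution uses the exact K2P transition-probability matrix at the branch's
depth (no discretised steps). Per-sample dropout is Bernoulli: amplification
fails with `dropout_pcr`, sequencing (given amplification) with
`dropout_seq`, so sequenced ⇒ amplified always holds. An arbitrary Newick
species tree can replace the star; the truth table then uses patristic
distances between species plus 2 × intra_depth.

What the generator does **not** emulate: indels and alignment error (output
is aligned by construction), rate heterogeneity across sites or lineages,
base-composition bias, within-species coalescent structure, and
contamination/mislabeling. Tests passing on synthetic data therefore show
the *pipeline* behaves correctly under its model assumptions, not that any
particular real locus will show a gap.

The all-pairs truth table is materialized lazily so very large simulated
cohorts (used for dropout-rate recovery at n = 10,000) don't pay a quadratic
cost.

## Problem sizes and determinism

The replicated end-to-end study runs 100 simulated datasets (34 samples ×
600 bp) with 200 bootstrap replicates each — enough for stable percentages
while keeping a full run under a minute on one core. Every random draw flows
from a single `numpy.random.Generator` seed; two runs with the same seed are
byte-identical, including FASTA and Newick output. The acceptance script
derives all of its sub-seeds from its `--seed` argument.

## Known limitations

* Only K2P and p-distances are implemented (plus percent identity); TN93/GTR
  or maximum-likelihood distances are out of scope.
* Percent identity is plain matches/compared-sites; proprietary similarity
  weightings of legacy software are not reproduced.
* The gap verdict is the strict min/max criterion; density-based or
  delimitation methods (ABGD, GMYC, PTP) are not provided.
* Bootstrap supports below ~70% on shallow within-species splits are
  expected noise when conspecific sequences are nearly identical; the marker
  report deliberately summarises only species-clade supports.
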