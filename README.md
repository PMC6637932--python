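# barcodekit

Tools for evaluating candidate **DNA-barcode markers** — loci whose sequence
variation discriminates species. Given an aligned marker region, a
sample→species map, and amplification/sequencing status, `barcodekit` answers
the two questions that decide whether a locus works as a barcode:

1. **Is it practical?** — PCR and sequencing success rates, raw length range.
2. **Is it diagnostic?** — does between-species variation cleanly exceed
   within-species variation (the *barcoding gap*), and do the samples of each
   species form exclusive, well-supported clades in a distance tree?

It was built with fungal multi-locus surveys in mind (ITS/IGS/nLSU/mtSSU/tef1
style marker panels across a handful of congeneric species) but is agnostic to
the organism.

## The statistics at its core

**K2P distance.** Pairwise divergence uses the Kimura 2-parameter model,
which separates transitions (A↔G, C↔T) from transversions:

    d = -(1/2) · ln[(1 - 2P - Q) · √(1 - 2Q)]

with *P* and *Q* the transition/transversion difference proportions among
compared sites. Sites with a gap or IUPAC ambiguity in either sequence are
excluded pair-by-pair (pairwise deletion; complete deletion available).
Pairs beyond the model's correctable range are flagged undefined, never
silently replaced.

**Barcoding gap.** Distances are partitioned into intra- and inter-specific
classes. The global verdict is strict: *clear gap* ⇔ min(inter) > max(intra).
Per-species summaries report the largest within-species distance, the smallest
distance to any other species and which species achieves it. Histograms use
half-open bins [k·w, (k+1)·w).

**Trees.** Neighbor-joining (Saitou–Nei, Studier–Keppler Q criterion) with
deterministic lexicographic tie-breaking; recovers additive matrices exactly.
Bootstrap supports by Felsenstein column resampling, outgroup rooting, and
per-species monophyly checks. Trees are `dendropy` objects, serialized as
Newick with supports as internal node labels.

**Simulator.** A K2P sequence generator (star species tree by default, or any
Newick species tree) with configurable inter/intra divergence depths,
transition/transversion ratio κ, and per-sample PCR/sequencing dropout — so
the whole pipeline runs and is testable with no external data.

## Worked example

```python
from barcodekit import SimConfig, simulate_dataset, evaluate_marker

sim = simulate_dataset(SimConfig(seed=8, region="markerA"))
rep = evaluate_marker(sim.alignment, sim.species_map, sim.status,
                      bootstrap_B=200, seed=3)
print(rep.tsv_header())
print(rep.to_tsv_row())
```

prints

```
region	length_range	n_total	n_amplified	pcr_rate	n_sequenced	seq_rate	gap_verdict	gap_margin	monophyletic_species	min_clade_support
markerA	600-600	34	34	100	34	100	clear gap	0.086716	8/8	100
```

Reading the row: all 34 samples amplified and sequenced (100%/100%); the
smallest between-species K2P distance exceeds the largest within-species
distance by 0.087 substitutions/site (a clear barcoding gap); all 8 species
are monophyletic in the bootstrapped NJ tree, and every multi-sample species
clade has 100% bootstrap support — the signature of a good barcode. The
`examples/` directory walks through each stage (simulation and distances, gap
analysis, trees and supports, marker reports, and the bundled survey
accounting) as short runnable scripts.

A CLI mirrors the stages:

```sh
barcodekit simulate --seed 11 --region ITSsim --out-dir sim/
barcodekit gapstats sim/ITSsim.fasta --species-map sim/ITSsim.species.tsv --out-dir gaps/
barcodekit tree sim/ITSsim.fasta --replicates 1000 --seed 5 --out tree.nwk
barcodekit evaluate sim/ITSsim.fasta --species-map sim/ITSsim.species.tsv \
    --status sim/ITSsim.status.tsv --out-dir eval/
```

## Bundled survey data

`barcodekit.datasets` ships the voucher-by-region accession table of a
published 8-species, 34-voucher *Lepista* barcoding survey (five candidate
regions). Per-region sequencing success is recomputed from accession
presence/absence; ITS comes out at 34/34 (100%) and tef1 at 21/34 (62%), with
134 sequences in total.

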