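"""Barcoding-gap analysis: partition distances, histogram, verdict.

A marker discriminates species when its smallest between-species distance
exceeds its largest within-species distance ("clear gap").
"""

from barcodekit import (
    SimConfig,
    build_histogram,
    gap_exists,
    pairwise_matrix,
    partition_distances,
    simulate_dataset,
    species_gap_summary,
)

sim = simulate_dataset(SimConfig(seed=42))
dm = pairwise_matrix(sim.alignment)
part = partition_distances(dm, sim.species_map)
print(f"intra-specific pairs: {len(part.intra)}, inter-specific: {len(part.inter)}")

result = gap_exists(part)
print(
    f"verdict: {result.verdict.value} "
    f"(max intra {result.max_intra:.4f}, min inter {result.min_inter:.4f}, "
    f"margin {result.margin:.4f})"
)

hist = build_histogram(part, w=0.004)
print("\ndistance histogram (bin width 0.004):")
print("bin_start  intra  inter")
for (lo, _hi), ci, cx in zip(hist.bin_edges(), hist.counts_intra, hist.counts_inter):
    if ci or cx:
        print(f"  {lo:7.3f} {ci:6d} {cx:6d}")
# intra counts pile up in the first bins, inter counts far to the right:
# the empty bins between them are the barcoding gap.

print("\nper-species closest-relative summary:")
for s in species_gap_summary(dm, sim.species_map):
    mi = "singleton" if s.max_intra is None else f"{s.max_intra:.4f}"
    print(
        f"  {s.species}: max_intra {mi}, min_inter {s.min_inter:.4f} "
        f"(nearest {s.nearest_species}), gap={s.gap_present}"
    )
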