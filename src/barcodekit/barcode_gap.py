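"""Barcoding-gap analysis: intra/inter partitioning, per-species summaries,
histograms and the global gap verdict.

A candidate barcode shows a "barcoding gap" when the distribution of
between-species (inter-specific) distances is separated from the
distribution of within-species (intra-specific) distances.  The global
criterion used here is strict: the smallest inter-specific distance must
exceed the largest intra-specific distance; a tie counts as overlap.

Per-species summaries mirror the closest-relative style of analysis: for
each species, the maximum intra-specific distance, the minimum distance to
any other species, and which species achieves that minimum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from barcodekit.distance import DistanceMatrix
from barcodekit.seq_io import SpeciesMap

logger = logging.getLogger(__name__)


class GapVerdict(str, Enum):
    CLEAR_GAP = "clear gap"
    OVERLAP = "overlap"


@dataclass(frozen=True)
class DistancePartition:
    """Defined pairwise distances split into intra- and inter-specific."""

    intra: tuple[tuple[str, float], ...]  # (species, distance)
    inter: tuple[tuple[str, str, float], ...]  # (species_a, species_b, distance)

    @property
    def intra_values(self) -> np.ndarray:
        return np.array([d for _, d in self.intra], dtype=float)

    @property
    def inter_values(self) -> np.ndarray:
        return np.array([d for _, _, d in self.inter], dtype=float)


@dataclass(frozen=True)
class SpeciesGapSummary:
    species: str
    max_intra: float | None  # None for singleton species
    min_inter: float
    nearest_species: str
    gap_present: bool


@dataclass(frozen=True)
class GapHistogram:
    """Counts of intra/inter distances in half-open bins [k*w, (k+1)*w)."""

    bin_width: float
    counts_intra: tuple[int, ...]
    counts_inter: tuple[int, ...]

    @property
    def n_bins(self) -> int:
        return len(self.counts_intra)

    def bin_edges(self) -> list[tuple[float, float]]:
        w = self.bin_width
        return [(k * w, (k + 1) * w) for k in range(self.n_bins)]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("bin_start\tbin_end\tintra_count\tinter_count\n")
            for (lo, hi), ci, cx in zip(
                self.bin_edges(), self.counts_intra, self.counts_inter
            ):
                fh.write(f"{lo:.6g}\t{hi:.6g}\t{ci}\t{cx}\n")


def partition_distances(m: DistanceMatrix, sp: SpeciesMap) -> DistancePartition:
    """Assign every defined unordered pair to the intra or inter class."""
    missing = [lab for lab in m.labels if lab not in sp]
    if missing:
        raise KeyError(
            f"matrix label(s) not in species map: {', '.join(missing)}"
        )
    intra: list[tuple[str, float]] = []
    inter: list[tuple[str, str, float]] = []
    n_undef = m.n_undefined_pairs
    for a, b, d in m.iter_pairs():
        sa, sb = sp[a], sp[b]
        if sa == sb:
            intra.append((sa, d))
        else:
            x, y = sorted((sa, sb))
            inter.append((x, y, d))
    if n_undef:
        logger.warning(
            "%d undefined pair(s) excluded from the intra/inter partition",
            n_undef,
        )
    return DistancePartition(tuple(intra), tuple(inter))


def species_gap_summary(
    m: DistanceMatrix, sp: SpeciesMap
) -> list[SpeciesGapSummary]:
    """Per-species closest-relative summary.

    For each species: the largest within-species distance (undefined for
    singletons), the smallest distance to any other species, the species
    achieving it (ties broken lexicographically), and whether that species
    shows a gap (min_inter > max_intra, or min_inter > 0 for singletons).
    """
    part = partition_distances(m, sp)
    species = [s for s in sp.species if any(sp[lab] == s for lab in m.labels)]
    if len(species) < 2:
        raise ValueError("need at least 2 species for gap summaries")
    out: list[SpeciesGapSummary] = []
    for s in species:
        intra_vals = [d for sp_name, d in part.intra if sp_name == s]
        max_intra = max(intra_vals) if intra_vals else None
        best: tuple[float, str] | None = None
        for a, b, d in part.inter:
            if s == a:
                other = b
            elif s == b:
                other = a
            else:
                continue
            if best is None or d < best[0] or (d == best[0] and other < best[1]):
                best = (d, other)
        if best is None:
            raise ValueError(
                f"species {s!r} has no defined inter-specific distances"
            )
        min_inter, nearest = best
        if max_intra is None:
            gap = min_inter > 0.0
        else:
            gap = min_inter > max_intra
        out.append(SpeciesGapSummary(s, max_intra, min_inter, nearest, gap))
    return out


def write_species_summaries_tsv(summaries, path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tmax_intra\tmin_inter\tnearest_species\tgap_present\n")
        for s in summaries:
            mi = "NA" if s.max_intra is None else f"{s.max_intra:.6f}"
            fh.write(
                f"{s.species}\t{mi}\t{s.min_inter:.6f}\t"
                f"{s.nearest_species}\t{int(s.gap_present)}\n"
            )


def build_histogram(p: DistancePartition, w: float) -> GapHistogram:
    """Bin intra and inter distances into half-open intervals of width w."""
    if w <= 0:
        raise ValueError("bin width must be positive")
    intra = p.intra_values
    inter = p.inter_values
    if intra.size + inter.size == 0:
        raise ValueError("no defined distances to bin")

    def _bin(vals: np.ndarray, n_bins: int) -> np.ndarray:
        counts = np.zeros(n_bins, dtype=int)
        if vals.size:
            # nudge guards against k*w landing infinitesimally below k
            idx = np.floor(vals / w + 1e-9).astype(int)
            for k in idx:
                counts[k] += 1
        return counts

    all_vals = np.concatenate([intra, inter])
    n_bins = int(np.floor(all_vals.max() / w + 1e-9)) + 1
    return GapHistogram(
        bin_width=w,
        counts_intra=tuple(_bin(intra, n_bins)),
        counts_inter=tuple(_bin(inter, n_bins)),
    )


@dataclass(frozen=True)
class GapResult:
    verdict: GapVerdict
    margin: float  # min(inter) - max(intra); positive iff clear gap
    max_intra: float
    min_inter: float


def gap_exists(p: DistancePartition) -> GapResult:
    """Global gap verdict: clear gap iff min(inter) > max(intra)."""
    if not p.intra or not p.inter:
        raise ValueError(
            "gap verdict needs both intra- and inter-specific distances"
        )
    max_intra = float(p.intra_values.max())
    min_inter = float(p.inter_values.min())
    margin = min_inter - max_intra
    verdict = GapVerdict.CLEAR_GAP if margin > 0 else GapVerdict.OVERLAP
    return GapResult(verdict, margin, max_intra, min_inter)
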