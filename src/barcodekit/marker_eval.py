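"""Per-marker accounting and the aggregated marker-evaluation report.

A candidate barcode is judged on two axes: how reliably it can be
amplified and sequenced across samples, and how cleanly its inter-specific
variation exceeds its intra-specific variation (barcoding gap plus
per-species monophyly in the NJ tree).  This module computes the
bookkeeping half (success rates, raw sequence length ranges) and composes
it with the gap and tree analyses into one report per marker.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

from barcodekit.barcode_gap import GapVerdict, gap_exists, partition_distances
from barcodekit.distance import pairwise_matrix
from barcodekit.nj_tree import (
    bootstrap_supports,
    monophyly_check,
    monophyly_unrooted,
    root_with_outgroup,
)
from barcodekit.seq_io import Alignment, RegionStatus, SpeciesMap


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def rate_percent(successes: int, total: int) -> int:
    """Success percentage, rounded to the nearest integer (half up)."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= successes <= total:
        raise ValueError("successes must lie in [0, total]")
    return _round_half_up(100.0 * successes / total)


def success_rates(status: RegionStatus) -> tuple[int, int]:
    """PCR and sequencing success rates (%) from a per-sample status table."""
    n = status.n_total
    return (
        rate_percent(status.n_amplified, n),
        rate_percent(status.n_sequenced, n),
    )


def length_range(lengths: Iterable[int]) -> tuple[int, int]:
    """(min, max) of raw (ungapped) sequence lengths in bp."""
    vals = list(lengths)
    if not vals:
        raise ValueError("no sequence lengths given")
    return (min(vals), max(vals))


@dataclass(frozen=True)
class MarkerReport:
    """One marker's evaluation: success accounting + gap + monophyly."""

    region: str
    n_total: int
    n_amplified: int
    n_sequenced: int
    pcr_rate: int
    seq_rate: int
    length_min: int
    length_max: int
    gap_verdict: str
    gap_margin: float
    n_species: int
    n_species_monophyletic: int
    min_clade_support: int | None

    def __post_init__(self) -> None:
        if not (
            0 <= self.n_sequenced <= self.n_amplified <= self.n_total
        ):
            raise ValueError(
                "counts must satisfy sequenced <= amplified <= total"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @staticmethod
    def tsv_header() -> str:
        return (
            "region\tlength_range\tn_total\tn_amplified\tpcr_rate\t"
            "n_sequenced\tseq_rate\tgap_verdict\tgap_margin\t"
            "monophyletic_species\tmin_clade_support"
        )

    def to_tsv_row(self) -> str:
        support = "NA" if self.min_clade_support is None else str(self.min_clade_support)
        return (
            f"{self.region}\t{self.length_min}-{self.length_max}\t"
            f"{self.n_total}\t{self.n_amplified}\t{self.pcr_rate}\t"
            f"{self.n_sequenced}\t{self.seq_rate}\t{self.gap_verdict}\t"
            f"{self.gap_margin:.6f}\t"
            f"{self.n_species_monophyletic}/{self.n_species}\t{support}"
        )


def evaluate_marker(
    aln: Alignment,
    sp: SpeciesMap,
    status: RegionStatus,
    *,
    model: str = "k2p",
    gap_mode: str = "pairwise",
    bootstrap_B: int = 1000,
    seed: int = 0,
    outgroup: str | None = None,
) -> MarkerReport:
    """Full evaluation chain for one marker region.

    Distances -> intra/inter partition -> gap verdict -> NJ + bootstrap ->
    monophyly, composed with the amplification/sequencing accounting.
    When an ``outgroup`` sample is given (present in the alignment but not
    the species map) the tree is rooted on it and monophyly is judged on
    clades; otherwise monophyly is judged on the unrooted bipartitions.
    """
    if status.n_total < 1:
        raise ValueError("empty status table")
    dm = pairwise_matrix(aln, model=model, gap_mode=gap_mode)
    ingroup = [s for s in aln.sample_ids if s != outgroup]
    part = partition_distances(
        _submatrix(dm, ingroup) if outgroup else dm, sp
    )
    gap = gap_exists(part)
    tree, boot = bootstrap_supports(aln, model=model, B=bootstrap_B, seed=seed)
    if outgroup is not None:
        rooted = root_with_outgroup(tree, outgroup)
        mono = monophyly_check(rooted, sp)
    else:
        mono = monophyly_unrooted(tree, sp)
    n_mono = sum(1 for st in mono.values() if st.monophyletic)
    supports = [
        st.support for st in mono.values() if st.support is not None
    ]
    min_support = min(supports) if supports else None
    lengths = [
        m.ungapped_length for m in aln.members if m.sample_id != outgroup
    ]
    pcr_rate, seq_rate = success_rates(status)
    return MarkerReport(
        region=aln.region,
        n_total=status.n_total,
        n_amplified=status.n_amplified,
        n_sequenced=status.n_sequenced,
        pcr_rate=pcr_rate,
        seq_rate=seq_rate,
        length_min=min(lengths),
        length_max=max(lengths),
        gap_verdict=gap.verdict.value,
        gap_margin=gap.margin,
        n_species=len(mono),
        n_species_monophyletic=n_mono,
        min_clade_support=min_support,
    )


def _submatrix(dm, labels: Sequence[str]):
    from barcodekit.distance import DistanceMatrix
    import numpy as np

    idx = [dm.labels.index(lab) for lab in labels]
    vals = np.asarray(dm.values)[np.ix_(idx, idx)]
    return DistanceMatrix(tuple(labels), vals)


def rank_markers(reports: Sequence[MarkerReport]) -> list[MarkerReport]:
    """Rank markers by sequencing success rate, then by gap margin."""
    return sorted(
        reports, key=lambda r: (r.seq_rate, r.gap_margin), reverse=True
    )
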