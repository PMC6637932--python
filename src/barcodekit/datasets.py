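"""Bundled reference tables from a published multi-locus barcoding survey
of *Lepista* (8 species, 34 vouchers, 5 candidate marker regions).

Two small TSVs ship with the package:

* ``lepista_accessions.tsv`` — per voucher and region, the GenBank
  accession obtained, or ``-`` where sequencing failed.  Sequence
  accounting (how many sequences each region yielded) derives from this
  presence/absence matrix.
* ``lepista_regions.tsv`` — per region, the raw sequence length range and
  the number of successful PCR amplifications (PCR outcomes are lab
  bookkeeping and cannot be derived from the accession list).
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from barcodekit.marker_eval import rate_percent
from barcodekit.seq_io import SpeciesMap

REGIONS = ("ITS", "IGS", "nLSU", "mtSSU", "tef1")


def _data_path(name: str):
    return files("barcodekit").joinpath("data", name)


def lepista_accession_table() -> pd.DataFrame:
    """Voucher x region accession matrix ('-' entries become NA)."""
    with _data_path("lepista_accessions.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    for r in REGIONS:
        df[r] = df[r].replace("-", pd.NA)
    return df


def lepista_species_map() -> SpeciesMap:
    df = lepista_accession_table()
    return SpeciesMap(dict(zip(df["sample_id"], df["species"])))


def lepista_region_info() -> pd.DataFrame:
    """Region length ranges and PCR success counts (indexed by region)."""
    with _data_path("lepista_regions.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df.set_index("region")


def lepista_sequenced_counts() -> dict[str, int]:
    """Sequences obtained per region, from accession presence/absence."""
    df = lepista_accession_table()
    return {r: int(df[r].notna().sum()) for r in REGIONS}


def lepista_marker_accounting() -> pd.DataFrame:
    """Per-region accounting: totals, PCR/sequencing counts and rates."""
    counts = lepista_sequenced_counts()
    info = lepista_region_info()
    rows = []
    for r in REGIONS:
        n_total = int(info.loc[r, "n_total"])
        n_pcr = int(info.loc[r, "n_pcr_success"])
        n_seq = counts[r]
        rows.append(
            {
                "region": r,
                "length_min": int(info.loc[r, "length_min"]),
                "length_max": int(info.loc[r, "length_max"]),
                "n_total": n_total,
                "n_pcr_success": n_pcr,
                "pcr_rate": rate_percent(n_pcr, n_total),
                "n_sequenced": n_seq,
                "seq_rate": rate_percent(n_seq, n_total),
            }
        )
    return pd.DataFrame(rows).set_index("region")
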