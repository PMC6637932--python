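"""Reading, validation and concatenation of aligned sequence data.

Input alignments are assumed to be pre-aligned (the usual Clustal/MAFFT
step is an external preprocessing concern); this module only checks that
the claimed alignment is well formed.  The FASTA header convention is that
the first whitespace-delimited token is the sample identifier and the rest
of the line is ignored.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
from Bio import SeqIO

PathLike = Union[str, Path]

# Nucleotides, alignment gap, and the IUPAC ambiguity codes.  Everything
# outside {A,C,G,T} is treated as missing by downstream site counting.
_CANONICAL = "ACGT"
_ALLOWED = frozenset(_CANONICAL + "-N" + "RYSWKMBDHV")

# Integer encoding used by the distance module: A,C,G,T -> 0..3, any gap or
# ambiguity code -> 4 ("missing").
_ENCODE = np.full(128, 4, dtype=np.int8)
for _i, _b in enumerate(_CANONICAL):
    _ENCODE[ord(_b)] = _i


class AlignmentError(ValueError):
    """Raised when sequence input violates an alignment invariant."""


@dataclass(frozen=True)
class AlignedSequence:
    """One row of an alignment: a sample and its uppercase residues."""

    sample_id: str
    residues: str
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise AlignmentError("sample_id must be a non-empty token")
        if not self.residues:
            raise AlignmentError(f"sequence for {self.sample_id!r} is empty")
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        for pos, ch in enumerate(residues):
            if ch not in _ALLOWED:
                raise AlignmentError(
                    f"illegal character {ch!r} at position {pos + 1} "
                    f"in sequence {self.sample_id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped_length(self) -> int:
        """Number of non-gap residues (the raw sequence length in bp)."""
        return len(self.residues) - self.residues.count("-")


@dataclass(frozen=True)
class Alignment:
    """An equal-length collection of sequences for one marker region."""

    region: str
    members: tuple[AlignedSequence, ...]

    def __init__(self, region: str, members: Iterable[AlignedSequence]) -> None:
        object.__setattr__(self, "region", region)
        object.__setattr__(self, "members", tuple(members))
        if not self.members:
            raise AlignmentError(f"alignment {region!r} has no sequences")
        length = len(self.members[0])
        bad = [m.sample_id for m in self.members if len(m) != length]
        if bad:
            raise AlignmentError(
                f"alignment {region!r} has unequal sequence lengths; "
                f"offending records: {', '.join(bad)}"
            )
        seen: set[str] = set()
        for m in self.members:
            if m.sample_id in seen:
                raise AlignmentError(f"duplicate sample_id {m.sample_id!r}")
            seen.add(m.sample_id)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def length(self) -> int:
        """Aligned length (columns)."""
        return len(self.members[0])

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(m.sample_id for m in self.members)

    def __getitem__(self, sample_id: str) -> AlignedSequence:
        for m in self.members:
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)

    def to_int_matrix(self) -> np.ndarray:
        """Encode as an (n_samples, n_columns) int8 matrix.

        A,C,G,T map to 0..3; gaps and ambiguity codes map to 4 and are
        excluded from pairwise site counts downstream.
        """
        buf = np.frombuffer(
            "".join(m.residues for m in self.members).encode("ascii"), dtype=np.uint8
        )
        return _ENCODE[buf].reshape(len(self.members), self.length)


class SpeciesMap(dict):
    """Mapping sample_id -> species name defining the intra/inter partition."""

    def __init__(self, mapping: Mapping[str, str]) -> None:
        super().__init__(mapping)
        if not self:
            raise AlignmentError("species map is empty")

    @property
    def species(self) -> tuple[str, ...]:
        """Species names in first-appearance order."""
        out: list[str] = []
        for sp in self.values():
            if sp not in out:
                out.append(sp)
        return tuple(out)

    def samples_of(self, species: str) -> tuple[str, ...]:
        return tuple(s for s, sp in self.items() if sp == species)

    def sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for sp in self.values():
            sizes[sp] = sizes.get(sp, 0) + 1
        return sizes


@dataclass(frozen=True)
class RegionStatus:
    """Per-sample amplification/sequencing flags for one marker region."""

    region: str
    amplified: Mapping[str, bool]
    sequenced: Mapping[str, bool]

    def __post_init__(self) -> None:
        if set(self.amplified) != set(self.sequenced):
            raise AlignmentError(
                f"status table for {self.region!r} lists different samples "
                "in its amplified and sequenced columns"
            )
        bad = [s for s in self.sequenced if self.sequenced[s] and not self.amplified[s]]
        if bad:
            raise AlignmentError(
                f"samples sequenced but not amplified in {self.region!r}: "
                f"{', '.join(sorted(bad))}"
            )

    @property
    def n_total(self) -> int:
        return len(self.amplified)

    @property
    def n_amplified(self) -> int:
        return sum(self.amplified.values())

    @property
    def n_sequenced(self) -> int:
        return sum(self.sequenced.values())


def read_fasta(path: PathLike, region: str | None = None) -> Alignment:
    """Read an aligned multi-FASTA file into an :class:`Alignment`.

    The first whitespace-delimited token of each header is the sample_id.
    Residues are uppercase-normalized; input order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    members = [AlignedSequence(rec.id, str(rec.seq)) for rec in records]
    return Alignment(region or path.stem, members)


def write_fasta(aln: Alignment, path: PathLike, width: int = 70) -> None:
    """Write an alignment as wrapped multi-FASTA."""
    with open(path, "w") as fh:
        for m in aln.members:
            fh.write(f">{m.sample_id}\n")
            for i in range(0, len(m.residues), width):
                fh.write(m.residues[i : i + width] + "\n")


def read_species_map(path: PathLike) -> SpeciesMap:
    """Read a two-column TSV (sample_id, species) into a :class:`SpeciesMap`.

    A header line is tolerated (detected as first row whose first field is
    ``sample_id``, case-insensitive).  Duplicate sample rows are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"species map not found: {path}")
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[1].strip():
                raise AlignmentError(
                    f"{path}:{lineno}: expected two tab-separated columns "
                    "(sample_id, species)"
                )
            sample, species = fields[0].strip(), fields[1].strip()
            if lineno == 1 and sample.lower() == "sample_id":
                continue
            if sample in mapping:
                raise AlignmentError(f"{path}:{lineno}: duplicate sample_id {sample!r}")
            mapping[sample] = species
    return SpeciesMap(mapping)


def read_region_status(path: PathLike, region: str | None = None) -> RegionStatus:
    """Read a three-column TSV (sample_id, amplified 0/1, sequenced 0/1)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"status table not found: {path}")
    amplified: dict[str, bool] = {}
    sequenced: dict[str, bool] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().lower() == "sample_id":
                continue
            if len(fields) < 3:
                raise AlignmentError(
                    f"{path}:{lineno}: expected three columns "
                    "(sample_id, amplified, sequenced)"
                )
            sample = fields[0].strip()
            try:
                amp, seq = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise AlignmentError(f"{path}:{lineno}: flags must be 0/1") from exc
            if amp not in (0, 1) or seq not in (0, 1):
                raise AlignmentError(f"{path}:{lineno}: flags must be 0/1")
            if sample in amplified:
                raise AlignmentError(f"{path}:{lineno}: duplicate sample_id {sample!r}")
            amplified[sample] = bool(amp)
            sequenced[sample] = bool(seq)
    if not amplified:
        raise AlignmentError(f"status table {path} is empty")
    return RegionStatus(region or path.stem, amplified, sequenced)


def concatenate_regions(
    alignments: Sequence[Alignment], sample_universe: Sequence[str]
) -> Alignment:
    """Concatenate per-region alignments into one supermatrix.

    Samples missing from a region contribute a full-length run of gap
    characters for that region.  A sample present in no region at all is an
    error rather than an all-gap row, because an all-gap row has undefined
    distance to everything.
    """
    if not alignments:
        raise AlignmentError("no regions to concatenate")
    pieces: dict[str, list[str]] = {s: [] for s in sample_universe}
    present: dict[str, bool] = {s: False for s in sample_universe}
    for aln in alignments:
        gap_run = "-" * aln.length
        rows = {m.sample_id: m.residues for m in aln.members}
        for s in sample_universe:
            if s in rows:
                pieces[s].append(rows[s])
                present[s] = True
            else:
                pieces[s].append(gap_run)
    orphans = [s for s in sample_universe if not present[s]]
    if orphans:
        raise AlignmentError(
            f"sample has no data in any region: {', '.join(orphans)}"
        )
    region = "+".join(a.region for a in alignments)
    members = [AlignedSequence(s, "".join(pieces[s])) for s in sample_universe]
    return Alignment(region, members)


def write_alignment_string(aln: Alignment) -> str:
    """Render an alignment as an unwrapped FASTA string (for tests/logs)."""
    out = io.StringIO()
    for m in aln.members:
        out.write(f">{m.sample_id}\n{m.residues}\n")
    return out.getvalue()
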