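"""Simulation of aligned multi-species datasets under the K2P process.

The generator emulates the structure of a small multi-locus barcoding
study: a handful of species, unequal numbers of samples per species,
aligned sequences a few hundred bp long, transition-biased substitution,
and per-sample amplification/sequencing dropout.

Model: a root sequence is drawn uniformly over {A,C,G,T}; each species
ancestor evolves from the root for ``inter_depth`` expected substitutions
per site under the K2P rate matrix (instantaneous transition rate = kappa
times each of the two transversion rates); each sample then evolves from
its species ancestor for ``intra_depth``.  The species tree is a star by
default, so the true expected distance is 2*intra_depth within species and
2*(inter_depth + intra_depth) between; an arbitrary Newick species tree
can be supplied instead.  No indels are simulated: the output is aligned
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import dendropy
import numpy as np

from barcodekit.seq_io import AlignedSequence, Alignment, RegionStatus, SpeciesMap

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# transition partner of A,C,G,T (indices 0..3): A<->G, C<->T
_TS_PARTNER = np.array([2, 3, 0, 1])

# Sample-size profile of a typical small barcoding study: 8 species with
# 1-8 vouchers each (34 samples total).
DEFAULT_SAMPLES_PER_SPECIES = (1, 3, 8, 6, 3, 6, 5, 2)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated marker-region dataset."""

    n_species: int = 8
    samples_per_species: tuple[int, ...] = DEFAULT_SAMPLES_PER_SPECIES
    seq_length: int = 600
    inter_depth: float = 0.08
    intra_depth: float = 0.005
    kappa: float = 2.0
    dropout_pcr: float = 0.0
    dropout_seq: float = 0.0
    seed: int = 0
    region: str = "sim"
    species_tree: str | None = None  # optional Newick over species names

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if len(self.samples_per_species) != self.n_species:
            raise ValueError(
                "samples_per_species must list one count per species"
            )
        if any(k < 1 for k in self.samples_per_species):
            raise ValueError("each species needs >= 1 sample")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.inter_depth < 0 or self.intra_depth < 0:
            raise ValueError("depths must be non-negative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        for p in (self.dropout_pcr, self.dropout_seq):
            if not 0.0 <= p <= 1.0:
                raise ValueError("dropout probabilities must lie in [0, 1]")

    def species_names(self) -> tuple[str, ...]:
        return tuple(f"species{c+1:02d}" for c in range(self.n_species))


@dataclass(frozen=True)
class SimResult:
    """A simulated dataset plus its ground truth.

    ``truth`` (all-pairs true expected distances) is materialized lazily,
    so very large simulated cohorts don't pay the quadratic cost unless
    the table is actually used.
    """

    alignment: Alignment
    species_map: SpeciesMap
    status: RegionStatus
    _intra_depth: float = field(repr=False)
    _inter_depth: float = field(repr=False)
    _species_depths: dict[frozenset, float] | None = field(repr=False)

    def true_distance(self, a: str, b: str) -> float:
        sa, sb = self.species_map[a], self.species_map[b]
        if sa == sb:
            if a == b:
                return 0.0
            return 2.0 * self._intra_depth
        if self._species_depths is not None:
            return (
                self._species_depths[frozenset((sa, sb))]
                + 2.0 * self._intra_depth
            )
        return 2.0 * (self._inter_depth + self._intra_depth)

    @cached_property
    def truth(self) -> dict[frozenset, float]:
        ids = self.alignment.sample_ids
        return {
            frozenset((a, b)): self.true_distance(a, b)
            for i, a in enumerate(ids)
            for b in ids[i + 1 :]
        }

    def write(self, out_dir) -> dict[str, Path]:
        """Write FASTA + species/status/truth TSVs; return the paths."""
        from barcodekit.seq_io import write_fasta

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        region = self.alignment.region
        paths = {
            "fasta": out / f"{region}.fasta",
            "species": out / f"{region}.species.tsv",
            "status": out / f"{region}.status.tsv",
            "truth": out / f"{region}.truth.tsv",
        }
        write_fasta(self.alignment, paths["fasta"])
        with open(paths["species"], "w") as fh:
            fh.write("sample_id\tspecies\n")
            for s, sp in self.species_map.items():
                fh.write(f"{s}\t{sp}\n")
        with open(paths["status"], "w") as fh:
            fh.write("sample_id\tamplified\tsequenced\n")
            for s in self.status.amplified:
                fh.write(
                    f"{s}\t{int(self.status.amplified[s])}"
                    f"\t{int(self.status.sequenced[s])}\n"
                )
        with open(paths["truth"], "w") as fh:
            fh.write("id_a\tid_b\ttrue_distance\n")
            for pair in sorted(self.truth, key=lambda p: tuple(sorted(p))):
                a, b = sorted(pair)
                fh.write(f"{a}\t{b}\t{self.truth[pair]:.6f}\n")
        return paths


def k2p_transition_matrix(depth: float, kappa: float) -> np.ndarray:
    """K2P substitution probability matrix at a given expected divergence.

    Rates are normalized so one time unit equals one expected substitution
    per site; with transition rate a = kappa*b and two transversion
    channels of rate b each, a + 2b = 1.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    b = 1.0 / (kappa + 2.0)
    a = kappa * b
    e1 = np.exp(-4.0 * b * depth)
    e2 = np.exp(-2.0 * (a + b) * depth)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 * (1.0 - e1)  # each of the two transversion targets
    M = np.full((4, 4), p_tv)
    np.fill_diagonal(M, p_same)
    for x in range(4):
        M[x, _TS_PARTNER[x]] = p_ts
    return M


def _evolve_ints(seq: np.ndarray, depth: float, kappa: float, rng) -> np.ndarray:
    if depth == 0.0:
        return seq.copy()
    M = k2p_transition_matrix(depth, kappa)
    cum = np.cumsum(M, axis=1)
    cum[:, -1] = 1.0  # guard against rounding
    u = rng.random(seq.size)
    return (u[:, None] >= cum[seq]).sum(axis=1).astype(seq.dtype)


def evolve_branch(seq: str, depth: float, kappa: float, rng) -> str:
    """Evolve a sequence along one branch of the K2P process.

    ``depth`` is the branch length in expected substitutions per site;
    ``rng`` is a ``numpy.random.Generator``.
    """
    ints = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    lut = np.full(128, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    coded = lut[ints]
    if (coded < 0).any():
        raise ValueError("evolve_branch requires a gap-free A/C/G/T sequence")
    out = _evolve_ints(coded, depth, kappa, rng)
    return _BASES[out].tobytes().decode("ascii")


def _species_depths(cfg: SimConfig) -> dict[frozenset, float] | None:
    """Pairwise path lengths between species on the optional species tree."""
    if cfg.species_tree is None:
        return None
    tree = dendropy.Tree.get(data=cfg.species_tree, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    names = {t.label for t in tree.taxon_namespace}
    expected = set(cfg.species_names())
    if names != expected:
        raise ValueError(
            f"species tree leaves {sorted(names)} do not match the "
            f"configured species {sorted(expected)}"
        )
    out: dict[frozenset, float] = {}
    for t1 in tree.taxon_namespace:
        for t2 in tree.taxon_namespace:
            if t1.label < t2.label:
                out[frozenset((t1.label, t2.label))] = pdm.patristic_distance(
                    t1, t2
                )
    return out


def simulate_dataset(cfg: SimConfig) -> SimResult:
    """Simulate one marker-region dataset; fully reproducible given seed."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.seq_length
    species = cfg.species_names()
    root = rng.integers(0, 4, size=L)

    custom_depths = _species_depths(cfg)
    if cfg.species_tree is None:
        ancestors = {
            sp: _evolve_ints(root, cfg.inter_depth, cfg.kappa, rng)
            for sp in species
        }
    else:
        # evolve along the given species tree; root sequence at its root
        tree = dendropy.Tree.get(data=cfg.species_tree, schema="newick")
        seqs = {id(tree.seed_node): root}
        ancestors = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            depth = node.edge.length or 0.0
            parent_seq = seqs[id(node.parent_node)]
            seqs[id(node)] = _evolve_ints(parent_seq, depth, cfg.kappa, rng)
            if node.is_leaf():
                ancestors[node.taxon.label] = seqs[id(node)]

    members: list[AlignedSequence] = []
    mapping: dict[str, str] = {}
    for sp, k in zip(species, cfg.samples_per_species):
        for r in range(1, k + 1):
            sid = f"{sp}_s{r}"
            seq = _evolve_ints(ancestors[sp], cfg.intra_depth, cfg.kappa, rng)
            members.append(
                AlignedSequence(sid, _BASES[seq].tobytes().decode("ascii"))
            )
            mapping[sid] = sp
    alignment = Alignment(cfg.region, members)
    species_map = SpeciesMap(mapping)

    amplified: dict[str, bool] = {}
    sequenced: dict[str, bool] = {}
    for sid in alignment.sample_ids:
        amp = bool(rng.random() >= cfg.dropout_pcr)
        seqd = amp and bool(rng.random() >= cfg.dropout_seq)
        amplified[sid] = amp
        sequenced[sid] = seqd
    status = RegionStatus(cfg.region, amplified, sequenced)
    return SimResult(
        alignment,
        species_map,
        status,
        _intra_depth=cfg.intra_depth,
        _inter_depth=cfg.inter_depth,
        _species_depths=custom_depths,
    )
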