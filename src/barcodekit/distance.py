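"""Site-pattern counting and pairwise evolutionary distances.

Distances follow the Kimura 2-parameter (K2P) model, which distinguishes
transitions (A<->G, C<->T) from transversions (all other changes among the
four bases):

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

where P and Q are the observed proportions of transition and transversion
differences among compared sites.  Sites where either sequence carries a
gap or an IUPAC ambiguity code are excluded pair-by-pair (pairwise
deletion); complete deletion (drop every column containing any gap or
ambiguity anywhere in the alignment) is available as a switch.

Saturated pairs -- those where the K2P logarithm's argument is not
positive -- have no finite distance estimate.  They are flagged as
undefined (NaN) rather than silently replaced, and a warning is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from barcodekit.seq_io import AlignedSequence, Alignment

logger = logging.getLogger(__name__)

_MODELS = ("k2p", "p", "identity")


class UndefinedComparisonError(ValueError):
    """No comparable sites between two sequences."""


class SaturationError(ValueError):
    """Observed differences exceed the K2P model's correctable range."""


@dataclass(frozen=True)
class PairCounts:
    """Transition/transversion/compared-site counts for one sequence pair."""

    transitions: int
    transversions: int
    compared_sites: int

    def __post_init__(self) -> None:
        s, v, L = self.transitions, self.transversions, self.compared_sites
        if s < 0 or v < 0 or L < 0 or s + v > L:
            raise ValueError(f"inconsistent counts: s={s}, v={v}, L={L}")

    @property
    def P(self) -> float:
        return self.transitions / self.compared_sites

    @property
    def Q(self) -> float:
        return self.transversions / self.compared_sites


def count_site_patterns(a: AlignedSequence, b: AlignedSequence) -> PairCounts:
    """Count transitions, transversions and comparable sites for a pair.

    Pairwise deletion: a site contributes only if both residues are in
    {A,C,G,T}.
    """
    if len(a) != len(b):
        raise ValueError(
            f"sequences {a.sample_id!r} ({len(a)}) and {b.sample_id!r} "
            f"({len(b)}) have different lengths"
        )
    ea = _encode_one(a)
    eb = _encode_one(b)
    valid = (ea < 4) & (eb < 4)
    L = int(valid.sum())
    if L == 0:
        raise UndefinedComparisonError(
            f"no comparable sites between {a.sample_id!r} and {b.sample_id!r}"
        )
    x, y = ea[valid], eb[valid]
    mismatch = x != y
    # purines A(0), G(2); pyrimidines C(1), T(3): transition <=> same parity
    same_type = (x % 2) == (y % 2)
    s = int((mismatch & same_type).sum())
    v = int((mismatch & ~same_type).sum())
    return PairCounts(s, v, L)


def k2p_from_counts(c: PairCounts) -> float:
    """K2P distance from pair counts; raises on saturation."""
    if c.compared_sites == 0:
        raise UndefinedComparisonError("no compared sites")
    P, Q = c.P, c.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P distance undefined for P={P:.4g}, Q={Q:.4g} "
            f"(1-2P-Q={w1:.4g}, 1-2Q={w2:.4g})"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def p_distance(c: PairCounts) -> float:
    """Uncorrected proportion of differing sites."""
    if c.compared_sites == 0:
        raise UndefinedComparisonError("no compared sites")
    return (c.transitions + c.transversions) / c.compared_sites


def percent_identity(a: AlignedSequence, b: AlignedSequence) -> float:
    """Percentage of matching residues among comparable sites."""
    c = count_site_patterns(a, b)
    return 100.0 * (1.0 - p_distance(c))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with explicit undefined entries.

    Undefined (saturated or incomparable) entries are stored as NaN; the
    diagonal is exactly zero.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if vals.shape != (n, n):
            raise ValueError(f"matrix shape {vals.shape} != ({n}, {n})")
        if not np.array_equal(vals, vals.T, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(vals) != 0.0):
            raise ValueError("diagonal must be exactly zero")
        defined = ~np.isnan(vals)
        if np.any(vals[defined] < 0):
            raise ValueError("defined distances must be non-negative")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def is_defined(self, a: str, b: str) -> bool:
        return not math.isnan(self.get(a, b))

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(len(self.labels), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def iter_pairs(self):
        """Yield (label_a, label_b, distance) over defined unordered pairs."""
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                d = self.values[i, j]
                if not math.isnan(d):
                    yield self.labels[i], self.labels[j], float(d)

    def write_square_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                row = "\t".join(
                    "NA" if math.isnan(v) else f"{v:.6f}" for v in self.values[i]
                )
                fh.write(f"{lab}\t{row}\n")

    def write_long_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id_a\tid_b\tdistance\n")
            n = len(self.labels)
            for i in range(n):
                for j in range(i + 1, n):
                    v = self.values[i, j]
                    txt = "NA" if math.isnan(v) else f"{v:.6f}"
                    fh.write(f"{self.labels[i]}\t{self.labels[j]}\t{txt}\n")


def pairwise_matrix(
    aln: Alignment, model: str = "k2p", gap_mode: str = "pairwise"
) -> DistanceMatrix:
    """Compute all pairwise distances for an alignment.

    Parameters
    ----------
    model:
        ``"k2p"`` (substitution-corrected), ``"p"`` (raw proportion of
        differences) or ``"identity"`` (percent identity, 0-100 scale).
    gap_mode:
        ``"pairwise"`` deletes gap/ambiguous sites per pair (default);
        ``"complete"`` drops every column containing any gap or ambiguity
        before all comparisons.
    """
    model = model.lower()
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {_MODELS}")
    if len(aln) < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    E = aln.to_int_matrix()
    if gap_mode == "complete":
        keep = np.all(E < 4, axis=0)
        E = E[:, keep]
        if E.shape[1] == 0:
            raise UndefinedComparisonError(
                "complete deletion removed every column"
            )
    elif gap_mode != "pairwise":
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    s, v, L = _all_pair_counts(E)
    n = len(aln)
    with np.errstate(divide="ignore", invalid="ignore"):
        if model == "k2p":
            P = s / L
            Q = v / L
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            ok = (L > 0) & (w1 > 0) & (w2 > 0)
            vals = np.where(ok, -0.5 * np.log(np.where(ok, w1 * np.sqrt(np.abs(w2)), 1.0)), np.nan)
        elif model == "p":
            vals = np.where(L > 0, (s + v) / L, np.nan)
        else:  # identity
            vals = np.where(L > 0, 100.0 * (1.0 - (s + v) / L), np.nan)
    if model == "identity":
        # stored as dissimilarity (100 - %identity) so the zero-diagonal
        # invariant holds; raw similarities available via identity_values
        diss = 100.0 - vals
        np.fill_diagonal(diss, 0.0)
        dm = DistanceMatrix(aln.sample_ids, diss)
        np.fill_diagonal(vals, 100.0)
        object.__setattr__(dm, "identity_values", vals)
        _warn_undefined(dm, aln.region)
        return dm
    np.fill_diagonal(vals, 0.0)
    vals[~np.isnan(vals) & (vals < 0)] = 0.0  # rounding noise only
    dm = DistanceMatrix(aln.sample_ids, vals)
    _warn_undefined(dm, aln.region)
    return dm


def _warn_undefined(dm: DistanceMatrix, region: str) -> None:
    k = dm.n_undefined_pairs
    if k:
        logger.warning(
            "%d pairwise distance(s) undefined (saturated or incomparable) "
            "in region %s; they are excluded from downstream summaries",
            k,
            region,
        )


def _encode_one(seq: AlignedSequence) -> np.ndarray:
    from barcodekit.seq_io import _ENCODE

    buf = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
    return _ENCODE[buf]


def _all_pair_counts(E: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized transition/transversion/compared-site counts for all pairs.

    Uses the identity: among comparable sites, transitions are mismatches
    where both bases are purines or both pyrimidines, so
    ts = (#both-purine) + (#both-pyrimidine) - (#match) and
    tv = L - (#both-purine) - (#both-pyrimidine).
    """
    valid = (E < 4).astype(np.float64)
    L = valid @ valid.T
    pu = (((E == 0) | (E == 2))).astype(np.float64)
    py = (((E == 1) | (E == 3))).astype(np.float64)
    same_type = pu @ pu.T + py @ py.T
    match = np.zeros_like(L)
    for b in range(4):
        Bb = (E == b).astype(np.float64)
        match += Bb @ Bb.T
    s = same_type - match
    v = L - same_type
    return s, v, L


def pair_site_classes(E: np.ndarray):
    """Per-pair, per-column site classifications for fast bootstrapping.

    Returns (pairs, TS, TV, VALID) where ``pairs`` lists the (i, j) index
    pairs (i < j) and the three (n_pairs, n_columns) float arrays mark, for
    each pair and column, whether that column is a transition difference, a
    transversion difference, or comparable at all.  A bootstrap replicate's
    counts are then single matrix products with the column-weight vector.
    """
    n, _ = E.shape
    idx = [(i, j) for i in range(n) for j in range(i + 1, n)]
    I = np.array([p[0] for p in idx])
    J = np.array([p[1] for p in idx])
    A = E[I]
    B = E[J]
    valid = (A < 4) & (B < 4)
    mismatch = valid & (A != B)
    same_type = (A % 2) == (B % 2)
    TS = (mismatch & same_type).astype(np.float64)
    TV = (mismatch & ~same_type).astype(np.float64)
    return idx, TS, TV, valid.astype(np.float64)
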