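"""Neighbor-joining trees, Newick I/O, bootstrap supports and monophyly.

The neighbor-joining (NJ) agglomeration follows Saitou & Nei with the
Studier-Keppler Q criterion, which recovers any additive distance matrix's
topology and branch lengths exactly.  Ties in Q are broken by joining the
pair whose (sorted) cluster keys -- the lexicographically smallest leaf
label in each cluster -- compare smallest, so output is deterministic
across platforms and input orderings.

Bootstrap supports use Felsenstein column resampling: alignment columns
are drawn with replacement (replicate length = original length), an NJ
tree is built per replicate, and each internal bipartition of the
reference tree is scored by the percentage of replicate trees containing
it.  Internally replicates run on a weighted-column fast path: resampling
columns with replacement is equivalent to giving each original column a
multinomial weight, so per-replicate transition/transversion counts are
single matrix products.

Trees are dendropy ``Tree`` objects throughout, so all dendropy facilities
(printing, traversal, comparison) apply directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from barcodekit.distance import DistanceMatrix, pair_site_classes
from barcodekit.seq_io import Alignment, SpeciesMap


class TreeError(ValueError):
    """Raised for invalid tree-building inputs."""


# ---------------------------------------------------------------------------
# core agglomeration
# ---------------------------------------------------------------------------

def _nj_agglomerate(D: np.ndarray, labels: list[str]):
    """Run NJ joins on a matrix; return join events and the final 3-way hub.

    Events are ``(id_i, id_j, len_i, len_j, new_id, new_mask)`` where ids
    are cluster identifiers (leaves are 0..n-1 in input order, new clusters
    n, n+1, ...) and masks are bitmasks over leaf indices.  The final entry
    is ``(ids, lengths)`` for the 3 clusters meeting at the unrooted hub.
    """
    n = len(labels)
    if n < 3:
        raise TreeError("neighbor-joining needs at least 3 taxa")
    D = np.array(D, dtype=float)
    ids = list(range(n))
    keys = list(labels)
    masks = [1 << i for i in range(n)]
    events = []
    next_id = n
    while len(ids) > 3:
        m = len(ids)
        R = D.sum(axis=1)
        # R_i + R_j grouped first so Q is exactly symmetric in floating point
        Q = (m - 2) * D - (R[:, None] + R[None, :])
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for i, j in np.argwhere(Q == qmin):
            if i >= j:
                continue
            kp = (keys[i], keys[j]) if keys[i] < keys[j] else (keys[j], keys[i])
            if best is None or kp < best[0]:
                best = (kp, int(i), int(j))
        _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (R[i] - R[j]) / (2.0 * (m - 2))
        lj = dij - li
        newrow = 0.5 * (D[i] + D[j] - dij)
        mask = masks[i] | masks[j]
        events.append((ids[i], ids[j], li, lj, next_id, mask))
        D[i, :] = newrow
        D[:, i] = newrow
        D[i, i] = 0.0
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        ids[i] = next_id
        keys[i] = min(keys[i], keys[j])
        masks[i] = mask
        del ids[j], keys[j], masks[j]
        next_id += 1
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = (
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    )
    return events, (tuple(ids), lengths)


def nj_build(m: DistanceMatrix) -> dendropy.Tree:
    """Build the unrooted NJ tree for a fully defined distance matrix.

    Negative branch lengths (possible on non-additive input) are retained;
    see :func:`to_newick` for optional clamping at output time.
    """
    if m.n_undefined_pairs:
        bad = sorted(
            {
                lab
                for i, lab in enumerate(m.labels)
                for j in range(len(m.labels))
                if i != j and math.isnan(m.values[i, j])
            }
        )
        raise TreeError(
            "distance matrix has undefined entries; drop the affected "
            f"samples first: {', '.join(bad)}"
        )
    labels = list(m.labels)
    events, (hub_ids, hub_lengths) = _nj_agglomerate(m.values, labels)
    tns = dendropy.TaxonNamespace(labels)
    nodes: dict[int, dendropy.Node] = {}
    for i, lab in enumerate(labels):
        leaf = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes[i] = leaf
    for id_i, id_j, li, lj, new_id, _mask in events:
        parent = dendropy.Node()
        parent.add_child(nodes[id_i])
        nodes[id_i].edge.length = float(li)
        parent.add_child(nodes[id_j])
        nodes[id_j].edge.length = float(lj)
        nodes[new_id] = parent
    hub = dendropy.Node()
    for cid, ln in zip(hub_ids, hub_lengths):
        hub.add_child(nodes[cid])
        nodes[cid].edge.length = float(ln)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = hub
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def to_newick(t: dendropy.Tree, clamp_negative: bool = False) -> str:
    """Serialize a tree to Newick (branch lengths to 6 decimals).

    Bootstrap supports, when present as internal node labels, are carried
    along.  ``clamp_negative=True`` writes negative branch lengths as 0.
    """
    if clamp_negative:
        t = t.clone(depth=1)
        for edge in t.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                edge.length = 0.0
    return t.as_string(
        schema="newick",
        real_value_format_specifier=".6f",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def from_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; internal node labels are kept (supports)."""
    try:
        return dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed Newick: {exc}") from exc


# ---------------------------------------------------------------------------
# rooting & bipartitions
# ---------------------------------------------------------------------------

def root_with_outgroup(t: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root a tree on the edge subtending the named outgroup leaf.

    The outgroup's terminal branch is split evenly across the new root.
    The input tree is not modified.
    """
    t2 = t.clone(depth=1)
    node = t2.find_node_with_taxon_label(outgroup)
    if node is None or not node.is_leaf():
        raise TreeError(f"outgroup {outgroup!r} is not a leaf of the tree")
    edge = node.edge
    if edge.length is not None:
        half = edge.length / 2.0
        t2.reroot_at_edge(edge, length1=half, length2=half)
    else:
        t2.reroot_at_edge(edge)
    t2.is_rooted = True
    return t2


def leaf_labels(t: dendropy.Tree) -> tuple[str, ...]:
    return tuple(lf.taxon.label for lf in t.leaf_node_iter())


def bipartitions(t: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical leaf-label sets.

    Each internal edge splits the leaves in two; the side containing the
    lexicographically smallest leaf label is the canonical representative.
    """
    all_leaves = frozenset(leaf_labels(t))
    anchor = min(all_leaves)
    out: set[frozenset[str]] = set()
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) < 2 or len(below) > len(all_leaves) - 2:
            continue
        side = below if anchor in below else all_leaves - below
        out.add(side)
    return out


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapResult:
    """Supports for the reference tree's internal bipartitions."""

    n_replicates: int
    seed: int
    supports: dict[frozenset[str], int]  # canonical side -> integer %
    n_dropped: int = 0

    def min_support(self) -> int:
        return min(self.supports.values()) if self.supports else 0


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def bootstrap_supports(
    aln: Alignment,
    model: str = "k2p",
    B: int = 1000,
    seed: int = 0,
    max_dropped_frac: float = 0.10,
) -> tuple[dendropy.Tree, BootstrapResult]:
    """Reference NJ tree plus bootstrap supports from B column resamples.

    Replicates whose distance matrix contains an undefined (saturated or
    incomparable) entry are dropped and counted; more than 10% dropped is
    an error.  Supports are attached to the reference tree's internal
    nodes as integer-percentage labels.  Fully reproducible given ``seed``.
    """
    from barcodekit.distance import pairwise_matrix

    if B < 1:
        raise ValueError("B must be >= 1")
    if model.lower() not in ("k2p", "p"):
        raise ValueError("bootstrap supports support model 'k2p' or 'p'")
    ref_dm = pairwise_matrix(aln, model=model)
    ref_tree = nj_build(ref_dm)
    labels = list(aln.sample_ids)
    n = len(labels)
    ref_bips = bipartitions(ref_tree)

    E = aln.to_int_matrix()
    L_cols = E.shape[1]
    idx, TS, TV, VALID = pair_site_classes(E)
    rng = np.random.default_rng(seed)
    # column weights for all replicates at once: (L_cols, B)
    W = rng.multinomial(L_cols, np.full(L_cols, 1.0 / L_cols), size=B).T.astype(
        np.float64
    )
    S = TS @ W  # (n_pairs, B)
    V = TV @ W
    Lc = VALID @ W
    iu = np.triu_indices(n, k=1)
    # mask-level bookkeeping: canonical mask contains the smallest label
    anchor_bit = 1 << labels.index(min(labels))
    full = (1 << n) - 1

    def _canon(mask: int) -> int:
        return mask if mask & anchor_bit else full ^ mask

    bit_of = {lab: 1 << i for i, lab in enumerate(labels)}
    ref_masks = {
        _canon(sum(bit_of[lab] for lab in bip)): bip for bip in ref_bips
    }
    mask_counts = {m_: 0 for m_ in ref_masks}
    n_dropped = 0
    use_k2p = model.lower() == "k2p"
    for b in range(B):
        s, v, Lb = S[:, b], V[:, b], Lc[:, b]
        with np.errstate(divide="ignore", invalid="ignore"):
            if use_k2p:
                P = s / Lb
                Q = v / Lb
                w1 = 1.0 - 2.0 * P - Q
                w2 = 1.0 - 2.0 * Q
                ok = (Lb > 0) & (w1 > 0) & (w2 > 0)
                if not ok.all():
                    n_dropped += 1
                    continue
                d = -0.5 * np.log(w1 * np.sqrt(w2))
            else:
                if not (Lb > 0).all():
                    n_dropped += 1
                    continue
                d = (s + v) / Lb
        D = np.zeros((n, n))
        D[iu] = d
        D += D.T
        events, _hub = _nj_agglomerate(D, labels)
        rep_masks = set()
        for e in events:
            mask = e[5]
            pop = mask.bit_count()
            if 2 <= pop <= n - 2:
                rep_masks.add(_canon(mask))
        for m_ in mask_counts:
            if m_ in rep_masks:
                mask_counts[m_] += 1
    n_valid = B - n_dropped
    if n_dropped > max_dropped_frac * B or n_valid == 0:
        raise TreeError(
            f"{n_dropped}/{B} bootstrap replicates had undefined distances"
        )
    supports = {
        ref_masks[m_]: _round_half_up(100.0 * c / n_valid)
        for m_, c in mask_counts.items()
    }
    _annotate_supports(ref_tree, supports)
    return ref_tree, BootstrapResult(B, seed, supports, n_dropped)


def _annotate_supports(t: dendropy.Tree, supports: dict[frozenset[str], int]) -> None:
    all_leaves = frozenset(leaf_labels(t))
    anchor = min(all_leaves)
    for node in t.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) < 2 or len(below) > len(all_leaves) - 2:
            continue
        side = below if anchor in below else all_leaves - below
        if side in supports:
            node.label = str(supports[side])


# ---------------------------------------------------------------------------
# monophyly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonophylyStatus:
    species: str
    monophyletic: bool
    support: int | None  # bootstrap % of the clade's edge, if annotated
    n_samples: int


def monophyly_check(
    t: dendropy.Tree, sp: SpeciesMap
) -> dict[str, MonophylyStatus]:
    """Check, per species, whether its samples form an exclusive clade.

    Expects a rooted tree whose species-map samples are leaves (an
    outgroup leaf not in the species map is ignored).  Singleton species
    are monophyletic by convention with support n/a.
    """
    leaves = set(leaf_labels(t))
    clades: dict[frozenset[str], str | None] = {}
    for node in t.preorder_node_iter():
        if node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        clades.setdefault(below, node.label)
    out: dict[str, MonophylyStatus] = {}
    for species in sp.species:
        samples = frozenset(s for s in sp.samples_of(species))
        missing = samples - leaves
        if missing or not samples:
            raise TreeError(
                f"species {species!r} has samples absent from the tree: "
                f"{', '.join(sorted(missing)) or '(none in tree)'}"
            )
        if len(samples) == 1:
            out[species] = MonophylyStatus(species, True, None, 1)
            continue
        if samples in clades:
            label = clades[samples]
            support = None
            if label is not None:
                try:
                    support = _round_half_up(float(label))
                except ValueError:
                    support = None
            out[species] = MonophylyStatus(species, True, support, len(samples))
        else:
            out[species] = MonophylyStatus(species, False, None, len(samples))
    return out


def monophyly_unrooted(
    t: dendropy.Tree, sp: SpeciesMap
) -> dict[str, MonophylyStatus]:
    """Monophyly on an unrooted tree: a species is monophyletic when some
    edge separates exactly its samples from everything else."""
    leaves = set(leaf_labels(t))
    sides: dict[frozenset[str], str | None] = {}
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        label = None if node.is_leaf() else node.label
        for side in (below, frozenset(leaves) - below):
            if side not in sides or sides[side] is None:
                sides[side] = label
    out: dict[str, MonophylyStatus] = {}
    for species in sp.species:
        samples = frozenset(sp.samples_of(species))
        missing = samples - leaves
        if missing or not samples:
            raise TreeError(
                f"species {species!r} has samples absent from the tree: "
                f"{', '.join(sorted(missing)) or '(none in tree)'}"
            )
        if len(samples) == 1:
            out[species] = MonophylyStatus(species, True, None, 1)
        elif samples in sides:
            support = None
            label = sides[samples]
            if label is not None:
                try:
                    support = _round_half_up(float(label))
                except ValueError:
                    support = None
            out[species] = MonophylyStatus(species, True, support, len(samples))
        else:
            out[species] = MonophylyStatus(species, False, None, len(samples))
    return out
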