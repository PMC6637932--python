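import numpy as np
import pytest

from barcodekit import SimConfig, simulate_dataset
from barcodekit.seq_io import AlignedSequence, Alignment, SpeciesMap


@pytest.fixture(scope="session")
def default_sim():
    """One simulated 8-species, 34-sample, 600 bp marker dataset."""
    return simulate_dataset(SimConfig(seed=7))


@pytest.fixture()
def toy_alignment():
    """Two 3-sample species, strongly divergent between species."""
    seqs = {
        "a1": "ACGTACGTACGTACGTACGT",
        "a2": "ACGTACGTACGTACGTACGA",
        "a3": "ACGTACGTACGTACGTACGT",
        "b1": "GTCAGTCAGTCAACGTACGT",
        "b2": "GTCAGTCAGTCAACGTACGA",
        "b3": "GTCAGTCAGTCAACGTACGT",
    }
    aln = Alignment("toy", [AlignedSequence(k, v) for k, v in seqs.items()])
    sp = SpeciesMap({k: ("A" if k.startswith("a") else "B") for k in seqs})
    return aln, sp


def random_additive_tree_matrix(rng, n):
    """Random additive distance matrix plus its generating bipartitions.

    Builds a random unrooted binary tree with positive branch lengths and
    returns (labels, D, bipartition set) where D holds exact path lengths.
    """
    import itertools

    labels = [f"t{i}" for i in range(n)]
    # random topology by sequential leaf attachment
    # edges: dict edge_id -> (node_a, node_b, length)
    next_node = n
    edges = {}
    eid = 0

    def add_edge(a, b, ln):
        nonlocal eid
        edges[eid] = [a, b, ln]
        eid += 1

    lengths = lambda: float(rng.uniform(0.05, 1.0))
    add_edge(0, 1, lengths())
    for leaf in range(2, n):
        keys_ = sorted(edges)
        target = keys_[int(rng.integers(0, len(keys_)))]
        a, b, ln = edges.pop(target)
        mid = next_node
        next_node += 1
        cut = float(rng.uniform(0.2, 0.8)) * ln
        add_edge(a, mid, cut)
        add_edge(mid, b, ln - cut)
        add_edge(mid, leaf, lengths())

    # adjacency for path lengths
    adj = {}
    for a, b, ln in edges.values():
        adj.setdefault(a, []).append((b, ln))
        adj.setdefault(b, []).append((a, ln))

    def path_len(src, dst):
        stack = [(src, -1, 0.0)]
        while stack:
            node, prev, acc = stack.pop()
            if node == dst:
                return acc
            for nxt, ln in adj[node]:
                if nxt != prev:
                    stack.append((nxt, node, acc + ln))
        raise AssertionError("disconnected")

    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = path_len(i, j)

    # bipartitions: split leaves by removing each internal edge
    def side_of(start, banned_a, banned_b):
        seen = set()
        stack = [start]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            for nxt, _ in adj[node]:
                if {node, nxt} == {banned_a, banned_b}:
                    continue
                stack.append(nxt)
        return frozenset(labels[k] for k in seen if k < n)

    bips = set()
    all_set = frozenset(labels)
    anchor = min(labels)
    for a, b, _ in edges.values():
        side = side_of(a, a, b)
        if 2 <= len(side) <= n - 2:
            bips.add(side if anchor in side else all_set - side)
    return labels, D, bips
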