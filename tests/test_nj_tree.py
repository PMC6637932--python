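import numpy as np
import pytest

from barcodekit.distance import DistanceMatrix, pairwise_matrix
from barcodekit.nj_tree import (
    TreeError,
    bipartitions,
    bootstrap_supports,
    from_newick,
    leaf_labels,
    monophyly_check,
    monophyly_unrooted,
    nj_build,
    root_with_outgroup,
    to_newick,
)
from barcodekit.seq_io import AlignedSequence, Alignment, SpeciesMap
from barcodekit.synthetic_data import SimConfig, simulate_dataset

from conftest import random_additive_tree_matrix


def _edge_lengths(tree):
    """Map canonical bipartition/leaf -> branch length."""
    out = {}
    labs = frozenset(leaf_labels(tree))
    anchor = min(labs)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = below if len(below) > 1 else next(iter(below))
        if isinstance(key, frozenset):
            key = key if anchor in key else labs - key
        out[key] = node.edge.length
    return out


class TestNJExactness:
    def test_worked_four_taxon_example(self):
        """NJ must recover the additive 4-taxon matrix exactly:
        topology {A,B}|{C,D}, lengths A:1 B:2 internal:1 C:3 D:4."""
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        t = nj_build(DistanceMatrix(("A", "B", "C", "D"), D))
        assert bipartitions(t) == {frozenset({"A", "B"})}
        el = _edge_lengths(t)
        assert el["A"] == pytest.approx(1.0)
        assert el["B"] == pytest.approx(2.0)
        assert el["C"] == pytest.approx(3.0)
        assert el["D"] == pytest.approx(4.0)
        assert el[frozenset({"A", "B"})] == pytest.approx(1.0)

    def test_three_taxon_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        t = nj_build(DistanceMatrix(("A", "B", "C"), D))
        el = _edge_lengths(t)
        assert el["A"] == pytest.approx(1.0)
        assert el["B"] == pytest.approx(2.0)
        assert el["C"] == pytest.approx(3.0)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_recovers_random_additive_matrices(self, n):
        """Four-point oracle: topology AND lengths of random additive
        matrices are recovered exactly (path metric of a random tree)."""
        rng = np.random.default_rng(100 + n)
        for rep in range(5):
            labels, D, true_bips = random_additive_tree_matrix(rng, n)
            t = nj_build(DistanceMatrix(tuple(labels), D))
            assert bipartitions(t) == true_bips
            # additivity: path lengths in the NJ tree reproduce D
            pdm = t.phylogenetic_distance_matrix()
            tax = {x.label: x for x in t.taxon_namespace}
            for i in range(n):
                for j in range(i + 1, n):
                    got = pdm.patristic_distance(
                        tax[labels[i]], tax[labels[j]]
                    )
                    assert got == pytest.approx(D[i, j], abs=1e-9)

    def test_matches_skbio_on_additive_matrix(self):
        """Independent implementation cross-check (scikit-bio nj)."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(42)
        labels, D, _ = random_additive_tree_matrix(rng, 7)
        mine = nj_build(DistanceMatrix(tuple(labels), D))
        theirs = skbio_nj(SkbioDM(D, ids=labels))
        their_bips = set()
        all_set = frozenset(labels)
        anchor = min(labels)
        for node in theirs.non_tips(include_self=False):
            below = frozenset(t.name for t in node.tips())
            if 2 <= len(below) <= len(labels) - 2:
                their_bips.add(below if anchor in below else all_set - below)
        assert bipartitions(mine) == their_bips

    def test_undefined_entries_rejected(self):
        D = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(TreeError, match="drop"):
            nj_build(DistanceMatrix(("a", "b", "c"), D))

    def test_order_invariance(self, default_sim):
        """Permuting input order permutes labels, not the topology."""
        dm = pairwise_matrix(default_sim.alignment)
        t1 = nj_build(dm)
        perm = np.random.default_rng(0).permutation(len(dm.labels))
        labels2 = tuple(dm.labels[i] for i in perm)
        vals2 = dm.values[np.ix_(perm, perm)]
        t2 = nj_build(DistanceMatrix(labels2, vals2))
        assert bipartitions(t1) == bipartitions(t2)

    def test_eight_cluster_matrix_yields_clades(self):
        sim = simulate_dataset(SimConfig(seed=3))
        dm = pairwise_matrix(sim.alignment)
        t = nj_build(dm)
        mono = monophyly_unrooted(t, sim.species_map)
        assert all(st.monophyletic for st in mono.values())


class TestNewick:
    def test_three_leaf_shape(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        t = nj_build(DistanceMatrix(("A", "B", "C"), D))
        nwk = to_newick(t)
        assert nwk.startswith("(") and nwk.endswith(";")
        assert "A:1.000000" in nwk and "C:3.000000" in nwk

    def test_round_trip_on_random_tree(self, default_sim):
        t = nj_build(pairwise_matrix(default_sim.alignment))
        back = from_newick(to_newick(t))
        assert bipartitions(back) == bipartitions(t)
        assert sorted(leaf_labels(back)) == sorted(leaf_labels(t))

    def test_supports_round_trip(self, default_sim):
        aln = Alignment("r", default_sim.alignment.members[:8])
        t, _ = bootstrap_supports(aln, B=20, seed=1)
        back = from_newick(to_newick(t))
        orig = {n.label for n in t.preorder_node_iter() if n.label}
        parsed = {n.label for n in back.preorder_node_iter() if n.label}
        assert orig and orig == parsed

    def test_malformed_newick(self):
        with pytest.raises(TreeError, match="malformed"):
            from_newick("((A:1,B:2;")

    def test_clamp_negative(self):
        t = from_newick("((A:1.0,B:-0.5):0.2,C:1.0);")
        assert ":-0.5" not in to_newick(t, clamp_negative=True)
        assert ":-0.500000" in to_newick(t)


class TestRooting:
    def _four_taxon(self):
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        return nj_build(DistanceMatrix(("A", "B", "C", "D"), D))

    def test_outgroup_sister_to_rest(self):
        t = root_with_outgroup(self._four_taxon(), "D")
        root_children = t.seed_node.child_nodes()
        assert len(root_children) == 2
        sides = [
            frozenset(lf.taxon.label for lf in c.leaf_iter())
            for c in root_children
        ]
        assert frozenset({"D"}) in sides
        assert frozenset({"A", "B", "C"}) in sides

    def test_rooting_preserves_bipartitions(self):
        t = self._four_taxon()
        rooted = root_with_outgroup(t, "C")
        assert bipartitions(rooted) == bipartitions(t)

    def test_unknown_outgroup(self):
        with pytest.raises(TreeError, match="ghost"):
            root_with_outgroup(self._four_taxon(), "ghost")

    def test_input_tree_unmodified(self):
        t = self._four_taxon()
        before = to_newick(t)
        root_with_outgroup(t, "A")
        assert to_newick(t) == before


class TestBootstrap:
    def _two_cluster_alignment(self, n_per=4, L=1000, frac=0.5):
        rng = np.random.default_rng(5)
        base = rng.integers(0, 4, L)
        other = base.copy()
        flip = rng.choice(L, int(L * frac), replace=False)
        other[flip] = (other[flip] + rng.integers(1, 4, flip.size)) % 4
        BASES = "ACGT"
        members = []
        for k in range(n_per):
            for name, seq in (("x", base), ("y", other)):
                s = seq.copy()
                # sprinkle a few private mutations so leaves differ
                pos = rng.choice(L, 3, replace=False)
                s[pos] = (s[pos] + 1) % 4
                members.append(
                    AlignedSequence(
                        f"{name}{k}", "".join(BASES[v] for v in s)
                    )
                )
        return Alignment("r", members)

    def test_determinism_given_seed(self, default_sim):
        aln = Alignment("r", default_sim.alignment.members[:10])
        _, b1 = bootstrap_supports(aln, B=50, seed=42)
        _, b2 = bootstrap_supports(aln, B=50, seed=42)
        assert b1.supports == b2.supports

    def test_different_seeds_differ_somewhere(self, default_sim):
        aln = Alignment("r", default_sim.alignment.members[:10])
        _, b1 = bootstrap_supports(aln, B=50, seed=1)
        _, b2 = bootstrap_supports(aln, B=50, seed=2)
        # same bipartition keys; values may (and generically do) differ
        assert set(b1.supports) == set(b2.supports)

    def test_central_split_high_support(self):
        """Two 4-sample clusters differing at 50% of 1,000 sites must give
        the central bipartition support >= 99 with B=200."""
        aln = self._two_cluster_alignment()
        t, boot = bootstrap_supports(aln, B=200, seed=9)
        central = frozenset(
            lab for lab in aln.sample_ids if lab.startswith("x")
        )
        labs = frozenset(aln.sample_ids)
        anchor = min(labs)
        key = central if anchor in central else labs - central
        assert boot.supports[key] >= 99

    def test_single_replicate_supports_binary(self, default_sim):
        aln = Alignment("r", default_sim.alignment.members[:8])
        _, boot = bootstrap_supports(aln, B=1, seed=0)
        assert set(boot.supports.values()) <= {0, 100}

    def test_supports_bounded_and_complete(self, default_sim):
        aln = Alignment("r", default_sim.alignment.members[:12])
        t, boot = bootstrap_supports(aln, B=60, seed=4)
        n = 12
        assert len(boot.supports) == len(bipartitions(t)) <= n - 3
        assert all(0 <= v <= 100 for v in boot.supports.values())

    def test_signal_free_alignment_low_support(self):
        """All-identical columns carry no signal: replicates can't prefer
        any split, supports stay bounded and reproducible."""
        members = [
            AlignedSequence(f"s{i}", "ACGTACGTAC") for i in range(6)
        ]
        aln = Alignment("r", members)
        _, b1 = bootstrap_supports(aln, B=30, seed=3)
        _, b2 = bootstrap_supports(aln, B=30, seed=3)
        assert b1.supports == b2.supports
        assert all(v <= 100 for v in b1.supports.values())


class TestMonophyly:
    def test_clean_pairs(self):
        t = from_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        t.is_rooted = True
        sp = SpeciesMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        mono = monophyly_check(t, sp)
        assert all(m.monophyletic for m in mono.values())

    def test_interleaved_not_monophyletic(self):
        t = from_newick("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        t.is_rooted = True
        sp = SpeciesMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        mono = monophyly_check(t, sp)
        assert not any(
            m.monophyletic for m in mono.values() if m.n_samples > 1
        )

    def test_singleton_by_convention(self):
        t = from_newick("((a1:1,a2:1):1,c1:2);")
        t.is_rooted = True
        sp = SpeciesMap({"a1": "A", "a2": "A", "c1": "C"})
        mono = monophyly_check(t, sp)
        assert mono["C"].monophyletic and mono["C"].support is None

    def test_absent_species_errors(self):
        t = from_newick("((a1:1,a2:1):1,c1:2);")
        sp = SpeciesMap({"a1": "A", "ghost": "G"})
        with pytest.raises(TreeError, match="G"):
            monophyly_check(t, sp)

    def test_eight_species_simulation_all_monophyletic(self):
        """Well-separated species must land as 8/8 exclusive clades."""
        sim = simulate_dataset(SimConfig(seed=21))
        dm = pairwise_matrix(sim.alignment)
        t = nj_build(dm)
        # root on a leaf of the largest species' sister: use unrooted check
        mono = monophyly_unrooted(t, sim.species_map)
        assert sum(m.monophyletic for m in mono.values()) == 8
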