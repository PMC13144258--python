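import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from herbiscan.phenotypes import ResistanceCall
from herbiscan.phylo import (
    DistanceMatrix,
    SSRProfile,
    TreeNode,
    annotate_tree,
    distance_matrix,
    dps_distance,
    neighbor_joining,
    read_ssr_table,
    tip_bipartitions,
    tree_path_distances,
    write_phylip,
)


def profile(gid, **loci):
    return SSRProfile(gid, {k: tuple(v) for k, v in loci.items()})


class TestDps:
    def test_hand_computed_per_locus(self):
        # locus L1 shares 1 of 2 alleles, locus L2 shares 0 of 2
        a = profile("a", L1=("100", "102"), L2=("200", "204"))
        b = profile("b", L1=("100", "104"), L2=("206", "208"))
        assert dps_distance(a, b) == pytest.approx(1 - (0.5 + 0.0) / 2)

    def test_pooled_mode_weights_by_alleles(self):
        # homozygous vs heterozygous locus: per-locus averages shares,
        # pooled divides total shared (1+0) by total comparable (2+2)
        a = profile("a", L1=("100", "100"), L2=("200", "204"))
        b = profile("b", L1=("100", "102"), L2=("206", "208"))
        assert dps_distance(a, b, mode="pooled") == pytest.approx(1 - 1 / 4)

    def test_identity_is_zero_and_disjoint_is_one(self):
        a = profile("a", L1=("1", "2"), L2=("3", "3"))
        twin = profile("b", L1=("1", "2"), L2=("3", "3"))
        other = profile("c", L1=("8", "9"), L2=("7", "7"))
        assert dps_distance(a, twin) == 0.0
        assert dps_distance(a, other) == 1.0

    def test_multiset_intersection_counts_copies(self):
        # AA vs AB share exactly one copy of A, not two
        a = profile("a", L1=("A", "A"))
        b = profile("b", L1=("A", "B"))
        assert dps_distance(a, b) == pytest.approx(0.5)

    def test_missing_locus_skipped(self):
        a = profile("a", L1=("1", "2"), L2=("3", "4"))
        b = profile("b", L1=("1", "2"))
        assert dps_distance(a, b) == 0.0

    def test_no_common_locus_raises(self):
        with pytest.raises(ValueError, match="share no scored locus"):
            dps_distance(profile("a", L1=("1",)), profile("b", L2=("1",)))

    def test_profile_validation(self):
        with pytest.raises(ValueError, match="no allele"):
            SSRProfile("g", {"L1": ()})
        with pytest.raises(ValueError, match="more than 2"):
            SSRProfile("g", {"L1": ("1", "2", "3")})

    def test_unknown_mode_rejected(self):
        a = profile("a", L1=("1",))
        with pytest.raises(ValueError, match="mode"):
            dps_distance(a, a, mode="median")

    @given(data=st.data())
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_axioms_on_random_profiles(self, data):
        """Dps is in [0, 1], symmetric, and zero on identical profiles."""
        alleles = st.sampled_from([str(s) for s in range(95, 120)])
        locus = st.tuples(alleles, alleles)
        n_loci = data.draw(st.integers(1, 6))
        names = [f"L{k}" for k in range(n_loci)]
        pa = profile("a", **{n: data.draw(locus) for n in names})
        pb = profile("b", **{n: data.draw(locus) for n in names})
        for mode in ("per_locus", "pooled"):
            d = dps_distance(pa, pb, mode)
            assert 0.0 <= d <= 1.0
            assert dps_distance(pb, pa, mode) == pytest.approx(d)
            assert dps_distance(pa, pa, mode) == 0.0


class TestDistanceMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], [[0, 1], [2, 0]])
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], [[1, 2], [2, 0]])
        with pytest.raises(ValueError, match="non-negative"):
            DistanceMatrix(["a", "b"], [[0, -1], [-1, 0]])
        with pytest.raises(ValueError, match="shape"):
            DistanceMatrix(["a"], [[0, 1], [1, 0]])

    def test_lookup_by_label(self):
        D = DistanceMatrix(["a", "b"], [[0, 0.3], [0.3, 0]])
        assert D["a", "b"] == pytest.approx(0.3)

    def test_from_profiles(self):
        ps = [
            profile("a", L1=("1", "2")),
            profile("b", L1=("1", "2")),
            profile("c", L1=("3", "4")),
        ]
        D = distance_matrix(ps)
        assert D["a", "b"] == 0.0
        assert D["a", "c"] == 1.0


def path_distance_error(D, tree):
    back = tree_path_distances(tree)
    assert back.labels == sorted(D.labels)
    order = [D.labels.index(lab) for lab in back.labels]
    return np.max(np.abs(back.values - D.values[np.ix_(order, order)]))


def random_additive_matrix(rng, n):
    """Path distances of a random binary tree with positive branch lengths."""
    nodes = [TreeNode(name=f"t{k}") for k in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(children=[
            (a, float(rng.uniform(0.05, 1.0))),
            (b, float(rng.uniform(0.05, 1.0))),
        ]))
    return tree_path_distances(nodes[0])


class TestNeighborJoining:
    def test_two_taxa_split_evenly(self):
        D = DistanceMatrix(["a", "b"], [[0, 0.4], [0.4, 0]])
        tree = neighbor_joining(D)
        lengths = sorted(l for _, l in tree.children)
        assert lengths == pytest.approx([0.2, 0.2])
        assert path_distance_error(D, tree) < 1e-12

    def test_three_taxa_closed_form(self):
        # v_i = (d(i,j) + d(i,k) - d(j,k)) / 2
        d_ab, d_ac, d_bc = 0.3, 0.5, 0.6
        D = DistanceMatrix(["a", "b", "c"],
                           [[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]])
        tree = neighbor_joining(D)
        expected = {
            "a": (d_ab + d_ac - d_bc) / 2,
            "b": (d_ab + d_bc - d_ac) / 2,
            "c": (d_ac + d_bc - d_ab) / 2,
        }
        back = tree_path_distances(tree)
        assert back["a", "b"] == pytest.approx(expected["a"] + expected["b"])
        assert path_distance_error(D, tree) < 1e-9

    def test_four_taxa_additive_topology_and_lengths(self):
        # ((a:1,b:2):3,(c:4,d:5)) -> unique non-trivial split {a,b}|{c,d}
        t = TreeNode(children=[
            (TreeNode(children=[(TreeNode(name="a"), 1.0),
                                (TreeNode(name="b"), 2.0)]), 1.5),
            (TreeNode(children=[(TreeNode(name="c"), 4.0),
                                (TreeNode(name="d"), 5.0)]), 1.5),
        ])
        D = tree_path_distances(t)
        tree = neighbor_joining(D)
        assert path_distance_error(D, tree) < 1e-9
        parts = {frozenset(p) for p in tip_bipartitions(tree)}
        assert parts <= {frozenset("ab"), frozenset("cd")}
        assert parts  # the split is recovered

    def test_random_additive_matrices_recovered_exactly(self):
        rng = np.random.default_rng(11)
        for n in (4, 5, 7, 9, 12):
            D = random_additive_matrix(rng, n)
            tree = neighbor_joining(D)
            assert path_distance_error(D, tree) < 1e-9

    def test_matches_reference_nj_on_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        D = random_additive_matrix(rng, 8)
        ours = neighbor_joining(D)
        ref = skbio.tree.nj(skbio.DistanceMatrix(D.values, ids=D.labels))
        for a, b in zip(D.labels, D.labels[1:]):
            assert tree_path_distances(ours)[a, b] == pytest.approx(
                ref.find(a).distance(ref.find(b)), abs=1e-9
            )

    def test_determinism_and_tip_conservation(self):
        ps = [profile(f"g{k}", **{f"L{j}": (str(k % 3), str((k + j) % 4))
                                  for j in range(4)})
              for k in range(9)]
        D = distance_matrix(ps)
        t1 = neighbor_joining(D)
        t2 = neighbor_joining(D)
        assert t1.to_newick() == t2.to_newick()
        assert sorted(t.name for t in t1.tips()) == sorted(D.labels)

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            neighbor_joining(DistanceMatrix(["a"], [[0.0]]))

    def test_branch_lengths_never_negative(self):
        # a deliberately non-additive (ultrametric-violating) matrix
        rng = np.random.default_rng(7)
        v = rng.uniform(0.1, 1.0, size=(6, 6))
        v = np.triu(v, 1)
        v = v + v.T
        tree = neighbor_joining(DistanceMatrix([f"t{k}" for k in range(6)], v))

        def walk(node):
            for child, length in node.children:
                assert length >= 0.0
                walk(child)

        walk(tree)


class TestNewickAndAnnotation:
    def test_newick_tip_count_and_terminator(self):
        rng = np.random.default_rng(5)
        D = random_additive_matrix(rng, 6)
        nwk = neighbor_joining(D).to_newick()
        assert nwk.endswith(";")
        for lab in D.labels:
            assert lab in nwk

    def test_annotation_classes(self):
        tree = TreeNode(children=[
            (TreeNode(name="res"), 0.1),
            (TreeNode(children=[(TreeNode(name="sus"), 0.1),
                                (TreeNode(name="untested"), 0.1)]), 0.1),
        ])
        calls = [
            ResistanceCall("res", "fluazifop-butyl", True, True, True),
            ResistanceCall("res", "nicosulfuron", True, False, True),
            ResistanceCall("sus", "nicosulfuron", False, False, False),
        ]
        tab = annotate_tree(tree, calls).set_index("tip")
        assert tab.loc["res", "resistance_class"] == "HRAC 1+2"
        assert tab.loc["sus", "resistance_class"] == "susceptible"
        assert tab.loc["untested", "resistance_class"] == "unknown"
        nwk = tree.to_newick(include_annotations=True)
        assert "res|1+2" in nwk and "sus|S" in nwk


class TestIO:
    def test_ssr_table_round_trip(self, tmp_path):
        p = tmp_path / "ssr.tsv"
        p.write_text(
            "genotype_id\tlocus\tallele\n"
            "g1\tL1\t100\n"
            "g1\tL1\t104\n"
            "g1\tL2\t200\n"
            "g2\tL1\t100\n"
            "g2\tL1\t100\n"
        )
        profiles = {pr.genotype_id: pr for pr in read_ssr_table(p)}
        assert profiles["g1"].loci == {"L1": ("100", "104"), "L2": ("200",)}
        assert profiles["g2"].loci == {"L1": ("100", "100")}
        assert 0 < dps_distance(profiles["g1"], profiles["g2"]) < 1

    def test_phylip_layout(self, tmp_path):
        D = DistanceMatrix(["alpha", "beta"], [[0, 0.25], [0.25, 0]])
        out = tmp_path / "d.phylip"
        write_phylip(D, out)
        lines = out.read_text().splitlines()
        assert lines[0].strip() == "2"
        assert lines[1].startswith("alpha")
        assert "0.250000" in lines[1]
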