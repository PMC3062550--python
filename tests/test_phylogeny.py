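import math

import numpy as np
import pytest

from its_profiler import synth
from its_profiler.align import progressive_align
from its_profiler.phylogeny import (
    DistanceError, DistanceMatrix, assign_genome, bootstrap_support,
    jc_distance, midpoint_root, neighbor_joining, nj_from_msa, p_distance,
)
from its_profiler.records import ItsRecord, MsaBlock
from its_profiler.trees import PhyloTree, TreeNode


class TestDistances:
    def test_p_identical(self):
        assert p_distance("ACGT" * 10, "ACGT" * 10) == 0.0

    def test_p_ten_of_hundred(self):
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        assert p_distance(a, b) == 0.1

    def test_p_gap_columns_excluded(self):
        # 6 columns; the gap and N columns are excluded -> 4 compared,
        # 1 difference (hand count)
        a = "AC-GTN"
        b = "ACCGAA"
        assert p_distance(a, b) == pytest.approx(1 / 4)

    def test_p_zero_compared(self):
        with pytest.raises(DistanceError):
            p_distance("--", "AC")

    def test_jc_zero(self):
        assert jc_distance(0.0) == 0.0

    def test_jc_closed_form(self):
        # -(3/4) ln(1 - 4*0.1/3) evaluated independently
        assert jc_distance(0.1) == pytest.approx(0.10732563, abs=1e-7)
        assert jc_distance(0.1) == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))

    def test_jc_saturation(self):
        assert jc_distance(0.74) > 2.0
        with pytest.raises(DistanceError):
            jc_distance(0.75)
        assert jc_distance(0.75, saturation_ceiling=5.0) == 5.0

    def test_jc_strictly_increasing(self):
        ps = np.linspace(0, 0.74, 200)
        ds = [jc_distance(p) for p in ps]
        assert all(d2 > d1 for d1, d2 in zip(ds, ds[1:]))

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]), "p")
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, np.nan], [np.nan, 0.0]]), "p")


def _additive_matrix_from_tree(tree: PhyloTree):
    """Oracle distances: sum of branch lengths along leaf-to-leaf paths."""
    parents = {}

    def walk(node, parent):
        parents[id(node)] = (parent, node.length)
        for c in node.children:
            walk(c, node)

    walk(tree.root, None)
    leaves = tree.leaves()

    def path_to_root(node):
        out = {}
        dist = 0.0
        while node is not None:
            out[id(node)] = dist
            parent, length = parents[id(node)]
            dist += length
            node = parent
        return out

    labels = [l.label for l in leaves]
    n = len(leaves)
    D = np.zeros((n, n))
    for i in range(n):
        pi = path_to_root(leaves[i])
        for j in range(i + 1, n):
            node = leaves[j]
            d = 0.0
            while id(node) not in pi:
                parent, length = parents[id(node)]
                d += length
                node = parent
            D[i, j] = D[j, i] = d + pi[id(node)]
    return tuple(labels), D


def _random_unrooted_tree(rng, n_leaves):
    nodes = [TreeNode(label=f"t{i}", length=float(rng.uniform(0.5, 3.0)))
             for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]],
                          length=float(rng.uniform(0.5, 3.0)))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return PhyloTree(root=TreeNode(children=nodes), rooted=False)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(("A", "B", "C"),
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float),
                            "p")
        tree = neighbor_joining(dm)
        lengths = {n.label: n.length for n in tree.root.children}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_four_taxon_additive_recovery(self):
        rng = np.random.default_rng(23)
        true = _random_unrooted_tree(rng, 4)
        labels, D = _additive_matrix_from_tree(true)
        tree = neighbor_joining(DistanceMatrix(labels, D, "p"))
        assert tree.robinson_foulds(true) == 0
        # branch-length check via recomputed path metric
        _, D2 = _additive_matrix_from_tree(tree)
        order = [tree.leaf_labels().index(lab) for lab in labels]
        assert np.allclose(D2[np.ix_(order, order)], D, atol=1e-9)

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 7, 8])
    def test_additive_recovery_random(self, n_leaves):
        rng = np.random.default_rng(100 + n_leaves)
        for _ in range(10):
            true = _random_unrooted_tree(rng, n_leaves)
            labels, D = _additive_matrix_from_tree(true)
            tree = neighbor_joining(DistanceMatrix(labels, D, "p"))
            assert tree.robinson_foulds(true) == 0
            _, D2 = _additive_matrix_from_tree(tree)
            order = [tree.leaf_labels().index(lab) for lab in labels]
            assert np.allclose(D2[np.ix_(order, order)], D, atol=1e-8)

    def test_equal_distances_deterministic(self):
        labels = ("a", "b", "c", "d")
        D = np.ones((4, 4)) - np.eye(4)
        t1 = neighbor_joining(DistanceMatrix(labels, D, "p"))
        t2 = neighbor_joining(DistanceMatrix(labels, D, "p"))
        from its_profiler.trees import tree_to_newick

        assert tree_to_newick(t1) == tree_to_newick(t2)
        terminal = [n.length for n in t1.root.walk() if n.is_leaf]
        assert np.allclose(terminal, 0.5)

    def test_too_few_labels(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("a", "b"),
                                            np.array([[0, 1], [1, 0]], float),
                                            "p"))


def _two_clade_msa(rng, n_sep=50, n_cols=600, per_clade=3):
    base = "".join(rng.choice(list("ACGT"), n_cols))
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    sep_idx = rng.choice(n_cols, n_sep, replace=False)
    other = list(base)
    for i in sep_idx:
        other[i] = flip[other[i]]
    other = "".join(other)

    def noisy(s, k):
        s = list(s)
        for i in rng.choice(n_cols, k, replace=False):
            s[i] = flip[s[i]]
        return "".join(s)

    labels, rows = [], []
    for k in range(per_clade):
        labels.append(f"a{k}")
        rows.append(noisy(base, 2))
    for k in range(per_clade):
        labels.append(f"b{k}")
        rows.append(noisy(other, 2))
    return MsaBlock(labels, rows)


class TestBootstrap:
    def test_strong_clade_support(self):
        rng = np.random.default_rng(3)
        msa = _two_clade_msa(rng)
        tree = bootstrap_support(msa, n_replicates=200, seed=5)
        split_support = None
        for node in tree.root.walk():
            if node.support is not None:
                leaves = sorted(x.label for x in node.walk() if x.is_leaf)
                if leaves in (["a0", "a1", "a2"], ["b0", "b1", "b2"]):
                    split_support = node.support
        assert split_support is not None
        assert split_support >= 99.0

    def test_supports_in_range(self):
        rng = np.random.default_rng(4)
        msa = _two_clade_msa(rng, n_sep=5, per_clade=3)
        tree = bootstrap_support(msa, n_replicates=100, seed=6)
        for node in tree.root.walk():
            if node.support is not None:
                assert 0.0 <= node.support <= 100.0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        msa = _two_clade_msa(rng)
        from its_profiler.trees import tree_to_newick

        t1 = bootstrap_support(msa, n_replicates=100, seed=7)
        t2 = bootstrap_support(msa, n_replicates=100, seed=7)
        assert tree_to_newick(t1) == tree_to_newick(t2)

    def test_bad_replicates(self):
        rng = np.random.default_rng(6)
        msa = _two_clade_msa(rng)
        with pytest.raises(ValueError):
            bootstrap_support(msa, n_replicates=0, seed=1)


class TestMidpointRoot:
    def test_symmetric_quartet_roots_on_central_edge(self):
        # ((A:1,B:1):1,(C:1,D:1):1) unrooted with internal edge length 2
        ab = TreeNode(children=[TreeNode(label="A", length=1.0),
                                TreeNode(label="B", length=1.0)], length=2.0)
        tree = PhyloTree(root=TreeNode(children=[
            ab, TreeNode(label="C", length=1.0), TreeNode(label="D", length=1.0)]))
        rooted = midpoint_root(tree)
        sides = [sorted(x.label for x in child.walk() if x.is_leaf)
                 for child in rooted.root.children]
        assert sorted(sides) == [["A", "B"], ["C", "D"]]
        assert rooted.root.children[0].length + rooted.root.children[1].length \
            == pytest.approx(2.0)

    def test_long_terminal_branch(self):
        tree = PhyloTree(root=TreeNode(children=[
            TreeNode(label="A", length=10.0),
            TreeNode(label="B", length=1.0),
            TreeNode(label="C", length=1.0)]))
        rooted = midpoint_root(tree)
        # root must sit on A's branch: one side is the leaf A
        side_labels = [sorted(x.label for x in child.walk() if x.is_leaf)
                       for child in rooted.root.children]
        assert ["A"] in side_labels
        a_side = rooted.root.children[side_labels.index(["A"])]
        assert a_side.length == pytest.approx(5.5)

    def test_idempotent(self):
        ab = TreeNode(children=[TreeNode(label="A", length=1.0),
                                TreeNode(label="B", length=3.0)], length=2.0)
        tree = PhyloTree(root=TreeNode(children=[
            ab, TreeNode(label="C", length=2.0), TreeNode(label="D", length=4.0)]))
        r1 = midpoint_root(tree)
        r2 = midpoint_root(r1)
        from its_profiler.trees import tree_to_newick

        assert tree_to_newick(r1) == tree_to_newick(r2)

    def test_all_zero_lengths_error(self):
        tree = PhyloTree(root=TreeNode(children=[
            TreeNode(label="A"), TreeNode(label="B"), TreeNode(label="C")]))
        with pytest.raises(ValueError):
            midpoint_root(tree)


@pytest.fixture(scope="module")
def refs(template_set):
    records, labels = [], {}
    for genome in ("A", "B", "S"):
        template = next(r for r in template_set.records if r.id == genome)
        for k in range(2):
            rid = f"{genome}ref{k}"
            records.append(synth.fixed_variant(
                template, template_set.annotation, 2,
                seed=60 + k + ord(genome), new_id=rid))
            labels[rid] = genome
    return progressive_align(records), labels


class TestGenomeAssignment:
    def test_query_equal_to_reference(self, refs, template_set):
        rmsa, labels = refs
        template = next(r for r in template_set.records if r.id == "B")
        query = ItsRecord(id="q", sequence=template.sequence, source="consensus")
        (result,) = assign_genome([query], rmsa, labels)
        assert result.genome == "B"
        assert result.margin > 0

    def test_hybrid_mixture(self, refs, template_set):
        rmsa, labels = refs
        templates = {r.id: r for r in template_set.records}
        queries, truth = synth.hybrid_types(templates, {"A": 1, "B": 1}, seed=8)
        results = assign_genome(queries, rmsa, labels)
        assert {r.query_id: r.genome for r in results} == truth

    def test_one_b_two_a_pattern(self, refs, template_set):
        rmsa, labels = refs
        templates = {r.id: r for r in template_set.records}
        queries, truth = synth.hybrid_types(templates, {"B": 1, "A": 2}, seed=9)
        results = assign_genome(queries, rmsa, labels)
        assert sorted(r.genome for r in results) == ["A", "A", "B"]
        assert {r.query_id: r.genome for r in results} == truth

    def test_unlabeled_reference_error(self, refs, template_set):
        rmsa, labels = refs
        bad = {k: v for k, v in labels.items() if k != "Aref0"}
        with pytest.raises(ValueError, match="Aref0"):
            assign_genome([template_set.records[0]], rmsa, bad)

    def test_accuracy_on_divergent_genomes(self, template_set, refs):
        """All templates assign to their own genome when between-genome
        divergence dominates within-genome noise."""
        rmsa, labels = refs
        for genome in ("A", "B", "S"):
            template = next(r for r in template_set.records if r.id == genome)
            noisy = synth.fixed_variant(template, template_set.annotation, 1,
                                        seed=99, new_id=f"q_{genome}")
            (result,) = assign_genome([noisy], rmsa, labels)
            assert result.genome == genome


class TestNjFromMsa:
    def test_lineage_topology_recovered(self, template_set):
        msa = progressive_align(template_set.records)
        tree = nj_from_msa(msa, model="jc")
        truth = template_set.true_tree
        shared = tree.bipartitions() & truth.bipartitions()
        assert shared == truth.bipartitions()
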