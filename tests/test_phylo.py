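"""Tree construction and incongruence tests: NJ correctness on additive
matrices (with scikit-bio as an independent cross-check), RF metric
behaviour (cross-checked against dendropy), monophyly, and the
element/species incongruence scan."""

import dendropy
import numpy as np
import pytest

from copiaht.phylo import (
    DistanceMatrix,
    bipartitions,
    incongruence_scan,
    monophyly,
    nj_tree,
    rf_distance,
)


def tree_from_newick(s):
    return dendropy.Tree.get(data=s, schema="newick")


def random_additive_tree(n_leaves, rng):
    """Random binary tree (dict nodes) with branch lengths in [0.1, 1];
    returns (labels, distance matrix, newick)."""
    labels = [f"T{i}" for i in range(n_leaves)]
    nodes = [{"label": lb, "children": [], "bl": None} for lb in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a["bl"] = round(0.1 + 0.9 * rng.random(), 6)
        b["bl"] = round(0.1 + 0.9 * rng.random(), 6)
        parent = {"label": None, "children": [nodes[i], nodes[j]], "bl": None}
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(parent)
    root = nodes[0]

    dists = {}

    def walk(node, acc):
        if not node["children"]:
            dists[node["label"]] = acc
            return
        for c in node["children"]:
            walk(c, acc + c["bl"])

    # leaf-to-leaf distances via root paths minus shared prefix: recompute
    # per pair by full traversal from each leaf instead (simpler): build
    # parent pointers
    parents = {}

    def link(node):
        for c in node["children"]:
            parents[id(c)] = node
            link(c)

    link(root)
    leaf_nodes = {}

    def collect(node):
        if not node["children"]:
            leaf_nodes[node["label"]] = node
        for c in node["children"]:
            collect(c)

    collect(root)

    def path_to_root(node):
        out = []
        while id(node) in parents:
            out.append(node)
            node = parents[id(node)]
        return out

    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi = path_to_root(leaf_nodes[labels[i]])
            pj = path_to_root(leaf_nodes[labels[j]])
            si = {id(x) for x in pi}
            sj = {id(x) for x in pj}
            dist = sum(x["bl"] for x in pi if id(x) not in sj)
            dist += sum(x["bl"] for x in pj if id(x) not in si)
            d[i, j] = d[j, i] = dist

    def nwk(node):
        if not node["children"]:
            return f"{node['label']}:{node['bl']}"
        inner = ",".join(nwk(c) for c in node["children"])
        bl = f":{node['bl']}" if node["bl"] is not None else ""
        return f"({inner}){bl}"

    return labels, d, nwk(root) + ";"


def patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1 in tree.taxon_namespace:
        for t2 in tree.taxon_namespace:
            out[(t1.label, t2.label)] = pdm.patristic_distance(t1, t2)
    return out


class TestNJ:
    def test_three_taxon_analytic(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.]]))
        tree = nj_tree(dm)
        dists = patristic(tree)
        assert dists[("A", "B")] == pytest.approx(2)
        assert dists[("A", "C")] == pytest.approx(4)
        assert dists[("B", "C")] == pytest.approx(4)
        # branch solution a=1, b=1, c=3
        bls = sorted(lf.edge.length for lf in tree.leaf_node_iter())
        assert bls == pytest.approx([1, 1, 3])

    def test_additive_four_taxon_roundtrip(self, rng):
        labels, d, nwk = random_additive_tree(4, rng)
        tree = nj_tree(DistanceMatrix(labels, d))
        dists = patristic(tree)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                assert dists[(a, b)] == pytest.approx(d[i, j], abs=1e-9)

    @pytest.mark.parametrize("n", [5, 7, 10])
    def test_additive_recovery_exact(self, n, rng):
        for _ in range(10):
            labels, d, nwk = random_additive_tree(n, rng)
            tree = nj_tree(DistanceMatrix(labels, d))
            truth = tree_from_newick(nwk)
            rf, norm = rf_distance(tree, truth)
            assert rf == 0
            dists = patristic(tree)
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    assert dists[(a, b)] == pytest.approx(d[i, j], abs=1e-9)

    def test_matches_scikit_bio_topology(self, rng):
        # independent NJ implementation as an oracle on noisy matrices
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj
        for _ in range(5):
            labels, d, _ = random_additive_tree(6, rng)
            noise = rng.uniform(0, 0.02, size=d.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            dn = d + noise
            mine = nj_tree(DistanceMatrix(labels, dn))
            theirs = tree_from_newick(str(skbio_nj(SkbioDM(dn, labels),
                                                   result_constructor=None)))
            rf, _ = rf_distance(mine, theirs)
            assert rf == 0

    def test_deterministic_under_ties(self):
        # ultrametric matrix with two equal joins
        labels = ["A", "B", "C", "D"]
        d = np.array([[0, 2, 6, 6],
                      [2, 0, 6, 6],
                      [6, 6, 0, 2],
                      [6, 6, 2, 0.]])
        t1 = nj_tree(DistanceMatrix(labels, d)).as_string(schema="newick")
        t2 = nj_tree(DistanceMatrix(labels, d)).as_string(schema="newick")
        assert t1 == t2

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0.]])))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.]]))


class TestRF:
    def test_identical_trees_zero(self):
        t = "((A,B),(C,D),E);"
        rf, norm = rf_distance(tree_from_newick(t), tree_from_newick(t))
        assert rf == 0 and norm == 0.0

    def test_single_nni_on_five_leaves(self):
        t1 = tree_from_newick("(((A,B),C),D,E);")
        t2 = tree_from_newick("(((A,C),B),D,E);")
        rf, _ = rf_distance(t1, t2)
        assert rf == 2

    def test_maximally_different_caterpillars(self):
        t1 = tree_from_newick("(((((A,B),C),D),E),F);")
        t2 = tree_from_newick("(((((A,F),D),B),E),C);")
        rf, norm = rf_distance(t1, t2)
        assert rf == 6 and norm == 1.0

    def test_matches_dendropy(self, rng):
        from dendropy.calculate import treecompare
        for _ in range(10):
            la, _, n1 = random_additive_tree(7, rng)
            _, _, n2 = random_additive_tree(7, rng)
            ns = dendropy.TaxonNamespace()
            t1 = dendropy.Tree.get(data=n1, schema="newick",
                                   taxon_namespace=ns)
            t2 = dendropy.Tree.get(data=n2, schema="newick",
                                   taxon_namespace=ns)
            t1.encode_bipartitions()
            t2.encode_bipartitions()
            expected = treecompare.symmetric_difference(t1, t2)
            got, _ = rf_distance(t1, t2)
            assert got == expected

    def test_metric_properties(self, rng):
        trees = []
        for _ in range(4):
            _, _, nwk = random_additive_tree(6, rng)
            trees.append(tree_from_newick(nwk))
        for t in trees:
            assert rf_distance(t, t)[0] == 0
        for a in trees:
            for b in trees:
                assert rf_distance(a, b)[0] == rf_distance(b, a)[0]
        for a in trees:
            for b in trees:
                for c in trees:
                    assert (rf_distance(a, c)[0]
                            <= rf_distance(a, b)[0] + rf_distance(b, c)[0])

    def test_restricted_to_shared_leaves(self):
        t1 = tree_from_newick("((A,B),(C,D),(E,X));")
        t2 = tree_from_newick("((A,B),(C,D),(E,Y));")
        rf, _ = rf_distance(t1, t2)  # shared {A..E}
        assert rf == 0

    def test_too_few_shared(self):
        with pytest.raises(ValueError):
            rf_distance(tree_from_newick("(A,B,C);"),
                        tree_from_newick("(A,B,C);"))


class TestMonophyly:
    def test_single_copy_species_true(self):
        t = tree_from_newick("((a1,b1),(b2,c1));")
        m = monophyly(t, {"a1": "a", "b1": "b", "b2": "b", "c1": "c"})
        assert m["a"] and m["c"]

    def test_interleaved_species_false(self):
        t = tree_from_newick("((a1,b1),(a2,b2));")
        m = monophyly(t, {"a1": "a", "a2": "a", "b1": "b", "b2": "b"})
        assert m == {"a": False, "b": False}

    def test_clean_clades_true(self):
        t = tree_from_newick("((a1,a2),(b1,b2));")
        m = monophyly(t, {"a1": "a", "a2": "a", "b1": "b", "b2": "b"})
        assert m == {"a": True, "b": True}

    def test_rerooting_invariance(self, rng):
        nwk = "((a1,a2),((b1,b2),(c1,(c2,c3))));"
        species = {lb: lb[0] for lb in
                   ["a1", "a2", "b1", "b2", "c1", "c2", "c3"]}
        base = monophyly(tree_from_newick(nwk), species)
        t = tree_from_newick(nwk)
        for edge in list(t.preorder_edge_iter())[3:6]:
            t2 = tree_from_newick(nwk)
            edges = list(t2.preorder_edge_iter())
            idx = list(t.preorder_edge_iter()).index(edge)
            if edges[idx].head_node.parent_node is None:
                continue
            t2.reroot_at_edge(edges[idx])
            assert monophyly(t2, species) == base

    def test_unmapped_leaf_rejected(self):
        with pytest.raises(ValueError):
            monophyly(tree_from_newick("(a1,b1,c1);"), {"a1": "a"})


class TestIncongruenceScan:
    SPECIES = "((((A,B),C),D),(E,F));"

    def _species_map(self, copies=2):
        return {f"{sp.lower()}{i}": sp
                for sp in "ABCDEF" for i in range(1, copies + 1)}

    def test_congruent_trees_no_conflicts(self):
        te = tree_from_newick(
            "((((a1,a2),(b1,b2)),((c1,c2),(d1,d2))),((e1,e2),(f1,f2)));"
            .replace("a0", "a"))
        te = tree_from_newick(
            "(((((a1,a2),(b1,b2)),(c1,c2)),(d1,d2)),((e1,e2),(f1,f2)));")
        report = incongruence_scan(te, tree_from_newick(self.SPECIES),
                                   self._species_map())
        assert report.rf == 0
        assert not report.incongruent
        assert report.implicated_species == []

    def test_single_regraft_implicates_that_species(self):
        # species D's copies moved next to A in the element tree
        te = tree_from_newick(
            "((((((a1,a2),(d1,d2)),(b1,b2)),(c1,c2))),((e1,e2),(f1,f2)));")
        report = incongruence_scan(te, tree_from_newick(self.SPECIES),
                                   self._species_map())
        assert report.incongruent
        assert "D" in report.implicated_species
        assert "F" not in report.implicated_species

    def test_non_monophyletic_species_flagged(self):
        te = tree_from_newick(
            "(((((a1,b1),(a2,b2)),(c1,c2)),(d1,d2)),((e1,e2),(f1,f2)));")
        report = incongruence_scan(te, tree_from_newick(self.SPECIES),
                                   self._species_map())
        assert report.monophyly["A"] is False
        assert report.monophyly["B"] is False
        assert {"A", "B"} <= set(report.implicated_species)

    def test_too_few_shared_species(self):
        te = tree_from_newick("((a1,b1),(c1,d1));")
        sp = tree_from_newick("((A,B),(C,D));")
        smap = {"a1": "A", "b1": "B", "c1": "C", "d1": "D"}
        report = incongruence_scan(te, sp, smap)
        assert report.rf == 0  # 4 shared species, congruent quartet

    def test_bipartitions_canonical(self):
        t = tree_from_newick("((A,B),(C,D),E);")
        bips = bipartitions(t)
        assert frozenset({"A", "B"}) in bips or \
            frozenset({"C", "D", "E"}) in bips
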