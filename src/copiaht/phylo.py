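"""Distance-based trees and element-vs-species incongruence analysis.

Trees are dendropy objects; the algorithms on them — Saitou–Nei neighbor
joining, bipartition extraction, Robinson–Foulds distance, monophyly testing
and the incongruence scan — are implemented here. NJ on Jukes–Cantor (or Ks)
distances stands in for external maximum-likelihood tree builders; the
incongruence logic itself is distance-method-agnostic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "DistanceMatrix",
    "IncongruenceReport",
    "jc_distance_matrix",
    "nj_tree",
    "bipartitions",
    "rf_distance",
    "monophyly",
    "incongruence_scan",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(self.matrix < 0):
            raise ValueError("negative distances")
        if not np.allclose(np.diag(self.matrix), 0):
            raise ValueError("nonzero diagonal")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        import pandas as pd
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.values)

    def to_tsv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.matrix, index=self.labels,
                     columns=self.labels).to_csv(path, sep="\t")


def jc_distance_matrix(alignment) -> DistanceMatrix:
    """Jukes–Cantor-corrected nucleotide distances from a CodonAlignment.

    Sites with a gap/ambiguity in either member of a pair are skipped
    pairwise. Saturated pairs (p >= 3/4) get a large finite distance (5.0)
    so NJ stays usable.
    """
    rows = [np.frombuffer(r.encode(), dtype="S1") for r in alignment.rows]
    valid = [np.isin(r, [b"A", b"C", b"G", b"T"]) for r in rows]
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            m = ok.sum()
            if m == 0:
                dist = 5.0
            else:
                p = (rows[i][ok] != rows[j][ok]).sum() / m
                dist = 5.0 if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(alignment.labels), d)


def _new_tree(taxa: list[str]) -> tuple[dendropy.Tree, dict]:
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = {}
    for t in ns:
        node = dendropy.Node(taxon=t)
        nodes[t.label] = node
    return tree, nodes


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic label-order
    tie-breaking; negative branch lengths are clamped to zero with the
    deficit transferred to the sibling branch."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    order = sorted(range(n), key=lambda i: dm.labels[i])
    labels = [dm.labels[i] for i in order]
    d = dm.matrix[np.ix_(order, order)].astype(float)

    tree, leaf_nodes = _new_tree(labels)
    active: list[dendropy.Node] = [leaf_nodes[lb] for lb in labels]
    names = list(labels)  # parallel to active, for tie-breaking only

    edge_len: dict[int, float] = {}

    def set_len(node, value):
        edge_len[id(node)] = value

    while len(active) > 2:
        m = len(active)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, min(names[i], names[j]), max(names[i], names[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2)) if m > 2 else 0.5 * dij
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(active[i])
        parent.add_child(active[j])
        set_len(active[i], li)
        set_len(active[j], lj)
        new_d = 0.5 * (d[:, i] + d[:, j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([np.hstack([d[np.ix_(keep, keep)],
                                  new_d[keep, None]]),
                       np.hstack([new_d[keep], [0.0]])])
        active = [active[k] for k in keep] + [parent]
        names = [names[k] for k in keep] + [min(names[i], names[j])]

    # join the last two nodes with a single edge
    a, b = active
    root = dendropy.Node()
    if a.is_leaf() and not b.is_leaf():
        a, b = b, a
    root = a
    root.add_child(b)
    set_len(b, max(d[0, 1], 0.0) if not a.is_leaf() else d[0, 1])
    tree.seed_node = root
    for node in tree:
        if node is not tree.seed_node:
            node.edge.length = edge_len.get(id(node), 0.0)
    tree.is_rooted = False
    return tree


def _canonical_side(side: frozenset, all_leaves: frozenset) -> frozenset:
    """Canonical representation of a bipartition: the side not containing
    the lexicographically smallest leaf."""
    anchor = min(all_leaves)
    return frozenset(all_leaves - side) if anchor in side else side


def bipartitions(tree: dendropy.Tree, leaf_subset=None,
                 include_trivial: bool = False) -> set[frozenset]:
    """Bipartitions of an (un)rooted tree, optionally restricted to a leaf
    subset (pruning implied); returned as canonical frozensets of labels."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if leaf_subset is not None:
        leaves &= set(leaf_subset)
    if len(leaves) < 2:
        return set()
    all_leaves = frozenset(leaves)
    out: set[frozenset] = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._below = frozenset([node.taxon.label]) & all_leaves
        else:
            node._below = frozenset().union(*(c._below for c in
                                              node.child_nodes()))
        side = node._below
        if not include_trivial and (len(side) < 2 or
                                    len(all_leaves - side) < 2):
            continue
        if 0 < len(side) < len(all_leaves):
            out.add(_canonical_side(side, all_leaves))
    return out


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree):
    """Robinson–Foulds distance restricted to the shared leaf set.

    Returns (rf: int, normalized: float) with normalization by 2(n-3), the
    maximum for binary trees on n shared leaves.
    """
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    shared = l1 & l2
    if len(shared) < 4:
        raise ValueError("need >= 4 shared leaves")
    b1 = bipartitions(t1, shared)
    b2 = bipartitions(t2, shared)
    rf = len(b1 ^ b2)
    return rf, rf / (2 * (len(shared) - 3))


def monophyly(tree: dendropy.Tree, species_map: dict[str, str]) -> dict[str, bool]:
    """Per-species monophyly in an unrooted sense: a species is monophyletic
    iff some bipartition separates exactly its copies from everything else
    (single-copy species are monophyletic by convention)."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unmapped = leaves - set(species_map)
    if unmapped:
        raise ValueError(f"unmapped leaves: {sorted(unmapped)}")
    all_leaves = frozenset(leaves)
    bips = bipartitions(tree, include_trivial=True)
    species = {species_map[lf] for lf in leaves}
    result = {}
    for sp in species:
        members = frozenset(lf for lf in leaves if species_map[lf] == sp)
        if len(members) <= 1 or len(members) == len(leaves):
            result[sp] = True
        else:
            result[sp] = _canonical_side(members, all_leaves) in bips
    return result


@dataclass
class IncongruenceReport:
    shared_bipartitions: list[tuple[str, ...]]
    conflicting_te: list[tuple[str, ...]]
    conflicting_species: list[tuple[str, ...]]
    monophyly: dict[str, bool]
    implicated_species: list[str]
    rf: int
    normalized_rf: float
    n_shared_species: int
    collapsed_te_newick: str = ""
    notes: list[str] = field(default_factory=list)

    @property
    def incongruent(self) -> bool:
        return bool(self.conflicting_te or self.conflicting_species)

    def to_json(self, path=None) -> str:
        payload = {
            "shared_bipartitions": [sorted(b) for b in self.shared_bipartitions],
            "conflicting_te": [sorted(b) for b in self.conflicting_te],
            "conflicting_species": [sorted(b) for b in self.conflicting_species],
            "monophyly": self.monophyly,
            "implicated_species": self.implicated_species,
            "rf": self.rf,
            "normalized_rf": self.normalized_rf,
            "n_shared_species": self.n_shared_species,
            "incongruent": self.incongruent,
            "collapsed_te_newick": self.collapsed_te_newick,
            "notes": self.notes,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _collapse_to_species(te_tree: dendropy.Tree,
                         species_map: dict[str, str],
                         mono: dict[str, bool]):
    """Collapse a copy-level tree to one tip per monophyletic species;
    maximal same-species clades of non-monophyletic species become separate
    tips ``species#k``."""
    tree = te_tree.clone(depth=1)
    counter: dict[str, int] = {}
    tip_species: dict[str, str] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._sp = {species_map[node.taxon.label]}
        else:
            node._sp = set().union(*(c._sp for c in node.child_nodes()))
    # find maximal nodes whose leaf species set is a single species
    new_tips = []
    def walk(node):
        if len(node._sp) == 1:
            new_tips.append(node)
            return
        for c in node.child_nodes():
            walk(c)
    walk(tree.seed_node)
    ns = tree.taxon_namespace
    for node in new_tips:
        sp = next(iter(node._sp))
        if mono.get(sp, True):
            name = sp
        else:
            counter[sp] = counter.get(sp, 0) + 1
            name = f"{sp}#{counter[sp]}"
        node.set_child_nodes([])
        taxon = ns.new_taxon(name)
        node.taxon = taxon
        tip_species[name] = sp
    # drop unary internal chains introduced by the collapse
    tree.suppress_unifurcations()
    return tree, tip_species


def incongruence_scan(te_tree: dendropy.Tree, species_tree: dendropy.Tree,
                      species_map: dict[str, str]) -> IncongruenceReport:
    """Compare the element tree (copy-level tips) against the species tree.

    The element tree is collapsed to one tip per monophyletic species;
    bipartitions are compared on the shared species set. Conflicting
    bipartitions implicate the species on their minority side; species whose
    copies are not monophyletic are flagged and implicated as well.
    """
    mono = monophyly(te_tree, species_map)
    collapsed, tip_species = _collapse_to_species(te_tree, species_map, mono)
    notes = []
    mono_species = {sp for sp, ok in mono.items() if ok}
    non_mono = sorted(sp for sp, ok in mono.items() if not ok)
    if non_mono:
        notes.append("non-monophyletic species excluded from bipartition "
                     f"comparison: {non_mono}")
    sp_leaves = {lf.taxon.label for lf in species_tree.leaf_node_iter()}
    shared = (mono_species & sp_leaves)
    if len(shared) < 4:
        raise ValueError("fewer than 4 shared, monophyletic species")
    b_te = bipartitions(collapsed, shared)
    b_sp = bipartitions(species_tree, shared)
    shared_b = b_te & b_sp
    conf_te = b_te - b_sp
    conf_sp = b_sp - b_te
    rf = len(conf_te) + len(conf_sp)

    # implicate species by leaf pruning: a species is implicated when
    # removing it alone restores full congruence; if no single removal
    # does, fall back to any removal that reduces the conflict count, and
    # finally to the union of minority sides of conflicting bipartitions
    implicated = set(non_mono)
    if rf > 0:
        restore, reduce = set(), set()
        for sp in shared:
            rest = shared - {sp}
            if len(rest) < 4:
                sub_rf = 0
            else:
                sub_rf = len(bipartitions(collapsed, rest)
                             ^ bipartitions(species_tree, rest))
            if sub_rf == 0:
                restore.add(sp)
            elif sub_rf < rf:
                reduce.add(sp)
        if restore:
            implicated |= restore
        elif reduce:
            implicated |= reduce
        else:
            for bip in conf_te | conf_sp:
                other = shared - bip
                implicated |= bip if len(bip) <= len(other) else other
    norm = rf / (2 * (len(shared) - 3)) if len(shared) > 3 else 0.0
    return IncongruenceReport(
        shared_bipartitions=sorted(tuple(sorted(b)) for b in shared_b),
        conflicting_te=sorted(tuple(sorted(b)) for b in conf_te),
        conflicting_species=sorted(tuple(sorted(b)) for b in conf_sp),
        monophyly=mono,
        implicated_species=sorted(implicated),
        rf=rf,
        normalized_rf=norm,
        n_shared_species=len(shared),
        collapsed_te_newick=collapsed.as_string(schema="newick").strip(),
        notes=notes,
    )
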