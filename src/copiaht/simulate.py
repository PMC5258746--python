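"""Synthetic codon-sequence evolution along a dated species tree.

The generator emulates the data structure the horizontal-transfer analysis
assumes: host genes descend strictly along a dated species tree; element
(TE) loci descend the same way except that a horizontal-transfer event
replaces the recipient's element lineage at a stated time with a copy of the
donor's lineage, and an amplification burst adds star-radiating copies from
a stated time to the present.

The substitution process is deliberately simple — per-nucleotide Poisson
proposals with equal exchange rates, classified per codon context:
synonymous proposals always accepted, nonsynonymous accepted with
probability min(omega, 1) (omega > 1 scales the nonsynonymous proposal rate
instead), proposals creating stop codons rejected. The proposal rate is
calibrated so the realized synonymous substitution rate per synonymous site
per year equals the requested clock rate r; the expected Nei–Gojobori
synonymous divergence between two descendants separated for time t each is
therefore about 2·r·t.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import dendropy
import numpy as np

from ._genetics import (
    CODONS,
    DEFAULT_PREFERRED_CODONS,
    code_table,
    synonymous_families,
)
from .codon import CodonAlignment

__all__ = [
    "LocusSpec",
    "HTEvent",
    "BurstEvent",
    "SimScenario",
    "SimOutput",
    "random_coding_sequence",
    "evolve_codon_sequence",
    "build_gene_tree",
    "simulate_dataset",
]

_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class LocusSpec:
    """One simulated locus.

    kind: 'host_gene' (vertical descent only) or 'te' (subject to HT/burst)
    syn_rate: substitutions per synonymous site per year
    omega: nonsynonymous/synonymous acceptance ratio (>= 0)
    preferred_codon_fraction: root-sequence codon bias in [0, 1]
    """

    name: str
    kind: str
    codon_count: int
    syn_rate: float
    omega: float = 0.5
    preferred_codon_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("host_gene", "te"):
            raise ValueError(f"unknown locus kind {self.kind!r}")
        if self.codon_count < 1:
            raise ValueError("codon_count must be >= 1")
        if self.syn_rate <= 0:
            raise ValueError("syn_rate must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if not 0 <= self.preferred_codon_fraction <= 1:
            raise ValueError("preferred_codon_fraction must be in [0, 1]")


@dataclass
class HTEvent:
    donor: str
    recipient: str
    time: float  # years before present

    def __post_init__(self) -> None:
        if self.donor == self.recipient:
            raise ValueError("HT donor equals recipient")
        if self.time <= 0:
            raise ValueError("HT time must be > 0")


@dataclass
class BurstEvent:
    species: str
    time: float
    n_copies: int

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("burst time must be > 0")
        if self.n_copies < 1:
            raise ValueError("burst needs >= 1 copies")


@dataclass
class SimScenario:
    """Full description of one simulated study.

    species_tree_newick: rooted ultrametric tree, branch lengths in years.
    copy_divergence_time: age (years) at which the ``copies_per_species``
    within-species copies star-radiate from the species lineage; 0 keeps
    them identical, which is the right default for single-copy host genes.
    """

    species_tree_newick: str
    loci: list[LocusSpec]
    ht_events: list[HTEvent] = field(default_factory=list)
    burst_events: list[BurstEvent] = field(default_factory=list)
    copies_per_species: int = 1
    copy_divergence_time: float = 0.0
    seed: int = 0

    def tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.species_tree_newick,
                                 schema="newick")

    def validate(self) -> None:
        tree = self.tree()
        tree.calc_node_ages(ultrametricity_precision=False)
        root_age = tree.seed_node.age
        taxa = {lf.taxon.label for lf in tree.leaf_node_iter()}
        for ev in self.ht_events:
            if ev.recipient not in taxa:
                raise ValueError(f"HT recipient {ev.recipient!r} not in tree")
            if ev.donor not in taxa:
                raise ValueError(f"HT donor {ev.donor!r} not in tree")
            if not 0 < ev.time < root_age:
                raise ValueError("HT time outside (0, root age)")
        for ev in self.burst_events:
            if ev.species not in taxa:
                raise ValueError(f"burst species {ev.species!r} not in tree")
            if not 0 < ev.time < root_age:
                raise ValueError("burst time outside (0, root age)")
        if self.copies_per_species < 1:
            raise ValueError("copies_per_species must be >= 1")


@dataclass
class SimOutput:
    alignments: dict[str, CodonAlignment]
    truth: dict

    def write(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, aln in self.alignments.items():
            aln.to_fasta(outdir / f"{name}.fasta")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


# amino-acid / stop lookup for base-4 packed ACGT codon indices
def _acgt_tables(code_id: int = 1):
    aa, stops = code_table(code_id)
    letters = "ACGT"
    aa_arr = np.zeros(64, dtype=np.int16)
    stop_arr = np.zeros(64, dtype=bool)
    for i in range(64):
        codon = letters[i // 16] + letters[(i // 4) % 4] + letters[i % 4]
        stop_arr[i] = codon in stops
        aa_arr[i] = ord(aa[codon])
    return aa_arr, stop_arr


_ACGT_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _acgt(code_id: int = 1):
    if code_id not in _ACGT_CACHE:
        _ACGT_CACHE[code_id] = _acgt_tables(code_id)
    return _ACGT_CACHE[code_id]


def default_preferred_codon(codon: str, code_id: int = 1) -> str:
    """The preferred codon of this codon's synonymous family under the
    package's default table (the codon itself for Met/Trp)."""
    for codons in synonymous_families(code_id).values():
        if codon in codons:
            return next((c for c in codons if c in DEFAULT_PREFERRED_CODONS),
                        codons[0])
    return codon


def random_coding_sequence(n_codons: int, rng: np.random.Generator,
                           preferred_fraction: float = 0.0,
                           code_id: int = 1) -> str:
    """Random stop-free coding sequence; with probability
    ``preferred_fraction`` each codon is swapped for its family's preferred
    codon, imposing codon bias at the root without touching the
    substitution process."""
    _, stops = code_table(code_id)
    non_stop = [c for c in CODONS if c not in stops]
    out = []
    for _ in range(n_codons):
        codon = non_stop[rng.integers(len(non_stop))]
        if preferred_fraction and rng.random() < preferred_fraction:
            codon = default_preferred_codon(codon, code_id)
        out.append(codon)
    return "".join(out)


def evolve_codon_sequence(ancestor: str, t: float, r: float, omega: float,
                          rng: np.random.Generator,
                          code_id: int = 1) -> str:
    """Evolve one coding sequence for ``t`` years at synonymous clock rate
    ``r`` and selection parameter ``omega``; returns the descendant."""
    if t < 0:
        raise ValueError("negative time")
    if len(ancestor) % 3:
        raise ValueError("ancestor length not divisible by 3")
    aa_of, stop = _acgt(code_id)
    seq = np.array([_NT_INDEX[ch] for ch in ancestor.upper()], dtype=np.int8)
    L = len(seq)
    if L == 0 or t == 0 or r == 0:
        return ancestor.upper()

    # Thinning of a dominating Poisson process: per-site proposal rate
    # r·max(1, omega); acceptance 1/max(1, omega) for synonymous and
    # omega/max(1, omega) for nonsynonymous proposals, which realizes
    # synonymous rate r per synonymous site and nonsynonymous rate r·omega.
    scale = max(1.0, omega)
    n_events = rng.poisson(r * scale * L * t)
    if n_events == 0:
        return ancestor.upper()
    positions = rng.integers(0, L, size=n_events)
    jumps = rng.integers(1, 4, size=n_events)  # cyclic shift: uniform other base
    accept_u = rng.random(n_events)
    p_syn = 1.0 / scale
    p_non = omega / scale

    pow3 = (16, 4, 1)
    for k in range(n_events):
        pos = positions[k]
        old = seq[pos]
        new = (old + jumps[k]) & 3
        c0 = pos - pos % 3
        idx_old = seq[c0] * 16 + seq[c0 + 1] * 4 + seq[c0 + 2]
        idx_new = idx_old + (new - old) * pow3[pos - c0]
        if stop[idx_new]:
            continue
        threshold = p_syn if aa_of[idx_new] == aa_of[idx_old] else p_non
        if accept_u[k] < threshold:
            seq[pos] = new
    return "".join("ACGT"[i] for i in seq)


# --- gene-tree construction -------------------------------------------------

class _GNode:
    """Minimal mutable node for genealogy assembly; ages in years before
    present, ``length`` the branch to the parent."""

    __slots__ = ("children", "length", "label", "age")

    def __init__(self, label=None, length=0.0, age=0.0):
        self.children: list[_GNode] = []
        self.length = float(length)
        self.label = label
        self.age = float(age)

    def add(self, child: "_GNode") -> "_GNode":
        self.children.append(child)
        return child

    def iter_with_parent(self):
        stack = [(self, None)]
        while stack:
            node, parent = stack.pop()
            yield node, parent
            for c in node.children:
                stack.append((c, node))

    def newick(self) -> str:
        def fmt(node):
            if not node.children:
                return f"{node.label}:{node.length:g}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:g}"
        return fmt(self) + ";"


def _species_gene_tree(tree: dendropy.Tree):
    """Copy a dated dendropy species tree into _GNode form; returns the root
    and, per species, the root-to-tip node path (tip last)."""
    tree = tree.clone(depth=1)
    tree.calc_node_ages(ultrametricity_precision=False)

    def build(dnode):
        g = _GNode(label=dnode.taxon.label if dnode.taxon else None,
                   length=dnode.edge.length or 0.0, age=dnode.age)
        for c in dnode.child_nodes():
            g.add(build(c))
        return g

    root = build(tree.seed_node)
    paths: dict[str, list[_GNode]] = {}

    def walk(node, path):
        path = path + [node]
        if not node.children:
            paths[node.label] = path
        for c in node.children:
            walk(c, path)

    walk(root, [])
    return root, paths


def _insert_on_path(paths: dict[str, list[_GNode]], species: str,
                    age: float) -> _GNode:
    """Insert (or reuse) a node at ``age`` on the lineage of ``species``."""
    path = paths[species]
    for node in path:
        if abs(node.age - age) < 1e-9:
            return node
    for i in range(1, len(path)):
        parent, child = path[i - 1], path[i]
        if parent.age > age > child.age:
            mid = _GNode(age=age, length=parent.age - age)
            mid.add(child)
            child.length = age - child.age
            parent.children[parent.children.index(child)] = mid
            paths[species] = path[:i] + [mid] + path[i:]
            return mid
    raise ValueError(f"age {age} not on the lineage of {species}")


def build_gene_tree(scenario: SimScenario, locus: LocusSpec) -> _GNode:
    """Locus genealogy: the species tree, plus (for TE loci) HT regrafts and
    burst stars, then per-species copy stars at ``copy_divergence_time``."""
    root, paths = _species_gene_tree(scenario.tree())

    if locus.kind == "te":
        for ev in sorted(scenario.ht_events, key=lambda e: -e.time):
            attach = _insert_on_path(paths, ev.donor, ev.time)
            # the transferred unit is the whole recipient-side clade whose
            # stem spans the transfer time (an HT older than the recipient's
            # split from its sister carries the sister along)
            rpath = paths[ev.recipient]
            moved = next(node for node in rpath if node.age < ev.time - 1e-9)
            for node, parent in root.iter_with_parent():
                if node is moved and parent is not None:
                    parent.children.remove(node)
                    break
            moved.length = ev.time - moved.age
            attach.add(moved)
            donor_prefix = paths[ev.donor][:paths[ev.donor].index(attach) + 1]
            for sp, p in paths.items():
                if moved in p:
                    paths[sp] = donor_prefix + p[p.index(moved):]

        for ev in scenario.burst_events:
            node = _insert_on_path(paths, ev.species, ev.time)
            for i in range(ev.n_copies):
                node.add(_GNode(label=f"{ev.species}|burst{i + 1}",
                                length=ev.time, age=0.0))

    for species in list(paths):
        tip = paths[species][-1]
        t0 = min(scenario.copy_divergence_time, tip.length)
        tip.label = None
        tip.length -= t0
        tip.age = t0
        for i in range(scenario.copies_per_species):
            tip.add(_GNode(label=f"{species}|c{i + 1}", length=t0, age=0.0))
    return root


def _evolve_tree(root: _GNode, root_seq: str, locus: LocusSpec,
                 rng: np.random.Generator) -> dict[str, str]:
    out: dict[str, str] = {}

    def recurse(node, seq):
        if not node.children:
            out[node.label] = seq
            return
        for child in node.children:
            recurse(child, evolve_codon_sequence(seq, child.length,
                                                 locus.syn_rate, locus.omega,
                                                 rng))

    recurse(root, root_seq)
    return out


def simulate_dataset(scenario: SimScenario) -> SimOutput:
    """Simulate every locus of a scenario; deterministic under the seed."""
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    alignments: dict[str, CodonAlignment] = {}
    truth_loci = {}
    for locus in scenario.loci:
        gtree = build_gene_tree(scenario, locus)
        root_seq = random_coding_sequence(locus.codon_count, rng,
                                          locus.preferred_codon_fraction)
        tip_seqs = _evolve_tree(gtree, root_seq, locus, rng)
        labels = sorted(tip_seqs)
        groups = {lb: lb.split("|")[0] for lb in labels}
        alignments[locus.name] = CodonAlignment(
            labels, [tip_seqs[lb] for lb in labels], groups)
        truth_loci[locus.name] = {
            "kind": locus.kind,
            "gene_tree_newick": gtree.newick(),
            "syn_rate": locus.syn_rate,
            "omega": locus.omega,
        }
    truth = {
        "seed": scenario.seed,
        "species_tree_newick": scenario.species_tree_newick.strip(),
        "ht_events": [{"donor": e.donor, "recipient": e.recipient,
                       "time": e.time} for e in scenario.ht_events],
        "burst_events": [{"species": e.species, "time": e.time,
                          "n_copies": e.n_copies}
                         for e in scenario.burst_events],
        "loci": truth_loci,
    }
    return SimOutput(alignments, truth)
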