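"""Codon-alignment preparation and divergence statistics.

Implements the sequence side of the horizontal-transfer analysis: in-frame
alignment clean-up (gap-column deletion, stops masked as missing), the
Nei–Gojobori (1986) Ka/Ks estimator with Jukes–Cantor correction, group
divergence summaries (mean ± SD over all between-group pairs), a global
nucleotide-identity filter, and the codon bias index (CBI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner

from ._genetics import (
    CODON_INDEX,
    CODONS,
    DEFAULT_PREFERRED_CODONS,
    MISSING,
    code_table,
    codon_pair_differences,
    codon_site_counts,
    encode_codons,
    ng86_tables,
    synonymous_families,
)

__all__ = [
    "CodonAlignment",
    "PairwiseDivergence",
    "GroupDivergenceSummary",
    "CbiResult",
    "prepare_codon_alignment",
    "identity_filter",
    "codon_sites",
    "codon_differences",
    "ng86",
    "group_divergence",
    "pairwise_divergence_table",
    "cbi",
]

GAP_CHARS = frozenset("-")


@dataclass
class CodonAlignment:
    """An in-frame nucleotide alignment with per-sequence group labels.

    ``groups`` maps each label to a group name (typically the species); rows
    are equal-length strings over {A,C,G,T,-,N}; length divisible by 3.
    """

    labels: list[str]
    rows: list[str]
    groups: dict[str, str] = field(default_factory=dict)
    genetic_code: int = 1

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")
        if not self.rows:
            raise ValueError("empty alignment")
        length = len(self.rows[0])
        if any(len(r) != length for r in self.rows):
            raise ValueError("rows have unequal lengths")
        if length % 3:
            raise ValueError("alignment length not divisible by 3")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]

    def labels_in_group(self, group: str) -> list[str]:
        return [lb for lb in self.labels if self.groups.get(lb) == group]

    def codon_matrix(self) -> np.ndarray:
        """(n_seq, n_codons) codon-index matrix; stops/gaps/ambiguity -> 64."""
        return np.vstack([encode_codons(r, self.genetic_code) for r in self.rows])

    @classmethod
    def from_fasta(cls, path, groups: dict[str, str] | None = None,
                   genetic_code: int = 1,
                   header_groups: bool = True) -> "CodonAlignment":
        """Read an aligned FASTA; with ``header_groups`` labels shaped
        ``species|copy`` assign the species as the group."""
        labels, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            rows.append(str(rec.seq).upper())
        if groups is None and header_groups:
            groups = {lb: lb.split("|")[0] for lb in labels}
        return cls(labels, rows, groups or {})

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for lb, row in zip(self.labels, self.rows):
                fh.write(f">{lb}\n{row}\n")


@dataclass
class PairwiseDivergence:
    label_a: str
    label_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    codons_compared: int
    defined: bool


@dataclass
class GroupDivergenceSummary:
    group_a: str
    group_b: str
    mean_Ks: float
    sd_Ks: float
    mean_Ka: float
    sd_Ka: float
    n_pairs: int
    n_undefined: int = 0


@dataclass
class CbiResult:
    N_total: int
    N_opt: int
    N_ran: float
    cbi: float | None


def prepare_codon_alignment(raw: CodonAlignment) -> CodonAlignment:
    """Apply the analysis alignment rules: complete deletion of every codon
    column containing a gap in any row, then per-row masking of stop codons
    as NNN (missing). Idempotent."""
    _, stops = code_table(raw.genetic_code)
    keep: list[int] = []
    for k in range(raw.n_codons):
        if all(not (GAP_CHARS & set(row[3 * k:3 * k + 3])) for row in raw.rows):
            keep.append(k)
    new_rows = []
    for row in raw.rows:
        codons = []
        for k in keep:
            codon = row[3 * k:3 * k + 3]
            codons.append("NNN" if codon in stops else codon)
        new_rows.append("".join(codons))
    return CodonAlignment(list(raw.labels), new_rows, dict(raw.groups),
                          raw.genetic_code)


_IDENTITY_ALIGNER: PairwiseAligner | None = None


def _identity_aligner() -> PairwiseAligner:
    # Needleman-Wunsch with gaps expensive relative to mismatches so that
    # unrelated sequence cannot inflate identity by gapping mismatches out
    # of the non-gap columns.
    global _IDENTITY_ALIGNER
    if _IDENTITY_ALIGNER is None:
        a = PairwiseAligner()
        a.mode = "global"
        a.match_score = 1.0
        a.mismatch_score = -1.0
        a.open_gap_score = -10.0
        a.extend_gap_score = -5.0
        _IDENTITY_ALIGNER = a
    return _IDENTITY_ALIGNER


def global_identity(seq_a: str, seq_b: str) -> float:
    """Matches / aligned non-gap columns under global alignment."""
    seq_a = seq_a.upper().replace("-", "")
    seq_b = seq_b.upper().replace("-", "")
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aln = _identity_aligner().align(seq_a, seq_b)[0]
    a_row, b_row = str(aln[0]), str(aln[1])
    matches = cols = 0
    for x, y in zip(a_row, b_row):
        if x == "-" or y == "-":
            continue
        cols += 1
        matches += x == y
    return matches / cols if cols else 0.0


def identity_filter(sequences: dict[str, str], reference: str,
                    threshold: float = 0.5):
    """Remove sequences whose global nucleotide identity to the reference is
    strictly below ``threshold``; identity exactly at threshold is retained.

    Returns (retained: dict, report: dict label -> identity).
    """
    if not sequences:
        raise ValueError("no sequences to filter")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    report = {lb: global_identity(s, reference) for lb, s in sequences.items()}
    retained = {lb: sequences[lb] for lb, ident in report.items()
                if ident >= threshold}
    return retained, report


def codon_sites(codon: str, code_id: int = 1,
                stop_rule: str = "nonsynonymous"):
    """NG86 (synonymous, nonsynonymous) site counts for one codon, or None
    for codons containing ambiguity/gap characters."""
    codon = codon.upper()
    if any(ch not in "ACGT" for ch in codon) or len(codon) != 3:
        return None
    return codon_site_counts(codon, code_id, stop_rule)


def codon_differences(a: str, b: str, code_id: int = 1):
    """Pathway-averaged (sd, nd) between two codons; None when all mutational
    pathways pass through stop codons."""
    return codon_pair_differences(a.upper(), b.upper(), code_id)


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86(seq_a: str, seq_b: str, code_id: int = 1,
         stop_rule: str = "nonsynonymous",
         label_a: str = "a", label_b: str = "b") -> PairwiseDivergence:
    """Nei–Gojobori divergence between two prepared in-frame sequences.

    Sites are averaged over the two sequences; codons missing (N or stop) in
    either sequence, or whose every mutational pathway crosses a stop, are
    skipped pairwise. Ks/Ka carry the Jukes–Cantor multiple-hit correction
    and are None (``defined=False``) at or beyond the correction boundary
    pS >= 3/4 (resp. pN).
    """
    ca = encode_codons(seq_a, code_id)
    cb = encode_codons(seq_b, code_id)
    if ca.shape != cb.shape:
        raise ValueError("sequences differ in length")
    t = ng86_tables(code_id, stop_rule)
    ok = (ca < MISSING) & (cb < MISSING)
    ok[ok] = t["valid_pair"][ca[ok], cb[ok]]
    if not ok.any():
        raise ValueError("zero comparable codons")
    ia, ib = ca[ok], cb[ok]
    S = 0.5 * (t["s_sites"][ia] + t["s_sites"][ib]).sum()
    N = 0.5 * (t["n_sites"][ia] + t["n_sites"][ib]).sum()
    Sd = t["sd"][ia, ib].sum()
    Nd = t["nd"][ia, ib].sum()
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = _jc_correct(pS)
    Ka = _jc_correct(pN)
    return PairwiseDivergence(label_a, label_b, S, N, Sd, Nd, pS, pN, Ks, Ka,
                              int(ok.sum()), Ks is not None and Ka is not None)


def _group_pairs(alignment: CodonAlignment, group_a: str, group_b: str):
    la = alignment.labels_in_group(group_a)
    lb = alignment.labels_in_group(group_b)
    if not la or not lb:
        raise ValueError(f"empty group among ({group_a!r}, {group_b!r})")
    if group_a == group_b:
        return [(la[i], la[j]) for i in range(len(la))
                for j in range(i + 1, len(la))]
    return [(x, y) for x in la for y in lb]


def group_divergence(alignment: CodonAlignment, group_a: str, group_b: str,
                     stop_rule: str = "nonsynonymous") -> GroupDivergenceSummary:
    """Mean ± sample SD of NG86 Ks and Ka over all pairs between two groups
    (unordered within-group pairs when ``group_a == group_b``); pairs with an
    undefined correction are excluded and counted."""
    pairs = _group_pairs(alignment, group_a, group_b)
    ks_vals, ka_vals, undef = [], [], 0
    for x, y in pairs:
        d = ng86(alignment.row(x), alignment.row(y), alignment.genetic_code,
                 stop_rule, x, y)
        if d.defined:
            ks_vals.append(d.Ks)
            ka_vals.append(d.Ka)
        else:
            undef += 1
    if not ks_vals:
        raise ValueError("no defined pairs between groups")
    ks = np.asarray(ks_vals)
    ka = np.asarray(ka_vals)
    sd_ks = float(ks.std(ddof=1)) if len(ks) > 1 else 0.0
    sd_ka = float(ka.std(ddof=1)) if len(ka) > 1 else 0.0
    return GroupDivergenceSummary(group_a, group_b, float(ks.mean()), sd_ks,
                                  float(ka.mean()), sd_ka, len(ks_vals), undef)


def pairwise_divergence_table(alignment: CodonAlignment,
                              stop_rule: str = "nonsynonymous"):
    """All unordered pairwise NG86 results, as a list of PairwiseDivergence."""
    out = []
    for i in range(len(alignment.labels)):
        for j in range(i + 1, len(alignment.labels)):
            out.append(ng86(alignment.rows[i], alignment.rows[j],
                            alignment.genetic_code, stop_rule,
                            alignment.labels[i], alignment.labels[j]))
    return out


def cbi(coding_sequence: str, preferred_codons=DEFAULT_PREFERRED_CODONS,
        code_id: int = 1) -> CbiResult:
    """Codon bias index of one in-frame sequence.

    CBI = (N_opt - N_ran) / (N_total - N_ran) where N_ran is the preferred
    count expected under uniform synonymous usage. Single-codon amino acids
    (Met, Trp) and stop codons are excluded from all counts. CBI is 0 at no
    bias, 1 when every counted codon is the preferred one, and None when the
    sequence is degenerate (N_total = N_ran).
    """
    fams = synonymous_families(code_id)
    aa_of = {}
    fam_size = {}
    for aa_letter, codons in fams.items():
        for c in codons:
            aa_of[c] = aa_letter
        fam_size[aa_letter] = len(codons)
    preferred = {c.upper() for c in preferred_codons}
    per_family = {}
    for aa_letter, codons in fams.items():
        chosen = [c for c in codons if c in preferred]
        if len(chosen) > 1:
            raise ValueError(f"multiple preferred codons for {aa_letter}")
        per_family[aa_letter] = chosen[0] if chosen else None

    seq = coding_sequence.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    n_total = n_opt = 0
    n_ran = 0.0
    for k in range(0, len(seq), 3):
        codon = seq[k:k + 3]
        aa_letter = aa_of.get(codon)
        if aa_letter is None:  # Met, Trp, stops, ambiguity
            continue
        n_total += 1
        n_ran += 1.0 / fam_size[aa_letter]
        if codon == per_family[aa_letter]:
            n_opt += 1
    if n_total == 0 or math.isclose(n_total, n_ran):
        return CbiResult(n_total, n_opt, n_ran, None)
    return CbiResult(n_total, n_opt, n_ran, (n_opt - n_ran) / (n_total - n_ran))
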