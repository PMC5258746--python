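"""Structural annotation of putative full-length LTR retroelements.

Covers the features used to characterize a Ty1/copia element: the LTR pair
(found by exact k-mer seeding between the terminal thirds plus greedy
X-drop extension, boundaries snapped to the canonical TG...CA termini),
the primer-binding site (reverse complement of a tRNA 3' tail just
downstream of the 5' LTR), the polypurine tract (purine-rich window just
upstream of the 3' LTR), IUPAC cis-motif scanning, forward-frame ORF
finding, and global amino-acid identity between elements.

Coordinates are 0-based half-open throughout; GFF3 export converts to
1-based closed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from ._genetics import code_table

__all__ = [
    "ElementAnnotation",
    "MotifTable",
    "find_ltr_pair",
    "annotate_priming_sites",
    "scan_motifs",
    "longest_orf",
    "aa_identity",
    "annotate_element",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

#: tRNA 3'-end tails commonly priming minus-strand synthesis; the PBS is the
#: reverse complement of such a tail. Key = tRNA name.
DEFAULT_TRNA_TAILS = {
    "tRNA-Met(i)": "AGGCTCTGATACCA",  # initiator Met: PBS TGGTATCAGAGCCT
    "tRNA-Met": "TGGCGCCCAACGTGGGGCTCGAACCCACGACCT"[-14:],
}


@dataclass
class MotifTable:
    """Named IUPAC motifs (promoter/cis-regulatory elements)."""

    entries: list[tuple[str, str, str, str]]  # (name, pattern, category, note)

    def __post_init__(self) -> None:
        seen = set()
        for name, pattern, *_ in self.entries:
            if not pattern:
                raise ValueError(f"empty pattern for motif {name!r}")
            bad = set(pattern.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC characters {bad} in {name!r}")
            key = (name, pattern.upper())
            if key in seen:
                raise ValueError(f"duplicate motif {key}")
            seen.add(key)

    @classmethod
    def from_tsv(cls, path) -> "MotifTable":
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                name, pattern = parts[0], parts[1]
                category = parts[2] if len(parts) > 2 else ""
                note = parts[3] if len(parts) > 3 else ""
                if name.lower() in ("name", "motif"):  # header row
                    continue
                entries.append((name, pattern, category, note))
        return cls(entries)


@dataclass
class ElementAnnotation:
    length: int
    ltr5: tuple[int, int] | None
    ltr3: tuple[int, int] | None
    ltr_identity: float | None
    termini_ok: bool
    pbs: dict | None
    ppt: dict | None
    orfs: list[dict] = field(default_factory=list)
    motif_counts: dict[str, int] = field(default_factory=dict)

    def to_gff3(self, seqid: str = "element") -> str:
        """GFF3 text (1-based closed coordinates)."""
        lines = ["##gff-version 3"]

        def row(ftype, start, end, attrs):
            lines.append("\t".join([seqid, "copiaht", ftype, str(start + 1),
                                    str(end), ".", "+", ".", attrs]))

        if self.ltr5:
            row("long_terminal_repeat", *self.ltr5, "ID=LTR5")
        if self.ltr3:
            row("long_terminal_repeat", *self.ltr3, "ID=LTR3")
        if self.pbs:
            row("primer_binding_site", *self.pbs["interval"],
                f"ID=PBS;tRNA={self.pbs.get('trna', '')}")
        if self.ppt:
            row("polypurine_tract", *self.ppt["interval"], "ID=PPT")
        for k, orf in enumerate(self.orfs):
            row("open_reading_frame", *orf["interval"],
                f"ID=ORF{k + 1};frame={orf['frame']}")
        return "\n".join(lines) + "\n"


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _xdrop_extend(seq: str, i0: int, i1: int, j0: int, j1: int,
                  match: int = 1, mismatch: int = -2, xdrop: int = 10):
    """Gapless extension of the diagonal-matched blocks [i0,i1)/[j0,j1)
    outward in both directions with an X-drop stop."""
    # left
    best = score = 0
    best_off = 0
    off = 0
    while i0 - off - 1 >= 0 and j0 - off - 1 >= 0:
        off += 1
        score += match if seq[i0 - off] == seq[j0 - off] else mismatch
        if score > best:
            best, best_off = score, off
        if best - score > xdrop:
            break
    i0 -= best_off
    j0 -= best_off
    # right
    best = score = 0
    best_off = 0
    off = 0
    n = len(seq)
    while i1 + off < j0 and j1 + off < n:  # 5' copy must not run into 3' copy
        score += match if seq[i1 + off] == seq[j1 + off] else mismatch
        off += 1
        if score > best:
            best, best_off = score, off
        if best - score > xdrop:
            break
    i1 += best_off
    j1 += best_off
    return i0, i1, j0, j1


def _interval_identity(a: str, b: str) -> float:
    if len(a) == len(b):
        return sum(x == y for x, y in zip(a, b)) / len(a) if a else 0.0
    return aa_identity(a, b) / 100.0  # general global-alignment fallback


def find_ltr_pair(sequence: str, min_len: int = 100,
                  min_identity: float = 0.7, k: int = 15,
                  terminus_window: int = 20):
    """Locate the 5'/3' LTR pair of an element sequence.

    Seeds exact ``k``-mer matches between the terminal thirds, picks the
    best diagonal band, extends it greedily (gapless X-drop), and snaps the
    boundaries to the nearest TG...CA frame within ``terminus_window`` bp
    when one exists. Returns (ltr5, ltr3, identity) with 0-based half-open
    intervals, or None when no pair passes the thresholds.
    """
    seq = sequence.upper()
    n = len(seq)
    if n <= 2 * min_len:
        raise ValueError("sequence shorter than twice min_len")
    third = n // 3
    prefix_end = third
    suffix_start = 2 * third

    kmers: dict[str, list[int]] = {}
    for i in range(prefix_end - k + 1):
        kmers.setdefault(seq[i:i + k], []).append(i)
    diagonals: dict[int, list[tuple[int, int]]] = {}
    for j in range(suffix_start, n - k + 1):
        for i in kmers.get(seq[j:j + k], ()):
            diagonals.setdefault(j - i, []).append((i, j))
    if not diagonals:
        return None

    # merge nearby diagonals into bands and score by seed coverage
    band = 20
    scored = []
    for d, hits in diagonals.items():
        cover = set()
        for i, _ in hits:
            cover.update(range(i, i + k))
        scored.append((len(cover), d, hits))
    # group diagonals within `band` of the best one
    scored.sort(reverse=True)
    _, d0, _ = scored[0]
    hits = [h for cov, d, hh in scored if abs(d - d0) <= band for h in hh]
    i0 = min(i for i, _ in hits)
    i1 = max(i for i, _ in hits) + k
    j0 = min(j for _, j in hits)
    j1 = max(j for _, j in hits) + k
    i0, i1, j0, j1 = _xdrop_extend(seq, i0, i1, j0, j1)

    # snap to TG...CA termini when present nearby
    def snap_start(pos):
        cands = [p for p in range(max(0, pos - terminus_window),
                                  min(n - 1, pos + terminus_window) + 1)
                 if seq[p:p + 2] == "TG"]
        return min(cands, key=lambda p: abs(p - pos)) if cands else pos

    def snap_end(pos):  # pos is exclusive end; CA occupies [pos-2, pos)
        cands = [p for p in range(max(2, pos - terminus_window),
                                  min(n, pos + terminus_window) + 1)
                 if seq[p - 2:p] == "CA"]
        return min(cands, key=lambda p: abs(p - pos)) if cands else pos

    s5, e5 = snap_start(i0), snap_end(i1)
    s3, e3 = snap_start(j0), snap_end(j1)
    if e5 - s5 < min_len or e3 - s3 < min_len or e5 > s3:
        return None
    identity = _interval_identity(seq[s5:e5], seq[s3:e3])
    if identity < min_identity:
        return None
    return (s5, e5), (s3, e3), identity


def termini_ok(sequence: str, ltr5, ltr3) -> bool:
    seq = sequence.upper()
    return all(seq[s:s + 2] == "TG" and seq[e - 2:e] == "CA"
               for s, e in (ltr5, ltr3))


def annotate_priming_sites(sequence: str, ltr5, ltr3,
                           trna_tails: dict[str, str] | None = None,
                           min_match: int = 12, max_offset: int = 20,
                           ppt_min_len: int = 10, ppt_window: int = 30,
                           ppt_purine_frac: float = 0.8):
    """Locate the PBS (reverse complement of a tRNA 3' tail within
    ``max_offset`` bp downstream of the 5' LTR) and the PPT (best
    purine-rich window within ``ppt_window`` bp upstream of the 3' LTR).
    Absent sites are reported as None, never as errors.
    """
    seq = sequence.upper()
    trna_tails = trna_tails if trna_tails is not None else DEFAULT_TRNA_TAILS
    ltr5_end = ltr5[1]
    ltr3_start = ltr3[0]

    pbs = None
    for trna, tail in trna_tails.items():
        target = _revcomp(tail.upper())
        # longest suffix-anchored match: the PBS pairs the tRNA 3' end, so
        # score candidate placements by longest exact block >= min_match
        for mlen in range(len(target), min_match - 1, -1):
            probe = target[:mlen]
            region = seq[ltr5_end:ltr5_end + max_offset + mlen]
            pos = region.find(probe)
            if pos >= 0:
                cand = {"interval": (ltr5_end + pos, ltr5_end + pos + mlen),
                        "offset": pos, "trna": trna, "match_length": mlen,
                        "sequence": probe}
                if pbs is None or mlen > pbs["match_length"]:
                    pbs = cand
                break

    ppt = None
    region_start = max(0, ltr3_start - ppt_window)
    region = seq[region_start:ltr3_start]
    best = None
    for length in range(len(region), ppt_min_len - 1, -1):
        for s in range(0, len(region) - length + 1):
            window = region[s:s + length]
            frac = sum(ch in "AG" for ch in window) / length
            if frac >= ppt_purine_frac:
                score = (length, frac)
                if best is None or score > best[0]:
                    best = (score, s, length)
        if best is not None:
            break  # longest qualifying window wins
    if best is not None:
        _, s, length = best
        ppt = {"interval": (region_start + s, region_start + s + length),
               "sequence": region[s:s + length],
               "purine_fraction": sum(ch in "AG" for ch in region[s:s + length]) / length}
    return pbs, ppt


def _iupac_regex(pattern: str) -> re.Pattern:
    return re.compile("".join(IUPAC[ch] for ch in pattern.upper()))


def scan_motifs(sequence: str, table: MotifTable,
                strands: str = "forward") -> dict[str, int]:
    """Count (possibly overlapping) IUPAC motif matches, case-insensitive.

    ``strands``: 'forward' (default) or 'both' (adds reverse-complement
    matches).
    """
    seq = sequence.upper()
    targets = [seq]
    if strands == "both":
        targets.append(_revcomp(seq))
    elif strands != "forward":
        raise ValueError("strands must be 'forward' or 'both'")
    counts: dict[str, int] = {}
    for name, pattern, *_ in table.entries:
        rx = re.compile("(?=(" + _iupac_regex(pattern).pattern + "))")
        total = sum(len(rx.findall(tgt)) for tgt in targets)
        counts[name] = counts.get(name, 0) + total
    return counts


def longest_orf(sequence: str, code_id: int = 1,
                min_len: int = 300) -> list[dict]:
    """Forward-frame ORFs from the first ATG of each start/stop pairing,
    length >= min_len nt, longest first; nested starts sharing a stop are
    suppressed (the outermost is kept)."""
    seq = sequence.upper()
    _, stops = code_table(code_id)
    orfs = []
    for frame in range(3):
        start = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos:pos + 3]
            if codon in stops:
                if start is not None and pos + 3 - start >= min_len:
                    orfs.append({"interval": (start, pos + 3), "frame": frame,
                                 "length": pos + 3 - start})
                start = None
            elif codon == "ATG" and start is None:
                start = pos
        if start is not None and len(seq) - start >= min_len:
            # open-ended ORF running off the sequence end
            end = start + (len(seq) - start) // 3 * 3
            orfs.append({"interval": (start, end), "frame": frame,
                         "length": end - start, "partial": True})
    orfs.sort(key=lambda o: -o["length"])
    return orfs


_AA_ALIGNER: PairwiseAligner | None = None


def _aa_aligner() -> PairwiseAligner:
    # identity scoring with affine gaps; documented defaults
    global _AA_ALIGNER
    if _AA_ALIGNER is None:
        a = PairwiseAligner()
        a.mode = "global"
        a.match_score = 1.0
        a.mismatch_score = 0.0
        a.open_gap_score = -2.0
        a.extend_gap_score = -0.5
        _AA_ALIGNER = a
    return _AA_ALIGNER


def aa_identity(protein_a: str, protein_b: str) -> float:
    """Percent identity (matches / aligned non-gap columns x 100) under
    global alignment with match +1, mismatch 0, gap open -2, extend -0.5."""
    if not protein_a or not protein_b:
        raise ValueError("empty sequence")
    aln = _aa_aligner().align(protein_a.upper(), protein_b.upper())[0]
    a_row, b_row = str(aln[0]), str(aln[1])
    matches = cols = 0
    for x, y in zip(a_row, b_row):
        if x == "-" or y == "-":
            continue
        cols += 1
        matches += x == y
    return matches / cols * 100.0 if cols else 0.0


def annotate_element(sequence: str, motif_table: MotifTable | None = None,
                     trna_tails: dict[str, str] | None = None,
                     min_ltr_len: int = 100, min_ltr_identity: float = 0.7,
                     orf_min_len: int = 300) -> ElementAnnotation:
    """Full structural annotation of one element sequence."""
    seq = sequence.upper()
    pair = find_ltr_pair(seq, min_ltr_len, min_ltr_identity)
    ltr5 = ltr3 = None
    identity = None
    tok = False
    pbs = ppt = None
    motif_counts: dict[str, int] = {}
    if pair is not None:
        ltr5, ltr3, identity = pair
        tok = termini_ok(seq, ltr5, ltr3)
        pbs, ppt = annotate_priming_sites(seq, ltr5, ltr3, trna_tails)
        if motif_table is not None:
            motif_counts = scan_motifs(seq[ltr5[0]:ltr5[1]], motif_table)
    orfs = longest_orf(seq, min_len=orf_min_len)
    return ElementAnnotation(len(seq), ltr5, ltr3, identity, tok, pbs, ppt,
                             orfs, motif_counts)
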