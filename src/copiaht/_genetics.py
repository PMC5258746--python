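"""Genetic-code constants and precomputed Nei–Gojobori lookup tables.

Everything here is derived once, at import, from Biopython's codon tables:
per-codon synonymous/nonsynonymous site fractions and per-codon-pair
pathway-averaged difference counts. The rest of the package works on codon
*indices* (0..63, 64 = missing) so that pairwise statistics reduce to table
lookups and numpy sums.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

NUCS = "TCAG"
CODONS = [a + b + c for a in NUCS for b in NUCS for c in NUCS]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
MISSING = 64  # sentinel codon index for gapped/ambiguous/stop-masked codons

STOP_RULES = ("nonsynonymous", "excluded")


@lru_cache(maxsize=None)
def code_table(code_id: int = 1):
    """Return (aa_by_codon: dict, stops: frozenset) for an NCBI table id."""
    table = unambiguous_dna_by_id[code_id]
    aa = dict(table.forward_table)
    stops = frozenset(table.stop_codons)
    for s in stops:
        aa[s] = "*"
    return aa, stops


def translate_codon(codon: str, code_id: int = 1) -> str:
    aa, _ = code_table(code_id)
    return aa.get(codon.upper(), "X")


@lru_cache(maxsize=None)
def is_stop_array(code_id: int = 1) -> np.ndarray:
    aa, stops = code_table(code_id)
    return np.array([CODONS[i] in stops for i in range(64)], dtype=bool)


@lru_cache(maxsize=None)
def aa_index_array(code_id: int = 1) -> np.ndarray:
    """Amino acid (as ord of letter; '*' for stops) per codon index."""
    aa, _ = code_table(code_id)
    return np.array([ord(aa[c]) for c in CODONS], dtype=np.int16)


def single_nt_neighbours(codon: str):
    """Yield (position, mutant codon) for the 9 single-nucleotide mutants."""
    for pos in range(3):
        for nt in NUCS:
            if nt != codon[pos]:
                yield pos, codon[:pos] + nt + codon[pos + 1:]


def codon_site_counts(codon: str, code_id: int = 1,
                      stop_rule: str = "nonsynonymous") -> tuple[float, float]:
    """NG86 fractional synonymous/nonsynonymous site counts for one codon.

    Under ``stop_rule='nonsynonymous'`` mutations to stop codons count as
    nonsynonymous changes (denominator 3 per position, s + n = 3); under
    ``'excluded'`` they are dropped from the denominator (PAML-style), with
    the position renormalised so s + n = 3 still holds.
    """
    aa, stops = code_table(code_id)
    if codon in stops:
        raise ValueError(f"stop codon {codon} has no site counts")
    if stop_rule not in STOP_RULES:
        raise ValueError(f"unknown stop_rule {stop_rule!r}")
    s = 0.0
    for pos in range(3):
        syn = 0
        counted = 0
        for nt in NUCS:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1:]
            if mut in stops:
                if stop_rule == "nonsynonymous":
                    counted += 1
                continue
            counted += 1
            if aa[mut] == aa[codon]:
                syn += 1
        s += syn / counted if counted else 0.0
    return s, 3.0 - s


def codon_pair_differences(a: str, b: str, code_id: int = 1):
    """Pathway-averaged (sd, nd) between two non-stop codons, or None.

    Averages the per-step synonymous/nonsynonymous classification over all
    orderings of the single-nucleotide steps, excluding orderings that pass
    through a stop codon. Returns None when every pathway is blocked.
    """
    aa, stops = code_table(code_id)
    if a in stops or b in stops:
        raise ValueError("stop codons cannot be compared")
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    sd_total = nd_total = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        cur = a
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in stops:
                ok = False
                break
            if aa[cur] == aa[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            sd_total += sd
            nd_total += nd
            n_paths += 1
    if n_paths == 0:
        return None
    return sd_total / n_paths, nd_total / n_paths


@lru_cache(maxsize=None)
def ng86_tables(code_id: int = 1, stop_rule: str = "nonsynonymous"):
    """Precomputed NG86 arrays keyed by codon index.

    Returns a dict with:
      ``s_sites``, ``n_sites``  (64,) site fractions (NaN for stops)
      ``sd``, ``nd``            (64, 64) pathway-averaged differences
      ``valid_pair``            (64, 64) bool, False where all pathways are
                                stop-blocked or either codon is a stop
    """
    aa, stops = code_table(code_id)
    s_sites = np.full(64, np.nan)
    n_sites = np.full(64, np.nan)
    for i, codon in enumerate(CODONS):
        if codon in stops:
            continue
        s, n = codon_site_counts(codon, code_id, stop_rule)
        s_sites[i] = s
        n_sites[i] = n
    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    valid = np.zeros((64, 64), dtype=bool)
    for i, a in enumerate(CODONS):
        if a in stops:
            continue
        for j, b in enumerate(CODONS):
            if b in stops:
                continue
            res = codon_pair_differences(a, b, code_id)
            if res is None:
                continue
            sd[i, j], nd[i, j] = res
            valid[i, j] = True
    return {"s_sites": s_sites, "n_sites": n_sites,
            "sd": sd, "nd": nd, "valid_pair": valid}


def encode_codons(seq: str, code_id: int = 1) -> np.ndarray:
    """Encode an in-frame nucleotide string as codon indices.

    Codons containing gaps, ambiguity characters, or translating to a stop
    are encoded as MISSING (64) and skipped by all pairwise statistics.
    """
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    _, stops = code_table(code_id)
    out = np.full(len(seq) // 3, MISSING, dtype=np.int16)
    for k in range(0, len(seq), 3):
        codon = seq[k:k + 3]
        idx = CODON_INDEX.get(codon)
        if idx is not None and codon not in stops:
            out[k // 3] = idx
    return out


def decode_codons(idx: np.ndarray) -> str:
    return "".join(CODONS[i] if i < 64 else "NNN" for i in idx)


# --- synonymous-family bookkeeping for the codon bias index -----------------

@lru_cache(maxsize=None)
def synonymous_families(code_id: int = 1) -> dict[str, tuple[str, ...]]:
    """aa letter -> codons, restricted to families with >= 2 codons.

    Met and Trp (single-codon families in the standard code) and stops are
    excluded, matching the usual CBI counting convention.
    """
    aa, stops = code_table(code_id)
    fam: dict[str, list[str]] = {}
    for codon in CODONS:
        if codon in stops:
            continue
        fam.setdefault(aa[codon], []).append(codon)
    return {a: tuple(cs) for a, cs in fam.items() if len(cs) >= 2}


#: A generic dicot-style preferred-codon set: one codon per multi-codon
#: family, following the majority usage of highly expressed plant nuclear
#: genes. Real analyses should supply the table appropriate to their taxon.
DEFAULT_PREFERRED_CODONS = frozenset({
    "GCT",  # Ala
    "CGT",  # Arg
    "AAC",  # Asn
    "GAT",  # Asp
    "TGC",  # Cys
    "CAA",  # Gln
    "GAA",  # Glu
    "GGT",  # Gly
    "CAT",  # His
    "ATT",  # Ile
    "CTT",  # Leu
    "AAG",  # Lys
    "TTC",  # Phe
    "CCT",  # Pro
    "TCT",  # Ser
    "ACT",  # Thr
    "TAC",  # Tyr
    "GTT",  # Val
})
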