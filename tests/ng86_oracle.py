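"""Independent brute-force Nei–Gojobori oracle used by the tests.

Deliberately written against Biopython's translation only, sharing no code
with the package implementation: explicit enumeration of the nine
single-nucleotide mutants per codon for site counting, explicit enumeration
of all mutational orderings for difference counting, and the Jukes–Cantor
correction in closed form.
"""

from functools import lru_cache
from itertools import permutations
from math import log

from Bio.Seq import Seq

BASES = "ACGT"


@lru_cache(maxsize=None)
def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_sites(codon: str, stop_rule: str = "nonsynonymous"):
    aa0 = _aa(codon)
    assert aa0 != "*"
    s = 0.0
    for pos in range(3):
        syn = 0
        denom = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if _aa(mut) == "*":
                if stop_rule == "nonsynonymous":
                    denom += 1
                continue
            denom += 1
            if _aa(mut) == aa0:
                syn += 1
        s += syn / denom if denom else 0.0
    return s, 3.0 - s


def oracle_differences(a: str, b: str):
    """Pathway-averaged (sd, nd); None when every ordering hits a stop."""
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    totals = []
    for order in permutations(positions):
        cur, sd, nd = a, 0, 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if _aa(nxt) == "*":
                blocked = True
                break
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            totals.append((sd, nd))
    if not totals:
        return None
    return (sum(t[0] for t in totals) / len(totals),
            sum(t[1] for t in totals) / len(totals))


def oracle_ng86(seq_a: str, seq_b: str, stop_rule: str = "nonsynonymous"):
    """Full brute-force NG86: returns dict with S, N, Sd, Nd, pS, pN, Ks, Ka
    or None values where the correction is undefined."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    S = N = Sd = Nd = 0.0
    compared = 0
    for k in range(0, len(seq_a), 3):
        ca, cb = seq_a[k:k + 3].upper(), seq_b[k:k + 3].upper()
        if any(ch not in BASES for ch in ca + cb):
            continue
        if _aa(ca) == "*" or _aa(cb) == "*":
            continue
        diffs = oracle_differences(ca, cb)
        if diffs is None:
            continue
        sa, na = oracle_sites(ca, stop_rule)
        sb, nb = oracle_sites(cb, stop_rule)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        Sd += diffs[0]
        Nd += diffs[1]
        compared += 1
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0

    def jc(p):
        return None if p >= 0.75 else -0.75 * log(1 - 4 * p / 3)

    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "pS": pS, "pN": pN,
            "Ks": jc(pS), "Ka": jc(pN), "codons": compared}
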