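"""Horizontal-transfer decision procedure and molecular-clock dating.

Three lines of evidence are combined into a verdict for a taxon pair:

1. synonymous divergence of the element between the taxa is comparable to
   (not substantially greater than) that of constrained host genes — a
   codon-resampling bootstrap test against a comparability constant c;
2. the element tree is incongruent with the species tree in a way that
   implicates the pair;
3. the element's codon bias is lower than every host gene's, ruling out
   selection on codon usage as the cause of the low divergence.

Transfer and amplification-burst times come from the strict molecular clock
T = Ks / (2 r): divergence accumulates along both lineages, so pairwise Ks
is twice the per-lineage path r·T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._genetics import MISSING, ng86_tables
from .codon import (
    CbiResult,
    CodonAlignment,
    GroupDivergenceSummary,
    _group_pairs,
    group_divergence,
)

__all__ = [
    "ClockRate",
    "KsComparison",
    "HTCall",
    "clock_date",
    "ks_comparison",
    "cbi_control",
    "call_ht",
]

NUCLEAR_TE_RATE = 1.3e-8   # synonymous substitutions / syn site / year
CHLOROPLAST_RATE = 1.3e-9  # rbcL-style chloroplast clock


@dataclass
class ClockRate:
    r: float
    label: str = "nuclear/TE"

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("clock rate must be positive")


def clock_date(ks: float, rate: ClockRate | float) -> float:
    """Divergence time in Mya: T = Ks / (2 r) / 1e6, two decimals."""
    r = rate.r if isinstance(rate, ClockRate) else float(rate)
    if r <= 0:
        raise ValueError("clock rate must be positive")
    if ks < 0:
        raise ValueError("negative Ks")
    return round(ks / (2.0 * r) / 1e6, 2)


@dataclass
class KsComparison:
    group_a: str
    group_b: str
    te_summary: GroupDivergenceSummary
    host_summaries: dict[str, GroupDivergenceSummary]
    ratios: dict[str, float]
    p_values: dict[str, float]
    c: float
    alpha: float
    n_boot: int
    passed: bool


def _column_contributions(alignment: CodonAlignment, group_a: str,
                          group_b: str, stop_rule: str = "nonsynonymous"):
    """Per-pair, per-codon-column NG86 contributions for bootstrapping.

    Returns (S, N, Sd, Nd) arrays of shape (n_pairs, n_codons); skipped
    codons contribute zero everywhere.
    """
    t = ng86_tables(alignment.genetic_code, stop_rule)
    cm = alignment.codon_matrix()
    index = {lb: i for i, lb in enumerate(alignment.labels)}
    pairs = _group_pairs(alignment, group_a, group_b)
    n_pairs, n_cod = len(pairs), alignment.n_codons
    S = np.zeros((n_pairs, n_cod))
    N = np.zeros((n_pairs, n_cod))
    Sd = np.zeros((n_pairs, n_cod))
    Nd = np.zeros((n_pairs, n_cod))
    for p, (la, lb) in enumerate(pairs):
        ia, ib = cm[index[la]], cm[index[lb]]
        ok = (ia < MISSING) & (ib < MISSING)
        ok[ok] = t["valid_pair"][ia[ok], ib[ok]]
        S[p, ok] = 0.5 * (t["s_sites"][ia[ok]] + t["s_sites"][ib[ok]])
        N[p, ok] = 0.5 * (t["n_sites"][ia[ok]] + t["n_sites"][ib[ok]])
        Sd[p, ok] = t["sd"][ia[ok], ib[ok]]
        Nd[p, ok] = t["nd"][ia[ok], ib[ok]]
    return S, N, Sd, Nd


def _mean_ks_from_columns(S, Sd, cols) -> float:
    """Mean JC-corrected Ks over pairs for a codon-column subset; undefined
    pairs (saturated or siteless) are dropped; NaN if all drop."""
    s = S[:, cols].sum(axis=1)
    sd = Sd[:, cols].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = np.where(s > 0, sd / np.maximum(s, 1e-300), np.nan)
    ok = np.isfinite(ps) & (ps < 0.75)
    if not ok.any():
        return float("nan")
    ks = -0.75 * np.log(1.0 - 4.0 * ps[ok] / 3.0)
    return float(ks.mean())


def ks_comparison(te_alignment: CodonAlignment,
                  host_alignments: dict[str, CodonAlignment],
                  group_a: str, group_b: str,
                  c: float = 1.5, alpha: float = 0.05,
                  n_boot: int = 200, seed: int = 0,
                  stop_rule: str = "nonsynonymous") -> KsComparison:
    """Bootstrap comparison of element vs host-gene synonymous divergence.

    Horizontal transfer predicts element divergence *comparable to* the
    host genes' (within a factor c); vertical descent of a fast-clock
    element predicts a large excess. For each host gene g the codon-column
    bootstrap estimates p = P*(mean Ks_TE <= c · mean Ks_g); a small p
    (<= alpha) means the element's divergence significantly exceeds the
    comparability band and the comparison fails for that gene. The
    comparison passes when p > alpha for every host gene.
    """
    if not host_alignments:
        raise ValueError("need at least one host gene")
    te_summary = group_divergence(te_alignment, group_a, group_b, stop_rule)
    host_summaries = {g: group_divergence(a, group_a, group_b, stop_rule)
                      for g, a in host_alignments.items()}
    ratios = {g: te_summary.mean_Ks / s.mean_Ks
              for g, s in host_summaries.items()}

    rng = np.random.default_rng(seed)
    S_te, _, Sd_te, _ = _column_contributions(te_alignment, group_a, group_b,
                                              stop_rule)
    host_cols = {g: _column_contributions(a, group_a, group_b, stop_rule)[0:3:2]
                 for g, a in host_alignments.items()}
    n_te = te_alignment.n_codons
    within = {g: 0 for g in host_alignments}
    valid = {g: 0 for g in host_alignments}
    for _ in range(n_boot):
        cols_te = rng.integers(0, n_te, size=n_te)
        ks_te = _mean_ks_from_columns(S_te, Sd_te, cols_te)
        for g, (S_h, Sd_h) in host_cols.items():
            n_h = S_h.shape[1]
            cols_h = rng.integers(0, n_h, size=n_h)
            ks_h = _mean_ks_from_columns(S_h, Sd_h, cols_h)
            if np.isnan(ks_te) or np.isnan(ks_h):
                continue
            valid[g] += 1
            if ks_te <= c * ks_h:
                within[g] += 1
    p_values = {g: (1 + within[g]) / (valid[g] + 1) if valid[g] else 0.0
                for g in host_alignments}
    passed = all(p > alpha for p in p_values.values())
    return KsComparison(group_a, group_b, te_summary, host_summaries,
                        ratios, p_values, c, alpha, n_boot, passed)


def cbi_control(te_cbi: list[CbiResult], host_cbi: list[CbiResult]) -> bool:
    """Pass iff mean element CBI is strictly below every host gene's CBI,
    i.e. codon-usage selection cannot explain the element's low synonymous
    divergence. Ties fail."""
    if not te_cbi or not host_cbi:
        raise ValueError("both CBI lists must be non-empty")
    te_vals = [x.cbi for x in te_cbi]
    host_vals = [x.cbi for x in host_cbi]
    if any(v is None for v in te_vals + host_vals):
        raise ValueError("undefined CBI value")
    return float(np.mean(te_vals)) < min(host_vals)


@dataclass
class HTCall:
    pair: tuple[str, str]
    ks_test_passed: bool
    incongruence_supported: bool
    cbi_control_passed: bool
    verdict: bool
    T_ht: float
    T_burst: float | None = None
    ratios: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "ks_test_passed": self.ks_test_passed,
            "incongruence_supported": self.incongruence_supported,
            "cbi_control_passed": self.cbi_control_passed,
            "verdict": self.verdict,
            "T_ht_mya": self.T_ht,
            "T_burst_mya": self.T_burst,
            "ratios": self.ratios,
            "p_values": self.p_values,
            "warnings": self.warnings,
        }


def call_ht(pair: tuple[str, str], ks_comp: KsComparison,
            incongruence_report, cbi_pass: bool,
            te_clock: ClockRate | float,
            within_recipient_summary: GroupDivergenceSummary | None = None,
            pair_species: set[str] | None = None) -> HTCall:
    """Combine the three evidence lines into a composite verdict and date
    the transfer (between-pair mean Ks) and, when a within-recipient summary
    is supplied, the amplification burst (within-recipient mean Ks)."""
    implicated = set(getattr(incongruence_report, "implicated_species", []))
    check = set(pair_species) if pair_species is not None else set(pair)
    incongruent = bool(getattr(incongruence_report, "incongruent", False)
                       and (implicated & check))
    verdict = ks_comp.passed and incongruent and cbi_pass
    t_ht = clock_date(ks_comp.te_summary.mean_Ks, te_clock)
    t_burst = None
    notes = []
    if within_recipient_summary is not None:
        t_burst = clock_date(within_recipient_summary.mean_Ks, te_clock)
        if t_burst > t_ht:
            msg = (f"burst date {t_burst} Mya is older than transfer date "
                   f"{t_ht} Mya")
            notes.append(msg)
            warnings.warn(msg, stacklevel=2)
    return HTCall(pair, ks_comp.passed, incongruent, cbi_pass, verdict,
                  t_ht, t_burst, dict(ks_comp.ratios), dict(ks_comp.p_values),
                  notes)
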