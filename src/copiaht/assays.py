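"""Deterministic assay arithmetic: qPCR standard curves and copy number,
terminal:internal ratios, 2^-ddCt expression fold change, and SSAP
band-polymorphism percentage.

All internal math is full precision; rounding (half-even, 2 decimals) is
applied only where a reported quantity is defined with it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "BandMatrix",
    "fit_standard_curve",
    "copies_from_ct",
    "terminal_internal_ratio",
    "ddct_fold_change",
    "band_polymorphism",
]


@dataclass
class StandardCurve:
    slope: float
    intercept: float
    r: float  # Pearson correlation of Ct with log10(copies)

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency, 1.0 = perfect doubling."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def ct_at(self, copies: float) -> float:
        return self.slope * np.log10(copies) + self.intercept


@dataclass
class BandMatrix:
    """Samples x bands presence/absence matrix."""

    samples: list[str]
    bands: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (len(self.samples), len(self.bands)):
            raise ValueError("matrix shape does not match labels")
        if not np.isin(self.matrix, [0, 1]).all():
            raise ValueError("band matrix entries must be 0/1")
        if len(self.samples) < 1:
            raise ValueError("need at least one sample")

    @classmethod
    def from_tsv(cls, path) -> "BandMatrix":
        import pandas as pd
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.values.astype(int))


def fit_standard_curve(copies, ct) -> StandardCurve:
    """OLS of Ct on log10(standard copy number); R is the Pearson
    correlation (1.0 by convention for an exact two-point fit)."""
    copies = np.asarray(copies, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if np.any(copies <= 0):
        raise ValueError("copy numbers must be positive")
    x = np.log10(copies)
    if len(np.unique(x)) < 2:
        raise ValueError("need >= 2 distinct dilution points")
    res = stats.linregress(x, ct)
    r = 1.0 if len(x) == 2 else float(res.rvalue)
    return StandardCurve(float(res.slope), float(res.intercept), r)


def copies_from_ct(ct, curve: StandardCurve, template_pg: float = 1.0,
                   aggregate: str = "mean_ct") -> float:
    """Copies per pg template inferred by inverting the standard curve.

    Replicate Ct values are averaged before inversion by default
    (``aggregate='mean_ct'``); ``'mean_copies'`` inverts each replicate and
    averages the copy numbers instead.
    """
    if curve.slope == 0:
        raise ValueError("degenerate standard curve (slope 0)")
    if template_pg <= 0:
        raise ValueError("template mass must be positive")
    ct = np.atleast_1d(np.asarray(ct, dtype=float))
    if aggregate == "mean_ct":
        copies = 10.0 ** ((ct.mean() - curve.intercept) / curve.slope)
    elif aggregate == "mean_copies":
        copies = (10.0 ** ((ct - curve.intercept) / curve.slope)).mean()
    else:
        raise ValueError("aggregate must be 'mean_ct' or 'mean_copies'")
    return float(copies) / template_pg


def _round2(x: float) -> float:
    """Banker's (half-even) rounding to 2 decimals."""
    import decimal
    return float(decimal.Decimal(repr(float(x))).quantize(
        decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_EVEN))


def terminal_internal_ratio(ltr_copies: float, internal_copies: float) -> float:
    """LTR : internal copy-number ratio, 2 decimals; values near 2 with few
    solo LTRs (each intact element carries two LTRs and one internal
    region), inflated well above 2 by solo-LTR accumulation."""
    if internal_copies <= 0:
        raise ValueError("internal copy number must be positive")
    return _round2(ltr_copies / internal_copies)


def ddct_fold_change(ct_target_treated: float, ct_ref_treated: float,
                     ct_target_control: float, ct_ref_control: float) -> float:
    """Relative expression by the 2^-ddCt method."""
    ddct = ((ct_target_treated - ct_ref_treated)
            - (ct_target_control - ct_ref_control))
    return float(2.0 ** (-ddct))


def band_polymorphism(m: BandMatrix) -> float:
    """Percentage of polymorphic bands P%: bands present in at least one
    but not all samples, over bands present in at least one sample; 2
    decimals."""
    if len(m.samples) < 2:
        raise ValueError("need >= 2 samples")
    present = m.matrix.sum(axis=0)
    observed = present > 0
    if not observed.any():
        raise ValueError("no bands present in any sample")
    polymorphic = observed & (present < len(m.samples))
    return _round2(polymorphic.sum() / observed.sum() * 100.0)
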