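"""Replicate-paired hypothesis testing for GP-vs-P comparisons.

The comparison of interest is one-tailed and paired by system: the null
hypothesis is that glycosylated (GP) and deglycosylated (P) values are
identical, the alternative that the deglycosylated values are larger.
With differences d_i = p_i - gp_i,

    t = mean(d) / (sd(d) / sqrt(n)),    df = n - 1,
    p = P(T_df >= t)   (upper tail).

Zero-variance inputs are handled explicitly instead of propagating NaN:
all-zero differences give p = 0.5 (no evidence either way), constant
nonzero differences give p = 0 or 1 by sign; both cases are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["PairedTestResult", "paired_t_one_tailed", "significance_call"]


@dataclass
class PairedTestResult:
    t: float
    df: int
    p_one_tailed: float
    direction: str = "P > GP"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("degrees of freedom must be >= 1")
        if not 0.0 <= self.p_one_tailed <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def paired_t_one_tailed(gp, p) -> PairedTestResult:
    """One-tailed paired t-test of H1: deglycosylated values are larger."""
    gp = np.asarray(gp, dtype=float)
    p = np.asarray(p, dtype=float)
    if gp.shape != p.shape or gp.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = len(gp)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = p - gp
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        mean = d.mean()
        if mean == 0.0:
            return PairedTestResult(t=0.0, df=df, p_one_tailed=0.5, degenerate=True)
        p_val = 0.0 if mean > 0 else 1.0
        t_val = np.inf if mean > 0 else -np.inf
        return PairedTestResult(t=t_val, df=df, p_one_tailed=p_val, degenerate=True)
    t_val = float(d.mean() / (sd / np.sqrt(n)))
    p_val = float(sps.t.sf(t_val, df))
    return PairedTestResult(t=t_val, df=df, p_one_tailed=p_val)


def significance_call(result: PairedTestResult, alpha: float = 0.05) -> bool:
    """Strict comparison against the significance level: p < alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return result.p_one_tailed < alpha
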