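"""Chi-square family for context-effect frequency tables.

Two flavours mirror the two questions asked of the classification
frequencies: a test of homogeneity across all groups with post hoc
inspection of adjusted standardized residuals, and pairwise 2 x 2
tests of independence against the control group using the N-1
correction (Pearson chi-square scaled by (N-1)/N), which keeps the
test calibrated at the modest cell counts of a two-group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import contingency_bf


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    std_residuals: np.ndarray
    residual_p_bonferroni: np.ndarray | None
    n_correction_applied: bool
    bf10: float
    expected: np.ndarray = field(repr=False, default=None)


def _pearson(obs: np.ndarray):
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    if (expected == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return chi2, expected, n


def _adjusted_residuals(obs: np.ndarray, expected: np.ndarray, n: float) -> np.ndarray:
    row_p = obs.sum(axis=1, keepdims=True) / n
    col_p = obs.sum(axis=0, keepdims=True) / n
    return (obs - expected) / np.sqrt(expected * (1 - row_p) * (1 - col_p))


def chi2_homogeneity(table, bf_a: float = 1.0) -> ChiSquareResult:
    """Pearson chi-square of homogeneity with residual post hocs.

    ``table`` is groups x categories counts.  Adjusted standardized
    residuals get two-sided normal p-values Bonferroni-corrected over
    the number of groups (one residual family per category column is
    redundant for two categories, so the family is the group count).
    """
    obs = np.asarray(table, dtype=float)
    chi2, expected, n = _pearson(obs)
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    res = _adjusted_residuals(obs, expected, n)
    fam = obs.shape[0]
    res_p = np.minimum(1.0, fam * 2 * stats.norm.sf(np.abs(res)))
    return ChiSquareResult(
        chi2=chi2,
        df=df,
        p=float(stats.chi2.sf(chi2, df)),
        std_residuals=res,
        residual_p_bonferroni=res_p,
        n_correction_applied=False,
        bf10=contingency_bf(obs, a=bf_a),
        expected=expected,
    )


def chi2_independence_ncorr(table_2x2, bf_a: float = 1.0) -> ChiSquareResult:
    """2 x 2 test of independence with the N-1 correction."""
    obs = np.asarray(table_2x2, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2 x 2 table")
    chi2, expected, n = _pearson(obs)
    chi2_adj = chi2 * (n - 1) / n
    return ChiSquareResult(
        chi2=float(chi2_adj),
        df=1,
        p=float(stats.chi2.sf(chi2_adj, 1)),
        std_residuals=_adjusted_residuals(obs, expected, n),
        residual_p_bonferroni=None,
        n_correction_applied=True,
        bf10=contingency_bf(obs, a=bf_a),
        expected=expected,
    )


def context_table(frequencies: pd.DataFrame, treatment: str) -> pd.DataFrame:
    """Groups x {present, absent} counts of the context effect for one
    treatment condition (healthy controls' single session included)."""
    sub = frequencies[frequencies["treatment"].isin([treatment, "NA"])]
    out = pd.DataFrame(
        {
            "present": sub.set_index("group")["n_context"],
            "absent": sub.set_index("group").apply(
                lambda r: r["n"] - r["n_context"], axis=1
            ),
        }
    )
    return out
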