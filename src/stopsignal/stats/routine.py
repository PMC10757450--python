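"""Routine assumption checks and nonparametric tests, delegated to
scipy's reference implementations and returned in a uniform shape."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    n: int


def routine_tests(data, which: str, *more) -> TestResult:
    """Run a named routine test.

    ``shapiro_wilk(x)``; ``levene(x, y, ...)`` (Brown-Forsythe median
    centring); ``spearman(x, y)``; ``wilcoxon_paired(x, y)``.
    """
    x = np.asarray(data, dtype=float)
    if which == "shapiro_wilk":
        if x.size < 3:
            raise ValueError("Shapiro-Wilk needs n >= 3")
        res = stats.shapiro(x)
        return TestResult("shapiro_wilk", float(res.statistic), float(res.pvalue), x.size)
    if which == "levene":
        groups = [x] + [np.asarray(g, dtype=float) for g in more]
        if len(groups) < 2:
            raise ValueError("Levene needs at least two groups")
        res = stats.levene(*groups, center="median")
        n = sum(g.size for g in groups)
        return TestResult("levene", float(res.statistic), float(res.pvalue), n)
    if which == "spearman":
        (y,) = more
        res = stats.spearmanr(x, np.asarray(y, dtype=float))
        return TestResult("spearman", float(res.statistic), float(res.pvalue), x.size)
    if which == "wilcoxon_paired":
        (y,) = more
        y = np.asarray(y, dtype=float)
        if np.allclose(x, y):
            # all-zero differences: no evidence against the null
            return TestResult("wilcoxon_paired", 0.0, 1.0, x.size)
        res = stats.wilcoxon(x, y)
        return TestResult("wilcoxon_paired", float(res.statistic), float(res.pvalue), x.size)
    raise ValueError(f"unknown test {which!r}")
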