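"""Default Bayes factors: JZS t-test and Dirichlet-multinomial
contingency tables.

The t-test Bayes factor places a Cauchy prior (scale ``rscale``) on the
standardized effect size under the alternative, equivalently a
scaled inverse-chi-square mixture over the variance ratio g, and
integrates the marginal likelihood ratio numerically.

The contingency-table Bayes factor is the independent-multinomial
(fixed row margins) form with Dirichlet priors of common concentration
``a``: under the alternative each row has its own Dirichlet(a,...,a)
cell-probability vector; under the null all rows share column
probabilities with a Dirichlet prior whose concentrations are the
column sums of the per-row priors.  Both marginal likelihoods are
available in closed form through Dirichlet-multinomial conjugacy.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate
from scipy.special import gammaln


def jzs_ttest_bf(
    t: float,
    nx: int,
    ny: int | None = None,
    paired: bool = False,
    rscale: float = 0.707,
) -> float:
    """JZS Bayes factor (BF10) for a t statistic.

    One-sample/paired when ``ny`` is None or ``paired``; independent
    two-sample otherwise.  ``rscale`` is the Cauchy prior scale on the
    effect size (0.707 = sqrt(2)/2, the conventional default).
    """
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    if paired or ny is None:
        if nx < 2:
            raise ValueError("need n >= 2")
        n_eff = float(nx)
        df = nx - 1
    else:
        if min(nx, ny) < 2:
            raise ValueError("need n >= 2 in both groups")
        n_eff = nx * ny / (nx + ny)
        df = nx + ny - 2

    r2 = rscale**2
    t2 = t * t

    def integrand(g: float) -> float:
        # likelihood ratio at variance-ratio g times the InvGamma(1/2, r^2/2) prior
        like = (1 + n_eff * g) ** -0.5 * (
            1 + t2 / ((1 + n_eff * g) * df)
        ) ** (-(df + 1) / 2)
        prior = (
            (r2 / 2) ** 0.5 / math.gamma(0.5) * g ** -1.5 * math.exp(-r2 / (2 * g))
        )
        return like * prior

    num, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    denom = (1 + t2 / df) ** (-(df + 1) / 2)
    return float(num / denom)


def contingency_bf(table, a: float = 1.0) -> float:
    """BF10 for association in an r x c count table (rows = independent
    multinomial samples, e.g. groups; columns = outcome categories).

    Dirichlet concentration ``a`` per cell under the alternative (the
    conventional default a = 1 is uniform).  Returns the ratio of the
    alternative's marginal likelihood to the shared-column-probability
    null's.
    """
    y = np.asarray(table, dtype=float)
    if y.ndim != 2:
        raise ValueError("table must be 2-D")
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    if y.sum(axis=1).min() <= 0:
        raise ValueError("every row needs at least one observation")
    r, c = y.shape

    def log_dirmult(counts: np.ndarray, alpha: np.ndarray) -> float:
        # log integral of multinomial likelihood under Dirichlet(alpha)
        return float(
            gammaln(alpha.sum())
            - gammaln(alpha.sum() + counts.sum())
            + np.sum(gammaln(alpha + counts) - gammaln(alpha))
        )

    alpha_row = np.full(c, a)
    log_m1 = sum(log_dirmult(y[i], alpha_row) for i in range(r))
    alpha_null = np.full(c, r * a)  # column sums of the per-row priors
    log_m0 = log_dirmult(y.sum(axis=0), alpha_null)
    return float(math.exp(log_m1 - log_m0))
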