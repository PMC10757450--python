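"""Split-plot (mixed-design) ANOVA for one between factor and up to two
within factors, with estimated marginal means and stratum-aware
pairwise contrasts.

The decomposition is the classical univariate approach: the
between-subject stratum tests the group effect against subject-within-
group variability; each within-subject stratum tests a within effect
(and its interaction with the group factor) against the corresponding
factor x subject interaction.  One observation per subject x within
cell (a cell mean) is required and every subject must be complete;
group sizes may differ (the within structure stays proportional, so
the sums of squares remain orthogonal).

Contrast standard errors combine the stratum mean squares through the
orthogonal within-subject projections, so marginal group comparisons
use subject-level error, within comparisons use the factor x subject
error, and cross-stratum cell contrasts blend the two.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import jzs_ttest_bf


@dataclass
class MixedAnovaFit:
    table: pd.DataFrame
    dv: str
    between: str
    within: list[str]
    subject: str
    group_levels: list
    within_levels: dict[str, list]
    groups: np.ndarray          # group label per subject (subject order)
    Y: np.ndarray               # (N, w1, w2) subject responses
    ms: dict[str, float] = field(default_factory=dict)       # stratum -> MS
    df_err: dict[str, float] = field(default_factory=dict)   # stratum -> df

    @property
    def n_per_group(self) -> dict:
        lv, ct = np.unique(self.groups, return_counts=True)
        return dict(zip(lv.tolist(), ct.tolist()))

    def cell_means(self) -> pd.DataFrame:
        """Group x within-cell means as a tidy table."""
        w1, w2 = self.within_levels_tuple()
        rows = []
        for gi, g in enumerate(self.group_levels):
            sel = self.groups == g
            for i1, l1 in enumerate(w1):
                for i2, l2 in enumerate(w2):
                    row = {self.between: g, "mean": float(self.Y[sel, i1, i2].mean())}
                    if self.within:
                        row[self.within[0]] = l1
                    if len(self.within) > 1:
                        row[self.within[1]] = l2
                    rows.append(row)
        return pd.DataFrame(rows)

    def within_levels_tuple(self):
        w1 = self.within_levels[self.within[0]] if self.within else [None]
        w2 = self.within_levels[self.within[1]] if len(self.within) > 1 else [None]
        return w1, w2


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    between: str,
    within: str | list[str] | None = None,
    subject: str = "participant_id",
) -> MixedAnovaFit:
    """Fit a balanced-within split-plot ANOVA.

    ``data`` is long format with one row per subject x within cell.
    ``within`` may be None (one-way between ANOVA), one factor, or two.
    Raises if any subject is missing a cell or has duplicates.
    """
    within = [] if within is None else ([within] if isinstance(within, str) else list(within))
    if len(within) > 2:
        raise ValueError("at most two within factors are supported")

    group_of = data.groupby(subject, observed=True)[between].agg(pd.unique)
    if group_of.map(len).max() > 1:
        raise ValueError("a subject appears in more than one group")
    group_of = group_of.map(lambda v: v[0])

    w_levels = {f: sorted(data[f].unique().tolist()) for f in within}
    w1 = w_levels[within[0]] if within else [None]
    w2 = w_levels[within[1]] if len(within) > 1 else [None]

    if within:
        wide = data.pivot_table(
            index=subject, columns=within, values=dv, aggfunc="mean", observed=True
        )
        count = data.pivot_table(
            index=subject, columns=within, values=dv, aggfunc="count", observed=True
        )
        if len(within) == 2:
            cols = pd.MultiIndex.from_product([w1, w2])
        else:
            cols = pd.Index(w1)
        wide = wide.reindex(columns=cols)
        count = count.reindex(columns=cols)
        if wide.isna().any().any() or (count != 1).any().any():
            raise ValueError("each subject needs exactly one observation per within cell")
        Y = wide.to_numpy(dtype=float).reshape(len(wide), len(w1), len(w2))
        subjects = wide.index
    else:
        ser = data.set_index(subject)[dv].astype(float)
        if ser.index.duplicated().any():
            raise ValueError("one observation per subject required")
        Y = ser.to_numpy().reshape(-1, 1, 1)
        subjects = ser.index

    groups = group_of.loc[subjects].to_numpy()
    g_levels = sorted(pd.unique(groups).tolist())
    N = Y.shape[0]
    n1, n2 = len(w1), len(w2)
    W = n1 * n2
    n_g = np.array([(groups == g).sum() for g in g_levels])
    if (n_g < 2).any():
        raise ValueError("every group needs at least two subjects")

    grand = Y.mean()
    ss_total = float(np.sum((Y - grand) ** 2))
    g_means = np.array([Y[groups == g].mean() for g in g_levels])
    s_means = Y.mean(axis=(1, 2))

    ss: dict[str, float] = {}
    dfs: dict[str, float] = {}
    err_of: dict[str, str] = {}

    G = len(g_levels)
    ss[between] = W * float(np.sum(n_g * (g_means - grand) ** 2))
    dfs[between] = G - 1
    g_of_subj = np.array([g_levels.index(g) for g in groups])
    ss["subject"] = W * float(np.sum((s_means - g_means[g_of_subj]) ** 2))
    dfs["subject"] = N - G
    err_of[between] = "subject"

    ga = np.stack([Y[groups == g].mean(axis=0) for g in g_levels])  # (G, n1, n2)

    if within:
        A = within[0]
        a_means = Y.mean(axis=(0, 2))                       # (n1,)
        ga_a = ga.mean(axis=2)                              # (G, n1)
        ss[A] = N * n2 * float(np.sum((a_means - grand) ** 2))
        dfs[A] = n1 - 1
        inter = ga_a - g_means[:, None] - a_means[None, :] + grand
        ss[f"{between} * {A}"] = n2 * float(np.sum(n_g[:, None] * inter**2))
        dfs[f"{between} * {A}"] = (G - 1) * (n1 - 1)
        ia = Y.mean(axis=2)                                 # (N, n1)
        resid = ia - s_means[:, None] - ga_a[g_of_subj] + g_means[g_of_subj][:, None]
        ss[f"{A} x subject"] = n2 * float(np.sum(resid**2))
        dfs[f"{A} x subject"] = (n1 - 1) * (N - G)
        err_of[A] = err_of[f"{between} * {A}"] = f"{A} x subject"

    if len(within) > 1:
        B = within[1]
        b_means = Y.mean(axis=(0, 1))
        ga_b = ga.mean(axis=1)
        ss[B] = N * n1 * float(np.sum((b_means - grand) ** 2))
        dfs[B] = n2 - 1
        inter = ga_b - g_means[:, None] - b_means[None, :] + grand
        ss[f"{between} * {B}"] = n1 * float(np.sum(n_g[:, None] * inter**2))
        dfs[f"{between} * {B}"] = (G - 1) * (n2 - 1)
        ib = Y.mean(axis=1)
        resid = ib - s_means[:, None] - ga_b[g_of_subj] + g_means[g_of_subj][:, None]
        ss[f"{B} x subject"] = n1 * float(np.sum(resid**2))
        dfs[f"{B} x subject"] = (n2 - 1) * (N - G)
        err_of[B] = err_of[f"{between} * {B}"] = f"{B} x subject"

        ab = Y.mean(axis=0)                                 # (n1, n2)
        inter = ab - a_means[:, None] - b_means[None, :] + grand
        ss[f"{A} * {B}"] = N * float(np.sum(inter**2))
        dfs[f"{A} * {B}"] = (n1 - 1) * (n2 - 1)
        inter3 = (
            ga
            - ga_a[:, :, None]
            - ga_b[:, None, :]
            - ab[None, :, :]
            + g_means[:, None, None]
            + a_means[None, :, None]
            + b_means[None, None, :]
            - grand
        )
        ss[f"{between} * {A} * {B}"] = float(np.sum(n_g[:, None, None] * inter3**2))
        dfs[f"{between} * {A} * {B}"] = (G - 1) * (n1 - 1) * (n2 - 1)
        ss[f"{A} x {B} x subject"] = ss_total - sum(
            v for k, v in ss.items() if k != f"{A} x {B} x subject"
        )
        dfs[f"{A} x {B} x subject"] = (n1 - 1) * (n2 - 1) * (N - G)
        err_of[f"{A} * {B}"] = err_of[f"{between} * {A} * {B}"] = f"{A} x {B} x subject"

    ms = {k: (ss[k] / dfs[k] if dfs[k] > 0 else np.nan) for k in ss}
    tol = 1e-10 * max(1.0, ss_total)
    rows = []
    for eff, err in err_of.items():
        ms_e, ms_err = ms[eff], ms[err]
        if ms_err <= tol:
            F = 0.0 if ss[eff] <= tol else np.inf
        else:
            F = ms_e / ms_err
        p = float(stats.f.sf(F, dfs[eff], dfs[err])) if np.isfinite(F) else 0.0
        denom = ss[eff] + ss[err]
        rows.append(
            {
                "effect": eff,
                "ss": ss[eff],
                "df_num": dfs[eff],
                "df_den": dfs[err],
                "F": F,
                "p": p,
                "partial_eta_sq": ss[eff] / denom if denom > 0 else 0.0,
                "error_term": err,
            }
        )
    table = pd.DataFrame(rows)

    fit = MixedAnovaFit(
        table=table,
        dv=dv,
        between=between,
        within=within,
        subject=subject,
        group_levels=g_levels,
        within_levels=w_levels,
        groups=groups,
        Y=Y,
        ms={k: ms[k] for k in ("subject", *[e for e in ms if "x subject" in e])},
        df_err={k: dfs[k] for k in dfs if k == "subject" or "x subject" in k},
    )
    fit.ss_all = ss  # full decomposition, used by invariants/tests
    fit.df_all = dfs
    return fit


def estimated_marginal_means(
    cells: pd.DataFrame, value: str, margins: list[str]
) -> pd.Series:
    """Unweighted averages of cell means over the collapsed factors.

    ``cells`` holds one row per design cell; on a complete grid a plain
    groupby mean is the unweighted (estimated marginal) mean.
    """
    if not margins:
        return pd.Series({"grand": cells[value].mean()})
    return cells.groupby(margins, observed=True)[value].mean()


# ---------------------------------------------------------------------------
# contrasts


def _projections(n1: int, n2: int) -> dict[tuple, np.ndarray]:
    """Orthogonal projections of the within-cell space, keyed by the
    subset of within factors they span (() = subject/constant stratum)."""
    J1, J2 = np.full((n1, n1), 1.0 / n1), np.full((n2, n2), 1.0 / n2)
    C1, C2 = np.eye(n1) - J1, np.eye(n2) - J2
    out = {(): np.kron(J1, J2)}
    if n1 > 1:
        out[(0,)] = np.kron(C1, J2)
    if n2 > 1:
        out[(1,)] = np.kron(J1, C2)
    if n1 > 1 and n2 > 1:
        out[(0, 1)] = np.kron(C1, C2)
    return out


def _stratum_name(fit: MixedAnovaFit, key: tuple) -> str:
    if key == ():
        return "subject"
    if key == (0, 1):
        return f"{fit.within[0]} x {fit.within[1]} x subject"
    return f"{fit.within[key[0]]} x subject"


def _match_weights(fit: MixedAnovaFit, spec: dict) -> np.ndarray:
    """Unweighted-average weights over the cells matching a margin spec.

    ``spec`` maps factor name (the between factor and/or within
    factors) to a level; unspecified factors are averaged over.
    Returns weights shaped (G, W).
    """
    w1, w2 = fit.within_levels_tuple()
    G = len(fit.group_levels)
    mask = np.zeros((G, len(w1) * len(w2)))
    unknown = set(spec) - {fit.between, *fit.within}
    if unknown:
        raise ValueError(f"unknown factors in spec: {sorted(unknown)}")
    for gi, g in enumerate(fit.group_levels):
        if fit.between in spec and spec[fit.between] != g:
            continue
        for ci, (l1, l2) in enumerate(itertools.product(w1, w2)):
            if fit.within and fit.within[0] in spec and spec[fit.within[0]] != l1:
                continue
            if len(fit.within) > 1 and fit.within[1] in spec and spec[fit.within[1]] != l2:
                continue
            mask[gi, ci] = 1.0
    if mask.sum() == 0:
        raise ValueError(f"spec matches no cells: {spec}")
    return mask / mask.sum()


def _contrast_variance(fit: MixedAnovaFit, v: np.ndarray) -> tuple[float, float]:
    """(variance, df) of a contrast with cell weights v (G, W)."""
    w1, w2 = fit.within_levels_tuple()
    projs = _projections(len(w1), len(w2))
    n_g = fit.n_per_group
    var = 0.0
    used: list[str] = []
    for key, P in projs.items():
        name = _stratum_name(fit, key)
        msq = fit.ms[name]
        for gi, g in enumerate(fit.group_levels):
            w = float(v[gi] @ P @ v[gi])
            if w > 1e-12:
                var += msq * w / n_g[g]
                if name not in used:
                    used.append(name)
    df = min(fit.df_err[name] for name in used)
    return var, df


def _subject_scores(fit: MixedAnovaFit, spec: dict) -> dict:
    """Per-subject unweighted means over the within cells a spec matches,
    grouped by between level (all groups if the spec fixes none)."""
    v = _match_weights(fit, spec)
    flat = fit.Y.reshape(fit.Y.shape[0], -1)
    out = {}
    for gi, g in enumerate(fit.group_levels):
        if fit.between in spec and spec[fit.between] != g:
            continue
        wcell = v[gi]
        wcell = wcell / wcell.sum()
        out[g] = flat[fit.groups == g] @ wcell
    return out


def cohens_d(kind: str, m_diff: float, sds: tuple[float, float], ns=None) -> float:
    """Effect size for a contrast.

    ``between_pooled``: difference over the pooled SD of the two
    groups' scores.  ``within_av``: difference over the plain average
    of the two condition SDs (paired designs).
    """
    s1, s2 = sds
    if kind == "between_pooled":
        n1, n2 = ns
        pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
        denom = pooled
    elif kind == "within_av":
        denom = (s1 + s2) / 2.0
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if denom == 0:
        raise ZeroDivisionError("zero SD in Cohen's d")
    return float(m_diff / denom)


def posthoc_pairwise(
    fit: MixedAnovaFit,
    comparisons: list[tuple[str, dict, dict]],
    family_size: int | None = None,
    bf_rscale: float = 0.707,
) -> pd.DataFrame:
    """Pairwise marginal comparisons with Bonferroni correction.

    Each comparison is (label, spec_a, spec_b); the estimate is the
    difference of the two marginal means.  The standard error combines
    the stratum mean squares appropriate to the contrast; the degrees
    of freedom are those of the contributing error stratum (the
    smallest when several contribute).  Cohen's d uses the pooled-SD
    form for between-group contrasts and the averaged-SD form for
    within contrasts; the Bayes factor is a default JZS t-test BF
    computed from t and the subject counts.
    """
    family_size = len(comparisons) if family_size is None else family_size
    rows = []
    for label, spec_a, spec_b in comparisons:
        va, vb = _match_weights(fit, spec_a), _match_weights(fit, spec_b)
        v = va - vb
        flat = fit.Y.reshape(fit.Y.shape[0], -1)
        cell_means = np.stack(
            [flat[fit.groups == g].mean(axis=0) for g in fit.group_levels]
        )
        m_diff = float(np.sum(v * cell_means))
        var, df = _contrast_variance(fit, v)
        se = float(np.sqrt(var))
        t = m_diff / se if se > 0 else 0.0
        p_raw = 2 * float(stats.t.sf(abs(t), df)) if se > 0 else 1.0
        tcrit = stats.t.ppf(0.975, df)
        scores_a = _subject_scores(fit, spec_a)
        scores_b = _subject_scores(fit, spec_b)
        ga, gb = spec_a.get(fit.between), spec_b.get(fit.between)
        if ga is not None and gb is not None and ga != gb:
            xa = scores_a[ga]
            xb = scores_b[gb]
            d = cohens_d(
                "between_pooled", m_diff, (xa.std(ddof=1), xb.std(ddof=1)),
                (len(xa), len(xb)),
            )
            bf = jzs_ttest_bf(t, len(xa), len(xb), rscale=bf_rscale)
        else:
            xa = np.concatenate([scores_a[g] for g in scores_a])
            xb = np.concatenate([scores_b[g] for g in scores_b])
            d = cohens_d("within_av", m_diff, (xa.std(ddof=1), xb.std(ddof=1)))
            bf = jzs_ttest_bf(t, len(xa), paired=True, rscale=bf_rscale)
        rows.append(
            {
                "label": label,
                "m_diff": m_diff,
                "se": se,
                "t": t,
                "df": df,
                "p_raw": p_raw,
                "p_bonferroni": min(1.0, p_raw * family_size),
                "ci95_lo": m_diff - tcrit * se,
                "ci95_hi": m_diff + tcrit * se,
                "cohens_d": d,
                "bf10": bf,
            }
        )
    return pd.DataFrame(rows)
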