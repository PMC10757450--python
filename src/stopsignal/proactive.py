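"""Proactive inhibition: the context effect and its three read-outs.

A participant under stop-signal pressure strategically delays movement
onset (longer no-stop RTs than go-only RTs) and, having had more time
to program the reach, executes it faster (shorter no-stop MTs).  This
"context effect" is quantified three ways:

* cell means of RT/MT per participant x trial type (feeding the ANOVAs),
* population cumulative distributions compared with dual one-tailed KS
  tests (one test's null matches the context-effect prediction, the
  other opposes it, so curve intersections are detectable), and
* an individual-level classification into context / no-context /
  inverse-context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ks import KSResult, ks_two_sample

CATEGORIES = ("context", "no_context", "inverse_context")


@dataclass
class ContextCategory:
    category: str
    rt_test: KSResult
    mt_test_expected: KSResult
    mt_test_opposite: KSResult


@dataclass
class PopulationCDF:
    grid: np.ndarray
    cdf: np.ndarray
    n_participants: int


def _pool(trials: pd.DataFrame, measure: str, trial_type: str) -> pd.DataFrame:
    """Valid response trials of one trial type with the measure recorded."""
    task = "go_only" if trial_type == "go_only" else "sst"
    sub = trials[
        (trials["task"] == task)
        & (trials["trial_type"] == trial_type)
        & trials["outcome"].isin(["correct", "overtime_reaching"])
        & trials[measure].notna()
    ]
    return sub


def context_cell_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean RT/MT of no-stop and go-only trials per participant x session."""
    rows = []
    for (pid, grp, trt), sub in trials.groupby(
        ["participant_id", "group", "treatment"], sort=False, observed=True
    ):
        row = {"participant_id": pid, "group": grp, "treatment": trt}
        for measure in ("rt", "mt"):
            for tt in ("no_stop", "go_only"):
                cell = _pool(sub, measure, tt)
                if cell.empty:
                    raise ValueError(f"missing cell {(pid, trt, measure, tt)}")
                row[f"{measure}_{tt}"] = float(cell[measure].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def build_population_cdf(
    trials: pd.DataFrame, measure: str, trial_type: str, min_trials: int = 5
) -> PopulationCDF:
    """Equal-weight average of per-participant empirical CDFs.

    Every participant contributes 1/n_participants to the population
    curve regardless of trial count, so fast-but-prolific participants
    do not dominate.
    """
    sub = _pool(trials, measure, trial_type)
    samples = [
        np.sort(g[measure].to_numpy())
        for _, g in sub.groupby("participant_id", sort=False, observed=True)
        if len(g) >= min_trials
    ]
    if len(samples) < 1:
        raise ValueError("no participant has enough trials")
    grid = np.unique(np.concatenate(samples))
    cdf = np.zeros_like(grid, dtype=float)
    for s in samples:
        cdf += np.searchsorted(s, grid, side="right") / s.size
    cdf /= len(samples)
    return PopulationCDF(grid=grid, cdf=cdf, n_participants=len(samples))


def _dual_ks(
    no_stop: np.ndarray, go_only: np.ndarray, expected_direction: str, alpha: float
) -> tuple[str, KSResult, KSResult]:
    """Run the expected-direction and opposite one-tailed KS tests.

    ``expected_direction`` is the alternative for the no-stop sample
    under the context effect ("greater" for RT, "less" for MT).
    Verdicts: 'expected' (only the predicted shift is significant),
    'intersection' (both are: the curves cross), 'opposite', 'none'.
    """
    opposite = "less" if expected_direction == "greater" else "greater"
    t_exp = ks_two_sample(no_stop, go_only, expected_direction)
    t_opp = ks_two_sample(no_stop, go_only, opposite)
    sig_exp = t_exp.p_value < alpha
    sig_opp = t_opp.p_value < alpha
    if sig_exp and sig_opp:
        verdict = "intersection"
    elif sig_exp:
        verdict = "expected"
    elif sig_opp:
        verdict = "opposite"
    else:
        verdict = "none"
    return verdict, t_exp, t_opp


def population_context_test(trials: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Population-level context-effect evaluation for one group x treatment.

    Trials of all participants are pooled per measure x trial type and
    the dual one-tailed KS pair is run for RTs (no-stop expected
    stochastically greater) and MTs (no-stop expected smaller).  The
    averaged population curves (see :func:`build_population_cdf`) are
    for display; the tests need trial-level sample sizes.  Overall
    verdict is 'context' iff both measures shift in the predicted
    direction and neither pair detects an intersection.
    """
    out: dict = {}
    for measure, direction in (("rt", "greater"), ("mt", "less")):
        ns = _pool(trials, measure, "no_stop")[measure].to_numpy()
        go = _pool(trials, measure, "go_only")[measure].to_numpy()
        if ns.size == 0 or go.size == 0:
            raise ValueError(f"empty {measure} pool")
        verdict, t_exp, t_opp = _dual_ks(ns, go, direction, alpha)
        out[f"{measure}_verdict"] = verdict
        out[f"{measure}_test_expected"] = t_exp
        out[f"{measure}_test_opposite"] = t_opp
    out["overall"] = (
        "context"
        if out["rt_verdict"] == "expected" and out["mt_verdict"] == "expected"
        else "no_context"
    )
    return out


def classify_individual_context(
    participant_trials: pd.DataFrame, alpha: float = 0.05
) -> ContextCategory:
    """Classify one participant x session.

    context: no-stop RTs stochastically greater AND no-stop MTs smaller
    (and no MT shift the other way); inverse_context: no-stop MTs
    significantly longer instead; no_context: anything else.
    """
    rt_ns = _pool(participant_trials, "rt", "no_stop")["rt"].to_numpy()
    rt_go = _pool(participant_trials, "rt", "go_only")["rt"].to_numpy()
    mt_ns = _pool(participant_trials, "mt", "no_stop")["mt"].to_numpy()
    mt_go = _pool(participant_trials, "mt", "go_only")["mt"].to_numpy()
    if min(rt_ns.size, rt_go.size, mt_ns.size, mt_go.size) == 0:
        raise ValueError("both task cells are required for classification")
    rt_test = ks_two_sample(rt_ns, rt_go, "greater")
    mt_exp = ks_two_sample(mt_ns, mt_go, "less")
    mt_opp = ks_two_sample(mt_ns, mt_go, "greater")
    rt_sig = rt_test.p_value < alpha
    exp_sig = mt_exp.p_value < alpha
    opp_sig = mt_opp.p_value < alpha
    if rt_sig and exp_sig and not opp_sig:
        category = "context"
    elif opp_sig and not exp_sig:
        category = "inverse_context"
    else:
        category = "no_context"
    return ContextCategory(
        category=category,
        rt_test=rt_test,
        mt_test_expected=mt_exp,
        mt_test_opposite=mt_opp,
    )


def individual_context_table(trials: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Individual classification for every participant x session."""
    rows = []
    for (pid, grp, trt), sub in trials.groupby(
        ["participant_id", "group", "treatment"], sort=False, observed=True
    ):
        cat = classify_individual_context(sub, alpha=alpha)
        rows.append(
            {
                "participant_id": pid,
                "group": grp,
                "treatment": trt,
                "category": cat.category,
                "rt_p": cat.rt_test.p_value,
                "mt_p_expected": cat.mt_test_expected.p_value,
                "mt_p_opposite": cat.mt_test_opposite.p_value,
            }
        )
    return pd.DataFrame(rows)


def context_frequencies(categories: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of each category per group x treatment."""
    rows = []
    for (grp, trt), sub in categories.groupby(
        ["group", "treatment"], sort=False, observed=True
    ):
        counts = sub["category"].value_counts()
        n = len(sub)
        row = {"group": grp, "treatment": trt, "n": n}
        for cat in CATEGORIES:
            c = int(counts.get(cat, 0))
            row[f"n_{cat}"] = c
            row[f"pct_{cat}"] = 100.0 * c / n
        rows.append(row)
    return pd.DataFrame(rows)
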