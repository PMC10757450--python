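"""Reactive inhibition: SSRT estimation and race-model assumption checks.

The stop-signal reaction time (SSRT) is estimated with the integration
method: the go-RT distribution (no-stop trials, overtime responses
included, omissions replaced by the maximum observed RT) is sorted, the
RT at rank ``ceil(p_failure * N)`` is located, and the mean stop-signal
delay is subtracted from it.  Under the independent horse-race model
this quantile marks the go finishing time that the stop process just
beats, so the difference is the stop latency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_RELIABLE_STOP_TRIALS = 50


@dataclass
class SSRTEstimate:
    ssrt: float
    p_failure: float
    mean_ssd: float
    n_stop: int
    n_go: int
    n_omissions: int

    @property
    def reliable(self) -> bool:
        return self.n_stop >= MIN_RELIABLE_STOP_TRIALS


@dataclass
class RaceCheckReport:
    mean_rt_stop_failure: float
    mean_rt_no_stop: float
    independence_ok: bool | None
    staircase_ok: bool
    p_failure: float


def stop_summaries(stop_trials: pd.DataFrame) -> tuple[float, float]:
    """(p_failure, mean SSD) over all stop trials of one session."""
    if stop_trials.empty:
        raise ValueError("no stop trials")
    p_failure = float((stop_trials["outcome"] == "stop_failure").mean())
    mean_ssd = float(stop_trials["ssd"].mean())
    return p_failure, mean_ssd


def estimate_ssrt_integration(
    go_rts: np.ndarray | list,
    p_failure: float,
    mean_ssd: float,
    n_omissions: int = 0,
    n_stop: int = 0,
) -> SSRTEstimate:
    """Integration-method SSRT with omission replacement.

    ``go_rts`` are the session's no-stop RTs (post-trim, overtime
    included); ``n_omissions`` counts no-stop trials aborted without an
    RT, each replaced by the maximum observed RT.  Undefined when the
    participant never or always failed to stop.
    """
    go_rts = np.asarray(go_rts, dtype=float)
    if go_rts.size == 0:
        raise ValueError("empty go-RT distribution")
    if not 0.0 < p_failure < 1.0:
        raise ValueError(f"SSRT undefined for p_failure={p_failure}")
    full = np.sort(np.concatenate([go_rts, np.full(n_omissions, go_rts.max())]))
    n = full.size
    rank = min(n, max(1, math.ceil(p_failure * n)))
    ssrt = float(full[rank - 1] - mean_ssd)
    return SSRTEstimate(
        ssrt=ssrt,
        p_failure=p_failure,
        mean_ssd=mean_ssd,
        n_stop=n_stop,
        n_go=int(go_rts.size),
        n_omissions=n_omissions,
    )


def session_ssrt(session_trials: pd.DataFrame) -> SSRTEstimate:
    """Estimate SSRT from one participant x session of (trimmed) SST trials."""
    sst = session_trials[session_trials["task"] == "sst"]
    stop = sst[sst["trial_type"] == "stop"]
    no_stop = sst[sst["trial_type"] == "no_stop"]
    p_failure, mean_ssd = stop_summaries(stop)
    go_rts = no_stop["rt"].dropna().to_numpy()
    n_omissions = int((no_stop["outcome"] == "aborted_over_900").sum())
    return estimate_ssrt_integration(
        go_rts, p_failure, mean_ssd, n_omissions=n_omissions, n_stop=len(stop)
    )


def check_race_assumptions(
    session_trials: pd.DataFrame, band: float = 0.1
) -> RaceCheckReport:
    """Verify the race-model prerequisites for one session.

    Independence: the mean stop-failure RT must undercut the mean
    no-stop RT (failed stops are the fast tail of the go distribution).
    Staircase: the stop-failure rate must sit within ``band`` of 0.5.
    """
    sst = session_trials[session_trials["task"] == "sst"]
    stop = sst[sst["trial_type"] == "stop"]
    p_failure, _ = stop_summaries(stop)
    fail_rts = stop.loc[stop["outcome"] == "stop_failure", "rt"].dropna()
    ns_rts = sst.loc[sst["trial_type"] == "no_stop", "rt"].dropna()
    mean_fail = float(fail_rts.mean()) if len(fail_rts) else float("nan")
    mean_ns = float(ns_rts.mean()) if len(ns_rts) else float("nan")
    independence_ok: bool | None
    if len(fail_rts) == 0 or len(ns_rts) == 0:
        independence_ok = None
    else:
        independence_ok = bool(mean_fail < mean_ns)
    return RaceCheckReport(
        mean_rt_stop_failure=mean_fail,
        mean_rt_no_stop=mean_ns,
        independence_ok=independence_ok,
        staircase_ok=bool(abs(p_failure - 0.5) <= band),
        p_failure=p_failure,
    )


def reactive_table(trials: pd.DataFrame, band: float = 0.1) -> pd.DataFrame:
    """Per participant x session reactive-inhibition summary.

    Expects preprocessed trials.  Sessions failing the independence
    check are flagged (not dropped).
    """
    rows = []
    for (pid, grp, trt), sub in trials[trials["task"] == "sst"].groupby(
        ["participant_id", "group", "treatment"], sort=False, observed=True
    ):
        est = session_ssrt(sub)
        check = check_race_assumptions(sub, band=band)
        rows.append(
            {
                "participant_id": pid,
                "group": grp,
                "treatment": trt,
                "ssrt": est.ssrt,
                "p_failure": est.p_failure,
                "mean_ssd": est.mean_ssd,
                "n_stop": est.n_stop,
                "n_go": est.n_go,
                "n_omissions": est.n_omissions,
                "reliable": est.reliable,
                "mean_rt_stop_failure": check.mean_rt_stop_failure,
                "mean_rt_no_stop": check.mean_rt_no_stop,
                "independence_ok": check.independence_ok,
                "staircase_ok": check.staircase_ok,
            }
        )
    return pd.DataFrame(rows)
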