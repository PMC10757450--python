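"""Trial-table cleaning: RT-limit handling, +/-3 SD trimming, accuracy.

The cleaning rules follow common stop-signal practice: reaction times
outside mean +/- 3 SD of their own participant x session x task x
trial-type cell are discarded in a single pass; responses between the
800 ms limit and the 900 ms grace ceiling (``overtime_reaching``) stay
in every RT analysis, while responses aborted beyond 900 ms contribute
no RT but still count against accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import pandas as pd

logger = logging.getLogger(__name__)

#: default grouping within which trimming statistics are computed
DEFAULT_SCOPE = ("participant_id", "treatment", "task", "trial_type")


@dataclass
class TrimReport:
    """Bookkeeping for one trimming scope."""

    scope: tuple
    n_input: int
    n_removed: int

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scope"] = list(self.scope)
        d["fraction_removed"] = self.fraction_removed
        return d


def trim_outliers(
    trials: pd.DataFrame, scope: tuple[str, ...] = DEFAULT_SCOPE
) -> tuple[pd.DataFrame, list[TrimReport]]:
    """Drop trials whose RT falls outside mean +/- 3 SD of its scope.

    Mean and sample SD (ddof=1) are computed on the untrimmed RTs of
    each scope; removal is single-pass (no re-trimming).  Trials without
    a recorded RT (successful stops, aborts) pass through untouched.
    Scopes with fewer than two RTs are left as-is with a warning.
    """
    has_rt = trials["rt"].notna()
    keep = pd.Series(True, index=trials.index)
    reports: list[TrimReport] = []
    for key, sub in trials[has_rt].groupby(list(scope), sort=False, observed=True):
        rts = sub["rt"]
        if len(rts) < 2:
            logger.warning("scope %s has <2 RTs; trimming skipped", key)
            reports.append(TrimReport(scope=key, n_input=len(rts), n_removed=0))
            continue
        m, s = rts.mean(), rts.std(ddof=1)
        out = (rts < m - 3 * s) | (rts > m + 3 * s)
        keep.loc[sub.index[out]] = False
        reports.append(TrimReport(scope=key, n_input=len(rts), n_removed=int(out.sum())))
    return trials[keep].copy(), reports


def apply_rt_limit(trials: pd.DataFrame) -> pd.DataFrame:
    """Return the RT-analysis pool: trials with a recorded RT.

    Overtime-reaching responses (800 < RT <= 900 ms) are retained;
    aborted trials (>900 ms, no RT) are excluded here but remain in the
    full table for accuracy computation.
    """
    return trials[trials["rt"].notna()].copy()


def compute_accuracy(
    trials: pd.DataFrame, task: str, overtime_as_correct: bool = True
) -> float:
    """Proportion of correct go-type trials for one participant x session.

    Accuracy is correct responses over all go-type trials of the task
    (misses, early releases, and >900 ms aborts count as errors).
    ``overtime_as_correct`` controls whether overtime-reaching responses
    count as correct (they did land on the target) or as errors (they
    broke the RT limit).
    """
    tt = "go_only" if task == "go_only" else "no_stop"
    sub = trials[(trials["task"] == task) & (trials["trial_type"] == tt)]
    if sub.empty:
        raise ValueError(f"no {tt} trials for task {task!r}")
    good = {"correct", "overtime_reaching"} if overtime_as_correct else {"correct"}
    return float(sub["outcome"].isin(good).mean())


def accuracy_table(trials: pd.DataFrame, overtime_as_correct: bool = True) -> pd.DataFrame:
    """Per-participant x session accuracy for both tasks."""
    rows = []
    for (pid, grp, trt), sub in trials.groupby(
        ["participant_id", "group", "treatment"], sort=False, observed=True
    ):
        row = {"participant_id": pid, "group": grp, "treatment": trt}
        for task in ("go_only", "sst"):
            if (sub["task"] == task).any():
                row[f"acc_{task}"] = compute_accuracy(sub, task, overtime_as_correct)
        rows.append(row)
    return pd.DataFrame(rows)


def preprocess(
    trials: pd.DataFrame, scope: tuple[str, ...] = DEFAULT_SCOPE
) -> tuple[pd.DataFrame, list[TrimReport]]:
    """Standard cleaning pass: one-shot +/-3 SD trimming on recorded RTs."""
    return trim_outliers(trials, scope)
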