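"""Group x treatment generator presets for the simulated cohort.

The presets encode the behavioural profile of each cell of the study
design: Parkinson's disease patients at Hoehn & Yahr stages 1-1.5
(``H&Y1``), 2 (``H&Y2``) and 2.5-3 (``H&Y3``), each assessed on
dopaminergic medication (``ON``) and after overnight withdrawal
(``OFF``), plus a healthy-control group (``HC``) assessed once.

Each cell stores, as (mean, between-participant SD) pairs in
milliseconds, the stop-signal reaction time (SSRT), the no-stop and
go-only reaction times (RT) and movement times (MT), together with the
target task accuracies.  These are the population-level quantities the
cohort generator reproduces; stop-failure RT, failure probability and
mean stop-signal delay are *emergent* properties of the race model and
are never set directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

GROUPS = ("H&Y1", "H&Y2", "H&Y3", "HC")
PATIENT_GROUPS = ("H&Y1", "H&Y2", "H&Y3")
TREATMENTS = ("OFF", "ON")


@dataclass(frozen=True)
class CellPreset:
    """Population means/SDs (ms) and accuracies for one group x treatment cell."""

    ssrt: tuple[float, float]
    rt_no_stop: tuple[float, float]
    rt_go_only: tuple[float, float]
    mt_no_stop: tuple[float, float]
    mt_go_only: tuple[float, float]
    acc_no_stop: float
    acc_go_only: float


#: (group, treatment) -> CellPreset.  Healthy controls are keyed with
#: treatment "NA" (single session).
DEFAULT_PRESETS: dict[tuple[str, str], CellPreset] = {
    ("H&Y1", "OFF"): CellPreset(
        ssrt=(227.0, 34.1), rt_no_stop=(614.4, 98.9), rt_go_only=(267.8, 52.0),
        mt_no_stop=(473.8, 163.0), mt_go_only=(539.8, 216.4),
        acc_no_stop=0.88, acc_go_only=0.90,
    ),
    ("H&Y1", "ON"): CellPreset(
        ssrt=(252.3, 37.7), rt_no_stop=(592.3, 105.2), rt_go_only=(274.9, 58.3),
        mt_no_stop=(468.9, 128.8), mt_go_only=(539.5, 169.9),
        acc_no_stop=0.87, acc_go_only=0.89,
    ),
    ("H&Y2", "OFF"): CellPreset(
        ssrt=(237.7, 29.4), rt_no_stop=(531.6, 72.2), rt_go_only=(294.1, 59.7),
        mt_no_stop=(664.2, 202.6), mt_go_only=(699.6, 207.6),
        acc_no_stop=0.87, acc_go_only=0.90,
    ),
    ("H&Y2", "ON"): CellPreset(
        ssrt=(254.6, 42.7), rt_no_stop=(517.3, 127.0), rt_go_only=(276.0, 53.8),
        mt_no_stop=(625.1, 219.7), mt_go_only=(634.7, 230.4),
        acc_no_stop=0.86, acc_go_only=0.87,
    ),
    ("H&Y3", "OFF"): CellPreset(
        ssrt=(277.2, 39.0), rt_no_stop=(513.6, 127.8), rt_go_only=(279.3, 61.4),
        mt_no_stop=(634.9, 175.8), mt_go_only=(646.2, 141.4),
        acc_no_stop=0.84, acc_go_only=0.86,
    ),
    ("H&Y3", "ON"): CellPreset(
        ssrt=(267.7, 42.6), rt_no_stop=(493.0, 136.4), rt_go_only=(293.7, 65.9),
        mt_no_stop=(636.1, 220.7), mt_go_only=(659.7, 219.3),
        acc_no_stop=0.82, acc_go_only=0.81,
    ),
    ("HC", "NA"): CellPreset(
        ssrt=(221.9, 25.7), rt_no_stop=(492.3, 99.3), rt_go_only=(306.5, 85.7),
        mt_no_stop=(443.8, 129.9), mt_go_only=(509.7, 152.2),
        acc_no_stop=0.89, acc_go_only=0.91,
    ),
}


def behavioural_summary(presets: dict | None = None) -> pd.DataFrame:
    """Return the preset cell means as a tidy table.

    One row per (group, treatment) cell with the preset mean of every
    behavioural measure.  This is the grid that marginal-mean and
    contrast arithmetic operates on.
    """
    presets = DEFAULT_PRESETS if presets is None else presets
    rows = []
    for (group, treatment), cell in presets.items():
        rows.append(
            {
                "group": group,
                "treatment": treatment,
                "ssrt": cell.ssrt[0],
                "rt_no_stop": cell.rt_no_stop[0],
                "rt_go_only": cell.rt_go_only[0],
                "mt_no_stop": cell.mt_no_stop[0],
                "mt_go_only": cell.mt_go_only[0],
                "acc_no_stop": cell.acc_no_stop,
                "acc_go_only": cell.acc_go_only,
            }
        )
    return pd.DataFrame(rows)
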