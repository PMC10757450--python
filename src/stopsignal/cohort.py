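"""Trial-level simulator for the go-only task and the stop-signal task (SST).

The generator implements an independent horse-race observer: on every
trial a go process draws a finishing time from an ex-Gaussian
distribution; on stop trials a stop process with constant latency
``ssrt_true`` starts at the stop-signal delay (SSD), and the response is
emitted iff the go process finishes before ``ssd + ssrt_true``.  The SSD
is tracked by a one-up/one-down staircase in 39.9 ms steps (three
screen-refresh quanta of 13.3 ms), starting at 119.7 ms, which drives
the stop-failure probability towards 50%.

Proactive slowing is encoded directly in the presets: the SST-context
(no-stop) reaction-time distribution sits above the go-only one, while
the SST movement times sit below the go-only ones.  No-stop responses
slower than the 800 ms limit are flagged (``overtime_reaching`` up to a
100 ms grace) or aborted (``aborted_over_900``, no RT recorded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .presets import DEFAULT_PRESETS, PATIENT_GROUPS, CellPreset

OUTCOMES = (
    "correct",
    "overtime_reaching",
    "aborted_over_900",
    "target_miss",
    "hold_violation",
    "stop_success",
    "stop_failure",
)

#: Column order of the long-format trial table.  ``session_order``
#: records the ON/OFF counterbalancing (1 = first session).
TRIAL_COLUMNS = (
    "participant_id",
    "group",
    "treatment",
    "task",
    "trial_type",
    "block",
    "ssd",
    "rt",
    "mt",
    "outcome",
    "session_order",
)


@dataclass(frozen=True)
class ExGauss:
    """Ex-Gaussian latency distribution (Gaussian mu/sigma plus exponential tau)."""

    mu: float
    sigma: float
    tau: float

    @property
    def mean(self) -> float:
        return self.mu + self.tau

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        out = rng.normal(self.mu, self.sigma, size=n)
        if self.tau > 0:
            out += rng.exponential(self.tau, size=n)
        return out

    def sf(self, x: float) -> float:
        """Survival function P(T > x)."""
        from scipy import stats

        if self.tau <= 0:
            if self.sigma <= 0:
                return float(self.mu > x)
            return float(stats.norm.sf(x, loc=self.mu, scale=self.sigma))
        return float(
            stats.exponnorm.sf(x, K=self.tau / self.sigma, loc=self.mu, scale=self.sigma)
        )


@dataclass
class ParticipantParams:
    """Generative parameters of one participant in one session."""

    participant_id: str
    group: str
    treatment: str
    go_only_rt: ExGauss
    sst_rt: ExGauss
    ssrt_true: float
    mt_mu_go_only: float
    mt_mu_no_stop: float
    mt_sigma: float
    lapse_go_only: float
    lapse_no_stop: float

    def __post_init__(self) -> None:
        if self.ssrt_true <= 0:
            raise ValueError("ssrt_true must be positive")
        for rate in (self.lapse_go_only, self.lapse_no_stop):
            if not 0.0 <= rate <= 0.2:
                raise ValueError("lapse rates must lie in [0, 0.2]")


@dataclass
class CohortConfig:
    """Study-design parameters for whole-cohort simulation."""

    presets: dict[tuple[str, str], CellPreset] = field(
        default_factory=lambda: dict(DEFAULT_PRESETS)
    )
    n_per_group: int = 20
    n_hc: int = 30
    n_go_only_trials: int = 100
    n_sst_trials: int = 480
    block_size: int = 120
    stop_proportion: float = 1.0 / 3.0
    ssd_init: float = 119.7
    ssd_step: float = 39.9
    refresh: float = 13.3
    rt_limit: float = 800.0
    rt_grace: float = 100.0
    within_subject_rho: float = 0.7
    # within-participant trial-level dispersion (free parameters of the
    # generator; the study reports only between-participant SDs)
    rt_sigma_no_stop: float = 60.0
    rt_tau_no_stop: float = 90.0
    rt_sigma_go_only: float = 40.0
    rt_tau_go_only: float = 60.0
    mt_sigma: float = 60.0
    # participant-level spread of the context-effect deltas (no-stop minus
    # go-only).  Carved out of the go-only between-participant SD so that
    # the marginal cell SDs stay at their preset values while individual
    # participants differ in how strongly they express the context effect.
    context_delta_sd_rt: float = 30.0
    context_delta_sd_mt: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isclose(self.ssd_init, 9 * self.refresh):
            raise ValueError("ssd_init must equal nine refresh quanta")
        if not math.isclose(self.ssd_step, 3 * self.refresh):
            raise ValueError("ssd_step must equal three refresh quanta")
        if not 0 < self.stop_proportion < 1:
            raise ValueError("stop_proportion must lie in (0, 1)")
        if self.n_sst_trials % self.block_size:
            raise ValueError("n_sst_trials must be a whole number of blocks")


@dataclass
class StaircaseState:
    """Current SSD of the tracking staircase plus its full history."""

    current_ssd: float
    history: list[tuple[float, str]] = field(default_factory=list)


def staircase_update(
    state: StaircaseState, outcome: str, config: CohortConfig
) -> StaircaseState:
    """Advance the SSD staircase after one stop trial.

    A successful stop makes the next stop harder (SSD + 39.9 ms); a
    failed stop makes it easier (SSD - 39.9 ms, clamped at 0).
    """
    if outcome not in ("stop_success", "stop_failure"):
        raise ValueError(f"not a stop-trial outcome: {outcome!r}")
    step = config.ssd_step if outcome == "stop_success" else -config.ssd_step
    new_ssd = max(0.0, state.current_ssd + step)
    return StaircaseState(
        current_ssd=new_ssd, history=state.history + [(state.current_ssd, outcome)]
    )


def _correlated_z(rng: np.random.Generator, rho: float, n: int) -> np.ndarray:
    """Draw n pairs of standard-normal effects with correlation rho, shape (n, 2)."""
    z0 = rng.standard_normal(n)
    z1 = rng.standard_normal(n)
    return np.column_stack([z0, rho * z0 + math.sqrt(max(0.0, 1 - rho**2)) * z1])


def _params_from_z(
    config: CohortConfig,
    group: str,
    treatment: str,
    participant_id: str,
    z_rt: float,
    z_mt: float,
    z_ssrt: float,
    z_rt_delta: float = 0.0,
    z_mt_delta: float = 0.0,
) -> ParticipantParams:
    try:
        cell = config.presets[(group, treatment)]
    except KeyError as exc:
        raise KeyError(f"no preset for cell {(group, treatment)!r}") from exc

    def _split(sd: float, delta_sd: float) -> tuple[float, float]:
        d = min(delta_sd, sd)
        return math.sqrt(sd * sd - d * d), d

    # participant-level means; the same z shifts both task contexts so a
    # participant who is slow in one context is slow in the other, while
    # the delta component individualizes the size of the context effect
    # without inflating the marginal go-only SD
    rt_ns = cell.rt_no_stop[0] + cell.rt_no_stop[1] * z_rt
    s_sh, s_d = _split(cell.rt_go_only[1], config.context_delta_sd_rt)
    rt_go = cell.rt_go_only[0] + s_sh * z_rt + s_d * z_rt_delta
    mt_ns = cell.mt_no_stop[0] + cell.mt_no_stop[1] * z_mt
    s_sh, s_d = _split(cell.mt_go_only[1], config.context_delta_sd_mt)
    mt_go = cell.mt_go_only[0] + s_sh * z_mt + s_d * z_mt_delta
    ssrt = cell.ssrt[0] + cell.ssrt[1] * z_ssrt

    sst_rt = ExGauss(
        mu=max(1.0, rt_ns - config.rt_tau_no_stop),
        sigma=config.rt_sigma_no_stop,
        tau=config.rt_tau_no_stop,
    )
    go_rt = ExGauss(
        mu=max(1.0, rt_go - config.rt_tau_go_only),
        sigma=config.rt_sigma_go_only,
        tau=config.rt_tau_go_only,
    )
    # lapse rates calibrated so that observed accuracy matches the preset
    # after accounting for >900 ms aborts on no-stop trials
    p_abort = sst_rt.sf(config.rt_limit + config.rt_grace)
    lapse_ns = min(0.2, max(0.0, 1.0 - cell.acc_no_stop / max(1e-12, 1.0 - p_abort)))
    lapse_go = min(0.2, max(0.0, 1.0 - cell.acc_go_only))
    return ParticipantParams(
        participant_id=participant_id,
        group=group,
        treatment=treatment,
        go_only_rt=go_rt,
        sst_rt=sst_rt,
        ssrt_true=max(50.0, ssrt),
        mt_mu_go_only=max(50.0, mt_go),
        mt_mu_no_stop=max(50.0, mt_ns),
        mt_sigma=config.mt_sigma,
        lapse_go_only=lapse_go,
        lapse_no_stop=lapse_ns,
    )


def sample_participant(
    config: CohortConfig,
    group: str,
    treatment: str,
    rng: np.random.Generator,
    participant_id: str = "P00",
) -> ParticipantParams:
    """Draw one participant's parameters for a single session."""
    z = rng.standard_normal(5)
    return _params_from_z(config, group, treatment, participant_id, *z)


def preset_mean_participant(
    config: CohortConfig, group: str, treatment: str, participant_id: str = "P00"
) -> ParticipantParams:
    """The population-mean observer of a cell (all random effects zero).

    Useful as the representative stationary observer of a preset; with
    extreme tail draws (e.g. a very fast go process) the SSD floor at
    0 ms can pin the staircase and hold the failure rate above 50%,
    which is a property of the individual, not of the tracking rule.
    """
    return _params_from_z(config, group, treatment, participant_id, 0, 0, 0, 0, 0)


def sample_participant_pair(
    config: CohortConfig,
    group: str,
    rng: np.random.Generator,
    participant_id: str = "P00",
) -> dict[str, ParticipantParams]:
    """Draw OFF/ON parameters for one patient.

    The participant's random effects (one per parameter family: RT, MT,
    stop latency) are shared across treatment sessions with correlation
    ``within_subject_rho``, mimicking the within-subject design.
    """
    rho = config.within_subject_rho
    # rows: rt, mt, ssrt, rt-delta, mt-delta; cols: OFF, ON
    z = _correlated_z(rng, rho, 5)
    out = {}
    for col, treatment in enumerate(("OFF", "ON")):
        out[treatment] = _params_from_z(
            config, group, treatment, participant_id,
            z[0, col], z[1, col], z[2, col], z[3, col], z[4, col],
        )
    return out


def _draw_mt(rng: np.random.Generator, mu: float, sigma: float) -> float:
    return max(1.0, rng.normal(mu, sigma))


def simulate_go_only(
    params: ParticipantParams,
    n: int,
    rng: np.random.Generator,
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Simulate one go-only block: always respond, no RT limit."""
    if n <= 0:
        raise ValueError("n must be positive")
    if config is None:
        config = CohortConfig()
    upper = config.rt_limit + config.rt_grace
    rts = params.go_only_rt.sample(rng, n)
    lapse_u = rng.random(n)
    rows = {k: [] for k in ("block", "ssd", "rt", "mt", "outcome")}
    for i in range(n):
        rt = max(1.0, rts[i])
        rows["block"].append(1)
        rows["ssd"].append(np.nan)
        if rt > upper:
            rows["rt"].append(np.nan)
            rows["mt"].append(np.nan)
            rows["outcome"].append("aborted_over_900")
            continue
        if lapse_u[i] < params.lapse_go_only / 2:
            outcome = "target_miss"
        elif lapse_u[i] < params.lapse_go_only:
            outcome = "hold_violation"
        elif rt > config.rt_limit:
            outcome = "overtime_reaching"
        else:
            outcome = "correct"
        rows["rt"].append(rt)
        rows["mt"].append(_draw_mt(rng, params.mt_mu_go_only, params.mt_sigma))
        rows["outcome"].append(outcome)
    df = pd.DataFrame(rows)
    df.insert(0, "trial_type", "go_only")
    df.insert(0, "task", "go_only")
    return _annotate(df, params)


def simulate_sst(
    params: ParticipantParams,
    config: CohortConfig,
    rng: np.random.Generator,
    n_trials: int | None = None,
) -> pd.DataFrame:
    """Simulate one SST session under staircase SSD tracking.

    Blocks contain exactly ``stop_proportion`` stop trials in random
    positions; the staircase runs continuously across blocks.
    """
    n_trials = config.n_sst_trials if n_trials is None else n_trials
    if n_trials <= 0 or n_trials % config.block_size:
        raise ValueError("n_trials must be a positive multiple of block_size")
    n_blocks = n_trials // config.block_size
    n_stop_per_block = round(config.block_size * config.stop_proportion)
    state = StaircaseState(current_ssd=config.ssd_init)
    upper = config.rt_limit + config.rt_grace

    cols: dict[str, list] = {k: [] for k in ("block", "ssd", "trial_type", "rt", "mt", "outcome")}
    for block in range(1, n_blocks + 1):
        is_stop = np.zeros(config.block_size, dtype=bool)
        is_stop[:n_stop_per_block] = True
        rng.shuffle(is_stop)
        t_go = params.sst_rt.sample(rng, config.block_size)
        lapse_u = rng.random(config.block_size)
        for i in range(config.block_size):
            go_time = max(1.0, t_go[i])
            cols["block"].append(block)
            if is_stop[i]:
                ssd = state.current_ssd
                cols["trial_type"].append("stop")
                cols["ssd"].append(ssd)
                if go_time < ssd + params.ssrt_true:
                    outcome = "stop_failure"
                    cols["rt"].append(min(go_time, upper))
                    cols["mt"].append(
                        _draw_mt(rng, params.mt_mu_no_stop, params.mt_sigma)
                    )
                else:
                    outcome = "stop_success"
                    cols["rt"].append(np.nan)
                    cols["mt"].append(np.nan)
                cols["outcome"].append(outcome)
                state = staircase_update(state, outcome, config)
            else:
                cols["trial_type"].append("no_stop")
                cols["ssd"].append(np.nan)
                if go_time > upper:
                    cols["rt"].append(np.nan)
                    cols["mt"].append(np.nan)
                    cols["outcome"].append("aborted_over_900")
                    continue
                cols["rt"].append(go_time)
                cols["mt"].append(_draw_mt(rng, params.mt_mu_no_stop, params.mt_sigma))
                if lapse_u[i] < params.lapse_no_stop / 2:
                    cols["outcome"].append("target_miss")
                elif lapse_u[i] < params.lapse_no_stop:
                    cols["outcome"].append("hold_violation")
                elif go_time > config.rt_limit:
                    cols["outcome"].append("overtime_reaching")
                else:
                    cols["outcome"].append("correct")
    df = pd.DataFrame(cols)
    df.insert(0, "task", "sst")
    return _annotate(df, params)


def _annotate(df: pd.DataFrame, params: ParticipantParams) -> pd.DataFrame:
    df.insert(0, "treatment", params.treatment)
    df.insert(0, "group", params.group)
    df.insert(0, "participant_id", params.participant_id)
    return df


def simulate_study(config: CohortConfig) -> pd.DataFrame:
    """Simulate the whole cohort as one long-format trial table.

    Patients (three groups) are simulated in two counterbalanced
    sessions (OFF and ON); healthy controls in a single session.
    Deterministic given ``config.seed``.
    """
    frames: list[pd.DataFrame] = []
    for g_idx, group in enumerate(PATIENT_GROUPS):
        for p_idx in range(config.n_per_group):
            pid = f"{group.replace('&', '')}-{p_idx:02d}"
            rng_params = np.random.default_rng([config.seed, g_idx, p_idx, 0])
            pair = sample_participant_pair(config, group, rng_params, pid)
            # counterbalancing: alternate which treatment comes first
            order = ("OFF", "ON") if p_idx % 2 == 0 else ("ON", "OFF")
            for s_idx, treatment in enumerate(order, start=1):
                rng_t = np.random.default_rng([config.seed, g_idx, p_idx, s_idx])
                params = pair[treatment]
                go = simulate_go_only(params, config.n_go_only_trials, rng_t, config)
                sst = simulate_sst(params, config, rng_t)
                session = pd.concat([go, sst], ignore_index=True)
                session["session_order"] = s_idx
                frames.append(session)
    for p_idx in range(config.n_hc):
        pid = f"HC-{p_idx:02d}"
        rng_p = np.random.default_rng([config.seed, 3, p_idx, 0])
        params = sample_participant(config, "HC", "NA", rng_p, pid)
        rng_t = np.random.default_rng([config.seed, 3, p_idx, 1])
        go = simulate_go_only(params, config.n_go_only_trials, rng_t, config)
        sst = simulate_sst(params, config, rng_t)
        session = pd.concat([go, sst], ignore_index=True)
        session["session_order"] = 1
        frames.append(session)
    out = pd.concat(frames, ignore_index=True)
    return out[list(TRIAL_COLUMNS)]


def validate_trials(df: pd.DataFrame) -> None:
    """Raise ValueError if a trial table violates the schema invariants."""
    missing = set(TRIAL_COLUMNS) - {"session_order"} - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bad = ~df["outcome"].isin(OUTCOMES)
    if bad.any():
        raise ValueError(f"unknown outcomes in rows {df.index[bad][:5].tolist()}")
    stop = df["trial_type"] == "stop"
    if df.loc[stop, "ssd"].isna().any() or df.loc[~stop, "ssd"].notna().any():
        raise ValueError("ssd must be present iff trial_type == 'stop'")
    no_rt = df["outcome"].isin(["stop_success", "aborted_over_900"])
    if df.loc[no_rt, "rt"].notna().any() or df.loc[~no_rt, "rt"].isna().any():
        raise ValueError("rt must be absent iff outcome is stop_success/aborted")
    rts = df["rt"].dropna()
    if ((rts <= 0) | (rts > 900)).any():
        raise ValueError("recorded RTs must lie in (0, 900]")


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table as TSV with 'NA' for missing values."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_trials(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    # healthy controls carry the literal treatment label "NA"
    if "treatment" in df.columns:
        df["treatment"] = df["treatment"].fillna("NA")
    return df
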