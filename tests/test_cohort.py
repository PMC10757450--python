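"""Generator unit and property tests: staircase, sampling, race model."""

import numpy as np
import pandas as pd
import pytest

from stopsignal.cohort import (
    CohortConfig,
    StaircaseState,
    read_trials,
    sample_participant,
    sample_participant_pair,
    simulate_go_only,
    simulate_sst,
    simulate_study,
    staircase_update,
    validate_trials,
    write_trials,
)

from conftest import make_params


class TestStaircase:
    def test_success_raises_ssd_by_one_step(self, config):
        state = StaircaseState(current_ssd=119.7)
        assert staircase_update(state, "stop_success", config).current_ssd == pytest.approx(159.6)

    def test_failure_lowers_ssd_by_one_step(self, config):
        state = StaircaseState(current_ssd=119.7)
        assert staircase_update(state, "stop_failure", config).current_ssd == pytest.approx(79.8)

    def test_clamped_at_zero(self, config):
        state = StaircaseState(current_ssd=0.0)
        assert staircase_update(state, "stop_failure", config).current_ssd == 0.0

    def test_rejects_non_stop_outcome(self, config):
        with pytest.raises(ValueError):
            staircase_update(StaircaseState(current_ssd=100.0), "correct", config)

    def test_history_appended(self, config):
        state = StaircaseState(current_ssd=119.7)
        state = staircase_update(state, "stop_success", config)
        state = staircase_update(state, "stop_failure", config)
        assert [o for _, o in state.history] == ["stop_success", "stop_failure"]


class TestSampling:
    def test_hc_ssrt_population_mean(self, config):
        rng = np.random.default_rng(5)
        draws = [
            sample_participant(config, "HC", "NA", rng).ssrt_true for _ in range(4000)
        ]
        assert np.mean(draws) == pytest.approx(221.9, abs=1.5)

    def test_perfect_within_subject_correlation(self):
        cfg = CohortConfig(within_subject_rho=1.0)
        pair = sample_participant_pair(cfg, "H&Y3", np.random.default_rng(0))
        # identical random effects -> OFF/ON params differ only through
        # the cell presets; equal-z means deterministic offset
        off, on = pair["OFF"], pair["ON"]
        z_off = (off.ssrt_true - 277.2) / 39.0
        z_on = (on.ssrt_true - 267.7) / 42.6
        assert z_off == pytest.approx(z_on)

    def test_zero_rho_gives_uncorrelated_effects(self):
        cfg = CohortConfig(within_subject_rho=0.0)
        rng = np.random.default_rng(1)
        off, on = [], []
        for _ in range(10_000):
            pair = sample_participant_pair(cfg, "H&Y1", rng)
            off.append(pair["OFF"].ssrt_true)
            on.append(pair["ON"].ssrt_true)
        r = np.corrcoef(off, on)[0, 1]
        assert abs(r) < 0.05

    def test_unknown_preset_raises(self, config, rng):
        with pytest.raises(KeyError):
            sample_participant(config, "H&Y9", "OFF", rng)


class TestGoOnly:
    def test_mean_rt_matches_generative_value(self, rng):
        params = make_params(lapse_go=0.0)
        trials = simulate_go_only(params, 10_000, rng)
        assert trials["rt"].mean() == pytest.approx(306.5, abs=3.0)

    def test_degenerate_distribution(self, rng):
        params = make_params(sigma_go=0.0, tau_go=0.0)
        trials = simulate_go_only(params, 50, rng)
        assert (trials["rt"] == params.go_only_rt.mu).all()

    def test_lapse_rate_binomial(self, rng):
        params = make_params(lapse_go=0.2)  # 0.1 target_miss + 0.1 hold
        trials = simulate_go_only(params, 10_000, rng)
        miss = (trials["outcome"] == "target_miss").mean()
        assert miss == pytest.approx(0.1, abs=0.01)

    def test_rejects_nonpositive_n(self, hc_params, rng):
        with pytest.raises(ValueError):
            simulate_go_only(hc_params, 0, rng)


class TestSST:
    def test_staircase_tracks_half_failures(self, config, hc_params):
        rng = np.random.default_rng(2)
        trials = simulate_sst(hc_params, config, rng, n_trials=1440)  # 480 stop
        stop = trials[trials["trial_type"] == "stop"]
        assert len(stop) == 480
        p_fail = (stop["outcome"] == "stop_failure").mean()
        assert abs(p_fail - 0.5) < 0.05

    def test_staircase_converged_in_second_half(self, config, hc_params):
        rng = np.random.default_rng(3)
        trials = simulate_sst(hc_params, config, rng, n_trials=2160)
        stop = trials[trials["trial_type"] == "stop"].reset_index(drop=True)
        late = stop.iloc[len(stop) // 2:]
        assert abs((late["outcome"] == "stop_failure").mean() - 0.5) < 0.05

    def test_infinite_stop_latency_never_stops(self, config, rng):
        params = make_params(ssrt=1e9)
        trials = simulate_sst(params, config, rng)
        stop = trials[trials["trial_type"] == "stop"]
        assert (stop["outcome"] == "stop_failure").all()

    def test_censoring_property_failure_rts_faster(self, config, hc_params):
        # stop failures are the fast tail of the go distribution
        rng = np.random.default_rng(4)
        trials = simulate_sst(hc_params, config, rng, n_trials=10_080)
        fail = trials.loc[trials["outcome"] == "stop_failure", "rt"]
        ns = trials.loc[trials["trial_type"] == "no_stop", "rt"].dropna()
        assert fail.mean() < ns.mean()

    def test_ssd_on_refresh_grid(self, config, hc_params, rng):
        trials = simulate_sst(hc_params, config, rng)
        ssds = trials["ssd"].dropna().to_numpy()
        steps = np.round(ssds / config.refresh)
        assert np.allclose(ssds, steps * config.refresh, atol=1e-6)

    def test_stop_proportion_exact_per_block(self, config, hc_params, rng):
        trials = simulate_sst(hc_params, config, rng)
        per_block = trials.groupby("block")["trial_type"].apply(
            lambda s: (s == "stop").mean()
        )
        assert np.allclose(per_block, 1 / 3)

    def test_mean_ssd_recovers_race_quantile(self, config):
        # at convergence the staircase sits where P(respond)=0.5:
        # mean SSD ~ median go finishing time minus the stop latency
        params = make_params(ssrt=250.0)
        rng = np.random.default_rng(6)
        trials = simulate_sst(params, config, rng, n_trials=30_240)  # ~10k stop
        stop = trials[trials["trial_type"] == "stop"]
        go_median = np.quantile(
            params.sst_rt.sample(np.random.default_rng(7), 200_000), 0.5
        )
        assert stop["ssd"].mean() == pytest.approx(go_median - 250.0, abs=15.0)


class TestStudy:
    def test_shape_and_determinism(self):
        cfg = CohortConfig(
            n_per_group=2, n_hc=2, n_go_only_trials=10, n_sst_trials=108,
            block_size=108, seed=9,
        )
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        pd.testing.assert_frame_equal(a, b)
        validate_trials(a)
        sessions = a.groupby(["participant_id", "treatment"]).ngroups
        assert sessions == 2 * 3 * 2 + 2  # patients x 2 sessions + HC x 1
        # counterbalancing alternates
        orders = a.groupby(["participant_id", "treatment"])["session_order"].first()
        assert set(orders) == {1, 2}

    def test_tsv_roundtrip(self, tmp_path):
        cfg = CohortConfig(
            n_per_group=2, n_hc=1, n_go_only_trials=5, n_sst_trials=108,
            block_size=108, seed=3,
        )
        df = simulate_study(cfg)
        path = tmp_path / "trials.tsv"
        write_trials(df, path)
        back = read_trials(path)
        assert (back["treatment"].isin(["ON", "OFF", "NA"])).all()
        pd.testing.assert_frame_equal(df, back, check_dtype=False)

    def test_generator_cell_means_match_presets(self):
        # per-cell grand means across replicate cohorts stay within
        # 2 SEM of the preset (study-sized n per cell)
        from stopsignal.preprocess import trim_outliers
        from stopsignal.proactive import context_cell_means
        from stopsignal.reactive import reactive_table

        cells: dict = {}
        n_rep = 5
        for rep in range(n_rep):
            cfg = CohortConfig(seed=100 + rep)
            trials = simulate_study(cfg)
            trimmed, _ = trim_outliers(trials)
            means = context_cell_means(trimmed)
            ssrt = reactive_table(trimmed)
            merged = means.merge(ssrt, on=["participant_id", "group", "treatment"])
            for (grp, trt), sub in merged.groupby(["group", "treatment"]):
                cells.setdefault((grp, trt), []).append(
                    sub[["rt_no_stop", "rt_go_only", "mt_no_stop", "mt_go_only", "ssrt"]].mean()
                )
        from stopsignal.presets import DEFAULT_PRESETS

        for key, reps in cells.items():
            avg = pd.concat(reps, axis=1).mean(axis=1)
            preset = DEFAULT_PRESETS[key]
            n = 30 if key[0] == "HC" else 20
            for field in ("rt_no_stop", "rt_go_only", "mt_no_stop", "mt_go_only", "ssrt"):
                mean, sd = getattr(preset, field)
                sem2 = 2 * sd / np.sqrt(n)
                assert abs(avg[field] - mean) < sem2, (key, field, avg[field], mean)
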