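"""Split-plot ANOVA against independent oracles (statsmodels OLS
decomposition, pingouin) plus marginal-mean and contrast arithmetic."""

import itertools

import numpy as np
import pandas as pd
import pytest

from stopsignal.stats import (
    cohens_d,
    estimated_marginal_means,
    mixed_anova,
    posthoc_pairwise,
)


def make_long(rng, n_groups=2, n_subj=4, w1=2, w2=None, sigma=1.0, effects=True):
    rows = []
    sid = 0
    for g in range(n_groups):
        for s in range(n_subj):
            sid += 1
            subj_eff = rng.normal(0, 1)
            for a in range(w1):
                for b in range(w2 or 1):
                    val = rng.normal(0, sigma) + subj_eff
                    if effects:
                        val += g * 1.5 + a * 0.8 + (g * a) * 0.5 + (b or 0) * 0.3
                    row = {
                        "participant_id": f"S{sid}",
                        "group": f"G{g}",
                        "w1": f"a{a}",
                        "dv": val,
                    }
                    if w2:
                        row["w2"] = f"b{b}"
                    rows.append(row)
    return pd.DataFrame(rows)


def projection_ss(data, within):
    """Independent oracle: quadratic forms of orthogonalized projection
    matrices built from raw dummy designs (pinv route, no cell-mean
    formulas).  Returns SS per effect including the error strata."""
    y = data["dv"].to_numpy(dtype=float)
    n = len(y)

    def proj(X):
        return X @ np.linalg.pinv(X)

    def dummies(*cols):
        key = data[list(cols)].astype(str).agg("|".join, axis=1)
        return pd.get_dummies(key).to_numpy(dtype=float)

    P0 = proj(np.ones((n, 1)))
    PG = proj(dummies("group"))
    PS = proj(dummies("participant_id"))
    out = {"group": PG - P0, "subject": PS - PG}
    if len(within) >= 1:
        PA = proj(dummies("w1"))
        PGA = proj(dummies("group", "w1"))
        PSA = proj(dummies("participant_id", "w1"))
        out["w1"] = PA - P0
        out["group * w1"] = PGA - PG - PA + P0
        out["w1 x subject"] = PSA - PS - PGA + PG
    if len(within) == 2:
        PB = proj(dummies("w2"))
        PGB = proj(dummies("group", "w2"))
        PSB = proj(dummies("participant_id", "w2"))
        PAB = proj(dummies("w1", "w2"))
        PGAB = proj(dummies("group", "w1", "w2"))
        out["w2"] = PB - P0
        out["group * w2"] = PGB - PG - PB + P0
        out["w2 x subject"] = PSB - PS - PGB + PG
        out["w1 * w2"] = PAB - PA - PB + P0
        out["group * w1 * w2"] = PGAB - PGA - PGB - PAB + PG + PA + PB - P0
        out["w1 x w2 x subject"] = np.eye(n) - P0 - sum(out.values())
    return {k: float(y @ P @ y) for k, P in out.items()}


class TestDecomposition:
    @pytest.mark.parametrize("w2", [None, 2, 3])
    def test_matches_projection_oracle(self, w2):
        rng = np.random.default_rng(0)
        within = ["w1"] + (["w2"] if w2 else [])
        data = make_long(rng, n_groups=3, n_subj=4, w1=2, w2=w2)
        fit = mixed_anova(data, "dv", "group", within)
        ref = projection_ss(data, within)
        for effect, ss_ref in ref.items():
            assert fit.ss_all[effect] == pytest.approx(ss_ref, abs=1e-8), effect

    def test_frozen_two_within_strata(self):
        # values independently verified with R's aov Error() strata for
        # this exact dataset (3 groups x 4 subjects x 2 x 3 within)
        rng = np.random.default_rng(0)
        rows, sid = [], 0
        for g in range(3):
            for s in range(4):
                sid += 1
                se = rng.normal()
                for a in range(2):
                    for b in range(3):
                        val = (
                            rng.normal() + se + g * 1.5 + a * 0.8
                            + g * a * 0.5 + b * 0.3 + a * b * 0.2
                        )
                        rows.append(
                            {
                                "participant_id": f"S{sid}",
                                "group": f"G{g}",
                                "w1": f"a{a}",
                                "w2": f"b{b}",
                                "dv": val,
                            }
                        )
        fit = mixed_anova(pd.DataFrame(rows), "dv", "group", ["w1", "w2"])
        expected = {
            "group": 170.65,
            "subject": 49.35,
            "w1": 46.11,
            "group * w1": 3.69,
            "w1 x subject": 6.22,
            "w2": 7.810,
            "group * w2": 3.297,
            "w2 x subject": 15.755,
            "w1 * w2": 0.913,
            "group * w1 * w2": 0.636,
            "w1 x w2 x subject": 20.853,
        }
        for effect, ss_ref in expected.items():
            assert fit.ss_all[effect] == pytest.approx(ss_ref, abs=0.005), effect

    def test_exhaustive_toy_2x2x2_designs(self):
        # all sign patterns of group/within/interaction effects on the
        # smallest balanced split-plot
        for sg, sa, si in itertools.product([-1, 0, 1], repeat=3):
            rows = []
            for g in range(2):
                for s in range(2):
                    for a in range(2):
                        val = (
                            0.37 * (s + 1) * (g + 1)  # subject offsets
                            + sg * g + sa * a + si * g * a
                        )
                        rows.append(
                            {
                                "participant_id": f"S{g}{s}",
                                "group": f"G{g}",
                                "w1": f"a{a}",
                                "dv": float(val),
                            }
                        )
            data = pd.DataFrame(rows)
            fit = mixed_anova(data, "dv", "group", "w1")
            ref = projection_ss(data, ["w1"])
            for effect, ss_ref in ref.items():
                assert fit.ss_all[effect] == pytest.approx(ss_ref, abs=1e-10), effect

    @pytest.mark.parametrize("w2", [None, 2])
    def test_ss_conservation(self, w2):
        rng = np.random.default_rng(1)
        data = make_long(rng, n_groups=3, n_subj=5, w1=3 if not w2 else 2, w2=w2)
        fit = mixed_anova(data, "dv", "group", ["w1"] + (["w2"] if w2 else []))
        total = ((data["dv"] - data["dv"].mean()) ** 2).sum()
        assert sum(fit.ss_all.values()) == pytest.approx(total, rel=1e-8)

    def test_matches_pingouin_one_within(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        data = make_long(rng, n_groups=3, n_subj=6, w1=2)
        fit = mixed_anova(data, "dv", "group", "w1")
        ref = pg.mixed_anova(
            data=data, dv="dv", between="group", within="w1", subject="participant_id"
        ).set_index("Source")
        tab = fit.table.set_index("effect")
        assert tab.loc["group", "F"] == pytest.approx(ref.loc["group", "F"])
        assert tab.loc["w1", "F"] == pytest.approx(ref.loc["w1", "F"])
        assert tab.loc["group * w1", "F"] == pytest.approx(ref.loc["Interaction", "F"])
        assert tab.loc["group", "partial_eta_sq"] == pytest.approx(ref.loc["group", "np2"])

    def test_constant_dv_all_zero(self):
        rng = np.random.default_rng(3)
        data = make_long(rng, sigma=0.0, effects=False)
        data["dv"] = 5.0
        fit = mixed_anova(data, "dv", "group", "w1")
        assert (fit.table["F"] == 0).all()
        assert (fit.table["partial_eta_sq"] == 0).all()
        assert (fit.table["p"] == 1).all()

    def test_incomplete_cell_raises(self):
        rng = np.random.default_rng(4)
        data = make_long(rng).iloc[:-1]
        with pytest.raises(ValueError):
            mixed_anova(data, "dv", "group", "w1")

    def test_between_only_matches_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(5)
        data = make_long(rng, n_groups=3, n_subj=8, w1=1).drop(columns="w1")
        fit = mixed_anova(data, "dv", "group", None)
        groups = [g["dv"].to_numpy() for _, g in data.groupby("group")]
        ref = sps.f_oneway(*groups)
        row = fit.table.iloc[0]
        assert row["F"] == pytest.approx(ref.statistic)
        assert row["p"] == pytest.approx(ref.pvalue)


class TestMarginalMeans:
    def test_single_cell_is_itself(self):
        cells = pd.DataFrame({"g": ["A"], "t": ["x"], "v": [3.0]})
        out = estimated_marginal_means(cells, "v", ["g"])
        assert out.loc["A"] == 3.0

    def test_2x2_grand_mean(self):
        cells = pd.DataFrame(
            {"g": ["A", "A", "B", "B"], "t": ["x", "y", "x", "y"], "v": [1, 2, 3, 4.0]}
        )
        assert estimated_marginal_means(cells, "v", []).iloc[0] == 2.5

    def test_hy3_marginal_ssrt(self):
        from stopsignal.presets import behavioural_summary

        cells = behavioural_summary()
        pats = cells[cells["group"] != "HC"]
        marg = estimated_marginal_means(pats, "ssrt", ["group"])
        assert marg.loc["H&Y3"] == pytest.approx(272.45)


class TestPosthoc:
    @pytest.fixture
    def fit(self):
        rng = np.random.default_rng(6)
        data = make_long(rng, n_groups=3, n_subj=8, w1=2)
        return mixed_anova(data, "dv", "group", "w1")

    def test_between_contrast_matches_hand_formula(self, fit):
        res = posthoc_pairwise(fit, [("G0-G1", {"group": "G0"}, {"group": "G1"})])
        ms_subj = fit.ms["subject"]
        w = 2
        se_hand = np.sqrt(ms_subj * (1 / 8 + 1 / 8) / w)
        assert res.loc[0, "se"] == pytest.approx(se_hand)
        assert res.loc[0, "df"] == fit.df_err["subject"]

    def test_within_contrast_uses_interaction_stratum(self, fit):
        res = posthoc_pairwise(fit, [("a0-a1", {"w1": "a0"}, {"w1": "a1"})])
        ms_ws = fit.ms["w1 x subject"]
        # marginal within contrast over 3 groups of 8 subjects
        se_hand = np.sqrt(ms_ws * 2 / 24)
        assert res.loc[0, "se"] == pytest.approx(se_hand)
        assert res.loc[0, "df"] == fit.df_err["w1 x subject"]

    def test_identical_cells_give_null_comparison(self):
        rows = []
        for s in range(4):
            for g in range(2):
                for a in range(2):
                    rows.append(
                        {
                            "participant_id": f"S{g}{s}",
                            "group": f"G{g}",
                            "w1": f"a{a}",
                            "dv": float(s),
                        }
                    )
        fit = mixed_anova(pd.DataFrame(rows), "dv", "group", "w1")
        res = posthoc_pairwise(fit, [("null", {"group": "G0"}, {"group": "G1"})])
        assert res.loc[0, "t"] == pytest.approx(0.0, abs=1e-10)
        assert res.loc[0, "p_bonferroni"] == 1.0

    def test_bonferroni_and_ci_invariants(self, fit):
        comps = [
            ("G0-G1", {"group": "G0"}, {"group": "G1"}),
            ("G0-G2", {"group": "G0"}, {"group": "G2"}),
            ("G1-G2", {"group": "G1"}, {"group": "G2"}),
        ]
        res = posthoc_pairwise(fit, comps)
        assert (res["p_bonferroni"] >= res["p_raw"] - 1e-15).all()
        assert (res["ci95_lo"] <= res["m_diff"]).all()
        assert (res["m_diff"] <= res["ci95_hi"]).all()


class TestCohensD:
    def test_unit_effect(self):
        assert cohens_d("between_pooled", 1.0, (1.0, 1.0), (10, 10)) == 1.0

    def test_within_average_sd_variant(self):
        # printed group summaries: means 227.0/252.3, SDs 34.1/37.7
        d = cohens_d("within_av", 252.3 - 227.0, (34.1, 37.7))
        assert d == pytest.approx(0.70, abs=0.01)

    def test_zero_sd_raises(self):
        with pytest.raises(ZeroDivisionError):
            cohens_d("within_av", 1.0, (0.0, 0.0))
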