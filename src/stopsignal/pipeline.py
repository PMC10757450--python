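"""End-to-end orchestration: simulate -> preprocess -> reactive ->
proactive -> statistics, emitting report tables as plain CSV plus a
JSON run manifest.  Everything is deterministic given the seed."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, simulate_study, validate_trials, write_trials
from .preprocess import DEFAULT_SCOPE, accuracy_table, trim_outliers
from .presets import PATIENT_GROUPS, TREATMENTS
from .proactive import (
    build_population_cdf,
    context_cell_means,
    context_frequencies,
    individual_context_table,
    population_context_test,
)
from .reactive import reactive_table
from .stats import (
    chi2_homogeneity,
    chi2_independence_ncorr,
    context_table,
    mixed_anova,
    posthoc_pairwise,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Tunable knobs of the full analysis run."""

    alpha: float = 0.05
    bf_rscale: float = 0.707
    trim_scope: tuple[str, ...] = DEFAULT_SCOPE
    ks_exact_limit: int = 10_000
    overtime_as_correct: bool = True
    seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(seed=self.seed, **self.cohort)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trim_scope"] = list(self.trim_scope)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "trim_scope" in d:
            d["trim_scope"] = tuple(d["trim_scope"])
        return cls(**d)

    def to_file(self, path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)


def _patients(df: pd.DataFrame) -> pd.DataFrame:
    return df[df["group"].isin(PATIENT_GROUPS)]


def ssrt_analysis(reactive: pd.DataFrame, cfg: AnalysisConfig) -> dict:
    """Stop-latency ANOVA and post hocs on the per-session estimates."""
    pats = _patients(reactive)
    fit = mixed_anova(pats, dv="ssrt", between="group", within="treatment")
    groups = sorted(pats["group"].unique())
    comps = [
        (f"{a} vs {b}", {"group": a}, {"group": b})
        for a, b in [(groups[0], groups[1]), (groups[0], groups[2]), (groups[1], groups[2])]
    ]
    posthoc_groups = posthoc_pairwise(fit, comps, bf_rscale=cfg.bf_rscale)
    comps_inter = [
        (
            f"{g} OFF vs ON",
            {"group": g, "treatment": "OFF"},
            {"group": g, "treatment": "ON"},
        )
        for g in groups
    ]
    posthoc_inter = posthoc_pairwise(fit, comps_inter, bf_rscale=cfg.bf_rscale)
    out = {
        "ssrt_anova": fit.table,
        "ssrt_posthoc_group": posthoc_groups,
        "ssrt_posthoc_treatment": posthoc_inter,
    }
    # one-way comparisons of each treatment state against healthy controls
    for trt in TREATMENTS:
        sub = reactive[
            (reactive["treatment"] == trt) | (reactive["group"] == "HC")
        ]
        fit_hc = mixed_anova(sub, dv="ssrt", between="group", within=None)
        out[f"ssrt_anova_vs_hc_{trt.lower()}"] = fit_hc.table
    return out


def context_mean_analysis(cell_means: pd.DataFrame, cfg: AnalysisConfig) -> dict:
    """Three-way RT and MT ANOVAs on the patient cell means."""
    pats = _patients(cell_means)
    out = {}
    for measure in ("rt", "mt"):
        long = pats.melt(
            id_vars=["participant_id", "group", "treatment"],
            value_vars=[f"{measure}_no_stop", f"{measure}_go_only"],
            var_name="trial_type",
            value_name=measure,
        )
        long["trial_type"] = long["trial_type"].str.replace(f"{measure}_", "", regex=False)
        fit = mixed_anova(
            long, dv=measure, between="group", within=["treatment", "trial_type"]
        )
        groups = sorted(pats["group"].unique())
        comps = [
            (
                "no-stop vs go-only",
                {"trial_type": "no_stop"},
                {"trial_type": "go_only"},
            )
        ]
        comps += [
            (
                f"no-stop {a} vs {b}",
                {"group": a, "trial_type": "no_stop"},
                {"group": b, "trial_type": "no_stop"},
            )
            for a, b in [(groups[0], groups[1]), (groups[0], groups[2]), (groups[1], groups[2])]
        ]
        comps += [
            (
                f"{g} no-stop vs go-only",
                {"group": g, "trial_type": "no_stop"},
                {"group": g, "trial_type": "go_only"},
            )
            for g in groups
        ]
        fit_posthoc = posthoc_pairwise(fit, comps, bf_rscale=cfg.bf_rscale)
        out[f"{measure}_anova"] = fit.table
        out[f"{measure}_posthoc"] = fit_posthoc
    return out


def frequency_analysis(frequencies: pd.DataFrame, cfg: AnalysisConfig) -> dict:
    """Chi-square homogeneity across groups and pairwise tests vs HC."""
    out = {}
    homog_rows, pair_rows = [], []
    for trt in TREATMENTS:
        tab = context_table(frequencies, trt)
        try:
            res = chi2_homogeneity(tab.to_numpy())
        except ValueError:
            logger.warning("degenerate %s homogeneity table (zero marginal)", trt)
            res = None
        for gi, grp in enumerate(tab.index):
            homog_rows.append(
                {
                    "treatment": trt,
                    "group": grp,
                    "chi2": res.chi2 if res else np.nan,
                    "df": res.df if res else np.nan,
                    "p": res.p if res else np.nan,
                    "bf10": res.bf10 if res else np.nan,
                    "std_residual": res.std_residuals[gi, 0] if res else np.nan,
                    "residual_p_bonferroni": (
                        res.residual_p_bonferroni[gi, 0] if res else np.nan
                    ),
                }
            )
        hc = tab.loc["HC"]
        for grp in tab.index:
            if grp == "HC":
                continue
            pair = np.array([hc.to_numpy(), tab.loc[grp].to_numpy()])
            try:
                pres = chi2_independence_ncorr(pair)
                chi2_v, p_v, bf_v = pres.chi2, pres.p, pres.bf10
            except ValueError:
                logger.warning("degenerate 2x2 table HC vs %s (%s)", grp, trt)
                chi2_v = p_v = bf_v = np.nan
            pair_rows.append(
                {
                    "comparison": f"HC vs {grp}",
                    "treatment": trt,
                    "N": int(pair.sum()),
                    "chi2": chi2_v,
                    "df": 1,
                    "p": p_v,
                    "bf10": bf_v,
                }
            )
    out["chi2_homogeneity"] = pd.DataFrame(homog_rows)
    out["chi2_vs_hc"] = pd.DataFrame(pair_rows)
    return out


def behavioural_summary_observed(
    trimmed: pd.DataFrame, reactive: pd.DataFrame, cell_means: pd.DataFrame,
    accuracy: pd.DataFrame,
) -> pd.DataFrame:
    """Observed per-cell mean +/- SD of every behavioural measure."""
    merged = reactive.merge(cell_means, on=["participant_id", "group", "treatment"])
    merged = merged.merge(accuracy, on=["participant_id", "group", "treatment"])
    sf = (
        trimmed[trimmed["outcome"] == "stop_failure"]
        .groupby(["participant_id", "group", "treatment"], observed=True)["rt"]
        .mean()
        .rename("rt_stop_failure")
        .reset_index()
    )
    merged = merged.merge(sf, on=["participant_id", "group", "treatment"], how="left")
    measures = [
        "ssrt", "p_failure", "mean_ssd", "rt_no_stop", "mt_no_stop",
        "rt_stop_failure", "rt_go_only", "mt_go_only", "acc_sst", "acc_go_only",
    ]
    rows = []
    for (grp, trt), sub in merged.groupby(["group", "treatment"], observed=True):
        for m in measures:
            if m in sub:
                rows.append(
                    {
                        "group": grp,
                        "treatment": trt,
                        "measure": m,
                        "mean": float(sub[m].mean()),
                        "sd": float(sub[m].std(ddof=1)),
                        "n": int(sub[m].notna().sum()),
                    }
                )
    return pd.DataFrame(rows)


def run_pipeline(
    config: AnalysisConfig,
    outdir: str | Path | None = None,
    trials: pd.DataFrame | None = None,
) -> dict:
    """Run the full analysis; returns a dict of result tables.

    When ``outdir`` is given every table is written as CSV (trial
    tables as TSV) together with ``manifest.json``.
    """
    if trials is None:
        trials = simulate_study(config.cohort_config())
    validate_trials(trials)

    trimmed, trim_reports = trim_outliers(trials, config.trim_scope)
    accuracy = accuracy_table(trials, config.overtime_as_correct)
    reactive = reactive_table(trimmed)
    n_flagged = int((reactive["independence_ok"] == False).sum())  # noqa: E712
    if n_flagged:
        logger.warning("%d sessions fail the race independence check", n_flagged)
    cell_means = context_cell_means(trimmed)

    results: dict = {
        "trials": trials,
        "trim_report": [r.to_dict() for r in trim_reports],
        "accuracy": accuracy,
        "reactive": reactive,
        "cell_means": cell_means,
    }
    results["behavioural_summary"] = behavioural_summary_observed(
        trimmed, reactive, cell_means, accuracy
    )
    results.update(ssrt_analysis(reactive, config))
    results.update(context_mean_analysis(cell_means, config))

    categories = individual_context_table(trimmed, alpha=config.alpha)
    frequencies = context_frequencies(categories)
    results["context_categories"] = categories
    results["context_frequencies"] = frequencies
    results.update(frequency_analysis(frequencies, config))

    pop_rows, cdf_rows = [], []
    for (grp, trt), sub in trimmed.groupby(["group", "treatment"], observed=True):
        pop = population_context_test(sub, alpha=config.alpha)
        pop_rows.append(
            {
                "group": grp,
                "treatment": trt,
                "rt_verdict": pop["rt_verdict"],
                "mt_verdict": pop["mt_verdict"],
                "overall": pop["overall"],
                "rt_p_expected": pop["rt_test_expected"].p_value,
                "mt_p_expected": pop["mt_test_expected"].p_value,
                "mt_p_opposite": pop["mt_test_opposite"].p_value,
            }
        )
        for measure in ("rt", "mt"):
            for tt in ("no_stop", "go_only"):
                cdf = build_population_cdf(sub, measure, tt)
                cdf_rows.append(
                    pd.DataFrame(
                        {
                            "group": grp,
                            "treatment": trt,
                            "measure": measure,
                            "trial_type": tt,
                            "grid": cdf.grid,
                            "cdf": cdf.cdf,
                        }
                    )
                )
    results["population_context"] = pd.DataFrame(pop_rows)
    results["population_cdfs"] = pd.concat(cdf_rows, ignore_index=True)

    if outdir is not None:
        _write_bundle(results, config, Path(outdir))
    return results


def _write_bundle(results: dict, config: AnalysisConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in results.items():
        if name == "trials":
            path = outdir / "trials.tsv"
            write_trials(obj, path)
        elif isinstance(obj, pd.DataFrame):
            path = outdir / f"{name}.csv"
            obj.to_csv(path, index=False)
        else:
            path = outdir / f"{name}.json"
            path.write_text(json.dumps(obj, indent=2))
        written.append(path.name)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "outputs": sorted(written),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
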