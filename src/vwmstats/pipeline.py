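"""End-to-end orchestration: read trials, apply exclusions, fit per-cell
estimates, run the full analysis graph, and emit a machine-readable report.

Canonical trial CSV schema (UTF-8, header required): participant_id, group,
phase, task, set_size, practice, target_deg, response_deg, change_trial,
response_key, rt_ms, omitted. Degrees use the [0, 360) convention; recall
errors are computed internally as target-relative angles in (-pi, pi].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import bic_bf_approx, gd_contingency_bf, jzs_bf_ttest
from .change_detection import pashler_k, summarize_detection_trials
from .circular import wrap_error
from .robust import TestResult, akp_delta, mixed_anova, rm_anova_2within, yuen_independent, yuen_paired
from .simulate import ODT, ORT, REPRODUCTION_TASKS, SRT, TEST_PHASES, TRAINING_PHASES, TRIAL_COLUMNS, VST
from .smm import FitConfig, InsufficientDataError, fit_smm

from scipy import stats

__all__ = [
    "ExclusionConfig",
    "ExclusionReport",
    "AnalysisConfig",
    "load_trials",
    "apply_exclusions",
    "fit_all_cells",
    "density_comparison",
    "run_full_analysis",
    "write_report",
]

log = logging.getLogger("vwmstats")

REQUIRED_COLUMNS = set(TRIAL_COLUMNS)


@dataclass(frozen=True)
class ExclusionConfig:
    """Participant exclusion thresholds.

    A participant is excluded when, in any task within a phase, the number of
    logged test trials exceeds the expected count by strictly more than
    ``extra_trials_frac`` (10%, i.e. more than 12 extra on a 120-trial task
    excludes; exactly 12 is retained). The RT and omission rules are
    configurable stand-ins for online attention-check criteria: excluded
    when the share of sub-floor RTs or of omissions in any task exceeds the
    ceiling.
    """

    expected_test_trials: int = 120
    expected_training_trials: int = 360
    extra_trials_frac: float = 0.10
    rt_floor_ms: float = 200.0
    fast_rt_max_frac: float = 0.20
    omission_max_frac: float = 0.20


@dataclass(frozen=True)
class ExclusionReport:
    participant_id: str
    rule_triggered: str  # extra_trials | rt_criterion | omission_criterion | missing_data
    detail: str

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "rule_triggered": self.rule_triggered,
            "detail": self.detail,
        }


@dataclass
class AnalysisConfig:
    fit: FitConfig = field(default_factory=FitConfig)
    exclusions: ExclusionConfig = field(default_factory=ExclusionConfig)
    density_bins: int = 8
    bf_prior_scale_t: float = 0.707
    gd_prior_concentration: float = 1.0
    clamp_pashler_k: bool = True
    seed: int | None = None


def load_trials(path) -> pd.DataFrame:
    """Read and schema-check a canonical trial CSV."""
    trials = pd.read_csv(path)
    validate_schema(trials)
    return trials


def validate_schema(trials: pd.DataFrame) -> None:
    missing = REQUIRED_COLUMNS - set(trials.columns)
    if missing:
        raise ValueError(f"trial table is missing required columns: {sorted(missing)}")
    if len(trials) == 0:
        raise ValueError("trial table is empty")
    for col, lo, hi in [("target_deg", 0.0, 360.0), ("response_deg", 0.0, 360.0)]:
        vals = pd.to_numeric(trials[col], errors="coerce").dropna()
        if len(vals) and ((vals < lo) | (vals >= hi)).any():
            raise ValueError(f"{col} must lie in [0, 360)")


def apply_exclusions(
    trials: pd.DataFrame, config: ExclusionConfig | None = None
) -> tuple[pd.DataFrame, list[ExclusionReport]]:
    """Drop participants violating trial-count, RT, or omission rules."""
    cfg = config or ExclusionConfig()
    validate_schema(trials)
    test = trials[~trials["practice"].astype(bool)]
    reports: list[ExclusionReport] = []

    counts = test.groupby(["participant_id", "phase", "task"], observed=True).size()
    for (pid, phase, task), n in counts.items():
        expected = (
            cfg.expected_training_trials
            if str(phase) in TRAINING_PHASES
            else cfg.expected_test_trials
        )
        extra = n - expected
        if extra > cfg.extra_trials_frac * expected:
            reports.append(
                ExclusionReport(
                    str(pid),
                    "extra_trials",
                    f"{extra} extra trials in {task}@{phase} (> {cfg.extra_trials_frac:.0%} of {expected})",
                )
            )

    for (pid, task), sub in test.groupby(["participant_id", "task"], observed=True):
        responded = sub[~sub["omitted"].astype(bool)]
        rt = pd.to_numeric(responded["rt_ms"], errors="coerce").dropna()
        if len(rt):
            fast = float((rt < cfg.rt_floor_ms).mean())
            if fast > cfg.fast_rt_max_frac:
                reports.append(
                    ExclusionReport(
                        str(pid),
                        "rt_criterion",
                        f"{fast:.1%} of {task} RTs below {cfg.rt_floor_ms:.0f} ms",
                    )
                )
        omission = float(sub["omitted"].astype(bool).mean())
        if omission > cfg.omission_max_frac:
            reports.append(
                ExclusionReport(
                    str(pid), "omission_criterion", f"{omission:.1%} omissions in {task}"
                )
            )

    # participants missing an expected pre/post cell entirely
    present_tasks = test.groupby("participant_id", observed=True)["task"].unique()
    all_tasks = set(test["task"].unique())
    for pid, tasks in present_tasks.items():
        phases_by_task = test[test["participant_id"] == pid].groupby("task", observed=True)["phase"].unique()
        for task in all_tasks & set(tasks):
            have = set(map(str, phases_by_task.get(task, [])))
            lacking = [p for p in TEST_PHASES if p not in have]
            if lacking and set(TEST_PHASES) <= set(map(str, test["phase"].unique())):
                reports.append(
                    ExclusionReport(str(pid), "missing_data", f"no {lacking} data for {task}")
                )

    excluded = {r.participant_id for r in reports}
    filtered = trials[~trials["participant_id"].astype(str).isin(excluded)]
    if len(filtered) == 0:
        log.warning("all participants excluded")
    return filtered, reports


def _fit_reproduction_cell(sub: pd.DataFrame, set_size: int, fit_config: FitConfig):
    errors = wrap_error(
        sub["target_deg"].to_numpy(dtype=float), sub["response_deg"].to_numpy(dtype=float)
    )
    return fit_smm(errors, set_size=set_size, config=fit_config)


def fit_all_cells(
    trials: pd.DataFrame,
    fit_config: FitConfig | None = None,
    clamp_pashler_k: bool = True,
) -> pd.DataFrame:
    """One estimate row per participant x phase x task x set-size cell.

    Reproduction cells get a mixture-model fit (capacity_K and precision
    rows); change-detection cells get Pashler's k; search cells get accuracy
    (omissions excluded) and mean correct RT. Cells that cannot be estimated
    are flagged (``ok = False``) rather than dropped.
    """
    fit_config = fit_config or FitConfig()
    validate_schema(trials)
    test = trials[~trials["practice"].astype(bool)]
    records: list[dict] = []

    def rec(pid, group, phase, task, set_size, estimate_type, value, n_used, ok=True, note=""):
        records.append(
            {
                "participant_id": pid,
                "group": group,
                "phase": phase,
                "task": task,
                "set_size": set_size,
                "estimate_type": estimate_type,
                "value": value,
                "n_trials_used": n_used,
                "ok": ok,
                "note": note,
            }
        )

    keys = ["participant_id", "group", "phase", "task", "set_size"]
    for (pid, group, phase, task, set_size), sub in test.groupby(keys, observed=True):
        set_size = int(set_size)
        if task in REPRODUCTION_TASKS:
            try:
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    fit = _fit_reproduction_cell(sub, set_size, fit_config)
            except InsufficientDataError as exc:
                rec(pid, group, phase, task, set_size, "capacity_K", np.nan, len(sub), False, str(exc))
                rec(pid, group, phase, task, set_size, "precision", np.nan, len(sub), False, str(exc))
                continue
            note = "boundary" if fit.boundary else ""
            rec(pid, group, phase, task, set_size, "capacity_K", fit.capacity_k, fit.n_trials, True, note)
            rec(pid, group, phase, task, set_size, "precision", fit.precision, fit.n_trials, True, note)
            rec(pid, group, phase, task, set_size, "guess_rate", fit.params.g, fit.n_trials, True, note)
            rec(pid, group, phase, task, set_size, "kappa", fit.params.kappa, fit.n_trials, True, note)
        elif task == ODT:
            responded = sub[~sub["omitted"].astype(bool) & sub["response_key"].notna()]
            try:
                summary = summarize_detection_trials(
                    responded["change_trial"].astype(bool).to_numpy(),
                    (responded["response_key"] == "change").to_numpy(),
                    set_size,
                )
                k = pashler_k(summary, clamp=clamp_pashler_k)
                rec(pid, group, phase, task, set_size, "pashler_k", k.k, len(responded))
            except ValueError as exc:
                rec(pid, group, phase, task, set_size, "pashler_k", np.nan, len(responded), False, str(exc))
        elif task == VST:
            responded = sub[~sub["omitted"].astype(bool)]
            if len(responded) == 0:
                rec(pid, group, phase, task, set_size, "accuracy", np.nan, 0, False, "all omissions")
                rec(pid, group, phase, task, set_size, "mean_rt", np.nan, 0, False, "all omissions")
                continue
            correct = np.where(
                responded["change_trial"].astype(bool),
                responded["response_key"] == "change",
                responded["response_key"] == "match",
            )
            rec(pid, group, phase, task, set_size, "accuracy", float(np.mean(correct)), len(responded))
            rts = pd.to_numeric(responded.loc[correct, "rt_ms"], errors="coerce").dropna()
            if len(rts):
                rec(pid, group, phase, task, set_size, "mean_rt", float(rts.mean()), len(rts))
            else:
                rec(pid, group, phase, task, set_size, "mean_rt", np.nan, 0, False, "no correct responses")
    return pd.DataFrame.from_records(records)


def density_comparison(responses_a, responses_b, n_bins: int = 8) -> TestResult:
    """Chi-square homogeneity test of two response distributions on [0, 360).

    Bins have width 360/n_bins anchored at 0 degrees; df = n_bins - 1 for two
    groups (e.g. 7 with the default 8 bins).
    """
    a = np.asarray(responses_a, dtype=float)
    b = np.asarray(responses_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both response pools must be non-empty")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    table = np.vstack([np.histogram(a, bins=edges)[0], np.histogram(b, bins=edges)[0]])
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(
        statistic=float(chi2),
        df=float(df),
        p=float(p),
        method="chi2_homogeneity",
        extras={"n": int(table.sum()), "n_bins": n_bins, "counts": table.tolist()},
    )


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

_MEASURES = [
    (ORT, "capacity_K"),
    (ORT, "precision"),
    (SRT, "capacity_K"),
    (SRT, "precision"),
    (ODT, "pashler_k"),
    (VST, "accuracy"),
    (VST, "mean_rt"),
]


def _wide_measure(cells: pd.DataFrame, task: str, estimate_type: str) -> pd.DataFrame | None:
    sub = cells[
        (cells["task"] == task)
        & (cells["estimate_type"] == estimate_type)
        & cells["phase"].isin(TEST_PHASES)
        & cells["ok"]
    ]
    if sub.empty:
        return None
    wide = sub.pivot_table(
        index=["participant_id", "group"], columns="phase", values="value", observed=True
    ).reset_index()
    if not {"pre", "post"} <= set(wide.columns):
        return None
    return wide.dropna(subset=["pre", "post"])


def _classic_t_paired(x, y) -> float:
    d = np.asarray(x, float) - np.asarray(y, float)
    return float(d.mean() / (d.std(ddof=1) / np.sqrt(d.size)))


def _classic_t_ind(x, y) -> float:
    return float(stats.ttest_ind(x, y, equal_var=False).statistic)


def run_full_analysis(trials: pd.DataFrame, config: AnalysisConfig | None = None) -> dict:
    """Run the complete analysis graph on a canonical trial table.

    Sections: exclusions, descriptives, baseline group comparisons, training
    ANOVAs, pre/post mixed ANOVAs (with BIC-approximate Bayes factors,
    tagged), follow-up trimmed-mean tests, and response-density comparisons.
    Deterministic: same input and config give an identical report.
    """
    cfg = config or AnalysisConfig()
    validate_schema(trials)
    filtered, exclusions = apply_exclusions(trials, cfg.exclusions)
    cells = fit_all_cells(filtered, cfg.fit, cfg.clamp_pashler_k)

    report: dict = {
        "config": {
            "density_bins": cfg.density_bins,
            "bf_prior_scale_t": cfg.bf_prior_scale_t,
            "gd_prior_concentration": cfg.gd_prior_concentration,
            "seed": cfg.seed,
        },
        "exclusions": [e.to_dict() for e in exclusions],
        "n_participants": {
            g: int(n)
            for g, n in filtered.groupby("group", observed=True)["participant_id"].nunique().items()
        },
    }

    # descriptive statistics: mean/SD per group x phase x measure x set size
    ok = cells[cells["ok"]]
    desc = (
        ok.groupby(["group", "phase", "task", "set_size", "estimate_type"], observed=True)["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    report["descriptives"] = desc.to_dict(orient="records")

    # baseline group comparisons at pre-test
    baseline = {}
    for task, measure in _MEASURES:
        wide = _wide_measure(cells, task, measure)
        if wide is None or wide["group"].nunique() != 2:
            continue
        x = wide.loc[wide["group"] == "experimental", "pre"].to_numpy()
        y = wide.loc[wide["group"] == "control", "pre"].to_numpy()
        if len(x) < 5 or len(y) < 5:
            continue
        res = yuen_independent(x, y)
        bf = jzs_bf_ttest(_classic_t_ind(x, y), len(x), len(y), r=cfg.bf_prior_scale_t)
        baseline[f"{task}.{measure}"] = {**res.to_dict(), "bf": bf.to_dict()}
    report["baseline"] = baseline

    # training ANOVAs (sessions x set size, within-subjects) per trained measure
    training = {}
    train_cells = cells[cells["phase"].isin(TRAINING_PHASES) & cells["ok"]]
    for task, measure in [(ORT, "capacity_K"), (ORT, "precision"), (VST, "accuracy"), (VST, "mean_rt")]:
        sub = train_cells[(train_cells["task"] == task) & (train_cells["estimate_type"] == measure)]
        if sub.empty:
            continue
        complete = sub.groupby("participant_id", observed=True).filter(
            lambda d: len(d) == d["phase"].nunique() * d["set_size"].nunique()
            and d["phase"].nunique() == len(TRAINING_PHASES)
        )
        if complete["participant_id"].nunique() < 3:
            continue
        res = rm_anova_2within(
            complete.rename(columns={"phase": "session"}),
            dv="value",
            within=("session", "set_size"),
            subject="participant_id",
        )
        training[f"{task}.{measure}"] = res.to_dict()
    report["training_anova"] = training

    # pre/post mixed ANOVAs per measure, plus follow-up robust tests
    prepost = {}
    followup = {}
    for task, measure in _MEASURES:
        wide = _wide_measure(cells, task, measure)
        if wide is None or wide["group"].nunique() != 2:
            continue
        long = wide.melt(
            id_vars=["participant_id", "group"],
            value_vars=["pre", "post"],
            var_name="time",
            value_name="value",
        )
        res = mixed_anova(long, dv="value", within="time", between="group")
        entry = res.to_dict()
        # BIC-approximate Bayes factors per effect (flagged; not default g-prior BFs)
        rss = res.extras["rss_chain"]
        dfm = res.extras["df_model"]
        n_obs = res.n_obs

        def bic(rss_v, k):
            return n_obs * np.log(rss_v / n_obs) + k * np.log(n_obs)

        entry["bf_approx"] = {
            "group": bic_bf_approx(bic(rss["null"], dfm["null"]), bic(rss["group"], dfm["group"])).to_dict(),
            "time": bic_bf_approx(bic(rss["subject"], dfm["subject"]), bic(rss["time"], dfm["time"])).to_dict(),
            "interaction": bic_bf_approx(
                bic(rss["time"], dfm["time"]), bic(rss["interaction"], dfm["interaction"])
            ).to_dict(),
        }
        prepost[f"{task}.{measure}"] = entry

        fu = {}
        for group in ("experimental", "control"):
            g = wide[wide["group"] == group]
            if len(g) < 5:
                continue
            res_w = yuen_paired(g["post"].to_numpy(), g["pre"].to_numpy())
            bf = jzs_bf_ttest(
                _classic_t_paired(g["post"].to_numpy(), g["pre"].to_numpy()),
                len(g),
                r=cfg.bf_prior_scale_t,
            )
            fu[f"{group}_post_vs_pre"] = {**res_w.to_dict(), "bf": bf.to_dict()}
        xe = wide.loc[wide["group"] == "experimental", "post"].to_numpy()
        xc = wide.loc[wide["group"] == "control", "post"].to_numpy()
        if len(xe) >= 5 and len(xc) >= 5:
            res_b = yuen_independent(xe, xc)
            bf = jzs_bf_ttest(_classic_t_ind(xe, xc), len(xe), len(xc), r=cfg.bf_prior_scale_t)
            fu["between_at_post"] = {**res_b.to_dict(), "bf": bf.to_dict()}
        followup[f"{task}.{measure}"] = fu
    report["prepost_anova"] = prepost
    report["followup"] = followup

    # response-density comparisons between groups at each time point
    density = {}
    repro = filtered[
        (filtered["task"] == ORT) & ~filtered["practice"].astype(bool)
    ]
    for phase in TEST_PHASES:
        sub = repro[repro["phase"] == phase]
        a = sub.loc[sub["group"] == "experimental", "response_deg"].dropna().to_numpy()
        b = sub.loc[sub["group"] == "control", "response_deg"].dropna().to_numpy()
        if len(a) and len(b):
            res = density_comparison(a, b, n_bins=cfg.density_bins)
            bf = gd_contingency_bf(
                np.asarray(res.extras["counts"]), a=cfg.gd_prior_concentration
            )
            density[phase] = {**res.to_dict(), "bf": bf.to_dict()}
    report["density"] = density
    report["cell_estimates"] = cells.to_dict(orient="records")
    return report


def write_report(report: dict, outdir) -> None:
    """Write the JSON report plus CSV tables mirroring the study's tables."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells = report.get("cell_estimates", [])
    slim = {k: v for k, v in report.items() if k != "cell_estimates"}
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(slim, fh, indent=2, sort_keys=True, default=_json_default)
    if cells:
        pd.DataFrame(cells).to_csv(outdir / "cell_estimates.csv", index=False)
    if report.get("descriptives"):
        pd.DataFrame(report["descriptives"]).to_csv(outdir / "descriptives.csv", index=False)
    rows = []
    for section in ("baseline", "prepost_anova"):
        for key, entry in report.get(section, {}).items():
            rows.append({"section": section, "measure": key, "json": json.dumps(entry, default=_json_default)})
    if rows:
        pd.DataFrame(rows).to_csv(outdir / "tests.csv", index=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
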