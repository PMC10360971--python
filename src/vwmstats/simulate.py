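"""Trial-level synthetic datasets with the statistical structure the
analysis pipeline assumes.

The simulated study has two groups (experimental n=30, control n=34 by
default), a pre-test, four training sessions, and a post-test. At pre/post
every participant completes 120 test trials (plus 20 flagged practice
trials) per task at set size 4 (16 for visual search). Each training session
has 360 trials: 120 per set size in {2, 4, 6} for reproduction training and
{8, 16, 24} for visual-search training. Group/phase effects enter only
through the per-cell (g, kappa) trajectory (and the per-cell detection /
search parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .circular import kappa_to_sd, sd_to_kappa

__all__ = [
    "TRIAL_COLUMNS",
    "StudySimConfig",
    "simulate_errors",
    "simulate_change_detection",
    "simulate_visual_search",
    "simulate_study",
    "quality_gain_config",
    "null_config",
]

GROUPS = ("experimental", "control")
TEST_PHASES = ("pre", "post")
TRAINING_PHASES = ("s1", "s2", "s3", "s4")
PHASES = ("pre",) + TRAINING_PHASES + ("post",)

ORT = "orientation_reproduction"
SRT = "shape_reproduction"
ODT = "change_detection"
VST = "visual_search"
TASKS = (ORT, SRT, ODT, VST)
REPRODUCTION_TASKS = (ORT, SRT)

TRIAL_COLUMNS = [
    "participant_id",
    "group",
    "phase",
    "task",
    "set_size",
    "practice",
    "target_deg",
    "response_deg",
    "change_trial",
    "response_key",
    "rt_ms",
    "omitted",
]


def simulate_errors(n: int, g: float, kappa: float, seed=None) -> np.ndarray:
    """Draw ``n`` recall errors (radians in (-pi, pi]) from the mixture model.

    With probability ``g`` an error is uniform on the circle, otherwise von
    Mises(0, kappa). ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if not (0.0 <= g <= 1.0):
        raise ValueError(f"g must be in [0, 1], got {g}")
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    guess = rng.random(n) < g
    errors = rng.vonmises(0.0, kappa, size=n)
    errors[guess] = rng.uniform(-np.pi, np.pi, size=int(guess.sum()))
    # numpy returns [-pi, pi]; fold the closed lower endpoint onto +pi
    errors[errors <= -np.pi] = np.pi
    return errors


def simulate_change_detection(
    k_true: float,
    set_size: int,
    n_trials: int,
    seed=None,
    guess_rate: float = 0.5,
) -> pd.DataFrame:
    """Whole-display change-detection trials under the guessing model.

    On a change trial the changed item is in memory with probability
    ``k_true / N`` (detection, respond "change"); otherwise the observer
    guesses "change" with probability ``guess_rate``. On match trials no
    mismatch can be detected, so FA = guess_rate. With this model
    E[(H - FA) / (1 - FA) * N] = k_true for any guess rate. Change and match
    trials are balanced.
    """
    if not (0.0 <= k_true <= set_size):
        raise ValueError(f"k_true must be in [0, set_size], got {k_true}")
    if not (0.0 <= guess_rate < 1.0):
        raise ValueError(f"guess_rate must be in [0, 1), got {guess_rate}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_change = n_trials // 2
    change = np.zeros(n_trials, dtype=bool)
    change[:n_change] = True
    rng.shuffle(change)
    detected = change & (rng.random(n_trials) < k_true / set_size)
    respond_change = detected | (~detected & (rng.random(n_trials) < guess_rate))
    return pd.DataFrame(
        {
            "set_size": set_size,
            "change_trial": change,
            "response_key": np.where(respond_change, "change", "match"),
        }
    )


def simulate_visual_search(
    accuracy: float,
    rt_median_ms: float,
    rt_sigma: float,
    omission_rate: float,
    n_trials: int,
    set_size: int,
    seed=None,
    rt_cap_ms: float = 5000.0,
) -> pd.DataFrame:
    """Visual-search trials: Bernoulli accuracy and log-normal RTs.

    RTs exceeding the response window (``rt_cap_ms``) and an extra
    ``omission_rate`` of trials are flagged as omissions (no response).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    correct = rng.random(n_trials) < accuracy
    rt = rng.lognormal(np.log(rt_median_ms), rt_sigma, size=n_trials)
    omitted = (rt > rt_cap_ms) | (rng.random(n_trials) < omission_rate)
    change = np.zeros(n_trials, dtype=bool)
    change[: n_trials // 2] = True
    rng.shuffle(change)
    respond_target = np.where(correct, change, ~change)
    key = np.where(respond_target, "change", "match").astype(object)
    key[omitted] = None
    rt = np.where(omitted, np.nan, np.minimum(rt, rt_cap_ms))
    return pd.DataFrame(
        {
            "set_size": set_size,
            "change_trial": change,
            "response_key": key,
            "rt_ms": rt,
            "omitted": omitted,
        }
    )


def _default_gk() -> dict:
    """Per-(group, phase, task, set_size) (g, kappa): a flat no-effect design."""
    base_g = {2: 0.08, 4: 0.36, 6: 0.50, "test": 0.36}
    base_kappa = {2: 18.0, 4: 12.0, 6: 10.0, "test": 12.0}
    gk = {}
    for group in GROUPS:
        for phase in TEST_PHASES:
            for task in REPRODUCTION_TASKS:
                gk[(group, phase, task, 4)] = (base_g["test"], base_kappa["test"])
        for phase in TRAINING_PHASES:
            for n in (2, 4, 6):
                gk[("experimental", phase, ORT, n)] = (base_g[n], base_kappa[n])
    return gk


def _default_detection() -> dict:
    return {(group, phase): 2.0 for group in GROUPS for phase in TEST_PHASES}


def _default_search() -> dict:
    # accuracy, median RT (ms), lognormal sigma
    acc = {8: 0.91, 16: 0.80, 24: 0.73}
    rt = {8: 2000.0, 16: 2800.0, 24: 3200.0}
    out = {}
    for group in GROUPS:
        for phase in TEST_PHASES:
            out[(group, phase, 16)] = (acc[16], rt[16], 0.25)
        for phase in TRAINING_PHASES:
            for n in (8, 16, 24):
                out[("control", phase, n)] = (acc[n], rt[n], 0.25)
    return out


@dataclass
class StudySimConfig:
    """Design constants and generative parameters of the synthetic study."""

    n_experimental: int = 30
    n_control: int = 34
    trials_per_cell: int = 120
    practice_trials: int = 20
    test_set_size: int = 4
    search_test_set_size: int = 16
    training_set_sizes: tuple[int, ...] = (2, 4, 6)
    search_set_sizes: tuple[int, ...] = (8, 16, 24)
    tasks: tuple[str, ...] = TASKS
    include_training: bool = True
    include_practice: bool = True
    gk_trajectory: dict = field(default_factory=_default_gk)
    detection_k: dict = field(default_factory=_default_detection)
    detection_guess_rate: float = 0.5
    search_params: dict = field(default_factory=_default_search)
    search_omission_rate: float = 0.02
    # between-subject heterogeneity (logit-g and log-kappa normal SDs)
    logit_g_sd: float = 0.3
    log_kappa_sd: float = 0.15
    seed: int = 0

    def participants(self):
        for i in range(self.n_experimental):
            yield f"exp{i + 1:03d}", "experimental"
        for i in range(self.n_control):
            yield f"ctl{i + 1:03d}", "control"

    def reproduction_cells(self):
        """Every (group, phase, task, set_size) cell that needs a (g, kappa)."""
        cells = []
        for group in GROUPS:
            for phase in TEST_PHASES:
                for task in REPRODUCTION_TASKS:
                    if task in self.tasks:
                        cells.append((group, phase, task, self.test_set_size))
            if self.include_training and group == "experimental" and ORT in self.tasks:
                for phase in TRAINING_PHASES:
                    for n in self.training_set_sizes:
                        cells.append((group, phase, ORT, n))
        return cells

    def validate(self):
        missing = [c for c in self.reproduction_cells() if c not in self.gk_trajectory]
        if ODT in self.tasks:
            missing += [
                ("detection_k", g, p)
                for g in GROUPS
                for p in TEST_PHASES
                if (g, p) not in self.detection_k
            ]
        if missing:
            raise ValueError(f"config is missing generative cells: {missing}")
        for key, (g, kappa) in self.gk_trajectory.items():
            if not (0.0 <= g <= 1.0 and kappa > 0):
                raise ValueError(f"invalid (g, kappa) for cell {key}: {(g, kappa)}")


def _reproduction_rows(rows, pid, group, phase, task, set_size, n_trials, practice,
                       g, kappa, rng):
    target = rng.uniform(0.0, 360.0, size=n_trials)
    err_deg = np.rad2deg(simulate_errors(n_trials, g, kappa, rng))
    response = np.mod(target + err_deg, 360.0)
    rt = np.minimum(rng.lognormal(np.log(1800.0), 0.35, size=n_trials), 10_000.0)
    rows.append(
        pd.DataFrame(
            {
                "participant_id": pid,
                "group": group,
                "phase": phase,
                "task": task,
                "set_size": set_size,
                "practice": practice,
                "target_deg": target,
                "response_deg": response,
                "change_trial": pd.NA,
                "response_key": None,
                "rt_ms": rt,
                "omitted": False,
            }
        )
    )


def simulate_study(config: StudySimConfig | None = None) -> pd.DataFrame:
    """Generate the full two-group trial table for the study design.

    Row counts follow the design exactly: 120 test trials per participant,
    phase, and task at pre/post (plus 20 practice trials when enabled) and
    360 trials per training session. Reproducible from ``config.seed``.
    """
    cfg = config or StudySimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows: list[pd.DataFrame] = []

    for pid, group in cfg.participants():
        subj_rng = np.random.default_rng(rng.integers(0, 2**63))
        # per-subject multiplicative offsets shared across cells
        g_off = subj_rng.normal(0.0, cfg.logit_g_sd)
        k_off = subj_rng.normal(0.0, cfg.log_kappa_sd)

        def cell_gk(group_, phase_, task_, n_):
            g0, k0 = cfg.gk_trajectory[(group_, phase_, task_, n_)]
            g0 = float(np.clip(g0, 1e-4, 1 - 1e-4))
            return float(expit(logit(g0) + g_off)), float(k0 * np.exp(k_off))

        for phase in TEST_PHASES:
            for task in cfg.tasks:
                blocks = []
                if cfg.include_practice and cfg.practice_trials > 0:
                    blocks.append((cfg.practice_trials, True))
                blocks.append((cfg.trials_per_cell, False))
                for n_trials, practice in blocks:
                    if task in REPRODUCTION_TASKS:
                        g, kappa = cell_gk(group, phase, task, cfg.test_set_size)
                        _reproduction_rows(rows, pid, group, phase, task,
                                           cfg.test_set_size, n_trials, practice,
                                           g, kappa, subj_rng)
                    elif task == ODT:
                        det = simulate_change_detection(
                            cfg.detection_k[(group, phase)],
                            cfg.test_set_size,
                            n_trials,
                            subj_rng,
                            cfg.detection_guess_rate,
                        )
                        det["rt_ms"] = np.minimum(
                            subj_rng.lognormal(np.log(900.0), 0.3, size=len(det)), 5000.0
                        )
                        det["omitted"] = False
                        _finish_block(rows, det, pid, group, phase, task, practice)
                    elif task == VST:
                        acc, rt_med, sigma = cfg.search_params[
                            (group, phase, cfg.search_test_set_size)
                        ]
                        vs = simulate_visual_search(
                            acc, rt_med, sigma, cfg.search_omission_rate,
                            n_trials, cfg.search_test_set_size, subj_rng,
                        )
                        _finish_block(rows, vs, pid, group, phase, task, practice)

        if cfg.include_training:
            trained = ORT if group == "experimental" else VST
            if trained not in cfg.tasks:
                continue
            sizes = cfg.training_set_sizes if trained == ORT else cfg.search_set_sizes
            for phase in TRAINING_PHASES:
                for n in sizes:
                    if trained == ORT:
                        g, kappa = cell_gk(group, phase, ORT, n)
                        _reproduction_rows(rows, pid, group, phase, ORT, n,
                                           cfg.trials_per_cell, False, g, kappa, subj_rng)
                    else:
                        acc, rt_med, sigma = cfg.search_params[(group, phase, n)]
                        vs = simulate_visual_search(
                            acc, rt_med, sigma, cfg.search_omission_rate,
                            cfg.trials_per_cell, n, subj_rng,
                        )
                        _finish_block(rows, vs, pid, group, phase, VST, False)

    out = pd.concat(rows, ignore_index=True)
    for col in TRIAL_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    return out[TRIAL_COLUMNS]


def _finish_block(rows, block, pid, group, phase, task, practice):
    block = block.copy()
    block["participant_id"] = pid
    block["group"] = group
    block["phase"] = phase
    block["task"] = task
    block["practice"] = practice
    block["target_deg"] = np.nan
    block["response_deg"] = np.nan
    rows.append(block)


# ---------------------------------------------------------------------------
# scenario builders
# ---------------------------------------------------------------------------

def null_config(seed: int = 0, **overrides) -> StudySimConfig:
    """A no-effect scenario: identical generative parameters in every cell."""
    return replace(StudySimConfig(seed=seed), **overrides)


def quality_gain_config(
    seed: int = 0,
    sd_gain: float = 0.2,
    **overrides,
) -> StudySimConfig:
    """Precision improves at post-test in the experimental group only.

    The post-test kappa of every experimental reproduction-at-test cell in
    the trained task is raised so the circular SD falls by ``sd_gain``
    (default 20%); guess rates are untouched, so capacity carries no
    group-by-time effect.
    """
    cfg = replace(StudySimConfig(seed=seed), **overrides)
    gk = dict(cfg.gk_trajectory)
    for (group, phase, task, n), (g, kappa) in list(gk.items()):
        if group == "experimental" and phase == "post" and task == ORT:
            gk[(group, phase, task, n)] = (g, sd_to_kappa(kappa_to_sd(kappa) * (1.0 - sd_gain)))
    cfg.gk_trajectory = gk
    return cfg
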