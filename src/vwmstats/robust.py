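"""Frequentist inference layer: trimmed-mean tests, robust effect sizes,
chi-square, and the two ANOVA designs used in the study, with both
generalized and partial eta-squared.

Yuen's tests use 20% trimming by default; the paired variant has
df = h - 1 with h = n - 2*floor(0.2 n), which gives df = 17 at n = 30 and
df = 21 at n = 34. ANOVAs report uncorrected univariate degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "AnovaResult",
    "trimmed_mean",
    "winsorize",
    "winsorized_variance",
    "yuen_independent",
    "yuen_paired",
    "akp_delta",
    "chi2_2x2",
    "mixed_anova",
    "rm_anova_2within",
    "eta_squared",
]


@dataclass
class TestResult:
    """A single statistical test: statistic, df, p, effect sizes, method tag."""

    statistic: float
    df: float | tuple[float, float]
    p: float
    effect_sizes: dict = field(default_factory=dict)
    method: str = ""
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        df = list(self.df) if isinstance(self.df, tuple) else self.df
        return {
            "statistic": self.statistic,
            "df": df,
            "p": self.p,
            "effect_sizes": dict(self.effect_sizes),
            "method": self.method,
            **{k: v for k, v in self.extras.items() if _jsonable(v)},
        }


def _jsonable(v) -> bool:
    return isinstance(v, (int, float, str, bool, list, dict, type(None)))


# ---------------------------------------------------------------------------
# trimming / winsorizing building blocks
# ---------------------------------------------------------------------------

def _check_trim(x, tr):
    x = np.sort(np.asarray(x, dtype=float))
    if x.size < 1:
        raise ValueError("empty sample")
    if not (0.0 <= tr < 0.5):
        raise ValueError(f"trim proportion must be in [0, 0.5), got {tr}")
    g = floor(tr * x.size)
    if x.size - 2 * g < 1:
        raise ValueError("all values would be trimmed")
    return x, g


def trimmed_mean(x, tr: float = 0.2) -> float:
    """Mean after removing floor(tr*n) smallest and largest values."""
    x, g = _check_trim(x, tr)
    return float(x[g : x.size - g].mean())


def winsorize(x, tr: float = 0.2) -> np.ndarray:
    """Replace the floor(tr*n) extreme values on each side by the nearest kept value."""
    x, g = _check_trim(x, tr)
    w = x.copy()
    w[:g] = x[g]
    w[x.size - g :] = x[x.size - g - 1]
    return w


def winsorized_variance(x, tr: float = 0.2) -> float:
    """Sample variance (n-1 denominator) of the winsorized sample."""
    w = winsorize(x, tr)
    return float(w.var(ddof=1))


def _effective_n(n: int, tr: float) -> int:
    return n - 2 * floor(tr * n)


# ---------------------------------------------------------------------------
# Yuen's t-tests and the AKP robust effect size
# ---------------------------------------------------------------------------

def yuen_independent(x, y, tr: float = 0.2) -> TestResult:
    """Yuen's two-sample trimmed-means test (Welch-style df), two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    h1, h2 = _effective_n(x.size, tr), _effective_n(y.size, tr)
    if h1 < 2 or h2 < 2:
        raise ValueError("effective (post-trim) sample sizes must be >= 2")
    d1 = (x.size - 1) * winsorized_variance(x, tr) / (h1 * (h1 - 1))
    d2 = (y.size - 1) * winsorized_variance(y, tr) / (h2 * (h2 - 1))
    if d1 + d2 <= 0:
        raise ValueError("zero winsorized variance in both samples; test undefined")
    t = (trimmed_mean(x, tr) - trimmed_mean(y, tr)) / np.sqrt(d1 + d2)
    df = (d1 + d2) ** 2 / (d1**2 / (h1 - 1) + d2**2 / (h2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(
        statistic=float(t),
        df=float(df),
        p=float(p),
        effect_sizes={"akp_delta": akp_delta(x, y, tr)},
        method="yuen_independent",
        extras={"trim": tr, "n": [int(x.size), int(y.size)]},
    )


def yuen_paired(x, y, tr: float = 0.2) -> TestResult:
    """Yuen's paired trimmed-means test; df = h - 1, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"paired samples differ in length: {x.size} vs {y.size}")
    n = x.size
    g = floor(tr * n)
    h = n - 2 * g
    if h < 2:
        raise ValueError("effective (post-trim) sample size must be >= 2")
    # winsorize each margin on its own order statistics, keeping pairs aligned
    order_x = np.sort(x)
    order_y = np.sort(y)
    wx = np.clip(x, order_x[g], order_x[n - g - 1])
    wy = np.clip(y, order_y[g], order_y[n - g - 1])
    q1 = (n - 1) * wx.var(ddof=1)
    q2 = (n - 1) * wy.var(ddof=1)
    q3 = (n - 1) * np.cov(wx, wy, ddof=1)[0, 1]
    se2 = (q1 + q2 - 2.0 * q3) / (h * (h - 1))
    diff = trimmed_mean(x, tr) - trimmed_mean(y, tr)
    if se2 <= 0:
        if diff == 0:
            return TestResult(0.0, float(h - 1), 1.0, {"akp_delta": 0.0},
                              "yuen_paired", {"trim": tr, "n": int(n)})
        raise ValueError("zero variance of trimmed differences; test undefined")
    t = diff / np.sqrt(se2)
    df = h - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(
        statistic=float(t),
        df=float(df),
        p=float(p),
        effect_sizes={"akp_delta": akp_delta(x, y, tr)},
        method="yuen_paired",
        extras={"trim": tr, "n": int(n)},
    )


def akp_delta(x, y, tr: float = 0.2) -> float:
    """Algina-Keselman-Penfield robust standardized mean difference.

    delta_t = 0.642 * (trimmed mean difference) / pooled winsorized SD, with
    the 0.642 factor rescaling to a normal-metric d at 20% trimming.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s2p = (
        (x.size - 1) * winsorized_variance(x, tr)
        + (y.size - 1) * winsorized_variance(y, tr)
    ) / (x.size + y.size - 2)
    if s2p <= 0:
        raise ValueError("zero pooled winsorized variance; effect size undefined")
    return float(0.642 * (trimmed_mean(x, tr) - trimmed_mean(y, tr)) / np.sqrt(s2p))


# ---------------------------------------------------------------------------
# chi-square for 2x2 tables
# ---------------------------------------------------------------------------

def chi2_2x2(table, correction: bool = True) -> TestResult:
    """Pearson chi-square on a 2x2 table, Yates-corrected by default.

    The Yates correction is clamped at zero, max(|O - E| - 0.5, 0), so a
    perfectly proportional table yields exactly 0.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if np.any(obs < 0):
        raise ValueError("counts must be >= 0")
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if np.any(rows <= 0) or np.any(cols <= 0):
        raise ValueError("every row and column margin must be positive")
    expected = np.outer(rows, cols) / obs.sum()
    dev = np.abs(obs - expected)
    if correction:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    return TestResult(
        statistic=chi2,
        df=1.0,
        p=float(stats.chi2.sf(chi2, 1)),
        method="chi2_yates" if correction else "chi2_pearson",
        extras={"expected": expected.tolist(), "n": int(obs.sum())},
    )


# ---------------------------------------------------------------------------
# ANOVA designs
# ---------------------------------------------------------------------------

def eta_squared(ss_effect: float, ss_error_effect: float, ss_subject_related: float):
    """(generalized, partial) eta-squared from a sums-of-squares decomposition.

    ``ss_subject_related`` is the sum of every subject-related error SS in the
    design (all factors treated as manipulated), which is the generalized
    denominator contribution; it always contains ``ss_error_effect``, so
    eta_p >= eta_g.
    """
    if min(ss_effect, ss_error_effect, ss_subject_related) < 0:
        raise ValueError("sums of squares must be >= 0")
    eta_p = ss_effect / (ss_effect + ss_error_effect) if ss_effect + ss_error_effect > 0 else 0.0
    eta_g = ss_effect / (ss_effect + ss_subject_related) if ss_effect + ss_subject_related > 0 else 0.0
    return float(eta_g), float(eta_p)


@dataclass
class AnovaResult:
    """Effects of one ANOVA, keyed by factor name plus ``"interaction"``."""

    effects: dict
    ss: dict
    method: str
    n_obs: int
    extras: dict = field(default_factory=dict)

    def __getitem__(self, key) -> TestResult:
        return self.effects[key]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_obs": self.n_obs,
            "effects": {k: v.to_dict() for k, v in self.effects.items()},
            "ss": {k: float(v) for k, v in self.ss.items()},
        }


def _rss(y, X):
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(resid @ resid)


def _f_test(ss_e, df_e, ss_err, df_err, eta_pair, method, extras=None):
    ms_e, ms_err = ss_e / df_e, ss_err / df_err
    f = ms_e / ms_err if ms_err > 0 else np.inf
    p = float(stats.f.sf(f, df_e, df_err))
    eta_g, eta_p = eta_pair
    return TestResult(
        statistic=float(f),
        df=(float(df_e), float(df_err)),
        p=p,
        effect_sizes={"eta_g_sq": eta_g, "eta_p_sq": eta_p},
        method=method,
        extras=extras or {},
    )


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "time",
    between: str = "group",
    subject: str = "participant_id",
) -> AnovaResult:
    """Two-way mixed ANOVA (one between-subjects, one within-subjects factor).

    Split-plot decomposition: the between effect is tested against
    subject-within-group variance and the within effect and interaction
    against the within x subject residual. Requires a complete design: every
    subject observed once at every level of ``within``.
    """
    df = data[[subject, between, within, dv]].copy()
    counts = df.groupby([subject, within], observed=True).size()
    if (counts != 1).any():
        bad = counts[counts != 1].index.tolist()
        raise ValueError(f"each subject needs exactly one value per {within} level; offenders: {bad[:10]}")
    wide = df.pivot(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"subjects missing a {within} level: {missing[:10]}")
    groups = df.groupby(subject, observed=True)[between].first()
    if groups.loc[wide.index].isna().any():
        raise ValueError("every subject must belong to a group")

    y = df[dv].to_numpy(dtype=float)
    n_obs = y.size
    subj_d = pd.get_dummies(df[subject].astype(str)).to_numpy(dtype=float)
    grp_d = pd.get_dummies(df[between].astype(str)).to_numpy(dtype=float)
    time_d = pd.get_dummies(df[within].astype(str)).to_numpy(dtype=float)
    inter_d = np.einsum("ij,ik->ijk", grp_d, time_d).reshape(n_obs, -1)

    ones = np.ones((n_obs, 1))
    rss0 = _rss(y, ones)
    rss1 = _rss(y, np.hstack([ones, grp_d]))
    rss2 = _rss(y, subj_d)  # subject dummies absorb intercept and group
    rss3 = _rss(y, np.hstack([subj_d, time_d]))
    rss4 = _rss(y, np.hstack([subj_d, time_d, inter_d]))

    n_subj = wide.shape[0]
    n_grp = groups.nunique()
    k = wide.shape[1]
    ss = {
        between: rss0 - rss1,
        "error_between": rss1 - rss2,
        within: rss2 - rss3,
        "interaction": rss3 - rss4,
        "error_within": rss4,
    }
    dfs = {
        between: n_grp - 1,
        "error_between": n_subj - n_grp,
        within: k - 1,
        "interaction": (n_grp - 1) * (k - 1),
        "error_within": (n_subj - n_grp) * (k - 1),
    }
    ss_subject_related = ss["error_between"] + ss["error_within"]
    effects = {}
    for name, err in [(between, "error_between"), (within, "error_within"),
                      ("interaction", "error_within")]:
        effects[name] = _f_test(
            max(ss[name], 0.0), dfs[name], ss[err], dfs[err],
            eta_squared(max(ss[name], 0.0), ss[err], ss_subject_related),
            "mixed_anova",
        )
    return AnovaResult(
        effects=effects,
        ss=ss,
        method="mixed_anova",
        n_obs=n_obs,
        extras={
            "rss_chain": {"null": rss0, between: rss1, "subject": rss2,
                          within: rss3, "interaction": rss4},
            "df_model": {"null": 1, between: n_grp, "subject": n_subj,
                         within: n_subj + k - 1,
                         "interaction": n_subj + k - 1 + (n_grp - 1) * (k - 1)},
        },
    )


def rm_anova_2within(
    data: pd.DataFrame,
    dv: str = "value",
    within: tuple[str, str] = ("time", "set_size"),
    subject: str = "participant_id",
) -> AnovaResult:
    """Repeated-measures ANOVA with two fully-crossed within-subjects factors.

    Univariate F tests with effect-specific subject-interaction error terms
    and no sphericity correction.
    """
    fa, fb = within
    df = data[[subject, fa, fb, dv]].copy()
    counts = df.groupby([subject, fa, fb], observed=True).size()
    if (counts != 1).any():
        bad = counts[counts != 1].index.tolist()
        raise ValueError(f"incomplete crossing of {within} within subjects; offenders: {bad[:10]}")
    subjects = df[subject].unique()
    a_levels = df[fa].unique()
    b_levels = df[fb].unique()
    n, a, b = len(subjects), len(a_levels), len(b_levels)
    if counts.size != n * a * b:
        raise ValueError("incomplete crossing: missing cells")

    cube = (
        df.set_index([subject, fa, fb])[dv]
        .unstack([fa, fb])
        .loc[subjects]
        .to_numpy(dtype=float)
        .reshape(n, a, b)
    )
    grand = cube.mean()
    m_s = cube.mean(axis=(1, 2))
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_ab = cube.mean(axis=0)
    m_as = cube.mean(axis=2)
    m_bs = cube.mean(axis=1)

    ss_subj = a * b * np.sum((m_s - grand) ** 2)
    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2)
    ss_bs = a * np.sum((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2)
    ss_total = np.sum((cube - grand) ** 2)
    ss_abs = ss_total - (ss_subj + ss_a + ss_b + ss_ab + ss_as + ss_bs)

    ss = {
        "subject": ss_subj, fa: ss_a, fb: ss_b, "interaction": ss_ab,
        f"error_{fa}": ss_as, f"error_{fb}": ss_bs, "error_interaction": ss_abs,
    }
    ss_subject_related = ss_subj + ss_as + ss_bs + ss_abs
    spec = [
        (fa, ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        (fb, ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        ("interaction", ss_ab, (a - 1) * (b - 1), max(ss_abs, 0.0), (a - 1) * (b - 1) * (n - 1)),
    ]
    effects = {
        name: _f_test(
            ss_e, df_e, ss_err, df_err,
            eta_squared(ss_e, ss_err, ss_subject_related),
            "rm_anova_2within",
        )
        for name, ss_e, df_e, ss_err, df_err in spec
    }
    return AnovaResult(effects=effects, ss=ss, method="rm_anova_2within", n_obs=int(cube.size))
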