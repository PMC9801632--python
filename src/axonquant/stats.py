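"""Statistical comparison layer.

One-way repeated-measures ANOVA (uncorrected df by default, optional
Greenhouse-Geisser) with an eta-squared effect size in the partial form
F*df1 / (F*df1 + df2); FDR-corrected follow-up decisions (two-stage
Benjamini-Krieger-Yekutieli step-up, matching the follow-up default of
common GUI statistics software, with plain Benjamini-Hochberg as a
variant); two-tailed two-sample t tests that switch to Welch's correction
when an F test rejects variance equality; Cohen's d; and a Monte-Carlo
power check for two-group designs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "rm_anova",
    "eta_squared_from_f",
    "fdr_followups",
    "two_sample_t",
    "cohens_d",
    "cohens_d_from_t",
    "power_check",
]


@dataclass
class StatResult:
    """A test outcome plus its decision trail.

    ``df`` is a float for single-df tests or a (df1, df2) pair for F tests;
    ``decisions`` records assumption-check p-values (variance-equality F
    test, Shapiro-Wilk) that steered automatic corrections.
    """

    test_name: str
    statistic: float
    df: object
    p_value: float
    effect_size: float
    effect_size_name: str
    correction: str = "none"
    decisions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")

    def report(self) -> str:
        """Human-readable one-liner in the conventional reporting style."""
        if isinstance(self.df, tuple):
            dfs = f"({self.df[0]:g},{self.df[1]:g})"
        else:
            dfs = f"({self.df:g})"
        return (f"{self.test_name} {dfs} = {self.statistic:.4g}, "
                f"p = {self.p_value:.4g}, {self.effect_size_name} = {self.effect_size:.4g}")


def eta_squared_from_f(f: float, df1: float, df2: float) -> float:
    """Partial eta-squared recovered from an F statistic and its dfs:
    F*df1 / (F*df1 + df2). Monotone increasing in F at fixed dfs."""
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    if np.isinf(f):
        return 1.0
    return f * df1 / (f * df1 + df2)


def rm_anova(
    table,
    greenhouse_geisser: bool = False,
) -> StatResult:
    """One-way repeated-measures ANOVA on a complete subjects x conditions
    table.

    Accepts a 2-D array or a wide DataFrame (rows = subjects, columns =
    conditions; no missing cells — the section-matching rule upstream
    guarantees completeness). F carries df (k-1, (k-1)(n-1)); the effect
    size is the partial eta-squared F*df1/(F*df1+df2), equivalently
    SS_condition/(SS_condition+SS_error). With ``greenhouse_geisser`` the
    dfs (and p) are epsilon-corrected; F is unchanged.

    A table with zero condition effect returns F = 0; zero residual error
    with a nonzero condition effect returns F = inf, p = 0.
    """
    if isinstance(table, pd.DataFrame):
        data = table.to_numpy(dtype=float)
    else:
        data = np.asarray(table, dtype=float)
    if data.ndim != 2:
        raise ValueError("expected a 2-D subjects x conditions table")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if np.isnan(data).any():
        raise ValueError("missing cells; repeated-measures table must be complete")

    grand = data.mean()
    subj_means = data.mean(axis=1)
    cond_means = data.mean(axis=0)
    ss_cond = n * float(((cond_means - grand) ** 2).sum())
    ss_subj = k * float(((subj_means - grand) ** 2).sum())
    ss_tot = float(((data - grand) ** 2).sum())
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
    df1, df2 = float(k - 1), float((k - 1) * (n - 1))

    if ss_err == 0.0:
        f = 0.0 if ss_cond == 0.0 else np.inf
        p = 1.0 if ss_cond == 0.0 else 0.0
    else:
        f = (ss_cond / df1) / (ss_err / df2)
        p = float(sps.f.sf(f, df1, df2))

    eps = 1.0
    if greenhouse_geisser and np.isfinite(f):
        # Greenhouse-Geisser epsilon from the doubly centred covariance.
        cov = np.cov(data, rowvar=False, ddof=1)
        centred = cov - cov.mean(axis=0)[None, :] - cov.mean(axis=1)[:, None] + cov.mean()
        num = np.trace(centred) ** 2
        den = (k - 1) * float((centred**2).sum())
        eps = float(np.clip(num / den if den > 0 else 1.0, 1.0 / (k - 1), 1.0))
        p = float(sps.f.sf(f, df1 * eps, df2 * eps))

    res = StatResult(
        test_name="F",
        statistic=float(f),
        df=(df1 * eps, df2 * eps) if greenhouse_geisser else (df1, df2),
        p_value=p,
        effect_size=eta_squared_from_f(f, df1, df2) if ss_cond or ss_err else 0.0,
        effect_size_name="eta_squared",
        correction="greenhouse_geisser" if greenhouse_geisser else "none",
        decisions={"ss_condition": ss_cond, "ss_subject": ss_subj, "ss_error": ss_err},
    )
    return res


def fdr_followups(
    p_values: Sequence[float],
    q: float = 0.05,
    method: str = "two-stage",
) -> np.ndarray:
    """Discovery flags for follow-up comparisons at FDR level ``q``.

    ``method='two-stage'`` is the adaptive two-stage Benjamini-Krieger-
    Yekutieli step-up procedure; ``'bh'`` is the plain Benjamini-Hochberg
    step-up. Returns a boolean array aligned with the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    key = {"two-stage": "fdr_tsbky", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown FDR method {method!r}")
    reject, *_ = multipletests(p, alpha=q, method=key)
    return reject


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen's d with the pooled standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if s2 == 0:
        raise ValueError("pooled SD is zero; d undefined")
    return float((x.mean() - y.mean()) / np.sqrt(s2))


def cohens_d_from_t(t: float, n1: int, n2: int) -> float:
    """Cohen's d recovered from a pooled two-sample t: d = t*sqrt(1/n1+1/n2)."""
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    return float(t * np.sqrt(1.0 / n1 + 1.0 / n2))


def _variance_f_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided F test p-value for equality of variances."""
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        return 1.0
    if v2 == 0 or v1 == 0:
        return 0.0
    if v1 >= v2:
        f, d1, d2 = v1 / v2, len(x) - 1, len(y) - 1
    else:
        f, d1, d2 = v2 / v1, len(y) - 1, len(x) - 1
    return float(min(1.0, 2.0 * sps.f.sf(f, d1, d2)))


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    alpha_variance: float = 0.05,
) -> StatResult:
    """Two-tailed two-sample t test with automatic Welch correction.

    In ``auto`` mode an F test for variance equality decides between the
    pooled Student test and Welch's test (Satterthwaite df); Shapiro-Wilk
    normality p-values are recorded in ``decisions`` but do not change the
    test. ``student`` and ``welch`` force either variant.
    """
    if mode not in ("auto", "student", "welch"):
        raise ValueError(f"unknown mode {mode!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if x.mean() == y.mean():
            raise ValueError("zero variance in both groups with equal means; t undefined")

    decisions: dict = {}
    if mode == "auto":
        p_var = _variance_f_test(x, y)
        decisions["variance_equality_f"] = p_var
        for name, g in (("shapiro_x", x), ("shapiro_y", y)):
            if len(g) >= 3 and g.var() > 0:
                decisions[name] = float(sps.shapiro(g).pvalue)
        use_welch = p_var < alpha_variance
    else:
        use_welch = mode == "welch"

    if use_welch:
        se2_1, se2_2 = v1 / n1, v2 / n2
        se = np.sqrt(se2_1 + se2_2)
        t = (x.mean() - y.mean()) / se
        df = (se2_1 + se2_2) ** 2 / (
            se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1)
        )
        correction = "welch"
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
        correction = "none"
    p = float(2.0 * sps.t.sf(abs(t), df))
    return StatResult(
        test_name="t",
        statistic=float(t),
        df=float(df),
        p_value=p,
        effect_size=cohens_d(x, y),
        effect_size_name="cohens_d",
        correction=correction,
        decisions=decisions,
    )


def power_check(
    effect_ratio: float,
    n_per_group: int = 5,
    noise_cv: float = 0.3,
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Monte-Carlo rejection rate of the automatic two-sample t test.

    Simulates cohorts whose second group's mean is ``effect_ratio`` times the
    first group's; per-mouse values carry lognormal noise with coefficient of
    variation ``noise_cv``. ``effect_ratio = 1`` calibrates the type-I error
    (rate ~ alpha).
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    if n_per_group < 2 or noise_cv < 0 or effect_ratio < 0:
        raise ValueError("invalid design parameters")
    rng = default_rng(seed)
    s2 = np.log1p(noise_cv**2)
    rejections = 0
    for _ in range(n_sim):
        a = np.exp(rng.normal(-0.5 * s2, np.sqrt(s2), n_per_group))
        b = effect_ratio * np.exp(rng.normal(-0.5 * s2, np.sqrt(s2), n_per_group))
        res = two_sample_t(a, b, mode="auto")
        rejections += res.p_value < alpha
    return rejections / n_sim
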