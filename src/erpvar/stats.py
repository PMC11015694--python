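"""Group-comparison tests and the three-tier logistic regression layer.

Two-sample t-tests (Student and Welch) accept either raw vectors or summary
triples (mean, SD, n), so printed cohort tables can be re-analysed without
raw data.  Logistic models relate one variability measure to MCI status in
three nested tiers: crude, + demographics (age, sex, education), + MMSE.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

__all__ = [
    "GroupComparisonResult",
    "LogisticModelResult",
    "ConvergenceError",
    "two_sample_t",
    "pearson_chi2",
    "fit_mci_logistic",
]

TIER_COVARIATES = {1: [], 2: ["age", "sex_male", "education"],
                   3: ["age", "sex_male", "education", "mmse"]}


class ConvergenceError(RuntimeError):
    """Logistic fit failed to converge (e.g. complete separation)."""


@dataclass
class GroupComparisonResult:
    variable: str
    test: str  # "student" | "welch" | "chi_squared"
    statistic: float
    df: float
    p_value: float
    group_summaries: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "test": self.test,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "group_summaries": self.group_summaries,
        }


@dataclass
class LogisticModelResult:
    predictor: str
    tier: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    predictor_scaling: str  # "raw" | "z_scored"

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "tier": self.tier,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_used": self.n_used,
            "predictor_scaling": self.predictor_scaling,
        }


def _summarize(group) -> tuple[float, float, int]:
    """Accept a raw vector or a (mean, sd, n) triple; return the triple."""
    if isinstance(group, (tuple, list)) and len(group) == 3 and np.isscalar(group[0]):
        mean, sd, n = group
        if n < 2:
            raise ValueError(f"need n >= 2 per group, got {n}")
        if sd < 0:
            raise ValueError(f"SD must be >= 0, got {sd}")
        return float(mean), float(sd), int(n)
    x = np.asarray(group, dtype=float)
    if x.size < 2:
        raise ValueError(f"need n >= 2 per group, got {x.size}")
    return float(x.mean()), float(x.std(ddof=1)), int(x.size)


def two_sample_t(
    group_a, group_b, variant: str = "auto", variable: str = ""
) -> GroupComparisonResult:
    """Two-sample t-test from raw vectors or (mean, sd, n) summaries.

    ``student`` pools variances with df = n_a + n_b - 2; ``welch`` uses
    per-group variances with Welch–Satterthwaite df; ``auto`` picks Welch
    when an F-test rejects variance equality at 0.05.  The statistic is
    (mean_a - mean_b) / SE.
    """
    if variant not in ("student", "welch", "auto"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    m1, s1, n1 = _summarize(group_a)
    m2, s2, n2 = _summarize(group_b)

    if variant == "auto":
        variant = "welch" if _variances_differ(s1, n1, s2, n2) else "student"

    diff = m1 - m2
    if s1 == 0.0 and s2 == 0.0:
        # degenerate: no within-group variance
        stat = 0.0 if diff == 0.0 else math.inf * np.sign(diff)
        df = float(n1 + n2 - 2)
        p = 1.0 if diff == 0.0 else 0.0
    elif variant == "student":
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
        stat = diff / se
        p = 2.0 * sps.t.sf(abs(stat), df)
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        stat = diff / se
        p = 2.0 * sps.t.sf(abs(stat), df)

    return GroupComparisonResult(
        variable=variable,
        test=variant,
        statistic=float(stat),
        df=float(df),
        p_value=float(p),
        group_summaries={
            "a": {"mean": m1, "sd": s1, "n": n1},
            "b": {"mean": m2, "sd": s2, "n": n2},
        },
    )


def _variances_differ(s1, n1, s2, n2, alpha: float = 0.05) -> bool:
    if s1 == 0.0 or s2 == 0.0:
        return s1 != s2
    if s1 >= s2:
        f, d1, d2 = (s1 / s2) ** 2, n1 - 1, n2 - 1
    else:
        f, d1, d2 = (s2 / s1) ** 2, n2 - 1, n1 - 1
    p = 2.0 * sps.f.sf(f, d1, d2)
    return min(p, 1.0) < alpha


def pearson_chi2(table, variable: str = "") -> GroupComparisonResult:
    """Classic Pearson chi-squared on a contingency table, no continuity
    correction; df = (rows - 1)(cols - 1)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError(f"need an r x c table with r, c >= 2, got {obs.shape}")
    if np.any(obs < 0):
        raise ValueError("cell counts must be non-negative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0) or total == 0:
        raise ValueError("contingency table has a zero margin")
    expected = row @ col / total
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = float((obs.shape[0] - 1) * (obs.shape[1] - 1))
    p = float(sps.chi2.sf(stat, df))
    return GroupComparisonResult(
        variable=variable,
        test="chi_squared",
        statistic=stat,
        df=df,
        p_value=p,
        group_summaries={"observed": obs.tolist()},
    )


def fit_mci_logistic(
    cohort: pd.DataFrame,
    measure: str,
    tier: int = 1,
    scaling: str = "z_scored",
    outcome: str = "mci",
) -> LogisticModelResult:
    """Maximum-likelihood logistic fit of MCI status on one measure.

    ``cohort`` needs the outcome column (1 = MCI, 0 = CN; a ``group``
    column with CN/MCI labels is accepted instead), the measure column and,
    for tiers 2–3, ``age``, ``sex`` (or ``sex_male``), ``education`` and
    ``mmse``.  Rows with missing values in any used column are dropped and
    counted out of ``n_used``.  95% CIs are Wald on the log-odds scale.
    """
    if tier not in TIER_COVARIATES:
        raise ValueError(f"tier must be 1, 2 or 3, got {tier}")
    if scaling not in ("raw", "z_scored"):
        raise ValueError(f"scaling must be raw or z_scored, got {scaling!r}")

    df = cohort.copy()
    if outcome not in df.columns and "group" in df.columns:
        df[outcome] = (df["group"] == "MCI").astype(int)
    if "sex_male" not in df.columns and "sex" in df.columns:
        df["sex_male"] = (df["sex"] == "M").astype(int)

    cols = [outcome, measure] + TIER_COVARIATES[tier]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")
    df = df[cols].dropna()
    n_used = len(df)

    y = df[outcome].to_numpy(dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("outcome has a single class; cannot fit")

    x = df[measure].to_numpy(dtype=float)
    if scaling == "z_scored":
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"measure {measure!r} has zero variance")
        x = (x - x.mean()) / sd

    X = np.column_stack(
        [x] + [df[c].to_numpy(dtype=float) for c in TIER_COVARIATES[tier]]
    )
    X = sm.add_constant(X, prepend=False)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (np.linalg.LinAlgError, PerfectSeparationError,
            PerfectSeparationWarning) as e:
        raise ConvergenceError(f"logistic fit for {measure!r} failed: {e}") from e
    if not fit.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"logistic fit for {measure!r} did not converge "
            "(possible complete separation)"
        )

    beta = fit.params[0]
    se = fit.bse[0]
    z = sps.norm.ppf(0.975)
    return LogisticModelResult(
        predictor=measure,
        tier=tier,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_value=float(fit.pvalues[0]),
        n_used=n_used,
        predictor_scaling=scaling,
    )
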