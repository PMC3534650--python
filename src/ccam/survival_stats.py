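"""Survival and group-comparison statistics for stratified cohorts.

Thin, contract-checked wrappers around lifelines (Kaplan-Meier, log-rank,
Cox proportional hazards with Efron tie handling) and scipy rank tests
(Kruskal-Wallis, Mann-Whitney) with Bonferroni adjustment as needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalTable",
    "KMCurve",
    "TestResult",
    "km_estimate",
    "logrank_test",
    "cox_ph",
    "group_compare",
]


@dataclass
class SurvivalTable:
    """Per-subject follow-up time, event indicator, stratum and covariates.

    ``table`` is indexed by sample id with columns ``time`` (nonnegative,
    one unit throughout), ``event`` (0/1, 1 = observed), optional
    ``stratum`` and any further numeric covariate columns.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("time", "event"):
            if col not in t.columns:
                raise ValueError(f"survival table requires a {col!r} column")
        if (t["time"] < 0).any():
            raise ValueError("times must be nonnegative")
        if not t["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def strata(self) -> pd.Series:
        if "stratum" not in self.table.columns:
            raise ValueError("survival table has no 'stratum' column")
        return self.table["stratum"]


@dataclass
class KMCurve:
    """Product-limit survival estimate at the observed event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival estimate must be nonincreasing")


@dataclass
class TestResult:
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float
    method: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_raw <= 1 or not 0 <= self.p_adjusted <= 1:
            raise ValueError("p-values must lie in [0, 1]")
        if self.p_adjusted < self.p_raw - 1e-12:
            raise ValueError("adjusted p cannot be below raw p")


def km_estimate(t: SurvivalTable, stratum=None) -> KMCurve:
    """Kaplan-Meier curve, optionally restricted to one stratum.

    With only censored observations the curve is constant 1.
    """
    table = t.table
    if stratum is not None:
        table = table[t.strata == stratum]
    if table.empty:
        raise ValueError(f"no subjects in stratum {stratum!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(table["time"], table["event"])
    et = kmf.event_table
    event_rows = et[et["observed"] > 0]
    times = event_rows.index.to_numpy(dtype=float)
    at_risk = event_rows["at_risk"].to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(event_times=times, at_risk=at_risk, survival=surv)


def logrank_test(t: SurvivalTable) -> TestResult:
    """k-sample log-rank test across the table's strata.

    Uses the observed-minus-expected formulation with hypergeometric
    variance; k strata give a chi-square statistic on k-1 degrees of freedom.
    """
    strata = t.strata
    levels = pd.unique(strata)
    if len(levels) < 2:
        raise ValueError("log-rank test needs at least 2 strata")
    if t.table["event"].sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(t.table["time"], strata, t.table["event"])
    return TestResult(
        statistic=float(res.test_statistic),
        df=float(len(levels) - 1),
        p_raw=float(res.p_value),
        p_adjusted=float(res.p_value),
        method="logrank",
    )


def cox_ph(
    t: SurvivalTable,
    covariates: list[str],
    mode: str = "multivariate",
) -> pd.DataFrame:
    """Cox proportional-hazards regression (Efron tie handling).

    ``mode='multivariate'`` fits one model with all covariates;
    ``'univariate'`` fits each covariate alone. Returns one row per
    covariate: hazard ratio, 95% CI and p-value.

    Raises
    ------
    ValueError
        For a constant covariate, too few events, or non-convergence.
    """
    table = t.table
    missing = [c for c in covariates if c not in table.columns]
    if missing:
        raise ValueError(f"covariates absent from table: {missing}")
    for cov in covariates:
        if table[cov].nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant")
    n_events = int(table["event"].sum())
    if n_events < len(covariates):
        raise ValueError(
            f"{n_events} events cannot support {len(covariates)} covariates"
        )
    if mode not in ("multivariate", "univariate"):
        raise ValueError("mode must be 'multivariate' or 'univariate'")

    def _fit(cols: list[str]) -> pd.DataFrame:
        cph = CoxPHFitter()
        try:
            cph.fit(
                table[["time", "event"] + cols],
                duration_col="time",
                event_col="event",
            )
        except ConvergenceError as err:  # pragma: no cover - depends on data
            raise ValueError(f"Cox model failed to converge: {err}") from err
        summ = cph.summary
        return pd.DataFrame(
            {
                "hazard_ratio": summ["exp(coef)"],
                "ci_lower": summ["exp(coef) lower 95%"],
                "ci_upper": summ["exp(coef) upper 95%"],
                "p": summ["p"],
            }
        )

    if mode == "multivariate":
        out = _fit(covariates)
    else:
        out = pd.concat([_fit([c]) for c in covariates])
    out.index.name = "covariate"
    return out.loc[covariates]


def group_compare(
    scores: pd.Series,
    groups: pd.Series,
    method: str = "kruskal_wallis",
    bonferroni: bool = False,
) -> TestResult:
    """Rank-based comparison of score distributions across groups.

    ``kruskal_wallis`` handles any number of groups; ``mann_whitney``
    requires exactly two (exact p for small tie-free samples). With
    ``bonferroni`` the p-value is multiplied by the number of pairwise group
    comparisons.
    """
    groups = groups.reindex(scores.index)
    levels = pd.unique(groups.dropna())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    samples = [scores[groups == g].to_numpy() for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    if method == "kruskal_wallis":
        stat, p = sps.kruskal(*samples)
        df = float(len(levels) - 1)
    elif method == "mann_whitney":
        if len(levels) != 2:
            raise ValueError("mann_whitney compares exactly two groups")
        stat, p = sps.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        df = float("nan")
    else:
        raise ValueError(f"unknown method {method!r}")
    n_pairs = len(levels) * (len(levels) - 1) // 2
    p_adj = min(1.0, p * n_pairs) if bonferroni else float(p)
    return TestResult(
        statistic=float(stat),
        df=df,
        p_raw=float(p),
        p_adjusted=float(p_adj),
        method=method + ("+bonferroni" if bonferroni else ""),
    )
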