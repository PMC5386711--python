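"""Median-split survival stratification: Kaplan–Meier curves and log-rank test.

A cohort of (time, event, expression) records is split at the median
expression value into a low and a high group (ties at the median go to the
low group, so the split is deterministic).  Each group's survival function
is estimated with the product-limit (Kaplan–Meier) estimator and the two
groups are compared with the standard two-sample log-rank test: at every
distinct event time a 2x2 table contributes observed events, expected
events under the null, and a hypergeometric variance; the statistic
``(O_A - E_A)^2 / V`` is referred to a chi-square distribution with one
degree of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class SurvivalCohort:
    """Per-sample follow-up records.

    ``data`` columns: ``sample_id``, ``time_months`` (>= 0), ``event``
    (1 = death observed, 0 = censored), ``expression`` (real).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "time_months", "event", "expression"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort table lacks columns {sorted(missing)}")
        if (self.data["time_months"] < 0).any():
            raise ValueError("times must be non-negative")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event flags must be 0 or 1")

    def __len__(self) -> int:
        return len(self.data)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SurvivalCohort":
        return cls(pd.read_csv(path, sep="\t"))


def median_split(cohort: SurvivalCohort) -> pd.Series:
    """Label samples ``high``/``low`` by the sample median of expression.

    Values strictly above the median are ``high``; values at or below the
    median are ``low`` (the declared tie rule), so with distinct values the
    split is exactly 50/50.
    """
    expr = cohort.data["expression"]
    if len(expr) < 2:
        raise ValueError("need >= 2 samples to split")
    if expr.nunique() == 1:
        raise ValueError("all expression values equal; no median split possible")
    med = expr.median()
    labels = np.where(expr > med, "high", "low")
    return pd.Series(labels, index=cohort.data["sample_id"].to_numpy(), name="group")


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``table`` is indexed by the distinct observed times with columns
    ``at_risk``, ``events``, ``survival``.  ``median`` is the smallest time
    with S(t) <= 0.5, or None when the curve never reaches 0.5.
    """

    table: pd.DataFrame
    median: float | None

    def survival_at(self, t: float) -> float:
        steps = self.table.index[self.table.index <= t]
        if len(steps) == 0:
            return 1.0
        return float(self.table.loc[steps[-1], "survival"])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "time_months"
        out.to_csv(path, sep="\t")


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier estimate for one group (lifelines product-limit fit)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty group")
    if (times < 0).any():
        raise ValueError("negative time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    # lifelines seeds its event table with t=0; keep only observed times
    et = kmf.event_table
    et = et[et.index.isin(times)]
    surv = kmf.survival_function_["KM_estimate"]
    table = pd.DataFrame(
        {
            "at_risk": et["at_risk"].astype(int),
            "events": et["observed"].astype(int),
            "survival": surv.loc[et.index].to_numpy(),
        },
        index=et.index,
    )
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KMCurve(table=table, median=median)


@dataclass
class LogRankResult:
    """Two-sample log-rank summary (group A vs group B, 1 df)."""

    observed: tuple[float, float]
    expected: tuple[float, float]
    variance: float
    chi_square: float
    p_value: float


def logrank_test(
    times_a, events_a, times_b, events_b
) -> LogRankResult:
    """Two-sample log-rank test from raw (time, event) vectors.

    At each distinct event time, with ``n`` subjects at risk (``n_a`` in
    group A) and ``d`` events, group A contributes expectation
    ``d * n_a / n`` and variance ``d (n_a/n)(1 - n_a/n)(n - d)/(n - 1)``.
    When no event time has subjects from both groups the variance is zero
    and p = 1 by convention.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("need at least one observed event")
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    O_a = E_a = V = 0.0
    d_total = 0.0
    for t in event_times:
        n_a = float((ta >= t).sum())
        n_b = float((tb >= t).sum())
        n = n_a + n_b
        d_a = float(((ta == t) & (ea == 1)).sum())
        d_b = float(((tb == t) & (eb == 1)).sum())
        d = d_a + d_b
        O_a += d_a
        E_a += d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
        d_total += d
    if V == 0:
        logger.warning("log-rank variance is zero (no comparable event times); p=1")
        chi2, p = 0.0, 1.0
    else:
        chi2 = (O_a - E_a) ** 2 / V
        p = float(stats.chi2.sf(chi2, df=1))
    O_b = d_total - O_a
    E_b = d_total - E_a
    return LogRankResult(
        observed=(O_a, O_b),
        expected=(E_a, E_b),
        variance=V,
        chi_square=chi2,
        p_value=p,
    )


def stratified_km(cohort: SurvivalCohort) -> dict:
    """Median split + per-group KM + log-rank, the full stratification step."""
    labels = median_split(cohort)
    d = cohort.data.set_index("sample_id")
    out = {"groups": labels}
    subsets = {}
    for g in ("low", "high"):
        sub = d.loc[labels.index[labels == g]]
        subsets[g] = sub
        out[f"km_{g}"] = km_estimate(sub["time_months"], sub["event"])
    out["logrank"] = logrank_test(
        subsets["low"]["time_months"],
        subsets["low"]["event"],
        subsets["high"]["time_months"],
        subsets["high"]["event"],
    )
    return out
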