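"""Survival analysis of fold-change-dichotomized expression groups.

Cases are split at a fold-change cutoff (low: FC < 1, high: FC >= 1 by
default), compared by Kaplan-Meier curves and the log-rank test, and the
relative event rate is estimated as a hazard ratio from a single-covariate
proportional-hazards model (Efron ties, Newton-Raphson partial-likelihood
maximization, via lifelines).  A Fisher exact test compares alteration
frequencies across binary clinical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "dichotomize_by_fc",
    "km_logrank",
    "cox_hr",
    "compare_alteration_frequency",
    "KmResult",
    "CoxResult",
    "FcSurvival",
]


def dichotomize_by_fc(fc: float, cutoff: float = 1.0) -> str:
    """Expression group of a case: "low" if FC < cutoff else "high".

    The cutoff itself belongs to the high group (FC >= 1 is "high").
    """
    if not np.isfinite(fc) or fc <= 0:
        raise ValueError("fold change must be a positive finite number")
    return "low" if fc < cutoff else "high"


@dataclass
class KmResult:
    """Kaplan-Meier curves per group with the log-rank comparison."""

    curves: dict[str, pd.DataFrame]
    medians: dict[str, float]  # np.inf when the median is not reached
    group_sizes: dict[str, int]
    statistic: float
    p: float


@dataclass
class CoxResult:
    """Single-covariate proportional-hazards fit (high vs low group)."""

    hr: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    se: float
    converged: bool
    message: str = ""


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = {"time", "event", "group"} - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rec = records.copy()
    rec["time"] = rec["time"].astype(float)
    rec["event"] = rec["event"].astype(int)
    if (rec["time"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    return rec


def km_logrank(records: pd.DataFrame) -> KmResult:
    """Product-limit survival estimates per group and the log-rank test.

    ``records`` needs columns time (months), event (1 = death observed),
    group.  The median is the first time the survival estimate drops to
    0.5 or below, np.inf when never reached.  Requires at least two groups.
    """
    rec = _check_records(records)
    groups = sorted(rec["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups for a survival comparison")
    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    sizes: dict[str, int] = {}
    for g in groups:
        sub = rec[rec["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"], label=str(g))
        curves[g] = kmf.survival_function_
        medians[g] = float(kmf.median_survival_time_)
        sizes[g] = len(sub)
    lr = multivariate_logrank_test(rec["time"], rec["group"], rec["event"])
    return KmResult(
        curves=curves,
        medians=medians,
        group_sizes=sizes,
        statistic=float(lr.test_statistic),
        p=float(lr.p_value),
    )


def cox_hr(records: pd.DataFrame, reference: str = "low") -> CoxResult:
    """Hazard ratio of the non-reference group from a Cox PH fit.

    The group indicator is coded 0 for ``reference`` and 1 otherwise, so the
    returned HR is the event-rate ratio of the other group relative to the
    reference.  Non-convergence is flagged in the result, not raised.
    """
    rec = _check_records(records)
    groups = sorted(rec["group"].unique())
    if len(groups) != 2:
        raise ValueError("Cox comparison requires exactly two groups")
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not present")
    df = pd.DataFrame(
        {
            "time": rec["time"],
            "event": rec["event"],
            "grp": (rec["group"] != reference).astype(float),
        }
    )
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        return CoxResult(
            hr=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
            coef=np.nan, se=np.nan, converged=False, message=str(exc),
        )
    coef = float(cph.params_["grp"])
    se = float(cph.standard_errors_["grp"])
    return CoxResult(
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.96 * se)),
        ci_high=float(np.exp(coef + 1.96 * se)),
        p=float(cph.summary.loc["grp", "p"]),
        coef=coef,
        se=se,
        converged=True,
    )


def compare_alteration_frequency(
    altered: pd.Series | np.ndarray, covariate: pd.Series | np.ndarray
) -> dict[str, float]:
    """2x2 Fisher exact comparison of alteration frequency by covariate level.

    Returns the table counts, per-level alteration proportions, and the
    two-sided Fisher exact p-value.
    """
    altered = np.asarray(altered, dtype=bool)
    covariate = np.asarray(covariate, dtype=bool)
    if altered.shape != covariate.shape:
        raise ValueError("altered and covariate vectors must align")
    if covariate.all() or not covariate.any():
        raise ValueError("both covariate levels must be present")
    a = int(np.sum(altered & covariate))
    b = int(np.sum(~altered & covariate))
    c = int(np.sum(altered & ~covariate))
    d = int(np.sum(~altered & ~covariate))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {
        "altered_with": a,
        "unaltered_with": b,
        "altered_without": c,
        "unaltered_without": d,
        "prop_altered_with": a / (a + b),
        "prop_altered_without": c / (c + d),
        "p": float(p),
    }


class FcSurvival(BaseEstimator):
    """Fold-change-dichotomized survival comparison (sklearn-style).

    ``fit`` takes a DataFrame with columns time, event, fc; cases are split
    at ``cutoff`` and compared.  Fitted attributes: ``group_sizes_``,
    ``medians_``, ``logrank_statistic_``, ``logrank_p_``, ``hazard_ratio_``,
    ``hr_ci_``, ``hr_p_``, ``km_`` (the full :class:`KmResult`), ``cox_``.
    """

    def __init__(self, cutoff: float = 1.0):
        self.cutoff = cutoff

    def fit(self, X: pd.DataFrame, y=None) -> "FcSurvival":
        missing = {"time", "event", "fc"} - set(X.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        rec = X.copy()
        rec["group"] = rec["fc"].map(lambda f: dichotomize_by_fc(f, self.cutoff))
        self.km_ = km_logrank(rec)
        self.cox_ = cox_hr(rec, reference="low")
        self.group_sizes_ = self.km_.group_sizes
        self.medians_ = self.km_.medians
        self.logrank_statistic_ = self.km_.statistic
        self.logrank_p_ = self.km_.p
        self.hazard_ratio_ = self.cox_.hr
        self.hr_ci_ = (self.cox_.ci_low, self.cox_.ci_high)
        self.hr_p_ = self.cox_.p
        return self
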