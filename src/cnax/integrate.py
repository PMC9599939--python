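"""Copy-number/expression correlation screens.

Correlates per-SNP tumor LRR (the copy-number signal) with exon-boundary
mRNA fold changes and with target-miR fold changes across cases, and mRNA
with miR fold changes, by Spearman rank correlation.  Pairs with fewer than
five complete cases are excluded (recorded as skipped, not errors).  Each
screen carries a nominal p < 0.05 flag and a Bonferroni flag at
alpha / m, where m is the full number of planned comparisons.

The Spearman p-value is exact (full permutation distribution) for n <= 9
without ties, and uses the t approximation with average ranks otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "SpearmanResult",
    "MultipleTestingPlan",
    "spearman",
    "classify_direction",
    "SpearmanScreen",
    "correlate_snp_vs_expression",
    "correlate_snp_vs_mirna",
    "correlate_expression_vs_mirna",
    "find_dual_correlated_snps",
    "compare_groups_by_alteration",
    "default_snp_subset",
]

_EXACT_MAX_N = 9


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int
    method: str  # "exact" | "t-approx"


@dataclass(frozen=True)
class MultipleTestingPlan:
    """Bonferroni correction plan over m planned comparisons."""

    alpha: float = 0.05
    m: int = 1

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.m


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p over all n! pairings of the (untied) rank vectors."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    # Untied ranks: rho = 1 - 6 * sum(d^2) / (n(n^2-1)).
    d = rx[np.newaxis, :] - ry[perms]
    rho_perm = 1.0 - 6.0 * np.sum(d * d, axis=1) / (n * (n * n - 1.0))
    return float(np.mean(np.abs(rho_perm) >= abs(rho_obs) - 1e-12))


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with a small-sample exact p-value.

    rho is the Pearson correlation of mid-ranks (ties averaged).  The
    p-value is the exhaustive permutation p for n <= 9 with no ties in
    either vector, and the two-sided t approximation
    ``t = rho * sqrt((n-2) / (1-rho^2))`` on n-2 df otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 2:
        raise ValueError("need at least two observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx = np.std(rx)
    sy = np.std(ry)
    if sx == 0 or sy == 0:
        raise ValueError("constant input has no defined rank correlation")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    rho = max(-1.0, min(1.0, rho))
    no_ties = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n <= _EXACT_MAX_N and no_ties:
        p = _exact_perm_p(rx, ry, rho)
        method = "exact"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
        method = "t-approx"
    return SpearmanResult(rho=rho, p=max(p, np.finfo(float).tiny), n=n, method=method)


def classify_direction(rho: float) -> str:
    """Concordance direction of a SNP/expression correlation.

    Positive rho means LRR and fold change move together — copy-number gain
    with overexpression or loss with underexpression; negative rho is the
    inverse pattern; exactly zero is undirected.
    """
    if not np.isfinite(rho):
        raise ValueError("rho must be finite")
    if rho > 0:
        return "positive"
    if rho < 0:
        return "negative"
    return "undirected"


class SpearmanScreen(BaseEstimator):
    """All-pairs Spearman screen between two case-aligned matrices.

    ``fit(X, Y)`` takes DataFrames indexed by case (X: cases x p features,
    Y: cases x q features), computes one correlation per (X-column,
    Y-column) pair over pairwise-complete cases, skips pairs with fewer
    than ``min_cases`` complete observations, and stores:

    results_
        Long DataFrame: id1, id2, n, rho, p, nominal, bonferroni, direction.
    plan_
        :class:`MultipleTestingPlan` with m = p * q unless overridden.
    skipped_
        List of (id1, id2, n) pairs excluded by the minimum-case rule.
    """

    def __init__(self, min_cases: int = 5, alpha: float = 0.05, m: int | None = None):
        self.min_cases = min_cases
        self.alpha = alpha
        self.m = m

    def fit(self, X: pd.DataFrame, Y: pd.DataFrame) -> "SpearmanScreen":
        if X.empty or Y.empty:
            raise ValueError("empty input matrix")
        common = X.index.intersection(Y.index)
        X = X.loc[common]
        Y = Y.loc[common]
        m = self.m if self.m is not None else X.shape[1] * Y.shape[1]
        plan = MultipleTestingPlan(alpha=self.alpha, m=m)
        rows, skipped = [], []
        xv = X.to_numpy(dtype=float)
        yv = Y.to_numpy(dtype=float)
        for i, id1 in enumerate(X.columns):
            xi = xv[:, i]
            for j, id2 in enumerate(Y.columns):
                yj = yv[:, j]
                ok = np.isfinite(xi) & np.isfinite(yj)
                n = int(ok.sum())
                if n < self.min_cases:
                    skipped.append((id1, id2, n))
                    continue
                res = spearman(xi[ok], yj[ok])
                rows.append(
                    {
                        "id1": id1,
                        "id2": id2,
                        "n": res.n,
                        "rho": res.rho,
                        "p": res.p,
                        "nominal": res.p < plan.alpha,
                        "bonferroni": res.p < plan.bonferroni_threshold,
                        "direction": classify_direction(res.rho),
                    }
                )
        self.results_ = pd.DataFrame(
            rows,
            columns=["id1", "id2", "n", "rho", "p", "nominal", "bonferroni", "direction"],
        )
        self.plan_ = plan
        self.skipped_ = skipped
        return self


def _screen(
    X: pd.DataFrame, Y: pd.DataFrame, min_cases: int, alpha: float, m: int | None
) -> tuple[pd.DataFrame, MultipleTestingPlan]:
    sc = SpearmanScreen(min_cases=min_cases, alpha=alpha, m=m).fit(X, Y)
    return sc.results_, sc.plan_


def correlate_snp_vs_expression(
    snp_lrr: pd.DataFrame,
    probe_fc: pd.DataFrame,
    snp_subset: Sequence[str],
    min_cases: int = 5,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, MultipleTestingPlan]:
    """Spearman screen of CNA-SNP LRR against exon-boundary mRNA FC.

    ``snp_subset`` restricts to SNPs carrying a somatic CNA; the Bonferroni
    family size is |subset| x number of probes, counting skipped pairs.
    """
    subset = list(snp_subset)
    if not subset:
        raise ValueError("empty SNP subset")
    m = len(subset) * probe_fc.shape[1]
    res, plan = _screen(snp_lrr[subset], probe_fc, min_cases, alpha, m)
    return res.rename(columns={"id1": "snp_id", "id2": "probe_id"}), plan


def correlate_snp_vs_mirna(
    snp_lrr: pd.DataFrame,
    mir_fc: pd.DataFrame,
    snp_subset: Sequence[str],
    mir_subset: Sequence[str] | None = None,
    min_cases: int = 5,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, MultipleTestingPlan]:
    """Spearman screen of CNA-SNP LRR against abnormally expressed miRs."""
    subset = list(snp_subset)
    if not subset:
        raise ValueError("empty SNP subset")
    mirs = list(mir_subset) if mir_subset is not None else list(mir_fc.columns)
    m = len(subset) * len(mirs)
    res, plan = _screen(snp_lrr[subset], mir_fc[mirs], min_cases, alpha, m)
    return res.rename(columns={"id1": "snp_id", "id2": "mir_id"}), plan


def correlate_expression_vs_mirna(
    probe_fc: pd.DataFrame,
    mir_fc: pd.DataFrame,
    min_cases: int = 5,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, MultipleTestingPlan]:
    """Spearman screen of exon-boundary mRNA FC against target-miR FC."""
    res, plan = _screen(probe_fc, mir_fc, min_cases, alpha, None)
    return res.rename(columns={"id1": "probe_id", "id2": "mir_id"}), plan


def find_dual_correlated_snps(
    mrna_results: pd.DataFrame, mirna_results: pd.DataFrame
) -> pd.DataFrame:
    """SNPs nominally significant against both mRNA and miR expression.

    Returns long format (one row per significant partner) restricted to
    SNPs present in the nominal-significant set of both screens.
    """
    if mrna_results.empty or mirna_results.empty:
        return pd.DataFrame(
            columns=["snp_id", "analysis", "partner_id", "n", "rho", "p"]
        )
    sig_m = mrna_results[mrna_results["nominal"]]
    sig_r = mirna_results[mirna_results["nominal"]]
    dual = sorted(set(sig_m["snp_id"]) & set(sig_r["snp_id"]))
    rows = []
    for snp in dual:
        for r in sig_m[sig_m["snp_id"] == snp].itertuples():
            rows.append(
                {"snp_id": snp, "analysis": "mrna", "partner_id": r.probe_id,
                 "n": r.n, "rho": r.rho, "p": r.p}
            )
        for r in sig_r[sig_r["snp_id"] == snp].itertuples():
            rows.append(
                {"snp_id": snp, "analysis": "mirna", "partner_id": r.mir_id,
                 "n": r.n, "rho": r.rho, "p": r.p}
            )
    return pd.DataFrame(rows, columns=["snp_id", "analysis", "partner_id", "n", "rho", "p"])


def compare_groups_by_alteration(
    fc_matrix: pd.DataFrame, altered: pd.Series
) -> pd.DataFrame:
    """Per-item mean FC in DNA-altered vs non-altered cases, with the ratio.

    ``fc_matrix`` is cases x items (probes or miRs); ``altered`` is a
    boolean case-indexed Series.  Both groups must be non-empty.
    """
    altered = altered.reindex(fc_matrix.index)
    if altered.isna().any():
        raise ValueError("alteration status missing for some cases")
    altered = altered.astype(bool)
    if altered.all() or not altered.any():
        raise ValueError("both altered and non-altered groups must be non-empty")
    mean_alt = fc_matrix.loc[altered].mean(axis=0, skipna=True)
    mean_not = fc_matrix.loc[~altered].mean(axis=0, skipna=True)
    return pd.DataFrame(
        {
            "item": fc_matrix.columns,
            "mean_fc_altered": mean_alt.to_numpy(),
            "mean_fc_unaltered": mean_not.to_numpy(),
            "ratio": (mean_alt / mean_not).to_numpy(),
        }
    )


def default_snp_subset(cna_matrix: pd.DataFrame, min_cases_with_cna: int = 1) -> list[str]:
    """SNPs with a CNA call in at least ``min_cases_with_cna`` cases."""
    counts = cna_matrix.astype(bool).sum(axis=0)
    return sorted(counts.index[counts >= min_cases_with_cna])
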