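"""Kaplan-Meier estimation, log-rank tests, Cox models and fixed-effect meta-analysis.

Kaplan-Meier curves and log-rank tests are delegated to lifelines. The Cox
proportional-hazards model is fitted here by Newton maximization of the
partial likelihood with Breslow tie handling (Efron optional), converged to
machine-level tolerance; inference is Wald, from the observed information.
The module also supplies the median stratification rule and inverse-variance
fixed-effect pooling of log hazard ratios.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "km_curve",
    "KMCurve",
    "logrank_test",
    "LogrankResult",
    "cox_fit",
    "CoxResult",
    "median_stratify",
    "StratificationResult",
    "meta_fixed_effect",
    "MetaResult",
]


def _validate_times(records: pd.DataFrame, duration_col: str) -> None:
    bad = records.index[records[duration_col] <= 0]
    if len(bad):
        raise ValueError(f"nonpositive survival time for record(s): {list(bad[:5])}")


@dataclass
class KMCurve:
    """Product-limit survival estimate: right-continuous step function."""

    times: np.ndarray
    survival: np.ndarray

    def at(self, t: float) -> float:
        """S(t); S(0) = 1, steps occur at event times only."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(
    records: pd.DataFrame, duration_col: str = "time", event_col: str = "event"
) -> KMCurve:
    """Kaplan-Meier estimate from a clinical table with time and event columns."""
    if len(records) == 0:
        raise ValueError("km_curve: no records")
    _validate_times(records, duration_col)
    kmf = KaplanMeierFitter()
    kmf.fit(records[duration_col], records[event_col])
    sf = kmf.survival_function_
    return KMCurve(sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float))


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    df: int
    p: float

    def __iter__(self):
        return iter((self.chi2, self.df, self.p))


def logrank_test(
    records: pd.DataFrame,
    group_col: str,
    duration_col: str = "time",
    event_col: str = "event",
) -> LogrankResult:
    """k-group log-rank test (df = k-1) with hypergeometric variance."""
    _validate_times(records, duration_col)
    groups = records[group_col]
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("logrank_test: need at least two non-empty groups")
    res = multivariate_logrank_test(
        records[duration_col], groups, records[event_col]
    )
    return LogrankResult(float(res.test_statistic), len(counts) - 1, float(res.p_value))


def _cox_loglik(
    beta: np.ndarray, x: np.ndarray, time: np.ndarray, event: np.ndarray, ties: str
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, gradient and Hessian (Breslow or Efron ties).

    Subjects must be pre-sorted by decreasing time so that running sums over
    the risk set can be accumulated; tied times are handled per event-time
    group.
    """
    n, p = x.shape
    eta = x @ beta
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    s0, s1 = 0.0, np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:  # group of tied times
            j += 1
        for k in range(i, j):  # everyone tied at this time enters the risk set
            s0 += w[k]
            s1 += w[k] * x[k]
            s2 += w[k] * np.outer(x[k], x[k])
        ev = [k for k in range(i, j) if event[k]]
        d = len(ev)
        if d:
            xe = x[ev]
            if ties == "breslow":
                ll += float(eta[ev].sum()) - d * math.log(s0)
                grad += xe.sum(axis=0) - d * s1 / s0
                hess -= d * (s2 / s0 - np.outer(s1 / s0, s1 / s0))
            else:  # efron
                t0 = float(w[ev].sum())
                t1 = (w[ev, None] * xe).sum(axis=0)
                t2 = (w[ev, None, None] * np.einsum("ij,ik->ijk", xe, xe)).sum(axis=0)
                ll += float(eta[ev].sum())
                for l in range(d):
                    f = l / d
                    a0 = s0 - f * t0
                    a1 = s1 - f * t1
                    a2 = s2 - f * t2
                    ll -= math.log(a0)
                    grad -= a1 / a0
                    hess -= a2 / a0 - np.outer(a1 / a0, a1 / a0)
                grad += xe.sum(axis=0)
        i = j
    return ll, grad, hess


def _cox_newton(
    x: np.ndarray, time: np.ndarray, event: np.ndarray, ties: str,
    tol: float = 1e-10, max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton-Raphson maximization; returns (beta, covariance)."""
    order = np.argsort(-time, kind="mergesort")
    x, time, event = x[order], time[order], event[order]
    beta = np.zeros(x.shape[1])
    for _ in range(max_iter):
        _, grad, hess = _cox_loglik(beta, x, time, event, ties)
        step = np.linalg.solve(hess, -grad)
        # halve overly large steps to keep exp(eta) finite
        while np.abs(x @ (beta + step)).max() > 500:
            step /= 2.0
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    else:
        raise RuntimeError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(last gradient norm {np.linalg.norm(grad):.3e})"
        )
    if np.abs(beta).max() > 20:
        warnings.warn(
            "cox_fit: extreme coefficient magnitude suggests separation", stacklevel=3
        )
    _, _, hess = _cox_loglik(beta, x, time, event, ties)
    cov = np.linalg.inv(-hess)
    return beta, cov


@dataclass
class CoxResult:
    """Per-covariate Cox proportional-hazards estimates."""

    summary: pd.DataFrame  # lnHR, se, z, p, HR, ci95_low, ci95_high per covariate
    n: int
    n_events: int
    log_likelihood: float

    @property
    def lnHR(self) -> pd.Series:
        return self.summary["lnHR"]

    @property
    def HR(self) -> pd.Series:
        return self.summary["HR"]

    def single(self) -> dict:
        """The one-covariate case as a flat dict."""
        if len(self.summary) != 1:
            raise ValueError("single() requires a univariate fit")
        return self.summary.iloc[0].to_dict()


def cox_fit(
    records: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
    ties: str = "breslow",
) -> CoxResult:
    """Cox proportional-hazards fit by partial-likelihood maximization.

    Wald z and p per covariate; 95% CI as lnHR ± 1.96·se. Requires at least
    one event and nonconstant covariates. Tied event times are handled by
    Breslow's approximation by default (``ties="efron"`` for Efron's); the
    two coincide when no times are tied.
    """
    if ties not in {"breslow", "efron"}:
        raise ValueError(f"cox_fit: ties must be 'breslow' or 'efron', got {ties!r}")
    _validate_times(records, duration_col)
    if records[event_col].sum() < 1:
        raise ValueError("cox_fit: no events in the data")
    for c in covariates:
        if records[c].nunique() < 2:
            raise ValueError(f"cox_fit: covariate {c!r} is constant")
    covariates = list(covariates)
    x = records[covariates].to_numpy(dtype=float)
    center = x.mean(axis=0)  # centering for numerical stability; slopes unaffected
    time = records[duration_col].to_numpy(dtype=float)
    event = records[event_col].to_numpy(dtype=float).astype(bool)
    beta, cov = _cox_newton(x - center, time, event, ties)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "lnHR": beta,
            "se": se,
            "z": z,
            "p": p,
            "HR": np.exp(beta),
            "ci95_low": np.exp(beta - 1.96 * se),
            "ci95_high": np.exp(beta + 1.96 * se),
        },
        index=pd.Index(covariates, name="covariate"),
    )
    order = np.argsort(-time, kind="mergesort")
    ll = _cox_loglik(beta, (x - center)[order], time[order], event[order], ties)[0]
    return CoxResult(out, len(records), int(event.sum()), float(ll))


@dataclass
class StratificationResult:
    labels: pd.Series  # "high" / "low"
    median: float
    n_high: int
    n_low: int


def median_stratify(scores: pd.Series) -> StratificationResult:
    """Split samples at the median score; ties at the median go to "high".

    For even n the median is the mean of the two central order statistics.
    All-identical scores cannot be stratified and raise.
    """
    scores = pd.Series(scores).astype(float)
    if len(scores) < 2:
        raise ValueError("median_stratify: need at least two samples")
    if scores.nunique() == 1:
        raise ValueError("median_stratify: all scores identical, no stratification possible")
    med = float(scores.median())
    labels = pd.Series(np.where(scores >= med, "high", "low"), index=scores.index, name="group")
    return StratificationResult(labels, med, int((labels == "high").sum()), int((labels == "low").sum()))


@dataclass
class MetaResult:
    """Inverse-variance fixed-effect pooling of per-study log hazard ratios."""

    pooled_lnHR: float
    se: float
    ci95: tuple[float, float]
    p: float
    q: float
    i2: float  # percent
    studies: pd.DataFrame = field(repr=False, default=None)

    @property
    def pooled_HR(self) -> float:
        return math.exp(self.pooled_lnHR)


def meta_fixed_effect(studies: Sequence[tuple[float, float]]) -> MetaResult:
    """Fixed-effect meta-analysis of (lnHR, se) pairs.

    Weights are 1/se²; the pooled estimate is the weighted mean with
    se = 1/sqrt(sum of weights). Cochran's Q and I² = max(0, (Q - df)/Q)·100
    quantify heterogeneity; a fixed-effect model is conventionally reserved
    for I² < 30%, so higher values trigger a warning.
    """
    studies = list(studies)
    if len(studies) < 2:
        raise ValueError("meta_fixed_effect: need at least two studies")
    lnhr = np.array([s[0] for s in studies], dtype=float)
    se = np.array([s[1] for s in studies], dtype=float)
    if (se <= 0).any():
        raise ValueError("meta_fixed_effect: all standard errors must be > 0")
    w = 1.0 / se**2
    pooled = float((w * lnhr).sum() / w.sum())
    pooled_se = float(1.0 / math.sqrt(w.sum()))
    q = float((w * (lnhr - pooled) ** 2).sum())
    dof = len(studies) - 1
    i2 = max(0.0, (q - dof) / q) * 100.0 if q > 0 else 0.0
    if i2 >= 30.0:
        warnings.warn(
            f"meta_fixed_effect: I² = {i2:.1f}% >= 30%; a fixed-effect model may be "
            "inappropriate under this heterogeneity",
            stacklevel=2,
        )
    z = pooled / pooled_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    ci = (pooled - 1.96 * pooled_se, pooled + 1.96 * pooled_se)
    table = pd.DataFrame({"lnHR": lnhr, "se": se, "weight": w / w.sum()})
    return MetaResult(pooled, pooled_se, ci, p, q, i2, table)
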