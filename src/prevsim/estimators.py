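"""Survival effect measures for simulated trial datasets.

One :class:`EffectSummary` collects the measures a prevention trial would
report: the Cox hazard ratio with Wald CI, the risk ratio of incidence
proportions, the difference in median survival time (bootstrap CI), the
restricted mean survival time difference at a truncation time tau, and
log-rank / Wald p-values.

Kaplan-Meier curves with Greenwood CIs come from lifelines; the bootstrap
internals use a fast numpy product-limit helper (validated against lifelines
in the test suite) so resampling stays cheap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import norm

from ._cox import CoxFit, cox_fit
from .trial_sim import TrialDataset

__all__ = [
    "KMEstimate",
    "EffectEstimate",
    "EffectSummary",
    "kaplan_meier",
    "cox_hr",
    "risk_ratio",
    "median_diff_bootstrap",
    "rmst_diff",
    "interaction_wald",
    "logrank_p",
    "effect_summary",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class KMEstimate:
    """Product-limit estimate with Greenwood 95% band for one group."""

    times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_at_risk: np.ndarray
    censor_times: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_at_risk": self.n_at_risk,
            }
        )

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class EffectEstimate:
    """Point estimate with a 95% CI and optionally a p-value."""

    estimate: float
    ci_low: float
    ci_high: float
    p_value: Optional[float] = None
    undefined: bool = False

    def as_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "undefined": self.undefined,
        }


@dataclass
class EffectSummary:
    """The full effect-measure suite for one two-arm dataset."""

    hr: EffectEstimate
    rr: EffectEstimate
    median_diff: EffectEstimate
    rmst_diff: EffectEstimate
    rmst_tau: float
    p_logrank: float

    def to_json(self, **kwargs) -> str:
        d = {
            "hr": self.hr.as_dict(),
            "rr": self.rr.as_dict(),
            "median_diff": self.median_diff.as_dict(),
            "rmst_diff": self.rmst_diff.as_dict(),
            "rmst_tau": self.rmst_tau,
            "p_logrank": self.p_logrank,
        }
        return json.dumps(d, **kwargs)


# --------------------------------------------------------------------------
# fast product-limit internals
# --------------------------------------------------------------------------

def _km_curve(time: np.ndarray, event: np.ndarray, counts: bool = False):
    """(event_times, survival) of the product-limit estimator, no CI.

    With ``counts=True`` also returns events and numbers at risk per
    distinct event time.
    """
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order].astype(bool)
    n = len(t)
    uniq, first = np.unique(t, return_index=True)
    d = np.add.reduceat(e.astype(float), first)
    at_risk = n - first
    surv = np.cumprod(1.0 - d / at_risk)
    has_event = d > 0
    if counts:
        return uniq[has_event], surv[has_event], d[has_event], at_risk[has_event]
    return uniq[has_event], surv[has_event]


def _km_median(time: np.ndarray, event: np.ndarray) -> float:
    """First time the KM curve drops to <= 0.5; inf when never reached."""
    t, s = _km_curve(time, event)
    below = s <= 0.5
    return float(t[below][0]) if below.any() else math.inf


def _km_rmst(time: np.ndarray, event: np.ndarray, tau: float) -> float:
    """Area under the KM step function up to tau."""
    t, s = _km_curve(time, event)
    keep = t < tau
    t, s = t[keep], s[keep]
    edges = np.concatenate([[0.0], t, [tau]])
    heights = np.concatenate([[1.0], s])
    return float(np.sum(heights * np.diff(edges)))


def _km_rmst_var(time: np.ndarray, event: np.ndarray, tau: float) -> float:
    """Plug-in (Greenwood-type) variance of the RMST estimator,

    Var = sum over event times t_i <= tau of
    [integral_{t_i}^{tau} S(u) du]^2 * d_i / (n_i (n_i - d_i)).
    """
    t, s, d, n_risk = _km_curve(time, event, counts=True)
    keep = t < tau
    t, s, d, n_risk = t[keep], s[keep], d[keep], n_risk[keep]
    if len(t) == 0:
        return 0.0
    # tail areas: integral of S from each event time to tau
    edges = np.concatenate([t, [tau]])
    seg = s * np.diff(edges)                # area on [t_i, t_{i+1})
    tail = np.cumsum(seg[::-1])[::-1]
    denom = n_risk * (n_risk - d)
    ok = denom > 0
    return float(np.sum(tail[ok] ** 2 * d[ok] / denom[ok]))


def _arm_arrays(dataset: TrialDataset, arm: str):
    mask = dataset.arm_mask(arm)
    tab = dataset.table
    return (
        tab["time_observed"].to_numpy()[mask],
        tab["event"].to_numpy().astype(bool)[mask],
    )


# --------------------------------------------------------------------------
# estimators
# --------------------------------------------------------------------------

def kaplan_meier(dataset: TrialDataset, arm: str, alpha: float = 0.05) -> KMEstimate:
    """KM survival curve with Greenwood-based CI for one arm."""
    time, event = _arm_arrays(dataset, arm)
    if len(time) == 0:
        raise ValueError(f"no subjects in arm {arm!r}")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(time, event)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy()
    return KMEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(),
        ci_low=ci.iloc[:, 0].to_numpy(),
        ci_high=ci.iloc[:, 1].to_numpy(),
        n_at_risk=at_risk,
        censor_times=np.sort(time[~event]),
    )


def cox_hr(
    dataset: TrialDataset,
    covariates: tuple[str, ...] = (),
    ties: str = "efron",
) -> EffectEstimate:
    """Hazard ratio (treated vs placebo) from Cox regression with Wald CI.

    ``covariates`` names extra columns of the dataset table to adjust for.
    Monotone likelihoods (e.g. no events in one arm) yield a non-finite
    estimate flagged ``undefined`` rather than an exception.
    """
    tab = dataset.table
    treat = (tab["arm"] != "placebo").to_numpy(dtype=float)
    X = np.column_stack([treat] + [tab[c].to_numpy(dtype=float) for c in covariates])
    fit = cox_fit(X, tab["time_observed"].to_numpy(), tab["event"].to_numpy(), ties=ties)
    return _wald_estimate(fit, 0)


def _wald_estimate(fit: CoxFit, j: int) -> EffectEstimate:
    b = fit.beta[j]
    if not (fit.converged and np.isfinite(b)):
        return EffectEstimate(
            estimate=float(np.exp(b)) if np.isfinite(b) else math.nan,
            ci_low=math.nan, ci_high=math.nan, p_value=math.nan, undefined=True,
        )
    se = fit.se[j]
    z = norm.ppf(0.975)
    return EffectEstimate(
        estimate=float(np.exp(b)),
        ci_low=float(np.exp(b - z * se)),
        ci_high=float(np.exp(b + z * se)),
        p_value=float(fit.wald_p()[j]),
    )


def risk_ratio(dataset: TrialDataset) -> EffectEstimate:
    """Ratio of incidence proportions, treated vs placebo, with log-scale CI.

    SE(log RR) = sqrt(1/a - 1/n_T + 1/b - 1/n_P) where a, b are the event
    counts. Zero events in the placebo arm flags a non-finite estimate.
    """
    tp, ep = _arm_arrays(dataset, "placebo")
    tt, et = _arm_arrays(dataset, "treated")
    n_p, n_t = len(tp), len(tt)
    a, b = int(et.sum()), int(ep.sum())
    if b == 0 or a == 0:
        rr = math.inf if b == 0 and a > 0 else (math.nan if b == 0 else 0.0)
        return EffectEstimate(rr, math.nan, math.nan, undefined=True)
    rr = (a / n_t) / (b / n_p)
    se = math.sqrt(1 / a - 1 / n_t + 1 / b - 1 / n_p)
    z = norm.ppf(0.975)
    return EffectEstimate(
        estimate=rr,
        ci_low=rr * math.exp(-z * se),
        ci_high=rr * math.exp(z * se),
    )


def median_diff_bootstrap(
    dataset: TrialDataset, B: int = 1000, seed=0
) -> EffectEstimate:
    """Difference in median survival (treated - placebo), percentile bootstrap CI.

    Medians are read off the KM curve where it first drops to <= 0.5.
    Resampling is stratified by arm. The result is flagged ``undefined`` when
    either arm's KM curve never reaches 0.5 (the CI then summarises only the
    resamples where both medians exist).
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    rng = np.random.default_rng(seed)
    tp, ep = _arm_arrays(dataset, "placebo")
    tt, et = _arm_arrays(dataset, "treated")
    med_p, med_t = _km_median(tp, ep), _km_median(tt, et)
    diff = med_t - med_p
    undefined = not (math.isfinite(med_p) and math.isfinite(med_t))

    boots = np.empty(B)
    for i in range(B):
        ip = rng.integers(0, len(tp), len(tp))
        it = rng.integers(0, len(tt), len(tt))
        boots[i] = _km_median(tt[it], et[it]) - _km_median(tp[ip], ep[ip])
    finite = boots[np.isfinite(boots)]
    if len(finite) < max(2, B // 20):
        return EffectEstimate(diff if not undefined else math.nan,
                              math.nan, math.nan, undefined=True)
    lo, hi = np.percentile(finite, [2.5, 97.5])
    return EffectEstimate(diff, float(lo), float(hi), undefined=undefined)


def rmst_diff(
    dataset: TrialDataset,
    tau: float,
    method: str = "bootstrap",
    B: int = 1000,
    seed=0,
) -> EffectEstimate:
    """RMST difference at tau (treated - placebo) with a 95% CI.

    The point estimate is the area under each arm's KM curve up to tau.
    ``method`` is "bootstrap" (default; percentile over arm-stratified
    resamples) or "asymptotic" (Greenwood-plug-in variance via lifelines).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if tau > dataset.horizon_months + 1e-9:
        raise ValueError("tau must not exceed the follow-up horizon")
    tp, ep = _arm_arrays(dataset, "placebo")
    tt, et = _arm_arrays(dataset, "treated")
    diff = _km_rmst(tt, et, tau) - _km_rmst(tp, ep, tau)

    if method == "asymptotic":
        se = math.sqrt(_km_rmst_var(tt, et, tau) + _km_rmst_var(tp, ep, tau))
        z = norm.ppf(0.975)
        return EffectEstimate(diff, diff - z * se, diff + z * se)

    rng = np.random.default_rng(seed)
    boots = np.empty(B)
    for i in range(B):
        ip = rng.integers(0, len(tp), len(tp))
        it = rng.integers(0, len(tt), len(tt))
        boots[i] = _km_rmst(tt[it], et[it], tau) - _km_rmst(tp[ip], ep[ip], tau)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return EffectEstimate(diff, float(lo), float(hi))


def interaction_wald(
    dataset: TrialDataset,
    modifier_col: str = "modifier",
    ties: str = "efron",
) -> EffectEstimate:
    """Wald test of the treatment-by-modifier interaction in a Cox model.

    Fits hazard ~ treatment + modifier + treatment:modifier and returns the
    interaction term as a ratio (exp scale) with its Wald p-value. Empty
    arm-by-modifier cells (for a binary modifier) flag a non-estimable result.
    """
    tab = dataset.table
    treat = (tab["arm"] != "placebo").to_numpy(dtype=float)
    mod = tab[modifier_col].to_numpy(dtype=float)
    if np.any(~np.isfinite(mod)):
        raise ValueError(f"column {modifier_col!r} has missing values")
    levels = np.unique(mod)
    if len(levels) == 2:
        for tv in (0.0, 1.0):
            for lv in levels:
                if not np.any((treat == tv) & (mod == lv)):
                    return EffectEstimate(math.nan, math.nan, math.nan,
                                          p_value=math.nan, undefined=True)
    X = np.column_stack([treat, mod, treat * mod])
    fit = cox_fit(X, tab["time_observed"].to_numpy(), tab["event"].to_numpy(), ties=ties)
    return _wald_estimate(fit, 2)


def logrank_p(dataset: TrialDataset) -> float:
    """Two-sided log-rank p-value, treated vs placebo (lifelines)."""
    tp, ep = _arm_arrays(dataset, "placebo")
    tt, et = _arm_arrays(dataset, "treated")
    res = logrank_test(tp, tt, event_observed_A=ep, event_observed_B=et)
    return float(res.p_value)


def effect_summary(
    dataset: TrialDataset,
    tau: Optional[float] = None,
    B: int = 1000,
    seed=0,
) -> EffectSummary:
    """Compute the full Fig-2-style effect-measure suite for one dataset."""
    tau = dataset.horizon_months if tau is None else tau
    rng = np.random.default_rng(seed)
    return EffectSummary(
        hr=cox_hr(dataset),
        rr=risk_ratio(dataset),
        median_diff=median_diff_bootstrap(dataset, B=B, seed=rng),
        rmst_diff=rmst_diff(dataset, tau, B=B, seed=rng),
        rmst_tau=tau,
        p_logrank=logrank_p(dataset),
    )
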