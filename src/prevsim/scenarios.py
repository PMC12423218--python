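"""Hazard and heterogeneity scenarios for virtual prevention trials.

A :class:`HazardScenario` describes one "world" in which a trial is run: a
constant baseline hazard calibrated so the placebo group reaches a given
cumulative risk by the end of follow-up, a treatment-effect specification,
and an optional frailty layer modelling unobserved heterogeneity in
progression risk.

Four treatment-effect kinds are supported:

``constant``
    one hazard ratio for everybody (efficacy = (1 - HR) x 100);
``distributed``
    each treated subject draws an individual log HR = a + b*U with U standard
    normal; (a, b) are calibrated so the mean efficacy in the lower and upper
    tails of U match requested values;
``subgroup``
    a binary effect modifier splits participants into weak and strong
    responders with separate hazard ratios;
``time_varying``
    the HR follows a log-linear path from hr_start at t=0 to hr_end at
    end_time.

All rates are per month and all times in months.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .errors import CalibrationError

__all__ = [
    "ConstantEffect",
    "DistributedEffect",
    "SubgroupEffect",
    "TimeVaryingEffect",
    "FrailtySpec",
    "HazardScenario",
    "calibrate_constant_hazard",
    "calibrate_modifier_distribution",
    "hr_path",
    "sample_frailty",
    "draw_event_times",
    "tn10_like",
]


# --------------------------------------------------------------------------
# treatment-effect specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstantEffect:
    """Proportional-hazards effect shared by all treated subjects."""

    hr: float
    kind: str = field(default="constant", init=False, repr=False)

    def __post_init__(self) -> None:
        if not (self.hr > 0 and math.isfinite(self.hr)):
            raise ValueError(f"hr must be a positive finite number, got {self.hr}")

    @property
    def efficacy(self) -> float:
        """Efficacy on the percentage scale, (1 - HR) x 100."""
        return (1.0 - self.hr) * 100.0


@dataclass(frozen=True)
class DistributedEffect:
    """Continuously distributed individual effect, log HR_i = a + b * U_i.

    U_i is standard normal; larger modifier values mean stronger efficacy
    (b <= 0). ``eff_low``/``eff_high`` are the mean efficacies required in
    the lower/upper ``tail_prob`` tails of the modifier distribution.
    """

    eff_low: float
    eff_high: float
    tail_prob: float = 0.15
    kind: str = field(default="distributed", init=False, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.eff_low < 1.0 and 0.0 < self.eff_high < 1.0):
            raise ValueError("tail efficacies must lie in (0, 1)")
        if not (0.0 < self.tail_prob < 0.5):
            raise ValueError("tail_prob must lie in (0, 0.5)")
        if self.eff_low > self.eff_high:
            raise CalibrationError(
                "eff_low > eff_high contradicts the convention that larger "
                "modifier values mean stronger efficacy"
            )

    def loghr_params(self) -> tuple[float, float]:
        """(a, b) of the individual log-HR law; see calibrate_modifier_distribution."""
        return calibrate_modifier_distribution(self.eff_low, self.eff_high, self.tail_prob)

    @property
    def mean_efficacy(self) -> float:
        """Population-mean efficacy, 1 - E[exp(a + b U)] = 1 - exp(a + b^2/2)."""
        a, b = self.loghr_params()
        return 1.0 - math.exp(a + 0.5 * b * b)


@dataclass(frozen=True)
class SubgroupEffect:
    """Binary effect modifier: strong vs weak responders."""

    hr_strong: float
    hr_weak: float
    prevalence_strong: float = 0.5
    kind: str = field(default="subgroup", init=False, repr=False)

    def __post_init__(self) -> None:
        if not (self.hr_strong > 0 and self.hr_weak > 0):
            raise ValueError("subgroup hazard ratios must be positive")
        if not (0.0 < self.prevalence_strong < 1.0):
            raise ValueError("prevalence_strong must lie in (0, 1)")


@dataclass(frozen=True)
class TimeVaryingEffect:
    """HR following a log-linear path between (0, hr_start) and (end_time, hr_end)."""

    hr_start: float
    hr_end: float
    end_time: float
    kind: str = field(default="time_varying", init=False, repr=False)

    def __post_init__(self) -> None:
        if not (self.hr_start > 0 and self.hr_end > 0):
            raise ValueError("hazard ratios must be positive")
        if not self.end_time > 0:
            raise ValueError("end_time must be positive")


TreatmentEffect = Union[ConstantEffect, DistributedEffect, SubgroupEffect, TimeVaryingEffect]


@dataclass(frozen=True)
class FrailtySpec:
    """Multiplicative frailty on the individual hazard; mean fixed at 1.

    Gamma with variance ``variance`` is the default (and currently only)
    family; variance 0 degenerates to no heterogeneity.
    """

    variance: float = 1.0
    distribution: str = "gamma"

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("frailty variance must be non-negative")
        if self.distribution != "gamma":
            raise ValueError(f"unsupported frailty distribution {self.distribution!r}")


@dataclass(frozen=True)
class HazardScenario:
    """One virtual-trial world: baseline hazard, treatment effect, frailty."""

    horizon_months: float
    placebo_cum_risk: float
    effect: TreatmentEffect
    frailty: Optional[FrailtySpec] = None

    def __post_init__(self) -> None:
        if not self.horizon_months > 0:
            raise ValueError("horizon_months must be positive")
        if not (0.0 < self.placebo_cum_risk < 1.0):
            raise ValueError("placebo_cum_risk must lie in (0, 1)")

    @property
    def baseline_rate(self) -> float:
        """Constant baseline hazard (events/month) implied by the placebo risk."""
        return calibrate_constant_hazard(self.placebo_cum_risk, self.horizon_months)

    # -- YAML round-trip -----------------------------------------------------
    def to_dict(self) -> dict:
        eff = {"kind": self.effect.kind}
        for k, v in self.effect.__dict__.items():
            if k != "kind":
                eff[k] = v
        d = {
            "horizon_months": self.horizon_months,
            "placebo_cum_risk": self.placebo_cum_risk,
            "effect": eff,
        }
        if self.frailty is not None:
            d["frailty"] = {
                "variance": self.frailty.variance,
                "distribution": self.frailty.distribution,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HazardScenario":
        eff = dict(d["effect"])
        kind = eff.pop("kind")
        classes = {
            "constant": ConstantEffect,
            "distributed": DistributedEffect,
            "subgroup": SubgroupEffect,
            "time_varying": TimeVaryingEffect,
        }
        try:
            effect = classes[kind](**eff)
        except KeyError:
            raise ValueError(f"unknown effect kind {kind!r}") from None
        frailty = None
        if d.get("frailty") is not None:
            frailty = FrailtySpec(**d["frailty"])
        return cls(
            horizon_months=d["horizon_months"],
            placebo_cum_risk=d["placebo_cum_risk"],
            effect=effect,
            frailty=frailty,
        )


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

def calibrate_constant_hazard(p: float, T: float) -> float:
    """Constant hazard rate giving cumulative risk ``p`` by time ``T``.

    Solves 1 - exp(-lam * T) = p, i.e. lam = -ln(1 - p) / T.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"cumulative risk must lie in (0, 1), got {p}")
    if not T > 0:
        raise ValueError(f"horizon must be positive, got {T}")
    return -math.log1p(-p) / T


def hr_path(spec: TimeVaryingEffect, t) -> np.ndarray | float:
    """HR(t) under a time-varying effect: log-linear between the two anchors.

    Beyond ``end_time`` the HR is held at ``hr_end``. ``t`` may be scalar or
    array; negative times raise.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    frac = np.clip(t_arr / spec.end_time, 0.0, 1.0)
    log_hr = (1.0 - frac) * math.log(spec.hr_start) + frac * math.log(spec.hr_end)
    out = np.exp(log_hr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def calibrate_modifier_distribution(
    eff_low: float, eff_high: float, tail: float
) -> tuple[float, float]:
    """Calibrate the individual log-HR law log HR_i = a + b * U_i.

    With U standard normal and cutpoint z_c = Phi^{-1}(tail), the truncated
    lognormal means give closed forms for the tail constraints::

        E[HR | U in lower tail] = exp(a + b^2/2) * Phi(z_c - b) / tail
        E[HR | U in upper tail] = exp(a + b^2/2) * Phi(z_c + b) / tail

    so b solves Phi(z_c - b)/Phi(z_c + b) = (1 - eff_low)/(1 - eff_high)
    (a one-dimensional root, monotone in b on b <= 0), and a follows.
    Returns (a, b) with b <= 0: larger modifier values mean stronger efficacy.
    """
    if not (0.0 < eff_low < 1.0 and 0.0 < eff_high < 1.0):
        raise CalibrationError("tail efficacies must lie in (0, 1)")
    if not (0.0 < tail < 0.5):
        raise CalibrationError("tail probability must lie in (0, 0.5)")
    if eff_low > eff_high:
        raise CalibrationError("eff_low must not exceed eff_high")
    if math.isclose(eff_low, eff_high):
        return math.log(1.0 - eff_low), 0.0

    zc = norm.ppf(tail)
    target = (1.0 - eff_low) / (1.0 - eff_high)  # > 1

    def ratio_minus_target(b: float) -> float:
        return norm.cdf(zc - b) / norm.cdf(zc + b) - target

    # ratio is 1 at b=0 and increases without bound as b -> -inf
    lo, hi = -1.0, 0.0
    while ratio_minus_target(lo) < 0:
        lo *= 2.0
        if lo < -60:
            raise CalibrationError("no solution for the modifier distribution")
    b = optimize.brentq(ratio_minus_target, lo, hi, xtol=1e-12, rtol=1e-14)
    a = math.log((1.0 - eff_low) * tail / norm.cdf(zc - b)) - 0.5 * b * b

    # verify both constraints to solver tolerance
    for cut_eff, cdf_arg in ((eff_low, zc - b), (eff_high, zc + b)):
        achieved = 1.0 - math.exp(a + 0.5 * b * b) * norm.cdf(cdf_arg) / tail
        if abs(achieved - cut_eff) > 1e-6:
            raise CalibrationError("modifier calibration failed to converge")
    return a, b


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_frailty(spec: FrailtySpec, n: int, seed) -> np.ndarray:
    """Draw ``n`` positive frailties with mean 1 and variance ``spec.variance``."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = _as_rng(seed)
    if spec.variance == 0:
        return np.ones(n)
    shape = 1.0 / spec.variance
    return rng.gamma(shape=shape, scale=spec.variance, size=n)


def draw_event_times(
    rate: float,
    multipliers,
    seed,
    effect: Optional[TimeVaryingEffect] = None,
    grid_step: float = 1.0,
) -> np.ndarray:
    """Draw latent event times by inverting each subject's cumulative hazard.

    ``multipliers`` is the time-constant part of each subject's hazard
    multiplier (frailty x exp of constant log-HR terms). With no
    time-varying effect the hazard is constant and times are exponential
    with rate ``rate * multiplier``. With a :class:`TimeVaryingEffect`, the
    cumulative hazard is accumulated on a piecewise-exponential grid of
    width ``grid_step`` months (hazard taken at interval midpoints) up to
    ``end_time`` and extended at the constant rate ``rate * hr_end`` beyond;
    draws invert that cumulative hazard exactly on the grid.
    """
    mult = np.asarray(multipliers, dtype=float)
    if not np.all(np.isfinite(mult)) or np.any(mult <= 0):
        raise ValueError("hazard multipliers must be positive and finite")
    rng = _as_rng(seed)
    exp_draw = rng.exponential(1.0, size=mult.shape)
    if effect is None:
        return exp_draw / (rate * mult)

    # piecewise-exponential inversion on the grid
    edges = np.arange(0.0, effect.end_time + grid_step, grid_step)
    edges[-1] = min(edges[-1], effect.end_time)
    if edges[-1] < effect.end_time:
        edges = np.append(edges, effect.end_time)
    mids = 0.5 * (edges[:-1] + edges[1:])
    haz = rate * np.asarray(hr_path(effect, mids))  # hazard per unit multiplier
    widths = np.diff(edges)
    cumhaz = np.concatenate([[0.0], np.cumsum(haz * widths)])  # at edges

    target = exp_draw / mult  # required cumulative hazard per unit multiplier
    idx = np.searchsorted(cumhaz, target, side="right") - 1
    inside = idx < len(haz)
    times = np.empty_like(target)
    i_in = idx[inside]
    times[inside] = edges[i_in] + (target[inside] - cumhaz[i_in]) / haz[i_in]
    tail_rate = rate * effect.hr_end
    times[~inside] = edges[-1] + (target[~inside] - cumhaz[-1]) / tail_rate
    return times


# --------------------------------------------------------------------------
# canonical TN10-like scenario worlds
# --------------------------------------------------------------------------

def tn10_like(variant: str = "a", frailty_variance: float = 1.0) -> HazardScenario:
    """The four TN10-imitating scenario worlds used throughout.

    ``a``: homogeneous risk and effect (HR 0.5);
    ``b``: gamma frailty on risk, same HR for everyone;
    ``c``: frailty plus a continuously distributed effect (mean 33% efficacy
    in the lowest 15% of the modifier distribution, 74% in the upper 15%);
    ``d``: homogeneous, but the HR weakens log-linearly from 0.15 at t=0 to
    0.7 at 84 months.

    Horizon 84 months with 90% placebo cumulative risk (placebo median time
    to progression about 25 months, in the range observed for stage 2
    disease); these anchors are package defaults, configurable via
    :class:`HazardScenario` directly.
    """
    base = dict(horizon_months=84.0, placebo_cum_risk=0.9)
    if variant == "a":
        return HazardScenario(effect=ConstantEffect(0.5), **base)
    if variant == "b":
        return HazardScenario(
            effect=ConstantEffect(0.5), frailty=FrailtySpec(frailty_variance), **base
        )
    if variant == "c":
        return HazardScenario(
            effect=DistributedEffect(0.33, 0.74, 0.15),
            frailty=FrailtySpec(frailty_variance),
            **base,
        )
    if variant == "d":
        return HazardScenario(
            effect=TimeVaryingEffect(hr_start=0.15, hr_end=0.7, end_time=84.0), **base
        )
    raise ValueError(f"unknown scenario variant {variant!r}")
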