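"""Per-subject trial dataset generation under a design and a hazard scenario.

Two-arm trials draw a latent event time for every subject from the scenario's
hazard (frailty and any individual effect applied multiplicatively), then a
censoring time from the design, and record the observed follow-up. A 2x2
factorial generator allocates 1:1:1:1 to placebo / A / B / A+B with hazard
multipliers given by summed log hazard ratios (an interaction term of 0 means
exact additivity on the log-HR scale).

The array-level generators (`simulate_trial_arrays`, `simulate_factorial_arrays`)
are the single source of randomness; the DataFrame wrappers build on them, so
the Monte-Carlo power engine and user-facing datasets share one code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .scenarios import (
    ConstantEffect,
    DistributedEffect,
    HazardScenario,
    SubgroupEffect,
    TimeVaryingEffect,
    draw_event_times,
    sample_frailty,
)

__all__ = [
    "CensoringSpec",
    "TrialDesign",
    "FactorialEffects",
    "TrialDataset",
    "simulate_trial",
    "simulate_trial_arrays",
    "simulate_factorial",
    "simulate_factorial_arrays",
    "two_arm_design",
    "factorial_design",
]

TWO_ARM_LABELS = ("placebo", "treated")
FACTORIAL_LABELS = ("placebo", "A", "B", "AB")


@dataclass(frozen=True)
class CensoringSpec:
    """Censoring mechanism on top of administrative censoring at the horizon.

    ``none_until_horizon``: administrative censoring only (complete
    compliance, no loss to follow-up). ``uniform_window``: each subject's
    censoring time is uniform on ``window`` (months), independent of arm,
    emulating staggered follow-up duration.
    """

    kind: str = "none_until_horizon"
    window: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("none_until_horizon", "uniform_window"):
            raise ValueError(f"unknown censoring kind {self.kind!r}")
        if self.kind == "uniform_window":
            if self.window is None or not (0 <= self.window[0] < self.window[1]):
                raise ValueError("uniform_window requires window=(min, max) with min < max")


@dataclass(frozen=True)
class TrialDesign:
    """Arms, allocation and follow-up for one trial."""

    n_total: int
    allocation: tuple = (1, 1)
    horizon_months: float = 84.0
    censoring: CensoringSpec = field(default_factory=CensoringSpec)

    def __post_init__(self) -> None:
        if self.n_total < len(self.allocation):
            raise ConfigurationError("n_total smaller than the number of arms")
        if any(w <= 0 for w in self.allocation):
            raise ValueError("allocation weights must be positive")
        if len(self.allocation) not in (2, 4):
            raise ConfigurationError("only two-arm and 2x2 factorial designs are supported")
        if not self.horizon_months > 0:
            raise ValueError("horizon_months must be positive")

    @property
    def arm_labels(self) -> tuple[str, ...]:
        return TWO_ARM_LABELS if len(self.allocation) == 2 else FACTORIAL_LABELS

    def arm_sizes(self) -> np.ndarray:
        """Deterministic arm sizes: floor shares, remainder to the first arms."""
        w = np.asarray(self.allocation, dtype=float)
        w = w / w.sum()
        sizes = np.floor(self.n_total * w).astype(int)
        for i in range(self.n_total - sizes.sum()):
            sizes[i % len(sizes)] += 1
        if np.any(sizes == 0):
            raise ConfigurationError("allocation rounding produced an empty arm")
        return sizes


@dataclass(frozen=True)
class FactorialEffects:
    """Log hazard ratios of a 2x2 factorial trial; interaction 0 = additivity."""

    log_hr_a: float
    log_hr_b: float
    log_hr_interaction: float = 0.0

    def arm_multipliers(self) -> dict[str, float]:
        """Hazard multiplier per arm; combined arm = exp of the summed log effects."""
        return {
            "placebo": 1.0,
            "A": math.exp(self.log_hr_a),
            "B": math.exp(self.log_hr_b),
            "AB": math.exp(self.log_hr_a + self.log_hr_b + self.log_hr_interaction),
        }


@dataclass
class TrialDataset:
    """Per-subject trial data; ``table`` has one row per subject.

    Columns: id, arm, modifier, frailty, time_latent, time_censor,
    time_observed, event. ``modifier``/``frailty`` are NaN when the scenario
    has no such layer.
    """

    table: pd.DataFrame
    design: TrialDesign
    horizon_months: float

    def arm_mask(self, arm: str) -> np.ndarray:
        return (self.table["arm"] == arm).to_numpy()

    def to_csv(self, path, **kwargs) -> None:
        self.table.to_csv(path, index=False, **kwargs)


# --------------------------------------------------------------------------
# internals shared by both generators
# --------------------------------------------------------------------------

def _censoring_times(design: TrialDesign, n: int, rng: np.random.Generator) -> np.ndarray:
    cs = design.censoring
    if cs.kind == "none_until_horizon":
        return np.full(n, design.horizon_months)
    lo, hi = cs.window
    return np.minimum(rng.uniform(lo, hi, size=n), design.horizon_months)


def _observe(latent: np.ndarray, censor: np.ndarray, horizon: float):
    cens = np.minimum(censor, horizon)
    observed = np.minimum(latent, cens)
    event = latent <= cens
    return observed, event


def simulate_trial_arrays(design: TrialDesign, scenario: HazardScenario, seed) -> dict:
    """Two-arm generator returning raw numpy arrays (no DataFrame overhead)."""
    if len(design.allocation) != 2:
        raise ConfigurationError("simulate_trial requires a two-arm design")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = design.arm_sizes()
    n = int(sizes.sum())
    arm = np.repeat(np.arange(2), sizes)  # 0 placebo, 1 treated
    rate = scenario.baseline_rate

    frailty = np.full(n, np.nan)
    mult = np.ones(n)
    if scenario.frailty is not None:
        frailty = sample_frailty(scenario.frailty, n, rng)
        mult = frailty.copy()

    modifier = np.full(n, np.nan)
    effect = scenario.effect
    treated = arm == 1
    tv_effect = None
    if isinstance(effect, ConstantEffect):
        mult[treated] *= effect.hr
    elif isinstance(effect, DistributedEffect):
        a, b = effect.loghr_params()
        modifier = rng.standard_normal(n)
        mult[treated] *= np.exp(a + b * modifier[treated])
    elif isinstance(effect, SubgroupEffect):
        # exact responder fraction within each arm: the subgroup composition
        # is part of the stated scenario, not an extra source of noise
        modifier = np.empty(n)
        for a in (0, 1):
            idx = np.flatnonzero(arm == a)
            n_strong = int(round(effect.prevalence_strong * len(idx)))
            lab = np.zeros(len(idx))
            lab[:n_strong] = 1.0
            modifier[idx] = rng.permutation(lab)
        hrs = np.where(modifier[treated] == 1.0, effect.hr_strong, effect.hr_weak)
        mult[treated] *= hrs
    elif isinstance(effect, TimeVaryingEffect):
        tv_effect = effect
    else:  # pragma: no cover - guarded by the scenario type
        raise ConfigurationError(f"unsupported effect kind {effect!r}")

    latent = np.empty(n)
    if tv_effect is None:
        latent = draw_event_times(rate, mult, rng)
    else:
        # placebo subjects follow the baseline hazard; treated follow the HR path
        latent[~treated] = draw_event_times(rate, mult[~treated], rng)
        latent[treated] = draw_event_times(rate, mult[treated], rng, effect=tv_effect)

    censor = _censoring_times(design, n, rng)
    observed, event = _observe(latent, censor, design.horizon_months)
    return {
        "arm": arm,
        "modifier": modifier,
        "frailty": frailty,
        "time_latent": latent,
        "time_censor": censor,
        "time_observed": observed,
        "event": event,
    }


def simulate_trial(design: TrialDesign, scenario: HazardScenario, seed) -> TrialDataset:
    """Simulate one two-arm trial; see the module docstring for the model."""
    arrays = simulate_trial_arrays(design, scenario, seed)
    return _to_dataset(arrays, design, TWO_ARM_LABELS)


def simulate_factorial_arrays(
    design: TrialDesign,
    scenario: HazardScenario,
    effects: FactorialEffects,
    seed,
) -> dict:
    """Four-arm (2x2 factorial) generator returning raw arrays.

    The scenario supplies the baseline hazard and optional frailty; arm
    effects come from ``effects`` (the scenario's own effect spec is ignored
    here, the factorial effects being the arm contrast of interest).
    """
    if len(design.allocation) != 4:
        raise ConfigurationError("simulate_factorial requires a four-arm design")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = design.arm_sizes()
    n = int(sizes.sum())
    arm = np.repeat(np.arange(4), sizes)
    rate = scenario.baseline_rate

    frailty = np.full(n, np.nan)
    mult = np.ones(n)
    if scenario.frailty is not None:
        frailty = sample_frailty(scenario.frailty, n, rng)
        mult = frailty.copy()

    arm_mult = effects.arm_multipliers()
    mult *= np.array([arm_mult[lab] for lab in FACTORIAL_LABELS])[arm]

    latent = draw_event_times(rate, mult, rng)
    censor = _censoring_times(design, n, rng)
    observed, event = _observe(latent, censor, design.horizon_months)
    return {
        "arm": arm,
        "modifier": np.full(n, np.nan),
        "frailty": frailty,
        "time_latent": latent,
        "time_censor": censor,
        "time_observed": observed,
        "event": event,
    }


def simulate_factorial(
    design: TrialDesign,
    scenario: HazardScenario,
    effects: FactorialEffects,
    seed,
) -> TrialDataset:
    arrays = simulate_factorial_arrays(design, scenario, effects, seed)
    return _to_dataset(arrays, design, FACTORIAL_LABELS)


def _to_dataset(arrays: dict, design: TrialDesign, labels: Sequence[str]) -> TrialDataset:
    n = len(arrays["arm"])
    table = pd.DataFrame(
        {
            "id": np.arange(n),
            "arm": pd.Categorical.from_codes(arrays["arm"], categories=list(labels)),
            "modifier": arrays["modifier"],
            "frailty": arrays["frailty"],
            "time_latent": arrays["time_latent"],
            "time_censor": arrays["time_censor"],
            "time_observed": arrays["time_observed"],
            "event": arrays["event"].astype(int),
        }
    )
    return TrialDataset(table=table, design=design, horizon_months=design.horizon_months)


# --------------------------------------------------------------------------
# convenience constructors
# --------------------------------------------------------------------------

def two_arm_design(
    n_total: int,
    horizon_months: float = 84.0,
    censoring: Optional[CensoringSpec] = None,
) -> TrialDesign:
    return TrialDesign(
        n_total=n_total,
        allocation=(1, 1),
        horizon_months=horizon_months,
        censoring=censoring or CensoringSpec(),
    )


def factorial_design(
    n_total: int,
    horizon_months: float = 84.0,
    censoring: Optional[CensoringSpec] = None,
) -> TrialDesign:
    return TrialDesign(
        n_total=n_total,
        allocation=(1, 1, 1, 1),
        horizon_months=horizon_months,
        censoring=censoring or CensoringSpec(),
    )
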