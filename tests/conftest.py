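import numpy as np
import pandas as pd
import pytest

from prevsim.trial_sim import CensoringSpec, TrialDataset, TrialDesign


def dataset_from_arrays(time, event, arm, horizon=84.0, modifier=None, frailty=None):
    """Build a TrialDataset directly from arrays (for hand-crafted examples)."""
    time = np.asarray(time, dtype=float)
    n = len(time)
    arm = np.asarray(arm)
    if arm.dtype.kind in "iub":
        labels = np.where(np.asarray(arm).astype(bool), "treated", "placebo")
    else:
        labels = arm
    table = pd.DataFrame(
        {
            "id": np.arange(n),
            "arm": pd.Categorical(labels, categories=["placebo", "treated"]),
            "modifier": np.full(n, np.nan) if modifier is None else np.asarray(modifier, float),
            "frailty": np.full(n, np.nan) if frailty is None else np.asarray(frailty, float),
            "time_latent": time,
            "time_censor": np.full(n, horizon),
            "time_observed": time,
            "event": np.asarray(event, dtype=int),
        }
    )
    design = TrialDesign(n_total=max(n, 2), allocation=(1, 1), horizon_months=horizon,
                         censoring=CensoringSpec())
    return TrialDataset(table=table, design=design, horizon_months=horizon)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def two_arm_exponential(rate_p, rate_t, n_per_arm, horizon, seed):
    """Exponential arms with administrative censoring at the horizon."""
    gen = np.random.default_rng(seed)
    tp = gen.exponential(1.0 / rate_p, n_per_arm)
    tt = gen.exponential(1.0 / rate_t, n_per_arm)
    time = np.concatenate([tp, tt])
    arm = np.concatenate([np.zeros(n_per_arm, int), np.ones(n_per_arm, int)])
    event = time <= horizon
    return dataset_from_arrays(np.minimum(time, horizon), event, arm, horizon=horizon)
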