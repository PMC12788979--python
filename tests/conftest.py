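import numpy as np
import pandas as pd
import pytest


def exponential_arms(n_per_arm, lam_treated, lam_control, cens_scale=None,
                     horizon=np.inf, seed=0):
    """Two-arm exponential trial as a TrialTable-style DataFrame."""
    rng = np.random.default_rng(seed)
    arm = np.repeat([1, 0], n_per_arm)
    lam = np.where(arm == 1, lam_treated, lam_control)
    t = rng.exponential(1.0 / lam)
    c = np.full(arm.size, horizon)
    if cens_scale is not None:
        c = np.minimum(c, rng.exponential(cens_scale, arm.size))
    return pd.DataFrame({
        "patient_id": np.arange(1, arm.size + 1),
        "arm": arm,
        "os_time": np.minimum(t, c),
        "os_event": (t <= c).astype(int),
    })


def exponential_rmst(lam, tau):
    return (1.0 - np.exp(-lam * tau)) / lam


@pytest.fixture
def tiny_sample():
    """Six subjects with mixed censoring, small enough for hand computation."""
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    event = np.array([1, 0, 1, 1, 0, 1])
    return time, event
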