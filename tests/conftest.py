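import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

import dcecurve as dc

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cohort():
    """Default 97-specimen synthetic cohort (fixed seed, shared read-only)."""
    curves, records, truth = dc.generate_cohort(seed=1)
    return curves, records, truth


@pytest.fixture(scope="session")
def full_feature_table(cohort):
    """Descriptors at native resolution and full length."""
    curves, records, _ = cohort
    return dc.build_feature_table(curves, records)


def make_step_curve(specimen_id="s1", s0=100.0, jump_at=32.0, high=200.0,
                    dt=1.6, n=513):
    """Noiseless baseline-then-step curve for onset tests."""
    t = np.arange(1, n + 1) * dt
    s = np.where(t < jump_at, s0, high)
    return dc.SignalIntensityCurve(specimen_id, t, s)


def make_piecewise_curve(specimen_id="s1", s0=100.0, t0=32.0, tp=52.0,
                         sm=200.0, sfinal=160.0, tmax=150.0, dt=2.0):
    """Noiseless rise-then-fall curve whose extracted anchors are exact.

    The rise is anchored one sample before ``t0`` so the sample at ``t0``
    already sits above the onset threshold: detection then returns exactly
    (t0, s0), and the peak/final anchors give the descriptor formulas in
    closed form.
    """
    n = int(round(tmax / dt))
    t = np.arange(1, n + 1) * dt
    rise = s0 + (sm - s0) * (t - (t0 - dt)) / (tp - (t0 - dt))
    fall = sm + (sfinal - sm) * (t - tp) / (tmax - tp)
    s = np.where(t <= t0 - dt, s0, np.where(t <= tp, rise, fall))
    return dc.SignalIntensityCurve(specimen_id, t, s)
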