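import numpy as np
import pytest

from rmmeff import (ConcentrationTrace, NoiseModel, TransferEvent,
                    simulate_preset)

#: measurement-scatter-only noise model (no movement spikes), used where a
#: test checks recovery of the decay parameters under instrument noise
MULT_ONLY = NoiseModel(multiplicative_sd=0.05, spike_rate_per_min=0.0, seed=0)


@pytest.fixture
def baseline_noiseless():
    """Noiseless gravity-transfer baseline trace (true EEC 454 ppm, ach 1/h)."""
    return simulate_preset(1)


@pytest.fixture
def exp_trace():
    """Factory for exact synthetic exponential-decay traces.

    Concentration is ``background + eec * exp(-k (t - t_end) / 60)`` after
    the event and a constant plateau before it, sampled every 20 s with a
    quiet 240 s pre-event window at the background level.
    """

    def make(eec=100.0, ach=11.0, background=0.0, target_ach=None,
             t_start=240.0, t_end=480.0, duration=2400.0, dt=20.0):
        t = np.arange(0.0, duration + dt / 2, dt)
        k = ach / 60.0
        c = np.full_like(t, float(background))
        rise = (t >= t_start) & (t < t_end)
        c[rise] = background + eec  # plateau stands in for the rise phase
        post = t >= t_end
        c[post] = background + eec * np.exp(-k * (t[post] - t_end) / 60.0)
        return ConcentrationTrace(
            t, c, TransferEvent(t_start, t_end),
            target_ach=target_ach if target_ach is not None else ach,
            trace_kind="transfer", scenario_id=99, replicate=1)

    return make
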