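import numpy as np
import pytest

from durakit.synth_electrode import CircuitParams, PulseTrain


@pytest.fixture
def rc_circuit() -> CircuitParams:
    """A fast-settling ideal-capacitor Randles cell (tau = 0.1 ms)."""
    rct = 15e3
    tau = 0.1e-3
    return CircuitParams(solution_resistance=5e3,
                         charge_transfer_resistance=rct,
                         interface_capacitance=tau / rct,
                         cpe_exponent=1.0)


@pytest.fixture
def slow_circuit() -> CircuitParams:
    """A slower cell (tau = 0.3 ms) whose edge steps are nearly pure-Ohmic.

    With tau well above the sampling interval the interface barely moves
    within the one-sample guard around an edge, so the measured step is the
    access voltage to well under 2%.
    """
    rct = 20e3
    tau = 0.3e-3
    return CircuitParams(solution_resistance=10e3,
                         charge_transfer_resistance=rct,
                         interface_capacitance=tau / rct,
                         cpe_exponent=1.0)


@pytest.fixture
def burst_train() -> PulseTrain:
    """The in-vitro stimulation protocol: 5 biphasic pulses, 0.6 ms / 200 us."""
    return PulseTrain(amplitude=50e-6)


def rc_burst_extrema(params: CircuitParams, train: PulseTrain
                     ) -> tuple[float, float]:
    """Closed-form piecewise-exponential oracle for the interface extremes.

    Walks the burst segment by segment, applying the exact constant-current
    RC update v_end = i*Rct + (v0 - i*Rct) * exp(-d/tau).  The interface
    voltage is monotone within each segment, so the burst extrema occur at
    segment boundaries.  Independent of the sampled simulator and of the
    transient-isolation pipeline.
    """
    rct = params.charge_transfer_resistance
    tau = rct * params.interface_capacitance
    pw, gap = train.cathodic_pulse_width, train.interphase_gap
    rest = 1.0 / train.pulse_frequency - (2 * pw + gap)
    sign = -1.0 if train.cathodic_first else 1.0
    segments = [(pw, sign * train.amplitude), (gap, 0.0),
                (pw, -sign * train.amplitude), (rest, 0.0)] \
        * train.pulses_per_burst
    v = 0.0
    lo = hi = 0.0
    for duration, current in segments:
        v = current * rct + (v - current * rct) * np.exp(-duration / tau)
        lo, hi = min(lo, v), max(hi, v)
    return lo, hi
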