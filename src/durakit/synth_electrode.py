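"""Equivalent-circuit electrode simulator.

Generates impedance spectra and stimulation voltage transients with known
ground truth, standing in for a three-electrode electrochemical cell
(working electrode on the array, large counter electrode, Ag/AgCl
reference).  The electrode-electrolyte interface is modelled as a Randles
cell: solution (access) resistance ``Rs`` in series with a charge-transfer
resistance ``Rct`` in parallel with a constant-phase element (CPE)

    Z_cpe(w) = 1 / (Q * (j*w)**alpha),   0 < alpha <= 1,

where ``alpha = 1`` recovers an ideal double-layer capacitor of value
``Q`` farads.  The Randles form is an implementation choice for the
synthetic cell, not a measured claim about any particular electrode
material.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CircuitParams",
    "PulseTrain",
    "VoltageTransient",
    "simulate_eis",
    "simulate_transient",
    "write_transient_csv",
    "read_transient_csv",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CircuitParams:
    """Randles-cell parameters of a synthetic electrode.

    Parameters
    ----------
    solution_resistance : float
        Access/electrolyte resistance Rs in ohms.
    charge_transfer_resistance : float
        Faradaic charge-transfer resistance Rct in ohms.
    interface_capacitance : float
        Double-layer / pseudo-capacitance in farads.  For ``cpe_exponent``
        below 1 this is the CPE magnitude Q in F·s^(alpha-1).
    cpe_exponent : float
        CPE exponent alpha in (0, 1]; 1 is an ideal capacitor.
    """

    solution_resistance: float
    charge_transfer_resistance: float
    interface_capacitance: float
    cpe_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.solution_resistance <= 0:
            raise ValueError("solution_resistance must be > 0")
        if self.charge_transfer_resistance <= 0:
            raise ValueError("charge_transfer_resistance must be > 0")
        if self.interface_capacitance <= 0:
            raise ValueError("interface_capacitance must be > 0")
        if not 0 < self.cpe_exponent <= 1:
            raise ValueError("cpe_exponent must be in (0, 1]")


@dataclass(frozen=True)
class PulseTrain:
    """Charge-balanced biphasic current-pulse burst descriptor.

    The default protocol is a burst of 5 biphasic charge-balanced pulses
    with a 0.6 ms pulse width and a 200 us interphase gap, cathodic phase
    first.  Each phase carries equal and opposite charge so the per-pulse
    net charge is zero.
    """

    amplitude: float                 # A, phase current magnitude (I_A)
    cathodic_pulse_width: float = 0.6e-3   # s (pw_c); anodic width equal
    interphase_gap: float = 200e-6   # s
    pulses_per_burst: int = 5
    pulse_frequency: float = 500.0   # Hz, within-burst pulse rate
    burst_frequency: float = 1.0     # Hz
    cathodic_first: bool = True
    sample_rate: float = 1e6         # Hz; 1 MHz keeps 0.6 ms edges single-sample

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0 (0 is a null-stimulus probe)")
        if self.cathodic_pulse_width <= 0 or self.interphase_gap <= 0:
            raise ValueError("pulse width and interphase gap must be > 0")
        if self.pulses_per_burst < 1:
            raise ValueError("pulses_per_burst must be >= 1")
        period = 1.0 / self.pulse_frequency
        if period < 2 * self.cathodic_pulse_width + self.interphase_gap:
            raise ValueError("pulse period shorter than the biphasic pulse itself")

    @property
    def pulse_duration(self) -> float:
        """Duration of one biphasic pulse (two phases + gap), seconds."""
        return 2 * self.cathodic_pulse_width + self.interphase_gap

    def current_waveform(self, n_pre: int, n_post: int) -> np.ndarray:
        """Sampled current of one burst with quiet padding (amperes).

        ``n_pre``/``n_post`` are numbers of zero-current samples before the
        first pulse and after the last.
        """
        fs = self.sample_rate
        period = int(round(fs / self.pulse_frequency))
        n_pw = int(round(self.cathodic_pulse_width * fs))
        n_gap = int(round(self.interphase_gap * fs))
        sign = -1.0 if self.cathodic_first else 1.0
        pulse = np.zeros(period)
        pulse[:n_pw] = sign * self.amplitude
        pulse[n_pw + n_gap:n_pw + n_gap + n_pw] = -sign * self.amplitude
        i = np.concatenate([
            np.zeros(n_pre),
            np.tile(pulse, self.pulses_per_burst),
            np.zeros(n_post),
        ])
        return i


@dataclass
class VoltageTransient:
    """Sampled reference-electrode voltage in response to a pulse burst."""

    time: np.ndarray        # s, uniform grid
    voltage: np.ndarray     # V
    pulse_train: PulseTrain
    circuit_truth: CircuitParams | None = None
    current: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.time.shape != self.voltage.shape:
            raise ValueError("time and voltage must have equal length")
        dt = np.diff(self.time)
        if len(dt) and (dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("time must be strictly increasing and uniform")

    @property
    def sample_rate(self) -> float:
        return self.pulse_train.sample_rate


# --------------------------------------------------------------------------
# impedance spectra
# --------------------------------------------------------------------------

def circuit_impedance(params: CircuitParams, frequencies: np.ndarray) -> np.ndarray:
    """Complex impedance Rs + Rct || Z_cpe at each frequency (Hz)."""
    f = np.asarray(frequencies, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be > 0")
    w = 2 * np.pi * f
    q = params.interface_capacitance
    a = params.cpe_exponent
    rct = params.charge_transfer_resistance
    # Rct || (1/(Q (jw)^a)) = Rct / (1 + Rct Q (jw)^a)
    return params.solution_resistance + rct / (1.0 + rct * q * (1j * w) ** a)


def simulate_eis(params: CircuitParams, frequencies) -> "ImpedanceSpectrum":
    """Synthesize an impedance spectrum for a Randles cell.

    Returns an :class:`~durakit.eis.ImpedanceSpectrum` with magnitude in
    ohms and phase in degrees.  |Z| tends to Rs at high frequency and to
    Rs + Rct at DC.
    """
    from .eis import ImpedanceSpectrum  # local import to avoid a cycle

    z = circuit_impedance(params, np.asarray(frequencies, dtype=float))
    return ImpedanceSpectrum(
        electrode_id="synthetic",
        frequency=np.asarray(frequencies, dtype=float),
        magnitude=np.abs(z),
        phase=np.degrees(np.angle(z)),
    )


# --------------------------------------------------------------------------
# voltage transients
# --------------------------------------------------------------------------

def _foster_fit(params: CircuitParams, f_lo: float, f_hi: float,
                n_elements: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Fit the interface branch Rct || CPE with a series Foster RC ladder.

    Returns (R_k, tau_k) such that sum_k R_k/(1 + j w tau_k) approximates
    Rct/(1 + Rct Q (jw)^alpha) over [f_lo, f_hi].  Non-negative least
    squares on stacked real and imaginary parts at log-spaced frequencies.
    """
    from scipy.optimize import nnls

    taus = 1.0 / (2 * np.pi * np.logspace(np.log10(f_lo), np.log10(f_hi), n_elements))
    f = np.logspace(np.log10(f_lo / 3), np.log10(f_hi * 3), 60)
    w = 2 * np.pi * f
    rct = params.charge_transfer_resistance
    q = params.interface_capacitance
    target = rct / (1.0 + rct * q * (1j * w) ** params.cpe_exponent)
    basis = 1.0 / (1.0 + 1j * np.outer(w, taus))          # (n_f, n_el)
    # weight by 1/|Z| so the fit minimizes relative, not absolute, error
    wgt = (1.0 / np.abs(target))[:, None]
    a = np.vstack([basis.real * wgt, basis.imag * wgt])
    b = np.concatenate([target.real / np.abs(target),
                        target.imag / np.abs(target)])
    r, _ = nnls(a, b)
    keep = r > 0
    return r[keep], taus[keep]


def simulate_transient(params: CircuitParams, train: PulseTrain,
                       polarization_offset: float = 0.0,
                       pre_time: float = 5e-3, post_time: float = 10e-3,
                       noise_sd: float = 0.0,
                       seed: int | None = None) -> VoltageTransient:
    """Simulate the reference-electrode voltage for one pulse burst.

    The recorded voltage is

        v(t) = polarization_offset + i(t) * Rs + v_interface(t)

    where the interface term is the voltage across Rct || CPE driven by the
    stimulation current.  For ``alpha = 1`` each constant-current segment is
    integrated exactly with the RC exponential update; for ``alpha < 1`` the
    interface branch is replaced by a 5-element Foster RC ladder fitted to
    its spectrum over the stimulation band.

    Parameters
    ----------
    polarization_offset : float
        Pre-existing electrode polarization (Eipp surrogate), volts.
    noise_sd : float
        Optional additive Gaussian measurement noise SD in volts
        (default 0, i.e. off); ``seed`` makes it reproducible.
    """
    fs = train.sample_rate
    if fs < 20.0 / train.cathodic_pulse_width:
        raise ValueError(
            "sample_rate must be at least 20 / pulse_width to resolve edges")
    n_pre = int(round(pre_time * fs))
    n_post = int(round(post_time * fs))
    i = train.current_waveform(n_pre, n_post)
    dt = 1.0 / fs

    if params.cpe_exponent == 1.0:
        r_k = np.array([params.charge_transfer_resistance])
        tau_k = np.array([params.charge_transfer_resistance
                          * params.interface_capacitance])
    else:
        # band: from below the burst repetition scale up to the edge scale
        f_lo = 1.0 / (train.pulses_per_burst / train.pulse_frequency * 10)
        f_hi = 10.0 / train.cathodic_pulse_width
        r_k, tau_k = _foster_fit(params, f_lo, f_hi)

    # exact piecewise-constant-current update per RC element:
    # v <- i*R + (v - i*R) * exp(-dt/tau)
    decay = np.exp(-dt / tau_k)
    v_int = np.zeros_like(i)
    state = np.zeros_like(r_k)
    for n in range(1, len(i)):
        target = i[n] * r_k
        state = target + (state - target) * decay
        v_int[n] = state.sum()

    v = polarization_offset + i * params.solution_resistance + v_int
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    t = np.arange(len(i)) * dt
    return VoltageTransient(time=t, voltage=v, pulse_train=train,
                            circuit_truth=params, current=i)


# --------------------------------------------------------------------------
# file formats
# --------------------------------------------------------------------------

def write_transient_csv(trace: VoltageTransient, csv_path, sidecar_path=None) -> None:
    """Write time_s/voltage_v CSV plus a JSON sidecar with the descriptors."""
    csv_path = Path(csv_path)
    pd.DataFrame({"time_s": trace.time, "voltage_v": trace.voltage}).to_csv(
        csv_path, index=False)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    meta = {
        "format_version": 1,
        "pulse_train": asdict(trace.pulse_train),
        "circuit_truth": asdict(trace.circuit_truth) if trace.circuit_truth else None,
    }
    sidecar.write_text(json.dumps(meta, indent=2))


def read_transient_csv(csv_path, sidecar_path=None) -> VoltageTransient:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    train = PulseTrain(**meta["pulse_train"])
    truth = CircuitParams(**meta["circuit_truth"]) if meta.get("circuit_truth") else None
    return VoltageTransient(time=df["time_s"].to_numpy(),
                            voltage=df["voltage_v"].to_numpy(),
                            pulse_train=train, circuit_truth=truth)
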