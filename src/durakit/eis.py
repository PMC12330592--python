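"""Impedance-spectrum analytics for micro-ECoG electrode characterization.

Implements the standard electrode figures of merit used to qualify surface
electrode arrays for recording:

* electrode impedance from the measured reference voltage and counter
  current, Z = V_ref / I_C;
* Johnson thermal noise of the interface, V_rms = sqrt(4 kB T R Δf), with
  R the real part of the impedance, R = |Z| cos(θ);
* theoretical SNR in dB, 20 log10(V_signal / V_noise,rms);
* electrodeposition charge cutoffs at a fixed areal charge density;
* population summary statistics (mean, SD, CV) of |Z| at a query
  frequency, and channel yield under a configurable working criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BOLTZMANN",
    "ImpedanceSpectrum",
    "NoiseModel",
    "ElectrodeGeometry",
    "impedance_from_vi",
    "thermal_noise_rms",
    "snr_db",
    "impedance_summary",
    "deposition_charge_cutoff",
    "channel_yield",
    "write_spectra_csv",
    "read_spectra_csv",
]

BOLTZMANN = 1.380649e-23  # J/K


@dataclass
class ImpedanceSpectrum:
    """Per-electrode frequency sweep of complex impedance.

    ``magnitude`` is |Z| in ohms and ``phase`` is θ in degrees (capacitive
    phase negative).  The real part R = |Z| cos(θ) is derived on demand.
    """

    electrode_id: str
    frequency: np.ndarray
    magnitude: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if not (len(self.frequency) == len(self.magnitude) == len(self.phase)):
            raise ValueError("frequency, magnitude, phase must have equal length")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be >= 0")

    @property
    def real_part(self) -> np.ndarray:
        """R = |Z| cos(θ), ohms."""
        return self.magnitude * np.cos(np.radians(self.phase))

    def at(self, frequency: float, rtol: float = 0.01) -> tuple[float, float]:
        """(|Z|, θ) at the grid point nearest ``frequency``.

        The nearest grid frequency must lie within ``rtol`` relative
        tolerance (default 1%; spectra grids differ between instruments).
        """
        idx = int(np.argmin(np.abs(self.frequency - frequency)))
        if abs(self.frequency[idx] - frequency) > rtol * frequency:
            raise ValueError(
                f"frequency {frequency} Hz not in sweep of {self.electrode_id} "
                f"(nearest {self.frequency[idx]} Hz)")
        return float(self.magnitude[idx]), float(self.phase[idx])


@dataclass(frozen=True)
class NoiseModel:
    """Thermal-noise model parameters: T (K) and bandwidth Δf (Hz)."""

    temperature: float = 300.0
    bandwidth: float = 30e3
    boltzmann: float = BOLTZMANN

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.bandwidth <= 0:
            raise ValueError("temperature and bandwidth must be > 0")


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Disc electrode geometry; GSA = π (d/2)²."""

    diameter_um: float

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter must be > 0")

    @property
    def gsa_um2(self) -> float:
        return math.pi * (self.diameter_um / 2.0) ** 2

    @property
    def gsa_cm2(self) -> float:
        return self.gsa_um2 * 1e-8


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def impedance_from_vi(reference_voltage, counter_current):
    """Electrode impedance Z = V_ref / I_C.

    Accepts real magnitudes or complex phasors; returns the same kind.
    """
    if counter_current == 0:
        raise ZeroDivisionError(
            "counter current is zero; impedance undefined (check the cell)")
    return reference_voltage / counter_current


def thermal_noise_rms(real_part: float, model: NoiseModel = NoiseModel()) -> float:
    """RMS Johnson noise sqrt(4 kB T R Δf) in volts."""
    if real_part < 0:
        raise ValueError("real part of impedance must be >= 0")
    return math.sqrt(4.0 * model.boltzmann * model.temperature
                     * real_part * model.bandwidth)


def snr_db(signal_amplitude: float, noise_rms: float) -> float:
    """Theoretical SNR in dB: 20 log10(V_signal / V_noise,rms)."""
    if noise_rms <= 0:
        raise ValueError("noise_rms must be > 0 (SNR would be infinite)")
    return 20.0 * math.log10(signal_amplitude / noise_rms)


def impedance_summary(spectra: Iterable[ImpedanceSpectrum],
                      frequency: float) -> dict:
    """Population statistics of |Z| at a query frequency.

    Returns mean, sample (n−1) standard deviation, coefficient of
    variation sd/mean, and n over the electrode set.
    """
    mags = [s.at(frequency)[0] for s in spectra]
    if not mags:
        raise ValueError("empty spectrum set")
    arr = np.asarray(mags)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return {"mean": mean, "sd": sd,
            "cv": sd / mean if mean else float("nan"), "n": len(arr)}


def deposition_charge_cutoff(geometry: ElectrodeGeometry,
                             density_uc_per_um2: float = 1.0) -> dict:
    """Electroplating charge cutoff = density × GSA.

    With the default 1 μC/μm² areal density the cutoff for a 40 μm disc is
    1256.64 μC (integer report 1256 μC, truncated toward zero).
    """
    if density_uc_per_um2 <= 0:
        raise ValueError("charge density must be > 0")
    q = density_uc_per_um2 * geometry.gsa_um2
    return {"charge_uc": q, "charge_uc_int": int(q)}


def _default_working(spectrum: ImpedanceSpectrum) -> bool:
    # "working" is not standardized; default: |Z|@1 kHz within [1 kΩ, 1 MΩ]
    try:
        mag, _ = spectrum.at(1000.0)
    except ValueError:
        return False
    return 1e3 <= mag <= 1e6


def channel_yield(spectra: Sequence[ImpedanceSpectrum],
                  working_criterion: Callable[[ImpedanceSpectrum], bool]
                  = _default_working) -> float:
    """Working channels divided by total electrodes."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("empty spectrum set")
    return sum(working_criterion(s) for s in spectra) / len(spectra)


# --------------------------------------------------------------------------
# CSV format (shared with synth_electrode)
# --------------------------------------------------------------------------

def write_spectra_csv(spectra: Iterable[ImpedanceSpectrum], path) -> None:
    frames = [pd.DataFrame({
        "frequency_hz": s.frequency,
        "z_mag_ohm": s.magnitude,
        "z_phase_deg": s.phase,
        "electrode_id": s.electrode_id,
    }) for s in spectra]
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False)


def read_spectra_csv(path) -> list[ImpedanceSpectrum]:
    df = pd.read_csv(Path(path))
    required = {"frequency_hz", "z_mag_ohm", "z_phase_deg", "electrode_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spectra CSV missing columns: {sorted(missing)}")
    out = []
    for eid, grp in df.groupby("electrode_id", sort=False):
        out.append(ImpedanceSpectrum(
            electrode_id=str(eid),
            frequency=grp["frequency_hz"].to_numpy(),
            magnitude=grp["z_mag_ohm"].to_numpy(),
            phase=grp["z_phase_deg"].to_numpy()))
    return out
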