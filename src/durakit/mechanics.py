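"""Bilayer membrane mechanics surrogate.

Analytic design model for a soft elastomer / stiff polymer bilayer
membrane clamped over a circular cranial window and loaded by uniform
CSF pressure (typically 1-10 mmHg, 133.32-1333.2 Pa):

* effective (Voigt, thickness-weighted) Young's modulus of the laminate;
* composite flexural rigidity D about the neutral axis, by the
  transformed-section method with E/(1-ν²) plane-strain weighting;
* center deflection of the clamped circular membrane from the Föppl
  small-deflection-plus-stretching interpolation

      P = (64 D / R⁴) w₀ + (8 E_eff t / (3 (1 − ν_eff) R⁴)) w₀³,

  solved for the positive root w₀.  The cubic stretching term makes the
  model usable beyond the thin-plate range where w₀ exceeds the
  thickness; it is an analytic surrogate for a hyperelastic FEM, so its
  absolute deflections are design-stage estimates, not FEM replicas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "MechLayer",
    "MembraneLoad",
    "effective_modulus",
    "flexural_rigidity",
    "membrane_deflection",
    "PDMS",
    "PARYLENE_C",
]


@dataclass(frozen=True)
class MechLayer:
    """One laminate layer: E (MPa), thickness (μm), Poisson ratio ν."""

    name: str
    youngs_modulus_mpa: float
    thickness_um: float
    poisson_ratio: float

    def __post_init__(self) -> None:
        if self.youngs_modulus_mpa <= 0:
            raise ValueError("Young's modulus must be > 0")
        if self.thickness_um <= 0:
            raise ValueError("thickness must be > 0")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must be in [0, 0.5)")


def PDMS(thickness_um: float) -> MechLayer:
    """Medical-grade silicone layer, E = 2 MPa, ν = 0.49 (assumed)."""
    return MechLayer("PDMS", 2.0, thickness_um, 0.49)


def PARYLENE_C(thickness_um: float) -> MechLayer:
    """Parylene C layer, E = 2.8 GPa, ν = 0.40 (assumed)."""
    return MechLayer("Parylene C", 2800.0, thickness_um, 0.40)


@dataclass(frozen=True)
class MembraneLoad:
    """Uniform pressure load on a clamped circular membrane."""

    radius_mm: float
    pressure_pa: float
    edge_condition: str = "clamped"

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius must be > 0")
        if self.pressure_pa < 0:
            raise ValueError("pressure must be >= 0")
        if self.edge_condition != "clamped":
            raise ValueError("only clamped edges are modelled")


def effective_modulus(layers: Sequence[MechLayer]) -> float:
    """Thickness-weighted (Voigt) average modulus, MPa.

    For the 250 μm PDMS (2 MPa) + 10 μm Parylene C (2.8 GPa) design stack
    this evaluates to 109.62 MPa, in the range of native dura.
    """
    layers = list(layers)
    if not layers:
        raise ValueError("at least one layer required")
    total_t = sum(l.thickness_um for l in layers)
    if total_t <= 0:
        raise ValueError("zero total thickness")
    return sum(l.youngs_modulus_mpa * l.thickness_um for l in layers) / total_t


def flexural_rigidity(layers: Sequence[MechLayer]) -> float:
    """Composite-plate bending stiffness D in N·m.

    Transformed-section method: each layer is weighted by
    E_i / (1 − ν_i²); the neutral axis z_n is the weighted centroid and

        D = Σ_i  w_i [ (z_i,top − z_n)³ − (z_i,bot − z_n)³ ] / 3.

    For a single layer this reduces to E t³ / (12 (1 − ν²)).
    """
    layers = list(layers)
    if not layers:
        raise ValueError("at least one layer required")
    w = [l.youngs_modulus_mpa * 1e6 / (1.0 - l.poisson_ratio ** 2)
         for l in layers]                       # Pa
    t = [l.thickness_um * 1e-6 for l in layers]  # m
    bounds = np.concatenate([[0.0], np.cumsum(t)])
    mids = 0.5 * (bounds[:-1] + bounds[1:])
    z_n = sum(wi * ti * zi for wi, ti, zi in zip(w, t, mids)) \
        / sum(wi * ti for wi, ti in zip(w, t))
    d = 0.0
    for wi, (zb, zt) in zip(w, zip(bounds[:-1], bounds[1:])):
        d += wi * ((zt - z_n) ** 3 - (zb - z_n) ** 3) / 3.0
    return d


def membrane_deflection(layers: Sequence[MechLayer], load: MembraneLoad) -> float:
    """Center deflection w₀ of the clamped pressurized laminate, mm.

    Solves P = (64D/R⁴) w₀ + (8 E_eff t / (3 (1 − ν_eff) R⁴)) w₀³ for the
    unique positive root (the cubic has exactly one for positive
    coefficients).  ν_eff is the thickness-weighted Poisson ratio and
    E_eff the Voigt modulus.  In the tiny-pressure limit this converges
    to the classic clamped-plate result w₀ = P R⁴ / (64 D).
    """
    layers = list(layers)
    if load.pressure_pa == 0:
        return 0.0
    r = load.radius_mm * 1e-3
    d = flexural_rigidity(layers)
    t = sum(l.thickness_um for l in layers) * 1e-6
    e_eff = effective_modulus(layers) * 1e6
    nu_eff = sum(l.poisson_ratio * l.thickness_um for l in layers) \
        / sum(l.thickness_um for l in layers)
    a1 = 64.0 * d / r ** 4
    a3 = 8.0 * e_eff * t / (3.0 * (1.0 - nu_eff) * r ** 4)
    roots = np.roots([a3, 0.0, a1, -load.pressure_pa])
    real = roots[np.isclose(roots.imag, 0.0, atol=1e-9)].real
    positive = real[real > 0]
    if positive.size == 0:
        raise ArithmeticError("no positive deflection root found")
    return float(positive.min()) * 1e3  # m -> mm
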