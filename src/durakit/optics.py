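"""Optical models and measurements for transparent electrode arrays.

Covers the three optical questions that matter for a see-through surface
array on a cranial window:

* Fresnel reflectance at each material interface at normal incidence and
  the resulting multilayer transmission (no etalon interference terms —
  multiple partial reflections are deliberately neglected);
* spectrometer dark/reference/sample processing into a transmission
  spectrum, T(λ) = (sample − dark) / (reference − dark);
* geometric optical access: the fraction of the circular window not
  blocked by opaque metal electrodes, traces, and tapers, computed as an
  exact polygon union (circles approximated by 64-gons), with an option
  to neglect traces narrower than a threshold (thin traces become
  effectively transparent when imaging below them).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union

__all__ = [
    "OpticalLayer",
    "SpectrumReading",
    "LayoutSpec",
    "fresnel_reflectance",
    "stack_transmission",
    "process_spectra",
    "optical_access",
]

# 64-sided polygonal approximation of circles; shapely's buffer uses
# 4*quad_segs segments per full circle
_QUAD_SEGS = 16


@dataclass(frozen=True)
class OpticalLayer:
    """One optical medium: refractive index n (>= 1), optional thickness.

    ``absorption_per_um`` is an optional Beer-Lambert attenuation
    coefficient (1/μm); with thickness it contributes exp(-a*t) to the
    transmitted power.
    """

    name: str
    refractive_index: float
    thickness_um: float | None = None
    absorption_per_um: float = 0.0

    def __post_init__(self) -> None:
        if self.refractive_index < 1:
            raise ValueError("refractive index must be >= 1")
        if self.absorption_per_um < 0:
            raise ValueError("absorption coefficient must be >= 0")


@dataclass
class SpectrumReading:
    """Raw spectrometer counts versus wavelength (nm)."""

    wavelength_nm: np.ndarray
    counts: np.ndarray
    kind: str = "sample"    # dark | reference | sample

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.wavelength_nm.shape != self.counts.shape:
            raise ValueError("wavelength and counts must have equal length")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in ("dark", "reference", "sample"):
            raise ValueError("kind must be dark, reference, or sample")


@dataclass
class LayoutSpec:
    """Opaque-feature geometry of an array on a circular window.

    Coordinates in millimeters, origin at the window center.  Electrodes
    are (x, y, diameter_um) discs; traces are polylines with a width in
    micrometers; tapers are arbitrary polygons (vertex lists in mm).
    """

    window_diameter_mm: float
    electrodes: list = field(default_factory=list)   # (x_mm, y_mm, d_um)
    traces: list = field(default_factory=list)       # {"points": [(x,y)...], "width_um": w}
    tapers: list = field(default_factory=list)       # [(x,y), ...] polygons

    def __post_init__(self) -> None:
        if self.window_diameter_mm <= 0:
            raise ValueError("window diameter must be > 0")
        for tr in self.traces:
            if tr["width_um"] <= 0:
                raise ValueError("trace widths must be > 0")

    # ---- JSON round trip -------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = json.dumps({
            "format_version": 1,
            "window_diameter_mm": self.window_diameter_mm,
            "electrodes": [list(e) for e in self.electrodes],
            "traces": [{"points": [list(p) for p in t["points"]],
                        "width_um": t["width_um"]} for t in self.traces],
            "tapers": [[list(p) for p in poly] for poly in self.tapers],
        }, indent=2)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, source) -> "LayoutSpec":
        text = Path(source).read_text() if not str(source).lstrip().startswith("{") \
            else str(source)
        d = json.loads(text)
        return cls(
            window_diameter_mm=d["window_diameter_mm"],
            electrodes=[tuple(e) for e in d.get("electrodes", [])],
            traces=[{"points": [tuple(p) for p in t["points"]],
                     "width_um": t["width_um"]} for t in d.get("traces", [])],
            tapers=[[tuple(p) for p in poly] for poly in d.get("tapers", [])],
        )


# --------------------------------------------------------------------------
# Fresnel / transmission
# --------------------------------------------------------------------------

def fresnel_reflectance(n1: float, n2: float) -> float:
    """Normal-incidence power reflectance ((n1 − n2)/(n1 + n2))²."""
    if n1 < 1 or n2 < 1:
        raise ValueError("refractive indices must be >= 1")
    return ((n1 - n2) / (n1 + n2)) ** 2


def stack_transmission(layers: Sequence[OpticalLayer]) -> float:
    """Incoherent transmission through an ordered stack of media.

    Product of (1 − R) over successive interfaces, times Beer-Lambert
    absorption for layers carrying a coefficient and thickness.  Etalon
    (multiple-reflection interference) effects are deliberately excluded.
    A single medium transmits identically 1.
    """
    layers = list(layers)
    if len(layers) < 1:
        raise ValueError("at least one medium required")
    t = 1.0
    for a, b in zip(layers, layers[1:]):
        t *= 1.0 - fresnel_reflectance(a.refractive_index, b.refractive_index)
    for layer in layers:
        if layer.absorption_per_um and layer.thickness_um:
            t *= float(np.exp(-layer.absorption_per_um * layer.thickness_um))
    return t


def process_spectra(dark: SpectrumReading, reference: SpectrumReading,
                    sample: SpectrumReading) -> dict:
    """Dark-corrected transmission spectrum from three raw readings.

    T(λ) = (sample − dark) / (reference − dark), with all readings
    linearly interpolated onto the sample's wavelength grid.  Wavelengths
    where the reference does not exceed the dark reading are masked out
    with a warning (the instrument saw no light there).
    """
    grid = sample.wavelength_nm
    dark_i = np.interp(grid, dark.wavelength_nm, dark.counts)
    ref_i = np.interp(grid, reference.wavelength_nm, reference.counts)
    denom = ref_i - dark_i
    valid = denom > 0
    if not valid.all():
        warnings.warn(
            f"reference equals dark at {np.count_nonzero(~valid)} wavelengths; masked",
            stacklevel=2)
    t = np.full_like(denom, np.nan)
    t[valid] = (sample.counts[valid] - dark_i[valid]) / denom[valid]
    return {"wavelength_nm": grid, "transmission": t, "valid": valid}


# --------------------------------------------------------------------------
# geometric optical access
# --------------------------------------------------------------------------

def _opaque_geometries(layout: LayoutSpec,
                       ignore_traces_narrower_than_um: float) -> list:
    geoms = []
    for x, y, d_um in layout.electrodes:
        geoms.append(Point(x, y).buffer(d_um / 2000.0, quad_segs=_QUAD_SEGS))
    for tr in layout.traces:
        if tr["width_um"] < ignore_traces_narrower_than_um:
            continue
        line = LineString(tr["points"])
        geoms.append(line.buffer(tr["width_um"] / 2000.0,
                                 quad_segs=_QUAD_SEGS, cap_style="flat"))
    for poly in layout.tapers:
        geoms.append(Polygon(poly))
    return geoms


def blocked_geometry(layout: LayoutSpec,
                     ignore_traces_narrower_than_um: float = 0.0):
    """Union of opaque features clipped to the window disc (shapely geometry)."""
    window = Point(0.0, 0.0).buffer(layout.window_diameter_mm / 2.0,
                                    quad_segs=_QUAD_SEGS)
    geoms = _opaque_geometries(layout, ignore_traces_narrower_than_um)
    if not geoms:
        return window.intersection(Polygon())  # empty
    union = unary_union(geoms)
    if not window.contains(union):
        warnings.warn("opaque features extend outside the window; clipped",
                      stacklevel=2)
    return union.intersection(window)


def optical_access(layout: LayoutSpec,
                   ignore_traces_narrower_than_um: float = 0.0) -> dict:
    """Blocked fraction and optical-access percentage of the window.

    Blocked area is the area of the union (not the sum) of all opaque
    features intersected with the window disc; features narrower than the
    ignore threshold are treated as effectively transparent.  The window
    area in the denominator is the exact disc area π(d/2)²; the features
    (and the clipping disc) are 64-gon approximations, an area error below
    0.2% of each circular feature.
    """
    r = layout.window_diameter_mm / 2.0
    window_area = np.pi * r * r
    blocked = blocked_geometry(layout, ignore_traces_narrower_than_um)
    frac = blocked.area / window_area
    return {"blocked_fraction": frac,
            "blocked_area_mm2": blocked.area,
            "window_area_mm2": window_area,
            "access_percent": 100.0 * (1.0 - frac)}
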