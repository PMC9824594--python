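"""Volumetric extrusion model: from strand geometry to the cumulative E axis.

A deposited strand is modelled with a *stadium* cross-section — a rectangle
of width ``w - h`` and height ``h`` capped by two semicircles of diameter
``h`` (the shape assumed by slicers such as Slic3r):

    A = (w - h) * h + pi * (h / 2)**2

Volume conservation between the filament advanced by the extruder motor and
the material laid down over a segment of length ``L_seg`` gives the E-axis
increment

    E = A * L_seg * 4 / (pi * d**2) * f

where ``d`` is a reference diameter and ``f`` the dimensionless extrusion
multiplier (values < 1 under-extrude; sufficiently small ``f`` produces the
thin-fiber regime this package targets).

.. note::
   The physically meaningful choice for ``d`` is the *filament* diameter
   (1.75 mm stock), since E is the length of filament fed by the extruder.
   The generator this package models used the *nozzle* diameter in the
   denominator, so ``e_denominator`` defaults to ``"nozzle"`` for fidelity;
   switch to ``"filament"`` for physical E values on real hardware.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .geometry import Toolpath

__all__ = [
    "ExtrusionParams",
    "FlowAccount",
    "StrandWidth",
    "cross_section_area",
    "extrusion_length",
    "assign_extrusion",
    "effective_strand_width",
    "flow_account",
]


@dataclass(frozen=True)
class ExtrusionParams:
    """Parameters of the volumetric extrusion model.

    ``w`` is the designed extrusion width (default 0.68 mm = 1.7 x the
    0.40 mm nozzle, the upper end of the recommended 1.05-1.7x window),
    ``h`` the layer height, ``f`` the extrusion multiplier, and
    ``e_denominator`` selects the diameter used in the E conversion
    (``"nozzle"`` or ``"filament"``; see module note).
    """

    w: float = 0.68
    h: float = 0.20
    d_nozzle: float = 0.40
    d_filament: float = 1.75
    f: float = 1.0
    e_denominator: str = "nozzle"

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise ValueError("layer height h must be positive")
        if self.w < self.h:
            raise ValueError("extrusion width w must be >= layer height h")
        if self.d_nozzle <= 0 or self.d_filament <= 0:
            raise ValueError("diameters must be positive")
        if self.f < 0:
            raise ValueError("extrusion multiplier f must be >= 0")
        if self.e_denominator not in ("nozzle", "filament"):
            raise ValueError("e_denominator must be 'nozzle' or 'filament'")

    @property
    def d(self) -> float:
        """Reference diameter used in the E conversion, mm."""
        return self.d_nozzle if self.e_denominator == "nozzle" else self.d_filament


@dataclass(frozen=True)
class FlowAccount:
    """Volume bookkeeping for a toolpath: filament in vs material out."""

    V_in: float  # volume advanced through the extruder, mm^3
    V_out: float  # volume deposited along the path, mm^3
    E_total: float  # final cumulative E, mm


@dataclass(frozen=True)
class StrandWidth:
    """Effective deposited strand width, with an under-extrusion flag.

    When the scaled cross-section area is too small to form a stadium of
    height ``h`` (``fiber_regime=True``), ``value`` is instead the
    equivalent circular diameter of the deposited filament.
    """

    value: float  # mm
    fiber_regime: bool


def cross_section_area(w: float, h: float) -> float:
    """Stadium cross-section area ``(w - h) * h + pi * (h/2)**2``, mm^2.

    Degenerates to a circle of diameter ``h`` when ``w == h``.  Raises for
    ``w < h``, where the cap geometry is undefined.
    """
    if not h > 0:
        raise ValueError("h must be positive")
    if w < h:
        raise ValueError("w must be >= h (stadium caps undefined otherwise)")
    return (w - h) * h + math.pi * (h / 2.0) ** 2


def extrusion_length(A: float, L_seg, params: ExtrusionParams):
    """E-axis increment for a segment: ``A * L_seg * 4 / (pi d^2) * f``.

    Vectorized over ``L_seg``.  Negative segment lengths are rejected.
    """
    L_seg = np.asarray(L_seg, dtype=float)
    if np.any(L_seg < 0):
        raise ValueError("segment length must be >= 0")
    out = A * L_seg * 4.0 / (math.pi * params.d**2) * params.f
    return float(out) if out.ndim == 0 else out


def assign_extrusion(toolpath: Toolpath, params: ExtrusionParams) -> Toolpath:
    """Assign cumulative E to a toolpath (travel segments leave E unchanged).

    The input path must not already carry an E axis; call
    :meth:`Toolpath.reset_extrusion` first to re-assign.  E is
    non-decreasing along the path by construction.
    """
    if toolpath.e is not None:
        raise ValueError(
            "toolpath already has E assigned; reset_extrusion() before re-assigning"
        )
    A = cross_section_area(params.w, params.h)
    lengths = toolpath.segment_lengths()
    inc = np.where(
        toolpath.extrude_mask(), extrusion_length(A, lengths, params), 0.0
    )
    e = np.concatenate([[0.0], np.cumsum(inc)]) if toolpath.n_points else np.zeros(0)
    return replace(toolpath, e=e)


def effective_strand_width(params: ExtrusionParams) -> StrandWidth:
    """Width of the strand actually deposited at multiplier ``f``.

    Solves ``(w_eff - h) * h + pi * (h/2)**2 = f * A_nominal`` for
    ``w_eff``.  If no solution with ``w_eff >= h`` exists — the deposited
    volume cannot fill a stadium of height ``h`` — the strand detaches
    from the layer-height constraint and the equivalent circular diameter
    ``2 * sqrt(f * A / pi)`` is returned flagged as ``fiber_regime``.
    """
    if params.f <= 0:
        raise ValueError("effective strand width is undefined for f <= 0")
    A_scaled = params.f * cross_section_area(params.w, params.h)
    cap = math.pi * (params.h / 2.0) ** 2
    if A_scaled >= cap:
        w_eff = params.h + (A_scaled - cap) / params.h
        return StrandWidth(value=w_eff, fiber_regime=False)
    return StrandWidth(value=2.0 * math.sqrt(A_scaled / math.pi), fiber_regime=True)


def flow_account(toolpath: Toolpath, params: ExtrusionParams) -> FlowAccount:
    """Volume bookkeeping: ``V_in`` from the E axis, ``V_out`` from geometry.

    ``V_in = pi * (d/2)**2 * E_total``; ``V_out = f * A * sum(L_seg)`` over
    extruding segments.  The two agree to floating-point rounding for a
    path whose E was assigned with the same parameters.
    """
    e_total = toolpath.total_e
    v_in = math.pi * (params.d / 2.0) ** 2 * e_total
    A = cross_section_area(params.w, params.h)
    v_out = params.f * A * toolpath.total_extrude_length()
    return FlowAccount(V_in=v_in, V_out=v_out, E_total=e_total)
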