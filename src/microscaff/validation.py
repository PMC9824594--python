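"""Printability rules for scaffold prints, and G-code flow audits.

The rules encode standard FDM practice for thermoplastic scaffold work
with PCL (polycaprolactone):

* R1 — layer height at most 80 % of the nozzle diameter (error: taller
  layers cannot be shaped by the nozzle);
* R2 — extrusion width within 1.05-1.7x the nozzle diameter (warning);
* R3 — print speed above 100 mm/s risks machine instability (warning);
* R4 — first-layer speed above 25 mm/s risks bed-adhesion failure
  (warning; the packaged experiment matrices pin the first layer at
  600 mm/min = 10 mm/s for exactly this reason);
* R5 — fan PWM within 0..255 (error: out-of-range values are meaningless);
* R6 — extruder and bed temperature within the material window
  (warning; PCL defaults: nozzle 130-170 °C, bed 30-45 °C).

Severities are a package choice: R1/R5 violations make the G-code
physically meaningless, the rest degrade quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
import pandas as pd

from . import extrusion as _ext
from . import gcode as _gcode
from .geometry import ScaffoldSpec, Toolpath

__all__ = [
    "PrinterProfile",
    "Finding",
    "ValidationReport",
    "MaterialWindow",
    "PCL_WINDOW",
    "validate",
    "audit_gcode",
    "AuditResult",
]


@dataclass(frozen=True)
class PrinterProfile:
    """Printer kinematics and tooling; defaults are a stock 0.4 mm Cartesian
    machine (max print 150 mm/s, travel 250 mm/s, 1.75 mm filament,
    XYZ resolution 0.05/0.05/0.10 mm)."""

    d_nozzle: float = 0.40
    d_filament: float = 1.75
    max_print_speed: float = 150.0  # mm/s
    max_travel_speed: float = 250.0  # mm/s
    xyz_resolution: tuple[float, float, float] = (0.05, 0.05, 0.10)

    def __post_init__(self) -> None:
        if min(self.d_nozzle, self.d_filament, self.max_print_speed,
               self.max_travel_speed, *self.xyz_resolution) <= 0:
            raise ValueError("all printer profile values must be positive")


@dataclass(frozen=True)
class MaterialWindow:
    """Recommended temperature windows for a material, °C."""

    extruder: tuple[float, float] = (130.0, 170.0)
    bed: tuple[float, float] = (30.0, 45.0)


PCL_WINDOW = MaterialWindow()


@dataclass(frozen=True)
class Finding:
    rule: str
    severity: str  # "error" | "warning"
    measured: float
    limit: float
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]

    def __str__(self) -> str:
        if self.ok:
            return "all printability rules passed"
        return "\n".join(
            f"[{f.severity}] {f.rule}: {f.message} (measured {f.measured:g}, limit {f.limit:g})"
            for f in self.findings
        )


def validate(
    profile: PrinterProfile,
    spec: ScaffoldSpec,
    settings: _gcode.PrintSettings,
    params: _ext.ExtrusionParams,
    material: MaterialWindow = PCL_WINDOW,
) -> ValidationReport:
    """Check a configuration against rules R1-R6; empty report = pass."""
    f: list[Finding] = []

    r1_limit = 0.8 * profile.d_nozzle
    if spec.layer_height > r1_limit:
        f.append(Finding("R1", "error", spec.layer_height, r1_limit,
                         "layer height exceeds 80% of the nozzle diameter"))

    w_lo, w_hi = 1.05 * profile.d_nozzle, 1.7 * profile.d_nozzle
    if not (w_lo <= params.w <= w_hi):
        f.append(Finding("R2", "warning", params.w, w_hi if params.w > w_hi else w_lo,
                         "extrusion width outside the 1.05-1.7x nozzle range"))

    speed_mm_s = settings.speed / 60.0
    if speed_mm_s >= 100.0:
        f.append(Finding("R3", "warning", speed_mm_s, 100.0,
                         "print speed at or above 100 mm/s may destabilize the machine"))

    fl_mm_s = settings.first_layer_speed / 60.0
    if fl_mm_s > 25.0:
        f.append(Finding("R4", "warning", fl_mm_s, 25.0,
                         "first-layer speed above 25 mm/s risks poor bed adhesion"))

    if not (0 <= settings.fan_pwm <= 255):
        f.append(Finding("R5", "error", settings.fan_pwm, 255,
                         "fan PWM outside 0..255"))

    et_lo, et_hi = material.extruder
    if not (et_lo <= settings.extruder_temp <= et_hi):
        f.append(Finding("R6", "warning", settings.extruder_temp,
                         et_hi if settings.extruder_temp > et_hi else et_lo,
                         "extruder temperature outside the material window"))
    bt_lo, bt_hi = material.bed
    if not (bt_lo <= settings.bed_temp <= bt_hi):
        f.append(Finding("R6", "warning", settings.bed_temp,
                         bt_hi if settings.bed_temp > bt_hi else bt_lo,
                         "bed temperature outside the material window"))

    return ValidationReport(findings=f)


@dataclass
class AuditResult:
    """Flow audit of a G-code document.

    ``segments`` has one row per extruding segment: length, E increment,
    implied extrusion multiplier, effective strand width (mm) and whether
    the segment is in the under-extruded fiber regime.
    """

    report: ValidationReport
    account: _ext.FlowAccount
    segments: pd.DataFrame


def audit_gcode(
    doc: "str | _gcode.GCodeDocument",
    profile: PrinterProfile,
    params: _ext.ExtrusionParams,
) -> AuditResult:
    """Reconstruct per-segment flow from G-code and re-check key rules.

    The E words are taken as ground truth; each extruding segment's
    implied multiplier is ``dE / (A * L * 4 / (pi d^2))`` and is converted
    to an effective strand width (flagged ``fiber_regime`` when the
    deposited volume cannot fill a stadium of the nominal layer height).
    Layer height (R1), fan PWM (R5) and speed (R3) are re-checked from
    the parsed values.
    """
    parsed = _gcode.parse(doc)
    tp = parsed.toolpath
    findings: list[Finding] = []

    zs = tp.distinct_z()
    if len(zs) >= 1:
        layer_heights = np.diff(np.concatenate([[0.0], zs]))
        h_max = float(layer_heights.max())
        r1_limit = 0.8 * profile.d_nozzle
        if h_max > r1_limit + 1e-9:
            findings.append(Finding("R1", "error", h_max, r1_limit,
                                    "layer height exceeds 80% of the nozzle diameter"))

    if not (0 <= parsed.settings.fan_pwm <= 255):
        findings.append(Finding("R5", "error", parsed.settings.fan_pwm, 255,
                                "fan PWM outside 0..255"))

    if tp.feed is not None and len(tp.feed):
        fmax = float(np.nanmax(tp.feed)) / 60.0
        if fmax >= 100.0:
            findings.append(Finding("R3", "warning", fmax, 100.0,
                                    "print speed at or above 100 mm/s may destabilize the machine"))

    A = _ext.cross_section_area(params.w, params.h)
    conv = A * 4.0 / (math.pi * params.d**2)  # E per unit length at f=1
    rows = []
    e_total = 0.0
    length_total = 0.0
    if tp.n_segments:
        lengths = tp.segment_lengths()
        de = np.diff(tp.e)
        for i in range(tp.n_segments):
            if tp.kinds[i] != "extrude" or lengths[i] == 0:
                continue
            implied_f = float(de[i] / (conv * lengths[i]))
            e_total += float(de[i])
            length_total += float(lengths[i])
            if implied_f > 0:
                sw = _ext.effective_strand_width(
                    _ext.ExtrusionParams(
                        w=params.w, h=params.h, d_nozzle=params.d_nozzle,
                        d_filament=params.d_filament, f=implied_f,
                        e_denominator=params.e_denominator,
                    )
                )
                width, fiber = sw.value, sw.fiber_regime
            else:
                width, fiber = 0.0, True
            rows.append(
                {
                    "segment": i,
                    "length_mm": float(lengths[i]),
                    "delta_e_mm": float(de[i]),
                    "implied_f": implied_f,
                    "effective_width_mm": width,
                    "fiber_regime": fiber,
                }
            )
    segments = pd.DataFrame.from_records(
        rows,
        columns=["segment", "length_mm", "delta_e_mm", "implied_f",
                 "effective_width_mm", "fiber_regime"],
    )
    v_in = math.pi * (params.d / 2.0) ** 2 * e_total
    v_out = A * sum(r["implied_f"] * r["length_mm"] for r in rows)
    account = _ext.FlowAccount(V_in=v_in, V_out=v_out, E_total=e_total)
    return AuditResult(report=ValidationReport(findings=findings),
                       account=account, segments=segments)
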