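"""Packaged sensitivity-analysis matrices and the no-Z-raise pass strategy.

Five experiment families probe which deposition conditions produce thin
fibers inside a printed scaffold:

* ``F`` — extrusion-multiplier sweep at the reference speed (fan off);
* ``V`` — printing-speed sweep at reduced multipliers (fan off);
* ``T`` — part-cooling fan (PWM) sweep;
* ``P`` — low-volume *surface passes* deposited on the last printed layer
  without raising Z, sweeping pass multiplier and pass speed;
* ``D`` — the diagonal-pass variant (45° passes at f=0.20, 5000 mm/min).

The tables ship verbatim in ``data/experiments.csv``, including the rows
whose first layer failed to adhere (V8B, T12B, T13B — flagged, excluded
from default sweep output) and the internally inconsistent printed PWM
percentage annotations (kept as notes; the numeric PWM is authoritative).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import extrusion as _ext
from . import gcode as _gcode
from .geometry import (
    EXTRUDE,
    TRAVEL,
    ScaffoldSpec,
    Toolpath,
    build_toolpath,
    generate_rectilinear_layer,
)
from .validation import PrinterProfile

__all__ = [
    "MATRICES",
    "SurfacePassSpec",
    "ExperimentRow",
    "load_matrix",
    "load_all_rows",
    "matrix_table",
    "add_surface_passes",
    "build_experiment",
    "run_sweep",
    "f_linearity_pairs",
]

MATRICES = ("F", "V", "T", "P", "D")

#: conditions of the 3 base layers under every surface-pass experiment
PASS_BASE_F = 1.0
PASS_BASE_SPEED = 600.0
PASS_BASE_FAN = 255
FIRST_LAYER_SPEED = 600.0


@dataclass(frozen=True)
class SurfacePassSpec:
    """Extra strands deposited on the last base layer without raising Z."""

    n_base_layers: int = 3
    pass_f: float = 0.20
    pass_speed: float = 5000.0
    pass_pattern: str = "parallel"  # or "diagonal" (45°)

    def __post_init__(self) -> None:
        if self.n_base_layers < 1:
            raise ValueError("n_base_layers must be >= 1")
        if self.pass_f < 0:
            raise ValueError("pass_f must be >= 0")
        if self.pass_speed <= 0:
            raise ValueError("pass_speed must be positive")
        if self.pass_pattern not in ("parallel", "diagonal"):
            raise ValueError("pass_pattern must be 'parallel' or 'diagonal'")


@dataclass(frozen=True)
class ExperimentRow:
    """One named experiment (e.g. T9B) binding its printing conditions.

    For pass experiments (P, D) ``f`` and ``speed`` refer to the surface
    pass, as the source tables print them; the base layers always use the
    fixed pass-base conditions.
    """

    id: str
    matrix: str
    f: float
    speed: float
    fan_pwm: int
    pwm_note: str = ""
    failed: bool = False
    notes: str = ""
    pass_spec: SurfacePassSpec | None = None


def _data_table() -> pd.DataFrame:
    with resources.files("microscaff").joinpath("data/experiments.csv").open() as fh:
        return pd.read_csv(fh, dtype={"pwm_note": str, "notes": str}, keep_default_na=False)


def _row_from_record(rec) -> ExperimentRow:
    pass_spec = None
    if rec["n_base_layers"] != "":
        pass_spec = SurfacePassSpec(
            n_base_layers=int(rec["n_base_layers"]),
            pass_f=float(rec["pass_f"]),
            pass_speed=float(rec["pass_speed"]),
            pass_pattern=str(rec["pass_pattern"]),
        )
    return ExperimentRow(
        id=str(rec["id"]),
        matrix=str(rec["matrix"]),
        f=float(rec["f"]),
        speed=float(rec["speed"]),
        fan_pwm=int(rec["fan_pwm"]),
        pwm_note=str(rec["pwm_note"]),
        failed=str(rec["failed"]) == "True",
        notes=str(rec["notes"]),
        pass_spec=pass_spec,
    )


def load_matrix(name: str) -> list[ExperimentRow]:
    """Load one experiment matrix (F, V, T, P or D) exactly as packaged."""
    if name not in MATRICES:
        raise KeyError(f"unknown matrix {name!r}; choose from {MATRICES}")
    df = _data_table()
    return [_row_from_record(rec) for rec in df[df["matrix"] == name].to_dict("records")]


def load_all_rows() -> list[ExperimentRow]:
    """All 35 experiment rows across the five matrices, in table order."""
    return [row for name in MATRICES for row in load_matrix(name)]


def matrix_table() -> pd.DataFrame:
    """The packaged source-of-truth table as a DataFrame (round-trippable)."""
    return _data_table()


def add_surface_passes(
    toolpath: Toolpath,
    spec: ScaffoldSpec,
    pass_spec: SurfacePassSpec,
    params: _ext.ExtrusionParams,
) -> Toolpath:
    """Append low-volume pass strands on the last layer without raising Z.

    Pass strands are laid over the scaffold footprint at the current top
    Z: ``parallel`` passes re-run the strand-along-Y field spaced ``d1``,
    ``diagonal`` passes run at 45° with perpendicular spacing ``d1``.  The
    pass E is computed with ``pass_spec.pass_f`` and continues the base
    path's cumulative E; every appended move (including the approach) has
    its feed pinned to ``pass_spec.pass_speed``.
    """
    if toolpath.n_points == 0:
        raise ValueError("cannot add passes to an empty toolpath")
    if toolpath.e is None:
        raise ValueError("base toolpath must have E assigned before adding passes")
    n_layers = int(toolpath.layers.max()) if toolpath.n_segments else 1
    if n_layers < pass_spec.n_base_layers:
        raise ValueError(
            f"toolpath has {n_layers} layers < n_base_layers {pass_spec.n_base_layers}"
        )
    z_top = float(toolpath.points[:, 2].max())

    if pass_spec.pass_pattern == "parallel":
        lp = generate_rectilinear_layer(replace(spec, angle_sequence=(90,)), 1)
        verts = lp.vertices
        kinds = lp.segment_kinds
    else:
        verts, kinds = _diagonal_field(spec)

    pass_params = replace(params, f=pass_spec.pass_f)
    A = _ext.cross_section_area(pass_params.w, pass_params.h)

    pts3 = np.column_stack([verts, np.full(len(verts), z_top)])
    new_points = np.vstack([toolpath.points, pts3])
    approach = np.asarray([TRAVEL], dtype=object)
    new_kinds = np.concatenate([toolpath.kinds, approach, kinds])
    layer = n_layers
    new_layers = np.concatenate(
        [toolpath.layers, [layer], np.full(len(kinds), layer, dtype=int)]
    )

    seg_vec = np.diff(np.vstack([toolpath.points[-1:], pts3]), axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    ext_mask = np.asarray([k == EXTRUDE for k in np.concatenate([approach, kinds])])
    inc = np.where(ext_mask, _ext.extrusion_length(A, seg_len, pass_params), 0.0)
    new_e = np.concatenate([toolpath.e, toolpath.e[-1] + np.cumsum(inc)])

    old_feed = (
        toolpath.feed
        if toolpath.feed is not None
        else np.full(toolpath.n_segments, np.nan)
    )
    new_feed = np.concatenate(
        [old_feed, np.full(1 + len(kinds), pass_spec.pass_speed)]
    )
    return Toolpath(
        points=new_points, kinds=new_kinds, layers=new_layers, e=new_e, feed=new_feed
    )


def _diagonal_field(spec: ScaffoldSpec):
    """45° serpentine lines over the L x L footprint, spacing d1 (perp.)."""
    L = spec.L
    step = spec.d1 * np.sqrt(2.0)  # offset along x+y=c for perpendicular spacing d1
    cs = np.arange(step, 2 * L - step / 2, step)
    verts: list[tuple[float, float]] = []
    kinds: list[str] = []
    for i, c in enumerate(cs):
        a = (max(0.0, c - L), min(L, c))  # (x, y) upper-left end
        b = (min(L, c), max(0.0, c - L))  # lower-right end
        p0, p1 = (a, b) if i % 2 == 0 else (b, a)
        if verts:
            verts.append(p0)
            kinds.append(TRAVEL)
        else:
            verts.append(p0)
        verts.append(p1)
        kinds.append(EXTRUDE)
    ox, oy = spec.origin
    out = np.asarray(verts, dtype=float) + np.asarray([ox, oy])
    return out, np.asarray(kinds, dtype=object)


def build_experiment(
    row: ExperimentRow,
    base_spec: ScaffoldSpec | None = None,
    params: _ext.ExtrusionParams | None = None,
) -> tuple[Toolpath, _gcode.PrintSettings]:
    """Build the E-assigned toolpath and settings for one experiment row."""
    spec = base_spec if base_spec is not None else ScaffoldSpec()
    params = params if params is not None else _ext.ExtrusionParams(h=spec.layer_height)
    if row.pass_spec is None:
        p = replace(params, f=row.f)
        tp = _ext.assign_extrusion(build_toolpath(spec), p)
        settings = _gcode.PrintSettings(
            speed=row.speed,
            first_layer_speed=FIRST_LAYER_SPEED,
            fan_pwm=row.fan_pwm,
            f=row.f,
        )
    else:
        base = replace(spec, n_layers=row.pass_spec.n_base_layers)
        p = replace(params, f=PASS_BASE_F)
        tp = _ext.assign_extrusion(build_toolpath(base), p)
        tp = add_surface_passes(tp, base, row.pass_spec, params)
        settings = _gcode.PrintSettings(
            speed=PASS_BASE_SPEED,
            first_layer_speed=FIRST_LAYER_SPEED,
            fan_pwm=PASS_BASE_FAN,
            f=PASS_BASE_F,
        )
    return tp, settings


def run_sweep(
    rows: list[ExperimentRow],
    base_spec: ScaffoldSpec | None = None,
    profile: PrinterProfile | None = None,
    outdir: str | Path = "runs",
    include_failed: bool = False,
) -> pd.DataFrame:
    """Write one G-code file per experiment row; return the manifest.

    Rows flagged as first-layer adhesion failures are skipped unless
    ``include_failed`` (mirroring the absence of their imaging results).
    Output is deterministic: re-running produces byte-identical files.
    The manifest (also written to ``manifest.csv``) lists the settings and
    total E per file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profile = profile if profile is not None else PrinterProfile()
    records = []
    for row in rows:
        if row.failed and not include_failed:
            continue
        tp, settings = build_experiment(row, base_spec=base_spec)
        doc = _gcode.emit(tp, settings, profile)
        path = outdir / f"{row.id}.gcode"
        path.write_text(doc.text)
        records.append(
            {
                "id": row.id,
                "matrix": row.matrix,
                "file": path.name,
                "f": row.f,
                "speed_mm_min": row.speed,
                "fan_pwm": row.fan_pwm,
                "pass_pattern": row.pass_spec.pass_pattern if row.pass_spec else "",
                "total_e_mm": tp.total_e,
                "n_layers": int(tp.layers.max()) if tp.n_segments else 0,
            }
        )
    manifest = pd.DataFrame.from_records(
        records,
        columns=[
            "id", "matrix", "file", "f", "speed_mm_min", "fan_pwm",
            "pass_pattern", "total_e_mm", "n_layers",
        ],
    )
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def f_linearity_pairs(rows: list[ExperimentRow] | None = None):
    """Pairs of rows identical except for the extrusion multiplier.

    Grouping keys are everything that affects the toolpath besides ``f``:
    speed, fan PWM, and (for pass rows) pass speed and pattern.  Used to
    check that total E scales exactly with the multiplier ratio.
    """
    rows = rows if rows is not None else load_all_rows()
    groups: dict[tuple, list[ExperimentRow]] = {}
    for row in rows:
        ps = row.pass_spec
        key = (
            ps is not None,
            row.speed,
            row.fan_pwm,
            ps.pass_speed if ps else None,
            ps.pass_pattern if ps else None,
        )
        groups.setdefault(key, []).append(row)
    pairs = []
    for members in groups.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if members[i].f != members[j].f:
                    pairs.append((members[i], members[j]))
    return pairs
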