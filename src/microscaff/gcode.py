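"""Emit and parse the RepRap-flavor G-code dialect used for scaffold prints.

The emitted dialect is deliberately small: ``M140``/``M190`` (bed set /
set-and-wait), ``M104``/``M109`` (nozzle set / set-and-wait), ``G28``
homing, ``G90`` absolute XYZ, ``M82`` absolute E, ``G92 E0`` E-axis zero,
``M106``/``M107`` fan, ``G1`` motion and ``M84`` motor release.  E is
absolute (cumulative) and there is no retraction.

Formatting is canonical — coordinates fixed-point 3 decimals, E 5 decimals,
F integers in mm/min, F/Z words only when they change — so re-emitting a
parsed document is byte-identical, which is what makes G-code files
auditable artifacts rather than write-only output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .geometry import EXTRUDE, TRAVEL, Toolpath

__all__ = [
    "PrintSettings",
    "GCodeDocument",
    "GCodeParseError",
    "ParsedGCode",
    "emit",
    "parse",
    "speed_display",
]


@dataclass(frozen=True)
class PrintSettings:
    """Per-print settings: speeds (mm/min), temperatures (°C), fan PWM.

    Defaults are the reference rectilinear print: 600 mm/min everywhere,
    nozzle 150 °C, bed 40 °C, fan off.  ``fan_from_layer`` is the 1-based
    layer at whose start the fan command is emitted (the fan state is
    constant per print, so the default is layer 1).  ``f`` records the
    extrusion multiplier used for the E axis.
    """

    speed: float = 600.0
    first_layer_speed: float = 600.0
    extruder_temp: float = 150.0
    bed_temp: float = 40.0
    fan_pwm: int = 0
    fan_from_layer: int = 1
    f: float = 1.0

    def __post_init__(self) -> None:
        if not (self.speed > 0 and self.first_layer_speed > 0):
            raise ValueError("speeds must be positive")
        if self.extruder_temp < 0 or self.bed_temp < 0:
            raise ValueError("temperatures must be >= 0")
        if not (0 <= self.fan_pwm <= 255):
            raise ValueError("fan_pwm must be within 0..255")
        if self.fan_from_layer < 1:
            raise ValueError("fan_from_layer must be >= 1")


@dataclass
class GCodeDocument:
    """A G-code file split into preamble, motion and postamble lines."""

    preamble: list[str] = field(default_factory=list)
    motion: list[str] = field(default_factory=list)
    postamble: list[str] = field(default_factory=list)

    @property
    def lines(self) -> list[str]:
        return [*self.preamble, *self.motion, *self.postamble]

    @property
    def text(self) -> str:
        return "\n".join(self.lines) + "\n"


class GCodeParseError(ValueError):
    """Malformed G-code; carries the 1-based offending line number."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


def _fmt_temp(t: float) -> str:
    return f"{t:g}"


def emit(toolpath: Toolpath, settings: PrintSettings, profile=None) -> GCodeDocument:
    """Emit a canonical G-code document for an E-assigned toolpath.

    The preamble heats bed and nozzle (set both, then wait on each), homes,
    selects absolute positioning and absolute E and zeroes E.  Layer-1
    moves carry ``first_layer_speed``, later layers ``speed``; per-segment
    ``toolpath.feed`` overrides win where finite.  ``M106 S<pwm>`` is
    emitted at the start of layer ``fan_from_layer`` when the fan is on.
    An empty toolpath yields preamble + postamble only.
    """
    if toolpath.n_segments > 0 and toolpath.e is None:
        raise ValueError("toolpath must have E assigned before emitting")

    s = settings
    preamble = [
        f"M140 S{_fmt_temp(s.bed_temp)}",
        f"M104 S{_fmt_temp(s.extruder_temp)}",
        f"M190 S{_fmt_temp(s.bed_temp)}",
        f"M109 S{_fmt_temp(s.extruder_temp)}",
        "G28",
        "G90",
        "M82",
        "G92 E0",
    ]
    postamble = ["M107", "M104 S0", "M140 S0", "M84"]

    motion: list[str] = []
    if toolpath.n_points == 0:
        return GCodeDocument(preamble=preamble, motion=motion, postamble=postamble)

    def default_feed(layer: int) -> float:
        return s.first_layer_speed if layer == 1 else s.speed

    n_seg = toolpath.n_segments
    feeds = np.empty(n_seg + 1)
    # move 0 positions the head at points[0]; it inherits segment 0's feed
    for i in range(n_seg):
        ov = toolpath.feed[i] if toolpath.feed is not None else np.nan
        feeds[i + 1] = ov if np.isfinite(ov) else default_feed(int(toolpath.layers[i]))
    feeds[0] = feeds[1] if n_seg else s.first_layer_speed

    move_layer = np.empty(n_seg + 1, dtype=int)
    move_layer[1:] = toolpath.layers if n_seg else []
    move_layer[0] = toolpath.layers[0] if n_seg else 1

    fan_pending = s.fan_pwm > 0
    state_f: float | None = None
    state_z: float | None = None
    for m in range(n_seg + 1):
        if fan_pending and move_layer[m] >= s.fan_from_layer:
            motion.append(f"M106 S{int(s.fan_pwm)}")
            fan_pending = False
        x, y, z = toolpath.points[m]
        words = ["G1"]
        fv = int(round(feeds[m]))
        if state_f != fv:
            words.append(f"F{fv}")
            state_f = fv
        words.append(f"X{x:.3f}")
        words.append(f"Y{y:.3f}")
        if state_z is None or z != state_z:
            words.append(f"Z{z:.3f}")
            state_z = z
        if m > 0 and toolpath.kinds[m - 1] == EXTRUDE:
            words.append(f"E{toolpath.e[m]:.5f}")
        motion.append(" ".join(words))
    if fan_pending:  # fan_from_layer beyond the last layer: emit at the end
        motion.append(f"M106 S{int(s.fan_pwm)}")

    return GCodeDocument(preamble=preamble, motion=motion, postamble=postamble)


@dataclass
class ParsedGCode:
    """Result of :func:`parse`: recovered toolpath, settings and leftovers.

    ``settings`` is partial — temperatures, fan and speeds are recovered
    from the text; the extrusion multiplier is not encoded in G-code and
    keeps its default.  ``unknown_lines`` preserves (line number, text) of
    commands outside the emitted dialect.
    """

    toolpath: Toolpath
    settings: PrintSettings
    unknown_lines: list[tuple[int, str]] = field(default_factory=list)


_WORD_RE = re.compile(r"([A-Za-z])([-+]?[0-9]*\.?[0-9]+)")


def _split_words(body: str, line_no: int) -> dict[str, float]:
    words: dict[str, float] = {}
    rest = body
    for letter, value in _WORD_RE.findall(body):
        letter = letter.upper()
        if letter in words:
            raise GCodeParseError(line_no, f"duplicate word {letter!r}")
        words[letter] = float(value)
    stripped = _WORD_RE.sub("", body).replace(" ", "")
    if stripped:
        raise GCodeParseError(line_no, f"unparseable text {stripped!r}")
    return words


def parse(text: str | GCodeDocument) -> ParsedGCode:
    """Parse G-code text back into a toolpath plus partial settings.

    Tracks absolute XYZ/E/F state across ``G1`` lines; a segment extrudes
    iff its E word increases the axis.  Layers are counted at Z increases,
    so surface passes at constant Z stay on their base layer.  Unknown
    commands are preserved verbatim.  Malformed lines (e.g. duplicate
    words) raise :class:`GCodeParseError` with the line number.
    """
    if isinstance(text, GCodeDocument):
        text = text.text

    points: list[tuple[float, float, float]] = []
    kinds: list[str] = []
    layers: list[int] = []
    e_vals: list[float] = []
    feed_ov: list[float] = []
    unknown: list[tuple[int, str]] = []

    x = y = z = None
    e_state = 0.0
    f_state: float | None = None
    layer_count = 0
    extruder_temp: float | None = None
    bed_temp: float | None = None
    extruder_wait = bed_wait = False
    fan_pwm: int | None = None
    fan_from_layer = 1
    first_layer_speed: float | None = None
    body_speed: float | None = None

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        cmd = line.split()[0].upper()
        body = line[len(cmd):]
        if cmd == "G1":
            words = _split_words(body, line_no)
            # unseen axes default to 0 (machine state after G28/G92)
            nx = words.get("X", x if x is not None else 0.0)
            ny = words.get("Y", y if y is not None else 0.0)
            nz = words.get("Z", z if z is not None else 0.0)
            if "F" in words:
                f_state = words["F"]
            if z is None or nz > z:
                layer_count += 1
            ne = words.get("E", e_state)
            if points:
                extruding = ne > e_state
                kinds.append(EXTRUDE if extruding else TRAVEL)
                layers.append(max(layer_count, 1))
                feed_ov.append(f_state if f_state is not None else np.nan)
            points.append((nx, ny, nz))
            e_vals.append(ne)
            if f_state is not None:
                if layer_count <= 1 and first_layer_speed is None:
                    first_layer_speed = f_state
                elif layer_count > 1 and body_speed is None:
                    body_speed = f_state
            x, y, z, e_state = nx, ny, nz, ne
        elif cmd in ("M104", "M109"):
            words = _split_words(body, line_no)
            wait = cmd == "M109"
            if "S" in words and (wait or not extruder_wait):
                extruder_temp = words["S"] if (wait or extruder_temp is None or not extruder_wait) else extruder_temp
                extruder_wait = extruder_wait or wait
        elif cmd in ("M140", "M190"):
            words = _split_words(body, line_no)
            wait = cmd == "M190"
            if "S" in words and (wait or not bed_wait):
                bed_temp = words["S"] if (wait or bed_temp is None or not bed_wait) else bed_temp
                bed_wait = bed_wait or wait
        elif cmd == "M106":
            words = _split_words(body, line_no)
            if fan_pwm is None:
                fan_pwm = int(words.get("S", 255))
                fan_from_layer = layer_count + 1
        elif cmd == "M107":
            if fan_pwm is None and not points:
                fan_pwm = 0
        elif cmd == "G92":
            words = _split_words(body, line_no)
            if "E" in words:
                e_state = words["E"]
        elif cmd in ("G28", "G90", "M82", "M84"):
            pass
        else:
            unknown.append((line_no, raw))

    tp = Toolpath(
        points=np.asarray(points, dtype=float).reshape(-1, 3),
        kinds=np.asarray(kinds, dtype=object),
        layers=np.asarray(layers, dtype=int),
        e=np.asarray(e_vals, dtype=float) if points else None,
        feed=np.asarray(feed_ov, dtype=float) if kinds else None,
    )
    settings = PrintSettings(
        speed=body_speed if body_speed is not None else (first_layer_speed or 600.0),
        first_layer_speed=first_layer_speed if first_layer_speed is not None else 600.0,
        extruder_temp=extruder_temp if extruder_temp is not None else 0.0,
        bed_temp=bed_temp if bed_temp is not None else 0.0,
        fan_pwm=fan_pwm if fan_pwm is not None else 0,
        fan_from_layer=fan_from_layer,
    )
    return ParsedGCode(toolpath=tp, settings=settings, unknown_lines=unknown)


def speed_display(F: float) -> float:
    """Convert a feed rate in mm/min to mm/s rounded to 1 decimal.

    Mirrors the dual "600 mm/min (10.0 mm/s)" notation used in reports.
    """
    if F < 0:
        raise ValueError("feed rate must be >= 0")
    return round(F / 60.0, 1)
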