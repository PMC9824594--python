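"""Layer-wise toolpath geometry for lattice scaffolds.

A scaffold is described by a :class:`ScaffoldSpec` — a square footprint of
side ``L`` filled with parallel strands spaced ``d1`` along X and ``d2``
along Y, stacked ``n_layers`` times at ``layer_height`` increments.  Two
primitive in-plane patterns are provided:

* *rectilinear* — straight parallel strands, alternating 90°/0° between
  layers (the classic scaffold lay-down pattern, giving rectangular
  macropores of ``d1`` x ``d2``);
* *triangular* — triangle-wave (zigzag) strands with apex spacing ``d1``
  along X and amplitude ``d2`` along Y.

All coordinates are absolute millimetres on the print bed; the first layer
sits at ``z = layer_height`` and layer ``k`` at ``z = k * layer_height``.
The generators produce :class:`LayerPath` objects (pure XY polylines with
per-segment extrude/travel kinds) which :func:`stack_layers` concatenates
into a :class:`Toolpath`.  Extrusion (the cumulative E axis) is assigned
separately by :mod:`microscaff.extrusion`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "EXTRUDE",
    "TRAVEL",
    "ScaffoldSpec",
    "LayerPath",
    "Toolpath",
    "generate_rectilinear_layer",
    "generate_triangular_layer",
    "stack_layers",
    "build_toolpath",
]

EXTRUDE = "extrude"
TRAVEL = "travel"

_PATTERNS = ("rectilinear", "triangular")


@dataclass(frozen=True)
class ScaffoldSpec:
    """Parametric description of a square lattice scaffold.

    Parameters
    ----------
    pattern:
        In-plane strand pattern, ``"rectilinear"`` or ``"triangular"``.
    L:
        Side length of the square footprint, mm.
    d1:
        Strand spacing measured along X, mm.
    d2:
        Strand spacing measured along Y, mm.
    layer_height:
        Z increment between deposited layers, mm.
    n_layers:
        Number of stacked layers (>= 1).
    origin:
        XY offset of the scaffold's lower-left corner on the bed, mm.
    angle_sequence:
        Per-layer strand directions for the rectilinear pattern, cycled
        over layers.  ``90`` means strands run along Y spaced ``d1`` in X;
        ``0`` means strands run along X spaced ``d2`` in Y.  The default
        ``(90, 0)`` is the standard 0°/90° alternation.
    links:
        Whether the short boustrophedon links joining adjacent strands are
        ``"extrude"`` (continuous deposition, default) or ``"travel"``.
    """

    pattern: str = "rectilinear"
    L: float = 20.0
    d1: float = 1.0
    d2: float = 2.5
    layer_height: float = 0.20
    n_layers: int = 4
    origin: tuple[float, float] = (0.0, 0.0)
    angle_sequence: tuple[int, ...] = (90, 0)
    links: str = EXTRUDE

    def __post_init__(self) -> None:
        if self.pattern not in _PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if not (self.L > 0 and self.d1 > 0 and self.d2 > 0):
            raise ValueError("L, d1 and d2 must be positive")
        if not self.layer_height > 0:
            raise ValueError("layer_height must be positive")
        if not (isinstance(self.n_layers, (int, np.integer)) and self.n_layers >= 1):
            raise ValueError("n_layers must be a positive integer")
        if self.d1 > self.L or self.d2 > self.L:
            raise ValueError("strand spacings d1, d2 cannot exceed L")
        if self.links not in (EXTRUDE, TRAVEL):
            raise ValueError("links must be 'extrude' or 'travel'")
        if not all(a in (0, 90) for a in self.angle_sequence):
            raise ValueError("angle_sequence entries must be 0 or 90")


@dataclass
class LayerPath:
    """A single layer's XY polyline with per-segment deposition kinds."""

    z: float
    vertices: np.ndarray  # (N, 2) XY, mm
    segment_kinds: np.ndarray  # (N-1,) EXTRUDE | TRAVEL

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.segment_kinds = np.asarray(self.segment_kinds, dtype=object)
        if self.z <= 0:
            raise ValueError("layer z must be positive")
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array")
        if len(self.segment_kinds) != len(self.vertices) - 1:
            raise ValueError("segment_kinds length must be n_vertices - 1")
        steps = np.diff(self.vertices, axis=0)
        if len(steps) and np.any(np.all(steps == 0.0, axis=1)):
            raise ValueError("consecutive duplicate vertices are forbidden")


@dataclass
class Toolpath:
    """Ordered motion segments of a whole print.

    ``points`` are the (N, 3) absolute XYZ targets; segment ``i`` runs from
    ``points[i]`` to ``points[i+1]`` with kind ``kinds[i]`` and belongs to
    1-based layer ``layers[i]``.  ``e`` (assigned by the extrusion module)
    is the cumulative extruder-axis position at each point, mm.  ``feed``
    holds optional per-segment feed-rate overrides in mm/min (NaN means
    "use the print settings' default for that layer").
    """

    points: np.ndarray
    kinds: np.ndarray
    layers: np.ndarray
    e: np.ndarray | None = None
    feed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.kinds = np.asarray(self.kinds, dtype=object)
        self.layers = np.asarray(self.layers, dtype=int)
        n_seg = max(len(self.points) - 1, 0)
        if len(self.kinds) != n_seg or len(self.layers) != n_seg:
            raise ValueError("kinds/layers must have n_points - 1 entries")
        if self.e is not None:
            self.e = np.asarray(self.e, dtype=float)
            if len(self.e) != len(self.points):
                raise ValueError("e must have one entry per point")
        if self.feed is not None:
            self.feed = np.asarray(self.feed, dtype=float)
            if len(self.feed) != n_seg:
                raise ValueError("feed must have one entry per segment")

    # -- basic queries ---------------------------------------------------

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_segments(self) -> int:
        return max(len(self.points) - 1, 0)

    def segment_lengths(self) -> np.ndarray:
        """Euclidean 3D length of every segment, mm."""
        if self.n_segments == 0:
            return np.zeros(0)
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    def extrude_mask(self) -> np.ndarray:
        return np.asarray([k == EXTRUDE for k in self.kinds], dtype=bool)

    def distinct_z(self) -> np.ndarray:
        """Sorted unique Z values visited by the path."""
        if self.n_points == 0:
            return np.zeros(0)
        return np.unique(self.points[:, 2])

    @property
    def total_e(self) -> float:
        if self.e is None:
            raise ValueError("extrusion has not been assigned to this toolpath")
        return float(self.e[-1]) if len(self.e) else 0.0

    def total_extrude_length(self) -> float:
        lengths = self.segment_lengths()
        mask = self.extrude_mask()
        return float(lengths[mask].sum()) if self.n_segments else 0.0

    def reset_extrusion(self) -> "Toolpath":
        """Return a copy with the E axis cleared (required before re-assigning)."""
        return replace(self, e=None)

    @classmethod
    def empty(cls) -> "Toolpath":
        return cls(
            points=np.zeros((0, 3)),
            kinds=np.zeros(0, dtype=object),
            layers=np.zeros(0, dtype=int),
        )


# ---------------------------------------------------------------------------
# layer generators


def _strand_positions(L: float, spacing: float) -> np.ndarray:
    """Strand coordinates 0, spacing, ..., L (round(L/spacing)+1 strands).

    When ``L`` is not an integer multiple of ``spacing`` the positions are
    spread evenly over [0, L] so the strand field always spans the full
    footprint (slicer-style spacing adjustment).
    """
    n_intervals = max(int(round(L / spacing)), 1)
    return np.linspace(0.0, L, n_intervals + 1)


def _check_layer_index(spec: ScaffoldSpec, layer_index: int) -> None:
    if not (1 <= layer_index <= spec.n_layers):
        raise IndexError(
            f"layer_index {layer_index} out of range 1..{spec.n_layers}"
        )


def _serpentine(positions: np.ndarray, L: float, along_y: bool, links: str):
    """Boustrophedon vertices for parallel strands at the given positions."""
    verts: list[tuple[float, float]] = []
    for i, p in enumerate(positions):
        lo, hi = (0.0, L) if i % 2 == 0 else (L, 0.0)
        a = (p, lo) if along_y else (lo, p)
        b = (p, hi) if along_y else (hi, p)
        verts.extend([a, b])
    # segments alternate strand, link, strand, link, ...
    kinds = [EXTRUDE if i % 2 == 0 else links for i in range(len(verts) - 1)]
    return np.asarray(verts, dtype=float), np.asarray(kinds, dtype=object)


def generate_rectilinear_layer(spec: ScaffoldSpec, layer_index: int) -> LayerPath:
    """Generate one rectilinear layer as a serpentine of parallel strands.

    The strand direction follows ``spec.angle_sequence`` cycled over the
    layer index: 90° layers run strands along Y spaced ``d1`` in X, 0°
    layers run strands along X spaced ``d2`` in Y.  Strand ends are joined
    in boustrophedon order by short links along the footprint boundary.
    The bounding box of extruding segments is exactly ``L`` x ``L``.
    """
    _check_layer_index(spec, layer_index)
    angle = spec.angle_sequence[(layer_index - 1) % len(spec.angle_sequence)]
    along_y = angle == 90
    spacing = spec.d1 if along_y else spec.d2
    positions = _strand_positions(spec.L, spacing)
    verts, kinds = _serpentine(positions, spec.L, along_y, spec.links)
    verts = verts + np.asarray(spec.origin)
    return LayerPath(z=layer_index * spec.layer_height, vertices=verts, segment_kinds=kinds)


def generate_triangular_layer(spec: ScaffoldSpec, layer_index: int) -> LayerPath:
    """Generate one triangular (triangle-wave) layer.

    Each row is a zigzag with apex spacing ``d1`` along X and amplitude
    ``d2`` along Y; rows tile the square at spacing ``d2`` and are visited
    in boustrophedon order.  Row-to-row links are travel moves so that
    every extruding segment is a wave flank of slope ``±d2 / (d1 / 2)``.
    """
    _check_layer_index(spec, layer_index)
    n_half = max(int(round(2 * spec.L / spec.d1)), 1)
    n_rows = max(int(round(spec.L / spec.d2)), 1)
    amp = spec.L / n_rows
    xs = np.linspace(0.0, spec.L, n_half + 1)
    verts: list[tuple[float, float]] = []
    kinds: list[str] = []
    for j in range(n_rows):
        base = j * amp
        ys = np.where(np.arange(n_half + 1) % 2 == 0, base, base + amp)
        row = np.column_stack([xs, ys])
        if j % 2 == 1:
            row = row[::-1]
        if not verts:
            verts.extend(map(tuple, row))
            kinds.extend([EXTRUDE] * (len(row) - 1))
        elif np.allclose(row[0], verts[-1]):
            # wave ended exactly where the next row starts: merge seamlessly
            verts.extend(map(tuple, row[1:]))
            kinds.extend([EXTRUDE] * (len(row) - 1))
        else:
            verts.append(tuple(row[0]))
            kinds.append(TRAVEL)
            verts.extend(map(tuple, row[1:]))
            kinds.extend([EXTRUDE] * (len(row) - 1))
    verts_arr = np.asarray(verts, dtype=float) + np.asarray(spec.origin)
    return LayerPath(
        z=layer_index * spec.layer_height,
        vertices=verts_arr,
        segment_kinds=np.asarray(kinds, dtype=object),
    )


def stack_layers(spec: ScaffoldSpec, layers: Sequence[LayerPath]) -> Toolpath:
    """Stack per-layer paths into one continuous toolpath.

    Consecutive layers are joined by a travel move from the end of one
    layer to the start of the next (at the new Z).  The resulting set of
    distinct Z values is ``{h, 2h, ..., n_layers*h}``.  The E axis is not
    assigned here — see :func:`microscaff.extrusion.assign_extrusion`.
    """
    if not layers:
        raise ValueError("cannot stack an empty layer list")
    pts: list[np.ndarray] = []
    kinds: list[str] = []
    lay: list[int] = []
    for k, lp in enumerate(layers, start=1):
        v3 = np.column_stack([lp.vertices, np.full(len(lp.vertices), lp.z)])
        if k == 1:
            pts.append(v3)
        else:
            pts.append(v3)
            kinds.append(TRAVEL)  # hop to the new layer's start point
            lay.append(k)
        kinds.extend(lp.segment_kinds.tolist())
        lay.extend([k] * len(lp.segment_kinds))
    points = np.vstack(pts)
    return Toolpath(
        points=points,
        kinds=np.asarray(kinds, dtype=object),
        layers=np.asarray(lay, dtype=int),
    )


def build_toolpath(spec: ScaffoldSpec) -> Toolpath:
    """Generate all layers of ``spec`` and stack them."""
    gen = (
        generate_rectilinear_layer
        if spec.pattern == "rectilinear"
        else generate_triangular_layer
    )
    return stack_layers(spec, [gen(spec, k) for k in range(1, spec.n_layers + 1)])
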