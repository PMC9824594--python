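"""Randomized toolpaths for fuzzing the emit/parse/extrusion pipeline.

These are not physical scaffolds: just well-formed multi-layer paths with
random XY walks and mixed extrude/travel segments, used by round-trip and
volume-conservation checks.
"""

from __future__ import annotations

import numpy as np

from .geometry import EXTRUDE, TRAVEL, Toolpath

__all__ = ["random_toolpath"]


def random_toolpath(
    rng: np.random.Generator,
    n_layers: int | None = None,
    max_segments_per_layer: int = 12,
    layer_height: float = 0.2,
    extrude_prob: float = 0.8,
) -> Toolpath:
    """Draw a random well-formed toolpath (E unassigned).

    Layers hold 3..max_segments_per_layer segments of random XY steps
    (length 0.2-11 mm); each segment extrudes with ``extrude_prob``.
    Layer hops are travel moves, as in generated scaffold paths.
    """
    if n_layers is None:
        n_layers = int(rng.integers(1, 4))
    points: list[tuple[float, float, float]] = []
    kinds: list[str] = []
    layers: list[int] = []
    pos = rng.uniform(0.0, 40.0, 2)
    for k in range(1, n_layers + 1):
        z = k * layer_height
        if k == 1:
            points.append((pos[0], pos[1], z))
        else:
            pos = pos + rng.uniform(1.0, 5.0, 2)
            points.append((pos[0], pos[1], z))
            kinds.append(TRAVEL)
            layers.append(k)
        n_seg = int(rng.integers(3, max_segments_per_layer + 1))
        for _ in range(n_seg):
            step = rng.uniform(-8.0, 8.0, 2)
            while np.linalg.norm(step) < 0.2:
                step = rng.uniform(-8.0, 8.0, 2)
            pos = pos + step
            points.append((pos[0], pos[1], z))
            kinds.append(EXTRUDE if rng.random() < extrude_prob else TRAVEL)
            layers.append(k)
    return Toolpath(
        points=np.asarray(points),
        kinds=np.asarray(kinds, dtype=object),
        layers=np.asarray(layers, dtype=int),
    )
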