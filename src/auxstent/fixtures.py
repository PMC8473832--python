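"""Canonical unit-cell density fixtures for tests and demos.

Each fixture is an analytic signed-distance-like field on the unit cell,
smoothed to the standard interface band, mimicking the morphology classes
that volume-constrained runs produce (open cells, crossed struts, flow-
aligned bars, re-entrant frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .levelset import DensityField, cell_centers, smoothed_heaviside

__all__ = ["FixtureSpec", "make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = (
    "full_solid",
    "empty",
    "centered_hole",
    "cross",
    "horizontal_bars",
    "reentrant",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Named canonical geometry with its shape parameters."""

    name: str
    radius: float = 0.2  # centered_hole
    bar_width: float = 0.15  # cross / horizontal_bars
    strut_width: float = 0.08  # reentrant

    def __post_init__(self):
        if self.name not in FIXTURE_NAMES:
            raise ValueError(f"unknown fixture {self.name!r}; choose from {FIXTURE_NAMES}")


def _segment_distance(p: np.ndarray, a, b) -> np.ndarray:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ab = b - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(p - (a + t[:, None] * ab), axis=1)


def _phi(spec: FixtureSpec, p: np.ndarray) -> np.ndarray:
    x, y = p[:, 0], p[:, 1]
    if spec.name == "full_solid":
        return np.full(len(p), 0.5)
    if spec.name == "empty":
        return np.full(len(p), -0.5)
    if spec.name == "centered_hole":
        return np.hypot(x - 0.5, y - 0.5) - spec.radius
    if spec.name == "cross":
        w = spec.bar_width / 2.0
        return np.maximum(w - np.abs(y - 0.5), w - np.abs(x - 0.5))
    if spec.name == "horizontal_bars":
        w = spec.bar_width / 2.0
        return np.maximum(w - np.abs(y - 0.25), w - np.abs(y - 0.75))
    if spec.name == "reentrant":
        # two flow-aligned bars joined by inward-pointing chevrons: the
        # re-entrant (auxetic) motif volume-constrained runs tend toward
        w = spec.strut_width
        segs = [
            ((0.0, 0.2), (1.0, 0.2)),
            ((0.0, 0.8), (1.0, 0.8)),
            ((0.15, 0.2), (0.5, 0.5)),
            ((0.85, 0.2), (0.5, 0.5)),
            ((0.15, 0.8), (0.5, 0.5)),
            ((0.85, 0.8), (0.5, 0.5)),
        ]
        d = np.min([_segment_distance(p, a, b) for a, b in segs], axis=0)
        return w - d
    raise AssertionError


def make_fixture(
    spec: FixtureSpec | str, nx: int, smoothing_cells: float = 2.0
) -> DensityField:
    """Analytic density field of a named geometry on an nx-by-nx element grid."""
    if isinstance(spec, str):
        spec = FixtureSpec(spec)
    p = cell_centers(nx, nx)
    return smoothed_heaviside(_phi(spec, p), smoothing_cells / nx)
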