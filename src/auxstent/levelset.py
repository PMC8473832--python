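"""Parametric level-set representation of the 2D unit-cell microstructure.

The microstructure boundary is the zero contour of a scalar field
``Phi(x) = sum_i phi_i(x) alpha_i`` expanded in compactly supported radial
basis functions (Wendland C2) centred at fixed knots.  ``Phi > 0`` marks
solid material, ``Phi < 0`` void/fluid.  Because the knots are fixed, the
design is fully described by the coefficient vector ``alpha``; boundary
evolution becomes an ordinary update of ``alpha`` instead of a
Hamilton-Jacobi PDE solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as spla

__all__ = [
    "KnotGrid",
    "LevelSetDesign",
    "DensityField",
    "wendland_c2",
    "basis_matrix",
    "evaluate_level_set",
    "smoothed_heaviside",
    "initialize_design",
    "update_coefficients",
    "grid_points",
    "cell_centers",
]


def wendland_c2(r):
    """Wendland C2 compactly supported radial basis value.

    Parameters
    ----------
    r : array_like
        Radial distance already normalized by the support radius; must be
        nonnegative.  ``r = 0`` is the knot itself, ``r >= 1`` is outside
        the compact support.

    Returns
    -------
    ndarray or float
        ``(1 - r)^4 (4 r + 1)`` for ``r <= 1`` and 0 beyond; C2-continuous
        across ``r = 1``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("normalized radius must be nonnegative")
    out = np.where(r < 1.0, (1.0 - np.minimum(r, 1.0)) ** 4 * (4.0 * r + 1.0), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class KnotGrid:
    """Fixed CSRBF knots on the closed unit cell [0,1]x[0,1]."""

    positions: np.ndarray  # (N, 2)
    support_radius: float

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "positions", pos)
        if pos.shape[0] < 4 or pos.shape[1] != 2:
            raise ValueError("need at least 4 knots with 2D positions")
        if pos.min() < -1e-12 or pos.max() > 1.0 + 1e-12:
            raise ValueError("knots must lie inside the closed unit cell")
        if not self.support_radius > 0:
            raise ValueError("support radius must be positive")

    @property
    def count(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def regular(cls, nx: int, ny: int | None = None, support_cells: float = 3.0) -> "KnotGrid":
        """Knots at the nodes of an ``nx x ny`` analysis grid.

        The support radius defaults to three grid spacings, which keeps the
        interpolation matrix sparse yet guarantees every point of the cell
        is covered by several knots.
        """
        ny = nx if ny is None else ny
        pos = grid_points(nx, ny)
        h = 1.0 / min(nx, ny)
        return cls(pos, support_cells * h)


def grid_points(nx: int, ny: int | None = None) -> np.ndarray:
    """Nodes of a uniform (nx x ny)-element grid on the unit cell, row-major in y."""
    ny = nx if ny is None else ny
    x = np.linspace(0.0, 1.0, nx + 1)
    y = np.linspace(0.0, 1.0, ny + 1)
    X, Y = np.meshgrid(x, y, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel()])


def cell_centers(nx: int, ny: int | None = None) -> np.ndarray:
    """Element midpoints of a uniform (nx x ny)-element grid on the unit cell."""
    ny = nx if ny is None else ny
    x = (np.arange(nx) + 0.5) / nx
    y = (np.arange(ny) + 0.5) / ny
    X, Y = np.meshgrid(x, y, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel()])


def basis_matrix(knots: KnotGrid, points: np.ndarray) -> sparse.csr_matrix:
    """Sparse CSRBF interpolation matrix B with B[p, i] = phi_i(x_p).

    Only knot/point pairs closer than the support radius contribute, so the
    matrix has O(points) nonzeros for a regular knot layout.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    from scipy.spatial import cKDTree

    tree = cKDTree(knots.positions)
    pairs = tree.query_ball_point(points, knots.support_radius)
    rows, cols, vals = [], [], []
    for p, idx in enumerate(pairs):
        if not idx:
            continue
        idx = np.asarray(idx, dtype=int)
        r = np.linalg.norm(points[p] - knots.positions[idx], axis=1) / knots.support_radius
        rows.append(np.full(idx.size, p))
        cols.append(idx)
        vals.append(wendland_c2(r))
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
    B = sparse.csr_matrix(
        (vals, (rows, cols)) if len(rows) else ((), ((), ())),
        shape=(points.shape[0], knots.count),
    )
    return B


@dataclass(frozen=True)
class LevelSetDesign:
    """A microstructure: knots plus the CSRBF expansion coefficients."""

    knots: KnotGrid
    alpha: np.ndarray
    alpha_bounds: tuple[float, float] = (-1e3, 1e3)

    def __post_init__(self):
        a = np.asarray(self.alpha, dtype=float).ravel()
        object.__setattr__(self, "alpha", a)
        if a.size != self.knots.count:
            raise ValueError(
                f"alpha length {a.size} does not match knot count {self.knots.count}"
            )
        if not np.all(np.isfinite(a)):
            raise ValueError("alpha must be finite")
        lo, hi = self.alpha_bounds
        if lo >= hi:
            raise ValueError("alpha bounds must satisfy lo < hi")


def evaluate_level_set(design: LevelSetDesign, points: np.ndarray, B=None) -> np.ndarray:
    """Evaluate Phi at ``points``; pass a precomputed basis matrix to amortize."""
    if B is None:
        B = basis_matrix(design.knots, points)
    if B.shape[1] != design.alpha.size:
        raise ValueError("basis matrix and alpha dimensions differ")
    return np.asarray(B @ design.alpha).ravel()


@dataclass(frozen=True)
class DensityField:
    """Smoothed material indicator H(Phi) and its derivative delta(Phi)."""

    H: np.ndarray
    delta: np.ndarray
    smoothing_width: float


def smoothed_heaviside(phi: np.ndarray, smoothing_width: float) -> DensityField:
    """Cubic-polynomial smoothed Heaviside of the level-set values.

    H = 0 for phi <= -w, 1 for phi >= w, and the odd-symmetric cubic
    ``1/2 + (3/4)(phi/w) - (1/4)(phi/w)^3`` inside the band; delta = dH/dphi
    vanishes identically outside ``|phi| < w`` and integrates to one across
    a transect where phi sweeps the band linearly.
    """
    if not smoothing_width > 0:
        raise ValueError("smoothing width must be positive")
    phi = np.asarray(phi, dtype=float)
    t = np.clip(phi / smoothing_width, -1.0, 1.0)
    H = 0.5 + 0.75 * t - 0.25 * t**3
    inside = np.abs(phi) < smoothing_width
    delta = np.where(inside, 0.75 * (1.0 - t**2) / smoothing_width, 0.0)
    return DensityField(H=H, delta=delta, smoothing_width=smoothing_width)


def holes_signed_distance(points: np.ndarray, holes) -> np.ndarray:
    """Signed distance of 'solid sheet with circular holes': positive in solid."""
    points = np.atleast_2d(points)
    if not holes:
        return np.full(points.shape[0], 0.5)
    d = np.full(points.shape[0], np.inf)
    for (cx, cy), r in holes:
        if not (0.0 <= cx <= 1.0 and 0.0 <= cy <= 1.0):
            raise ValueError("hole centers must lie inside the unit cell")
        d = np.minimum(d, np.hypot(points[:, 0] - cx, points[:, 1] - cy) - r)
    return d


def initialize_design(
    knots: KnotGrid,
    hole_pattern=(),
    alpha_bounds: tuple[float, float] = (-1e3, 1e3),
) -> LevelSetDesign:
    """Fit alpha so the CSRBF expansion interpolates the signed distance of
    a solid cell punctured by the given circular holes.

    The fit collocates at the knots themselves; the Wendland interpolation
    matrix is symmetric positive definite for distinct knots, so the solve
    is direct and the projection is idempotent (re-fitting a field already
    in the CSRBF space reproduces it).
    """
    target = holes_signed_distance(knots.positions, list(hole_pattern))
    A = basis_matrix(knots, knots.positions).tocsc()
    try:
        alpha = spla.spsolve(A, target)
    except Exception as exc:  # pragma: no cover - conditioning safeguard
        raise RuntimeError(
            "singular CSRBF fitting system; increase the support radius"
        ) from exc
    if not np.all(np.isfinite(alpha)):
        raise RuntimeError("singular CSRBF fitting system; increase the support radius")
    return LevelSetDesign(knots=knots, alpha=alpha, alpha_bounds=alpha_bounds)


def fit_alpha(knots: KnotGrid, phi_at_knots: np.ndarray) -> np.ndarray:
    """Project an arbitrary field sampled at the knots onto the CSRBF space."""
    A = basis_matrix(knots, knots.positions).tocsc()
    return np.asarray(spla.spsolve(A, np.asarray(phi_at_knots, float))).ravel()


def update_coefficients(
    design: LevelSetDesign, descent_direction: np.ndarray, step: float
) -> tuple[LevelSetDesign, bool]:
    """Projected coefficient update alpha' = clip(alpha + step * d, bounds).

    Returns the updated design and a stagnation flag that is True when the
    bound projection cancelled the entire step (every component clipped
    back to its previous value).
    """
    d = np.asarray(descent_direction, dtype=float).ravel()
    if d.size != design.alpha.size:
        raise ValueError("direction length does not match design")
    if not np.all(np.isfinite(d)):
        raise ValueError("descent direction must be finite")
    if not step > 0:
        raise ValueError("step must be positive")
    lo, hi = design.alpha_bounds
    new_alpha = np.clip(design.alpha + step * d, lo, hi)
    moved = np.any(new_alpha != design.alpha) or np.all(d == 0.0)
    stagnated = bool(np.any(d != 0.0) and not np.any(new_alpha != design.alpha))
    return replace(design, alpha=new_alpha), stagnated
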