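"""Macroscale stent sheet: compliance of a uniform array of effective cells.

The flattened stent is a rectangular sheet of (by default) 20 x 20 unit
cells, each carrying the homogenized constitutive matrix of the current
microstructure (one Q4 element per cell).  Loading mimics the stent's
working state: vertical displacements are fixed on the top and bottom
edges, and a unit relative horizontal stretch is prescribed between the
left and right edges (-1/2 on the left, +1/2 on the right).  The
compliance objective is the stored strain energy

    J_MA = 1/2 int eps(u)^T DH eps(u) dOmega

and its design sensitivity is propagated through dDH/dalpha with the
displacement field frozen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as spla

from .elasticity import EffectiveElasticity, quad_stiffness

__all__ = ["MacroModel", "MacroSolution", "macro_compliance", "compliance_sensitivity"]


@dataclass(frozen=True)
class MacroModel:
    """Uniform-cell macro sheet with stretch boundary conditions."""

    nx: int = 20
    ny: int = 20
    stretch: float = 1.0  # total prescribed relative horizontal displacement

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1:
            raise ValueError("cell counts must be positive")

    @property
    def n_nodes(self) -> int:
        return (self.nx + 1) * (self.ny + 1)

    def nodes(self) -> np.ndarray:
        x = np.arange(self.nx + 1, dtype=float)
        y = np.arange(self.ny + 1, dtype=float)
        X, Y = np.meshgrid(x, y, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel()])

    def connectivity(self) -> np.ndarray:
        ex, ey = np.meshgrid(np.arange(self.nx), np.arange(self.ny), indexing="ij")
        ex, ey = ex.ravel(), ey.ravel()
        stride = self.ny + 1
        n00 = ex * stride + ey
        return np.column_stack([n00, n00 + stride, n00 + stride + 1, n00 + 1])

    def boundary_conditions(self) -> tuple[np.ndarray, np.ndarray]:
        """(prescribed dof ids, prescribed values); disjoint by construction."""
        nodes = self.nodes()
        dofs, vals = [], []
        left = np.isclose(nodes[:, 0], 0.0)
        right = np.isclose(nodes[:, 0], self.nx)
        bottom = np.isclose(nodes[:, 1], 0.0)
        top = np.isclose(nodes[:, 1], self.ny)
        for n in np.flatnonzero(left):
            dofs.append(2 * n)
            vals.append(-self.stretch / 2.0)
        for n in np.flatnonzero(right):
            dofs.append(2 * n)
            vals.append(+self.stretch / 2.0)
        for n in np.flatnonzero(bottom | top):
            dofs.append(2 * n + 1)
            vals.append(0.0)
        dofs = np.asarray(dofs, dtype=int)
        vals = np.asarray(vals, dtype=float)
        if len(np.unique(dofs)) != len(dofs):
            raise AssertionError("prescribed dof sets overlap")
        return dofs, vals


@dataclass(frozen=True)
class MacroSolution:
    """Displacements and per-Gauss-point strains of the macro solve."""

    u: np.ndarray  # (n_nodes, 2)
    gauss_strains: np.ndarray  # (n_elem, 4, 3)
    gauss_weights: np.ndarray  # (4,) integration measures
    compliance: float


def _assemble(model: MacroModel, DH: np.ndarray):
    ke, Bg, wdet = quad_stiffness(DH, 1.0, 1.0)
    conn = model.connectivity()
    edofs = np.empty((conn.shape[0], 8), dtype=int)
    edofs[:, 0::2] = 2 * conn
    edofs[:, 1::2] = 2 * conn + 1
    ndof = 2 * model.n_nodes
    rows = np.repeat(edofs, 8, axis=1).ravel()
    cols = np.tile(edofs, (1, 8)).ravel()
    vals = np.tile(ke.ravel(), conn.shape[0])
    K = sparse.coo_matrix((vals, (rows, cols)), shape=(ndof, ndof)).tocsc()
    return K, edofs, Bg, wdet


def macro_compliance(
    eff: EffectiveElasticity | np.ndarray, model: MacroModel
) -> MacroSolution:
    """Solve the macro elastostatic problem and return its strain energy."""
    DH = eff.DH if isinstance(eff, EffectiveElasticity) else np.asarray(eff, float)
    diag = np.diag(DH)
    if np.any(diag <= 0):
        bad = [f"D{i+1}{i+1}={diag[i]:.3g}" for i in range(3) if diag[i] <= 0]
        raise ValueError("degenerate effective stiffness: " + ", ".join(bad))
    K, edofs, Bg, wdet = _assemble(model, DH)
    ndof = 2 * model.n_nodes
    pdofs, pvals = model.boundary_conditions()
    free = np.setdiff1d(np.arange(ndof), pdofs)
    u = np.zeros(ndof)
    u[pdofs] = pvals
    rhs = -K[np.ix_(free, pdofs)] @ pvals
    u[free] = spla.spsolve(K[np.ix_(free, free)].tocsc(), rhs)

    ue = u[edofs]  # (n_elem, 8)
    strains = np.einsum("gab,eb->ega", Bg, ue)  # (n_elem, 4, 3)
    energy = 0.5 * np.einsum("ega,ab,egb,g->", strains, DH, strains, wdet)
    return MacroSolution(
        u=u.reshape(-1, 2),
        gauss_strains=strains,
        gauss_weights=wdet,
        compliance=float(energy),
    )


def compliance_sensitivity(sol: MacroSolution, dDH_dalpha: np.ndarray) -> np.ndarray:
    """Frozen-displacement derivative of the macro compliance.

    dJ/dalpha_n = 1/2 int eps^T (dDH/dalpha_n) eps dOmega with the current
    displacement field held fixed; linear in dDH/dalpha.
    """
    dDH = np.asarray(dDH_dalpha, dtype=float)
    if dDH.ndim != 3 or dDH.shape[1:] != (3, 3):
        raise ValueError("dDH_dalpha must be (N, 3, 3)")
    return 0.5 * np.einsum(
        "ega,nab,egb,g->n", sol.gauss_strains, dDH, sol.gauss_strains, sol.gauss_weights
    )
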