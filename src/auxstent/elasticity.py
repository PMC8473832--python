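"""Periodic homogenization of the unit cell's effective elasticity.

The microstructure is analysed on a fixed uniform grid of 4-node
quadrilaterals in plane stress.  Three unit test strains (11, 22, 12 in
Voigt order with engineering shear) are imposed through the standard
cell problems with periodic boundary conditions, and the effective
stiffness follows from the averaged strain energy of the corrected
fields:

    DH_ij = (1/|Y|) sum_e (u0_i - chi_i)^T k_e (u0_j - chi_j)

with the element stiffness scaled by the material indicator
``max(H_e, ersatz)`` so void elements keep a tiny ersatz stiffness.
The two directional Poisson's ratios are read off the Voigt matrix as
Mu1 = D12/D11 (loading along the flow axis) and Mu2 = D12/D22.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as spla

from .levelset import (
    DensityField,
    LevelSetDesign,
    basis_matrix,
    cell_centers,
    grid_points,
)

__all__ = [
    "BaseMaterial",
    "MicroMesh2D",
    "EffectiveElasticity",
    "UnitStrainFields",
    "base_elasticity",
    "quad_stiffness",
    "homogenize_elasticity",
    "poisson_ratios",
    "elasticity_sensitivity",
]


@dataclass(frozen=True)
class BaseMaterial:
    """Solid constituent: isotropic, plane stress, with an ersatz floor for void."""

    E: float = 1.0
    nu: float = 0.3
    plane_stress: bool = True
    ersatz: float = 1e-4

    def __post_init__(self):
        if not self.E > 0:
            raise ValueError("Young's modulus must be positive")
        if not -1.0 < self.nu < 0.5:
            raise ValueError("Poisson's ratio must lie in (-1, 0.5)")
        if not 0 < self.ersatz <= 1e-3:
            raise ValueError("ersatz stiffness must be in (0, 1e-3]")


def base_elasticity(material: BaseMaterial) -> np.ndarray:
    """Plane-stress constitutive matrix of the solid in Voigt order (11, 22, 12)."""
    E, nu = material.E, material.nu
    if material.plane_stress:
        return (E / (1.0 - nu**2)) * np.array(
            [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]]
        )
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    return np.array(
        [[lam + 2 * mu, lam, 0.0], [lam, lam + 2 * mu, 0.0], [0.0, 0.0, mu]]
    )


def quad_stiffness(D: np.ndarray, hx: float, hy: float):
    """Stiffness (8x8) and strain-displacement operators of a Q4 rectangle.

    Returns ``(ke, B_gauss, wdet)`` with the four 2x2 Gauss-point B matrices,
    plus the centroid B used for elementwise strain recovery.
    """
    gp = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    ke = np.zeros((8, 8))
    Bs, wdet = [], []
    detJ = hx * hy / 4.0
    for xi in gp:
        for eta in gp:
            B = _bmat(xi, eta, hx, hy)
            ke += B.T @ D @ B * detJ
            Bs.append(B)
            wdet.append(detJ)
    return ke, np.array(Bs), np.array(wdet)


def _bmat(xi: float, eta: float, hx: float, hy: float) -> np.ndarray:
    # shape function derivatives on the parent square, nodes CCW from (-1,-1)
    dNdxi = 0.25 * np.array(
        [-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)]
    )
    dNdeta = 0.25 * np.array(
        [-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)]
    )
    dNdx = dNdxi * 2.0 / hx
    dNdy = dNdeta * 2.0 / hy
    B = np.zeros((3, 8))
    B[0, 0::2] = dNdx
    B[1, 1::2] = dNdy
    B[2, 0::2] = dNdy
    B[2, 1::2] = dNdx
    return B


@dataclass(frozen=True)
class MicroMesh2D:
    """Uniform Q4 grid on the unit cell with periodic opposite-edge pairing."""

    nx: int
    ny: int

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1:
            raise ValueError("element counts must be positive")

    @property
    def n_elements(self) -> int:
        return self.nx * self.ny

    @property
    def spacing(self) -> tuple[float, float]:
        return 1.0 / self.nx, 1.0 / self.ny

    @property
    def nodes(self) -> np.ndarray:
        return grid_points(self.nx, self.ny)

    @property
    def element_centers(self) -> np.ndarray:
        return cell_centers(self.nx, self.ny)

    def connectivity(self) -> np.ndarray:
        """(n_elem, 4) node ids, CCW; element index e = ex * ny + ey."""
        ex, ey = np.meshgrid(np.arange(self.nx), np.arange(self.ny), indexing="ij")
        ex, ey = ex.ravel(), ey.ravel()
        stride = self.ny + 1
        n00 = ex * stride + ey
        return np.column_stack([n00, n00 + stride, n00 + stride + 1, n00 + 1])

    def periodic_map(self) -> np.ndarray:
        """Map every node id to its periodic master (right/top edges folded back)."""
        ix, iy = np.meshgrid(
            np.arange(self.nx + 1), np.arange(self.ny + 1), indexing="ij"
        )
        return ((ix % self.nx) * self.ny + (iy % self.ny)).ravel()

    @property
    def n_master_nodes(self) -> int:
        return self.nx * self.ny


@dataclass(frozen=True)
class UnitStrainFields:
    """Periodic corrector displacements for the three unit test strains."""

    chi: np.ndarray  # (3, n_nodes, 2) full-grid corrector fields
    element_energies: np.ndarray  # (n_elem, 3, 3) beta per element (solid-material energy density)


@dataclass(frozen=True)
class EffectiveElasticity:
    """Homogenized 3x3 Voigt stiffness and the two directional Poisson's ratios."""

    DH: np.ndarray
    Mu1: float
    Mu2: float
    fields: UnitStrainFields | None = field(default=None, repr=False, compare=False)


def _unit_strain_displacements(mesh: MicroMesh2D) -> np.ndarray:
    """Element corner displacements u0 (3 cases, 8 dofs) of the unit test strains."""
    hx, hy = mesh.spacing
    corners = np.array([[0, 0], [hx, 0], [hx, hy], [0, hy]], dtype=float)
    u0 = np.zeros((3, 8))
    # eps = (1,0,0): u = (x, 0); eps = (0,1,0): u = (0, y)
    u0[0, 0::2] = corners[:, 0]
    u0[1, 1::2] = corners[:, 1]
    # engineering shear gamma_xy = 1: u = (y/2, x/2)
    u0[2, 0::2] = corners[:, 1] / 2.0
    u0[2, 1::2] = corners[:, 0] / 2.0
    return u0


def homogenize_elasticity(
    density: DensityField,
    material: BaseMaterial,
    mesh: MicroMesh2D,
) -> EffectiveElasticity:
    """Solve the three periodic cell problems and average the strain energy.

    ``density.H`` must hold one (element-averaged) material fraction per
    element in the mesh's ``e = ex * ny + ey`` ordering.
    """
    H = np.asarray(density.H, dtype=float).ravel()
    if H.size != mesh.n_elements:
        raise ValueError("density must provide one H value per element")
    coeff = np.maximum(H, material.ersatz)
    if np.all(H <= material.ersatz):
        warnings.warn("all-void cell: effective stiffness is at the ersatz floor")

    D = base_elasticity(material)
    hx, hy = mesh.spacing
    ke, _, _ = quad_stiffness(D, hx, hy)
    conn = mesh.connectivity()
    pmap = mesh.periodic_map()
    ndof = 2 * mesh.n_master_nodes

    # reduced (periodic) dof indices per element: (n_elem, 8)
    mnodes = pmap[conn]
    edofs = np.empty((mesh.n_elements, 8), dtype=int)
    edofs[:, 0::2] = 2 * mnodes
    edofs[:, 1::2] = 2 * mnodes + 1

    rows = np.repeat(edofs, 8, axis=1).ravel()
    cols = np.tile(edofs, (1, 8)).ravel()
    vals = (coeff[:, None, None] * ke[None, :, :]).ravel()
    K = sparse.coo_matrix((vals, (rows, cols)), shape=(ndof, ndof)).tocsc()

    u0 = _unit_strain_displacements(mesh)
    F = np.zeros((ndof, 3))
    fe = coeff[:, None, None] * (ke @ u0.T)[None, :, :]  # (n_elem, 8, 3)
    for j in range(8):
        np.add.at(F, edofs[:, j], fe[:, j, :])

    # pin master node 0 (both dofs) to remove rigid translation
    fixed = np.array([0, 1])
    free = np.setdiff1d(np.arange(ndof), fixed)
    chi_red = np.zeros((ndof, 3))
    Kff = K[np.ix_(free, free)]
    solve = spla.factorized(Kff)
    for i in range(3):
        chi_red[free, i] = solve(F[free, i])

    # elementwise corrected displacements and energies with the SOLID material
    diff = u0.T[None, :, :] - chi_red[edofs]  # (n_elem, 8, 3)
    beta = np.einsum("eai,ab,ebj->eij", diff, ke, diff)  # solid energy per element
    area = hx * hy
    DH = np.einsum("e,eij->ij", coeff, beta)  # |Y| = 1
    DH = 0.5 * (DH + DH.T)
    beta_density = beta / area  # beta as an energy density for sensitivities

    # expand correctors to the full grid for export/inspection
    chi_full = chi_red.reshape(-1, 2, 3)[pmap]  # (n_nodes, 2, 3)
    chi_full = np.moveaxis(chi_full, 2, 0)

    fields = UnitStrainFields(chi=chi_full, element_energies=beta_density)
    Mu1, Mu2 = poisson_ratios(DH)
    return EffectiveElasticity(DH=DH, Mu1=Mu1, Mu2=Mu2, fields=fields)


def poisson_ratios(DH: np.ndarray) -> tuple[float, float]:
    """Directional Poisson's ratios Mu1 = D12/D11 and Mu2 = D12/D22."""
    DH = np.asarray(DH, dtype=float)
    if DH[0, 0] <= 0 or DH[1, 1] <= 0:
        raise ValueError("degenerate design: nonpositive diagonal stiffness")
    return float(DH[0, 1] / DH[0, 0]), float(DH[0, 1] / DH[1, 1])


def elasticity_sensitivity(
    fields: UnitStrainFields,
    density: DensityField,
    design: LevelSetDesign,
    mesh: MicroMesh2D,
    Bc: sparse.csr_matrix | None = None,
) -> np.ndarray:
    """Shape derivative of DH with respect to every expansion coefficient.

    dDH_ij/dalpha_n = (1/|Y|) int beta_ij phi_n(x) delta(Phi) dY, evaluated
    with the elementwise energy density beta of the current correctors; the
    Dirac factor confines the integral to the interface band, so knots whose
    support misses the band get exactly zero.

    Returns an (N, 3, 3) array.
    """
    if Bc is None:
        Bc = basis_matrix(design.knots, mesh.element_centers)
    delta = np.asarray(density.delta, dtype=float).ravel()
    if delta.size != mesh.n_elements:
        raise ValueError("density must provide one delta value per element")
    hx, hy = mesh.spacing
    area = hx * hy
    w = delta * area  # per-element measure of the Dirac layer
    # (N, 3, 3) = sum_e Bc[e, n] * w[e] * beta[e, i, j]
    weighted = fields.element_energies * w[:, None, None]
    out = sparse.csr_matrix(Bc).T @ weighted.reshape(mesh.n_elements, 9)
    return np.asarray(out).reshape(-1, 3, 3)
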