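"""Coupled Darcy-Stokes flow past the stent microstructure and the MFP tensor.

The 3D computational domain is a box: an inlet blood region, the unit
cell, and an outlet blood region in the flow (x) direction; a thin stent
layer at the bottom and a free blood layer on top.  The stent layer's
fluid indicator ``H^f`` is the complement of the 2D design's material
indicator, constant through the layer thickness (the strut cross-section
is assumed constant).

One unified mixed system covers both regimes on the fixed grid: fluid
elements carry the Stokes viscous operator, solid elements a Darcy
penalization ``(mu/k) u = -grad p`` with a very low permeability that
drives the velocity toward zero and thereby enforces approximate no-slip
on the implicit interfaces, with no explicit interface conditions.
Equal-order trilinear velocity/pressure interpolation is stabilized by a
pressure-Laplacian term scaled per regime.

The modified fluid permeability (MFP) quantifies how much the
microstructure obstructs the near-wall flow: with ``w^(1), w^(2)`` the
in-plane velocity component fields extracted on the design plane and
``A`` the plane-restricted Darcy-Stokes viscosity operator,

    K^H_ij = (1/|Y_2D|) w^(i)^T A w^(j).

Minimizing the transverse entry K22 reduces flow deflected off the flow
axis by the struts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as spla

from .levelset import DensityField, LevelSetDesign, basis_matrix

__all__ = [
    "FlowParams",
    "DomainGeometry",
    "ComputationalDomain3D",
    "FlowSolution",
    "MFPTensor",
    "build_domain",
    "assemble_system",
    "solve_flow",
    "extract_design_plane_velocity",
    "mfp_tensor",
    "mfp_sensitivity",
]

REGION_INLET = 0
REGION_OUTLET = 1
REGION_TOP = 2
REGION_STENT = 3


@dataclass(frozen=True)
class FlowParams:
    """Normalized fluid constants and the solid Darcy penalty."""

    mu: float = 1.0
    rho: float = 1.0
    inlet_speed: float = 1.0
    k_solid: float = 1e-5
    stab_const: float = 0.02

    def __post_init__(self):
        if not self.mu > 0:
            raise ValueError("viscosity must be positive")
        if not self.inlet_speed > 0:
            raise ValueError("inlet speed must be positive")
        if not 0 < self.k_solid <= 1e-4:
            raise ValueError("k_solid must be in (0, 1e-4]")


@dataclass(frozen=True)
class DomainGeometry:
    """Box layout: inlet + cell + outlet along x, stent + top layer along z."""

    inlet_length: float = 1.0
    cell_length: float = 1.0
    outlet_length: float = 1.0
    width: float = 1.0
    stent_thickness: float = 0.25
    top_thickness: float = 0.25

    def __post_init__(self):
        for name in (
            "inlet_length",
            "cell_length",
            "outlet_length",
            "width",
            "stent_thickness",
            "top_thickness",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def length(self) -> float:
        return self.inlet_length + self.cell_length + self.outlet_length

    @property
    def height(self) -> float:
        return self.stent_thickness + self.top_thickness


def _count(length: float, resolution: int, name: str) -> int:
    n = length * resolution
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"resolution {resolution} does not divide {name}={length}")
    return int(round(n))


@dataclass(frozen=True)
class ComputationalDomain3D:
    """Uniform 8-node-brick mesh with per-element region labels and H^f."""

    geometry: DomainGeometry
    resolution: int
    Hf: np.ndarray  # (n_elem,) fluid indicator
    region: np.ndarray  # (n_elem,) region codes

    def __post_init__(self):
        Hf = np.asarray(self.Hf, float).ravel()
        if Hf.size != self.n_elements:
            raise ValueError("Hf must have one value per element")
        if Hf.min() < -1e-12 or Hf.max() > 1 + 1e-12:
            raise ValueError("Hf must lie in [0, 1]")
        object.__setattr__(self, "Hf", np.clip(Hf, 0.0, 1.0))

    @property
    def nx(self) -> int:
        return _count(self.geometry.length, self.resolution, "length")

    @property
    def ny(self) -> int:
        return _count(self.geometry.width, self.resolution, "width")

    @property
    def nz(self) -> int:
        return _count(self.geometry.height, self.resolution, "height")

    @property
    def h(self) -> float:
        return 1.0 / self.resolution

    @property
    def n_elements(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def n_nodes(self) -> int:
        return (self.nx + 1) * (self.ny + 1) * (self.nz + 1)

    def node_coords(self) -> np.ndarray:
        x = np.linspace(0, self.geometry.length, self.nx + 1)
        y = np.linspace(0, self.geometry.width, self.ny + 1)
        z = np.linspace(0, self.geometry.height, self.nz + 1)
        X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def connectivity(self) -> np.ndarray:
        """(n_elem, 8) node ids; element e = ex*ny*nz + ey*nz + ez."""
        ex, ey, ez = np.meshgrid(
            np.arange(self.nx), np.arange(self.ny), np.arange(self.nz), indexing="ij"
        )
        ex, ey, ez = ex.ravel(), ey.ravel(), ez.ravel()
        sy = self.nz + 1
        sx = (self.ny + 1) * sy
        n0 = ex * sx + ey * sy + ez
        # parent-cube node order: (-,-,-),(+,-,-),(+,+,-),(-,+,-),(-,-,+),(+,-,+),(+,+,+),(-,+,+)
        return np.column_stack(
            [
                n0,
                n0 + sx,
                n0 + sx + sy,
                n0 + sy,
                n0 + 1,
                n0 + sx + 1,
                n0 + sx + sy + 1,
                n0 + sy + 1,
            ]
        )

    def element_centers(self) -> np.ndarray:
        h = self.h
        x = (np.arange(self.nx) + 0.5) * h
        y = (np.arange(self.ny) + 0.5) * h
        z = (np.arange(self.nz) + 0.5) * h
        X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


def build_domain(
    density: DensityField | np.ndarray,
    geometry: DomainGeometry = DomainGeometry(),
    resolution: int = 8,
) -> ComputationalDomain3D:
    """Extrude the 2D design into the stent layer of the 3D box.

    ``density`` holds the 2D *solid* fraction H on the
    ``(cell_length * resolution) x (width * resolution)`` plane-element
    grid (row-major in y); stent-layer elements get ``H^f = 1 - H``
    column-wise, every other element is pure fluid.
    """
    H2d = density.H if isinstance(density, DensityField) else np.asarray(density, float)
    nxc = _count(geometry.cell_length, resolution, "cell_length")
    nyc = _count(geometry.width, resolution, "width")
    H2d = np.asarray(H2d, float).reshape(nxc, nyc)

    nx = _count(geometry.length, resolution, "length")
    ny = _count(geometry.width, resolution, "width")
    nz = _count(geometry.height, resolution, "height")
    nzs = _count(geometry.stent_thickness, resolution, "stent_thickness")
    i0 = _count(geometry.inlet_length, resolution, "inlet_length")

    region = np.empty((nx, ny, nz), dtype=np.int8)
    region[:i0, :, :] = REGION_INLET
    region[i0 + nxc :, :, :] = REGION_OUTLET
    region[i0 : i0 + nxc, :, :] = REGION_TOP
    region[i0 : i0 + nxc, :, :nzs] = REGION_STENT
    region[:i0, :, :nzs] = REGION_INLET
    region[i0 + nxc :, :, :nzs] = REGION_OUTLET

    Hf = np.ones((nx, ny, nz))
    Hf[i0 : i0 + nxc, :, :nzs] = (1.0 - H2d)[:, :, None]
    return ComputationalDomain3D(
        geometry=geometry,
        resolution=resolution,
        Hf=Hf.ravel(),
        region=region.ravel(),
    )


# ---------------------------------------------------------------------------
# reference element matrices (uniform cubes/squares, 2-point Gauss)


def hex_matrices(h: float):
    """Scalar Laplacian, mass, and three gradient matrices of a trilinear cube."""
    g = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    signs = np.array(
        [
            [-1, -1, -1],
            [1, -1, -1],
            [1, 1, -1],
            [-1, 1, -1],
            [-1, -1, 1],
            [1, -1, 1],
            [1, 1, 1],
            [-1, 1, 1],
        ],
        dtype=float,
    )
    detJ = (h / 2.0) ** 3
    lap = np.zeros((8, 8))
    mass = np.zeros((8, 8))
    grad = np.zeros((3, 8, 8))
    for xi in g:
        for eta in g:
            for zeta in g:
                p = np.array([xi, eta, zeta])
                N = np.prod(1 + signs * p, axis=1) / 8.0
                dN = np.empty((8, 3))
                for d in range(3):
                    others = [i for i in range(3) if i != d]
                    dN[:, d] = (
                        signs[:, d]
                        * np.prod(1 + signs[:, others] * p[others], axis=1)
                        / 8.0
                        * 2.0
                        / h
                    )
                lap += dN @ dN.T * detJ
                mass += np.outer(N, N) * detJ
                for d in range(3):
                    grad[d] += np.outer(dN[:, d], N) * detJ
    # lump the mass matrix: the Darcy penalization then acts nodally, which
    # removes spurious velocity oscillations the consistent form admits
    mass = np.diag(mass.sum(axis=1))
    return lap, mass, grad


def quad_scalar_matrices(h: float):
    """Scalar Laplacian and mass matrices of a bilinear square element."""
    g = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    signs = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
    detJ = (h / 2.0) ** 2
    lap = np.zeros((4, 4))
    mass = np.zeros((4, 4))
    for xi in g:
        for eta in g:
            p = np.array([xi, eta])
            N = np.prod(1 + signs * p, axis=1) / 4.0
            dN = np.empty((4, 2))
            for d in range(2):
                o = 1 - d
                dN[:, d] = signs[:, d] * (1 + signs[:, o] * p[o]) / 4.0 * 2.0 / h
            lap += dN @ dN.T * detJ
            mass += np.outer(N, N) * detJ
    mass = np.diag(mass.sum(axis=1))  # lumped, matching the 3D penalization
    return lap, mass


@dataclass
class FlowSystem:
    """Assembled saddle-point blocks [[K, -G], [G^T, M]] on the full dof set."""

    K: sparse.csr_matrix  # (3n, 3n) blended viscous/Darcy operator
    G: sparse.csr_matrix  # (3n, n) pressure gradient coupling
    M: sparse.csr_matrix  # (n, n) pressure stabilization (negative semidefinite)
    domain: ComputationalDomain3D
    params: FlowParams


def assemble_system(domain: ComputationalDomain3D, params: FlowParams) -> FlowSystem:
    h = domain.h
    lap, mass, grad = hex_matrices(h)
    conn = domain.connectivity()
    ne = domain.n_elements
    n = domain.n_nodes
    Hf = domain.Hf

    # Brinkman blending: the viscous operator is kept everywhere and the
    # Darcy penalization is switched on by the solid fraction, so H^f = 1
    # elements are exactly stabilized Stokes while in H^f = 0 elements the
    # absorption term (mu/k ~ 1e5) dominates viscosity by orders of
    # magnitude and the element behaves as a Darcy medium, without losing
    # inf-sup control of the pressure.
    cs = np.full_like(Hf, params.mu)
    cd = (1.0 - Hf) * params.mu / params.k_solid  # Darcy penalty weight
    # regime-blended pressure stabilization: h^2/mu in fluid (Brezzi-
    # Pitkaranta scale) and k/mu in solid, where the momentum operator is
    # the Darcy penalty; keeps the artificial continuity flux tau*grad(p)
    # negligible against the physical flux in both regimes
    tau = params.stab_const * (
        Hf * h**2 / params.mu + (1.0 - Hf) * params.k_solid / params.mu
    )

    # velocity block: per component d, K[d::3, d::3] gets cs*lap + cd*mass
    ke = cs[:, None, None] * lap[None] + cd[:, None, None] * mass[None]  # (ne, 8, 8)
    udofs = np.stack([3 * conn + d for d in range(3)], axis=2)  # (ne, 8, 3)
    rows = np.repeat(conn, 8, axis=1)  # (ne, 64) node rows
    cols = np.tile(conn, (1, 8))
    Krows = np.concatenate([(3 * rows + d).ravel() for d in range(3)])
    Kcols = np.concatenate([(3 * cols + d).ravel() for d in range(3)])
    Kvals = np.concatenate([ke.reshape(ne, 64).ravel()] * 3)
    K = sparse.coo_matrix((Kvals, (Krows, Kcols)), shape=(3 * n, 3 * n)).tocsr()

    # coupling block G[(a,d), b] = int dN_a/dx_d * N_b (same in both regimes)
    Grows = np.concatenate([(3 * rows + d).ravel() for d in range(3)])
    Gcols = np.concatenate([cols.ravel()] * 3)
    Gvals = np.concatenate([np.tile(grad[d].ravel(), ne) for d in range(3)])
    G = sparse.coo_matrix((Gvals, (Grows, Gcols)), shape=(3 * n, n)).tocsr()

    # pressure stabilization: M = +tau * Laplacian so the pressure Schur
    # complement G^T K^-1 G + tau L stays positive definite
    Mvals = (tau[:, None, None] * lap[None]).reshape(ne, 64).ravel()
    M = sparse.coo_matrix((Mvals, (rows.ravel(), cols.ravel())), shape=(n, n)).tocsr()
    return FlowSystem(K=K, G=G, M=M, domain=domain, params=params)


@dataclass(frozen=True)
class FlowSolution:
    """Nodal velocity/pressure fields on the 3D mesh."""

    u: np.ndarray  # (n_nodes, 3)
    p: np.ndarray  # (n_nodes,)


def _boundary_dofs(
    domain: ComputationalDomain3D,
    params: FlowParams,
    pressure_drop: float | None = None,
):
    """(velocity Dirichlet dofs, values, pressure Dirichlet nodes, values).

    Default driving: plug inflow on the left face with a traction-free
    (weakly zero-pressure) outlet; keeping every continuity row then makes
    the global mass balance exact.  With ``pressure_drop`` given, the flow
    is driven by prescribed pressures (drop, 0) on the end faces instead
    and the end-face velocities are left free.
    """
    xyz = domain.node_coords()
    g = domain.geometry
    tol = 1e-9
    on_inlet = xyz[:, 0] < tol
    on_outlet = xyz[:, 0] > g.length - tol
    on_wall = (
        (xyz[:, 1] < tol)
        | (xyz[:, 1] > g.width - tol)
        | (xyz[:, 2] < tol)
        | (xyz[:, 2] > g.height - tol)
    )
    uval = np.full((domain.n_nodes, 3), np.nan)
    if pressure_drop is None:
        # uniform plug profile at the inlet, all three components prescribed
        uval[on_inlet] = [params.inlet_speed, 0.0, 0.0]
    # no-slip wins on the remaining exterior surfaces (incl. face rims)
    uval[on_wall] = 0.0
    fixed = ~np.isnan(uval).any(axis=1)
    udofs = (3 * np.flatnonzero(fixed)[:, None] + np.arange(3)).ravel()
    uvals = uval[fixed].ravel()
    rhs = np.zeros(4 * domain.n_nodes)
    if pressure_drop is not None:
        # drive with a normal traction -p_in * n on the inlet face (consistent
        # surface load); the outlet stays traction-free, so the head between
        # the faces is pressure_drop and every continuity row is kept
        h = domain.h
        iy = ((xyz[:, 1] + 1e-12) // h).astype(int)
        iz = ((xyz[:, 2] + 1e-12) // h).astype(int)
        wy = np.where((xyz[:, 1] < tol) | (xyz[:, 1] > g.width - tol), 0.5, 1.0)
        wz = np.where((xyz[:, 2] < tol) | (xyz[:, 2] > g.height - tol), 0.5, 1.0)
        inlet_nodes = np.flatnonzero(on_inlet)
        rhs[3 * inlet_nodes] = pressure_drop * wy[inlet_nodes] * wz[inlet_nodes] * h**2
    return udofs, uvals, rhs


def solve_flow(
    system: FlowSystem,
    domain: ComputationalDomain3D | None = None,
    params: FlowParams | None = None,
    pressure_drop: float | None = None,
) -> FlowSolution:
    """Sparse direct solve of the mixed system with the standard conditions:
    plug inflow on the left face, zero pressure on the right face, no-slip on
    every other exterior surface, nothing imposed on implicit interfaces."""
    domain = domain or system.domain
    params = params or system.params
    n = domain.n_nodes
    udofs, uvals, load = _boundary_dofs(domain, params, pressure_drop)

    A = sparse.bmat([[system.K, -system.G], [system.G.T, system.M]], format="csr")
    nd = 3 * n + n
    fixed = udofs
    fixed_vals = uvals
    free = np.setdiff1d(np.arange(nd), fixed)
    x = np.zeros(nd)
    x[fixed] = fixed_vals
    rhs = load - A[:, fixed] @ fixed_vals
    Aff = A[np.ix_(free, free)].tocsc()
    try:
        x[free] = spla.spsolve(Aff, rhs[free])
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(
            "Darcy-Stokes solve failed (singular or ill-conditioned system); "
            f"stabilization constant {params.stab_const}, k_solid {params.k_solid}"
        ) from exc
    if not np.all(np.isfinite(x)):
        raise RuntimeError("Darcy-Stokes solve produced non-finite values")
    return FlowSolution(u=x[: 3 * n].reshape(n, 3), p=x[3 * n :])


def face_flux(sol: FlowSolution, domain: ComputationalDomain3D, ix: int) -> float:
    """Volumetric x-flux through the node plane ``ix`` (bilinear face quadrature)."""
    ux = sol.u[:, 0].reshape(domain.nx + 1, domain.ny + 1, domain.nz + 1)[ix]
    w_y = np.ones(domain.ny + 1)
    w_y[[0, -1]] = 0.5
    w_z = np.ones(domain.nz + 1)
    w_z[[0, -1]] = 0.5
    return float(np.einsum("yz,y,z->", ux, w_y, w_z) * domain.h**2)


def mass_conservation_error(sol: FlowSolution, domain: ComputationalDomain3D) -> float:
    """|outflow - inflow| / inflow across the whole domain."""
    qin = face_flux(sol, domain, 0)
    qout = face_flux(sol, domain, domain.nx)
    return abs(qout - qin) / abs(qin)


def extract_design_plane_velocity(
    sol: FlowSolution, domain: ComputationalDomain3D
) -> np.ndarray:
    """In-plane velocity (ux, uy) on the stent-layer mid-plane over the cell.

    Returns an ``((nxc+1)*(nyc+1), 2)`` array in the 2D grid-point ordering
    (x-major) used by the level-set module; the mid-plane is taken at the
    nearest node layer, which is exact for even stent-layer element counts.
    """
    g = domain.geometry
    res = domain.resolution
    nzs = _count(g.stent_thickness, res, "stent_thickness")
    iz = nzs // 2
    i0 = _count(g.inlet_length, res, "inlet_length")
    nxc = _count(g.cell_length, res, "cell_length")
    u3 = sol.u.reshape(domain.nx + 1, domain.ny + 1, domain.nz + 1, 3)
    w = u3[i0 : i0 + nxc + 1, :, iz, :2]  # (nxc+1, ny+1, 2)
    return w.reshape(-1, 2)


@dataclass(frozen=True)
class MFPTensor:
    """Homogenized 2x2 modified-fluid-permeability tensor on the design plane."""

    K2D: np.ndarray

    def __post_init__(self):
        K = np.asarray(self.K2D, float)
        if K.shape != (2, 2):
            raise ValueError("K2D must be 2x2")
        object.__setattr__(self, "K2D", K)

    @property
    def K11(self) -> float:
        return float(self.K2D[0, 0])

    @property
    def K22(self) -> float:
        return float(self.K2D[1, 1])


def _plane_operator_pieces(density: DensityField | np.ndarray, params: FlowParams):
    H = density.H if isinstance(density, DensityField) else np.asarray(density, float)
    H = np.asarray(H, float)
    if H.ndim == 1:
        m = int(round(np.sqrt(H.size)))
        if m * m != H.size:
            raise ValueError("flat plane density must be square")
        H = H.reshape(m, m)
    nxe, nye = H.shape
    if nxe != nye:
        raise ValueError("design plane grid must be square")
    h = 1.0 / nxe
    lap, mass = quad_scalar_matrices(h)
    Ks = params.mu * lap
    Kd = params.mu / params.k_solid * mass
    Hf = 1.0 - H.ravel()
    return Hf, Ks, Kd, nxe, h


def _plane_connectivity(nxe: int) -> np.ndarray:
    ex, ey = np.meshgrid(np.arange(nxe), np.arange(nxe), indexing="ij")
    ex, ey = ex.ravel(), ey.ravel()
    stride = nxe + 1
    n00 = ex * stride + ey
    return np.column_stack([n00, n00 + stride, n00 + stride + 1, n00 + 1])


def mfp_tensor(
    w2d: np.ndarray, density: DensityField | np.ndarray, params: FlowParams
) -> MFPTensor:
    """MFP from the extracted plane velocities and the plane viscosity matrix.

    ``density`` holds the solid fraction per plane element on the unit-cell
    grid the velocities were extracted on; ``w2d`` is ``(n_nodes, 2)``.
    """
    Hf, Ks, Kd, nxe, _ = _plane_operator_pieces(density, params)
    conn = _plane_connectivity(nxe)
    w2d = np.asarray(w2d, float)
    if w2d.shape != ((nxe + 1) ** 2, 2):
        raise ValueError("w2d shape does not match the plane grid")
    Ae = Hf[:, None, None] * Ks[None] + (1.0 - Hf)[:, None, None] * Kd[None]
    we = w2d[conn]  # (ne, 4, 2)
    K = np.einsum("eai,eab,ebj->ij", we, Ae, we)  # |Y_2D| = 1
    return MFPTensor(K2D=0.5 * (K + K.T))


def mfp_sensitivity(
    w2d: np.ndarray,
    density: DensityField,
    design: LevelSetDesign,
    params: FlowParams,
    component: tuple[int, int] = (1, 1),
    Bc: sparse.csr_matrix | None = None,
    dH_dalpha: sparse.spmatrix | None = None,
) -> np.ndarray:
    """Frozen-velocity shape derivative of one MFP component.

    dK_ij/dalpha_n = (1/|Y|) sum_e w_i^T (Kd - Ks) w_j phi_n(x_e) * dH^f/dalpha_n,
    with dH^f/dPhi = -delta(Phi) because the fluid indicator is the
    complement of the material one.  For a self-adjoint, force-driven
    permeability cell problem this operator-derivative form is the exact
    gradient (the velocity-variation term equals its negative twice); here
    the extracted velocities come from the 3D solve, so it is a
    first-order approximation.
    """
    Hf, Ks, Kd, nxe, h = _plane_operator_pieces(density, params)
    delta = np.asarray(density.delta, float).ravel()
    if delta.size != nxe * nxe:
        raise ValueError("density.delta must match the plane element grid")
    conn = _plane_connectivity(nxe)
    we = np.asarray(w2d, float)[conn]  # (ne, 4, 2)
    i, j = component
    dKe = Kd - Ks  # dA_e/dH_solid
    s = -np.einsum("ea,ab,eb->e", we[:, :, i], dKe, we[:, :, j])
    if dH_dalpha is not None:
        return np.asarray(dH_dalpha.T @ s).ravel()
    if Bc is None:
        Bc = basis_matrix(design.knots, plane_element_centers(nxe))
    return np.asarray(Bc.T @ (s * delta)).ravel()


def plane_element_centers(nxe: int) -> np.ndarray:
    h = 1.0 / nxe
    X, Y = np.meshgrid(
        (np.arange(nxe) + 0.5) * h, (np.arange(nxe) + 0.5) * h, indexing="ij"
    )
    return np.column_stack([X.ravel(), Y.ravel()])


def mfp_sensitivity_adjoint(
    sol: FlowSolution,
    system: FlowSystem,
    density: DensityField,
    design: LevelSetDesign,
    params: FlowParams,
    component: tuple[int, int] = (1, 1),
    Bc: sparse.csr_matrix | None = None,
    pressure_drop: float | None = None,
    dH_dalpha: sparse.spmatrix | None = None,
) -> np.ndarray:
    """Exact design gradient of one MFP component through the 3D solve.

    Adds to the operator-derivative (frozen-velocity) term the variation of
    the extracted velocities, obtained from one adjoint solve of the
    transposed Darcy-Stokes system.  ``density`` is the solid fraction on
    the design-plane element grid used for the MFP.  ``dH_dalpha``, when
    given, replaces the midpoint chain rule delta(Phi) * phi_n with a
    precomputed (n_plane_elements x N) derivative of the element-averaged
    solid fraction (used when the plane density is a block average of a
    finer design grid).
    """
    domain = system.domain
    g = domain.geometry
    res = domain.resolution
    n = domain.n_nodes
    Hf2, Ks, Kd, nxe, h = _plane_operator_pieces(density, params)
    delta = np.asarray(density.delta, float).ravel()
    conn2 = _plane_connectivity(nxe)
    if Bc is None:
        Bc = basis_matrix(design.knots, plane_element_centers(nxe))

    w2d = extract_design_plane_velocity(sol, domain)
    i, j = component
    if i != j:
        raise NotImplementedError("adjoint gradient implemented for diagonal entries")
    we = w2d[conn2]

    # direct (operator) term on the plane: + w^T (Kd - Ks) w * dH/dalpha
    s_direct = np.einsum("ea,ab,eb->e", we[:, :, i], Kd - Ks, we[:, :, j])
    if dH_dalpha is not None:
        grad = np.asarray(dH_dalpha.T @ s_direct).ravel()
    else:
        grad = np.asarray(Bc.T @ (s_direct * delta)).ravel()

    # dJ/dx: 2 * A w scattered onto the extracted in-plane velocity dofs
    Ae = Hf2[:, None, None] * Ks[None] + (1.0 - Hf2)[:, None, None] * Kd[None]
    rows = np.repeat(conn2, 4, axis=1).ravel()
    cols = np.tile(conn2, (1, 4)).ravel()
    np2 = (nxe + 1) ** 2
    Aplane = sparse.coo_matrix(
        (Ae.reshape(-1, 16).ravel(), (rows, cols)), shape=(np2, np2)
    ).tocsr()
    dJdw = 2.0 * (Aplane @ w2d[:, i])

    nzs = _count(g.stent_thickness, res, "stent_thickness")
    iz = nzs // 2
    i0 = _count(g.inlet_length, res, "inlet_length")
    nxc = _count(g.cell_length, res, "cell_length")
    sy = domain.nz + 1
    sx = (domain.ny + 1) * sy
    ixs, iys = np.meshgrid(
        np.arange(i0, i0 + nxc + 1), np.arange(domain.ny + 1), indexing="ij"
    )
    plane_nodes = (ixs * sx + iys * sy + iz).ravel()
    rhs_full = np.zeros(4 * n)
    rhs_full[3 * plane_nodes + i] = dJdw

    # adjoint solve on the transposed reduced system
    A = sparse.bmat([[system.K, -system.G], [system.G.T, system.M]], format="csc")
    udofs, _, _ = _boundary_dofs(domain, params, pressure_drop)
    free = np.setdiff1d(np.arange(4 * n), udofs)
    lam = np.zeros(4 * n)
    lam[free] = spla.spsolve(A[np.ix_(free, free)].T.tocsc(), rhs_full[free])

    # per-element pairing lambda^T (dA/dHf) x over stent-layer elements
    lap3, mass3, grad3 = hex_matrices(domain.h)
    conn3 = domain.connectivity()
    stent = np.flatnonzero(domain.region == REGION_STENT)
    cmu_k = params.mu / params.k_solid
    dtau = params.stab_const * (domain.h**2 - params.k_solid) / params.mu
    u3 = sol.u
    p3 = sol.p
    t = np.zeros(stent.size)
    for d in range(3):
        ue = u3[conn3[stent], d]
        le = lam[3 * conn3[stent] + d]
        t += -cmu_k * np.einsum("ea,ab,eb->e", le, mass3, ue)
    pe = p3[conn3[stent]]
    lpe = lam[3 * n + conn3[stent]]
    t += dtau * np.einsum("ea,ab,eb->e", lpe, lap3, pe)

    # dHf/dalpha_n = -delta * phi_n at the element's in-plane center; the
    # plane delta/basis apply to every z-level of the element column
    centers3 = domain.element_centers()[stent]
    exi = ((centers3[:, 0] - g.inlet_length) * nxe / g.cell_length).astype(int)
    eyi = (centers3[:, 1] * nxe / g.width).astype(int)
    e2d = exi * nxe + eyi
    accum = np.zeros(nxe * nxe)
    np.add.at(accum, e2d, t)
    # indirect term: -lam^T A' x with dHf/dalpha = -dH/dalpha -> + t * dH/dalpha
    if dH_dalpha is not None:
        grad += np.asarray(dH_dalpha.T @ accum).ravel()
    else:
        grad += np.asarray(Bc.T @ (accum * delta)).ravel()
    return grad
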