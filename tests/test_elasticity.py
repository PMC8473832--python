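"""Periodic elastic homogenization against closed forms and a dense oracle."""

import numpy as np
import pytest

from auxstent import elasticity as el
from auxstent import levelset as ls
from auxstent.fixtures import make_fixture


def dense_periodic_homogenization(Hvals, material, nx):
    """Independent brute-force oracle: dense assembly, explicit periodic
    index folding, numpy direct solve, energy-average of corrected fields."""
    D = el.base_elasticity(material)
    h = 1.0 / nx
    gp = np.array([-1, 1]) / np.sqrt(3)
    ke = np.zeros((8, 8))
    for xi in gp:
        for eta in gp:
            B = np.zeros((3, 8))
            dNdx = 0.25 * np.array([-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)]) * 2 / h
            dNdy = 0.25 * np.array([-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)]) * 2 / h
            B[0, 0::2] = dNdx
            B[1, 1::2] = dNdy
            B[2, 0::2] = dNdy
            B[2, 1::2] = dNdx
            ke += B.T @ D @ B * (h * h / 4)
    coeff = np.maximum(np.asarray(Hvals, float).ravel(), material.ersatz)
    nmast = nx * nx
    K = np.zeros((2 * nmast, 2 * nmast))
    F = np.zeros((2 * nmast, 3))
    corners = np.array([[0, 0], [h, 0], [h, h], [0, h]])
    u0 = np.zeros((3, 8))
    u0[0, 0::2] = corners[:, 0]
    u0[1, 1::2] = corners[:, 1]
    u0[2, 0::2] = corners[:, 1] / 2
    u0[2, 1::2] = corners[:, 0] / 2
    emap = []
    for ex in range(nx):
        for ey in range(nx):
            nodes = [
                (ex % nx) * nx + ey % nx,
                ((ex + 1) % nx) * nx + ey % nx,
                ((ex + 1) % nx) * nx + (ey + 1) % nx,
                (ex % nx) * nx + (ey + 1) % nx,
            ]
            dofs = []
            for nmid in nodes:
                dofs += [2 * nmid, 2 * nmid + 1]
            emap.append(dofs)
    for e, dofs in enumerate(emap):
        K[np.ix_(dofs, dofs)] += coeff[e] * ke
        F[dofs, :] += coeff[e] * (ke @ u0.T)
    keep = np.arange(2, 2 * nmast)  # pin node 0
    chi = np.zeros((2 * nmast, 3))
    chi[keep] = np.linalg.solve(K[np.ix_(keep, keep)], F[keep])
    DH = np.zeros((3, 3))
    for e, dofs in enumerate(emap):
        diff = u0.T - chi[dofs]
        DH += coeff[e] * diff.T @ ke @ diff
    return DH


class TestBaseElasticity:
    def test_nu_zero(self):
        D = el.base_elasticity(el.BaseMaterial(E=1.0, nu=0.0))
        assert np.allclose(D, np.diag([1.0, 1.0, 0.5]))

    def test_plane_stress_entry(self):
        D = el.base_elasticity(el.BaseMaterial(E=1.0, nu=0.3))
        assert D[0, 0] == pytest.approx(1 / (1 - 0.09))
        assert np.allclose(D, D.T)

    def test_invalid_poisson_rejected(self):
        with pytest.raises(ValueError):
            el.BaseMaterial(nu=0.6)


class TestHomogenize:
    def test_full_solid_recovers_base(self):
        mesh = el.MicroMesh2D(8, 8)
        mat = el.BaseMaterial()
        dens = ls.DensityField(H=np.ones(64), delta=np.zeros(64), smoothing_width=0.1)
        eff = el.homogenize_elasticity(dens, mat, mesh)
        D0 = el.base_elasticity(mat)
        assert np.abs(eff.DH - D0).max() < 1e-8 * np.abs(D0).max()

    def test_all_void_at_ersatz_floor(self):
        mesh = el.MicroMesh2D(8, 8)
        mat = el.BaseMaterial()
        dens = ls.DensityField(H=np.zeros(64), delta=np.zeros(64), smoothing_width=0.1)
        with pytest.warns(UserWarning):
            eff = el.homogenize_elasticity(dens, mat, mesh)
        assert np.linalg.norm(eff.DH) <= mat.ersatz * np.linalg.norm(
            el.base_elasticity(mat)
        ) * (1 + 1e-9)

    def test_void_block_matches_dense_oracle(self):
        nx = 8
        H = np.ones((nx, nx))
        H[2:6, 2:6] = 0.0
        mat = el.BaseMaterial()
        mesh = el.MicroMesh2D(nx, nx)
        dens = ls.DensityField(H=H.ravel(), delta=np.zeros(nx * nx), smoothing_width=0.1)
        eff = el.homogenize_elasticity(dens, mat, mesh)
        DH_oracle = dense_periodic_homogenization(H.ravel(), mat, nx)
        assert np.abs(eff.DH - DH_oracle).max() < 1e-6 * np.abs(DH_oracle).max()

    def test_four_fold_symmetry_gives_square_symmetry(self):
        dens = make_fixture("cross", 32)
        eff = el.homogenize_elasticity(dens, el.BaseMaterial(), el.MicroMesh2D(32, 32))
        assert eff.DH[0, 0] == pytest.approx(eff.DH[1, 1], abs=1e-8)

    def test_monotone_in_uniform_scaling(self):
        dens = make_fixture("centered_hole", 16)
        mat = el.BaseMaterial()
        mesh = el.MicroMesh2D(16, 16)
        prev = None
        for c in (0.4, 0.7, 1.0):
            scaled = ls.DensityField(
                H=c * dens.H, delta=dens.delta, smoothing_width=dens.smoothing_width
            )
            DH = el.homogenize_elasticity(scaled, mat, mesh).DH
            if prev is not None:
                assert np.all(np.diag(DH) >= np.diag(prev) - 1e-12)
            prev = DH

    def test_laminate_recovers_voigt_bound(self):
        # layered along y with phases (1.0, 0.5); loading along the lamina,
        # with nu = 0 the axial modulus is exactly the Voigt average
        nx = 64
        H = np.ones((nx, nx))
        H[:, : nx // 2] = 0.5
        mat = el.BaseMaterial(E=1.0, nu=0.0)
        dens = ls.DensityField(H=H.ravel(), delta=np.zeros(nx * nx), smoothing_width=0.1)
        eff = el.homogenize_elasticity(dens, mat, el.MicroMesh2D(nx, nx))
        voigt = 0.5 * (1.0 + 0.5) * 1.0
        assert eff.DH[0, 0] == pytest.approx(voigt, rel=0.02)


class TestPoissonRatios:
    def test_printed_converged_tensor(self):
        DH = np.array([[0.1082, -0.0339, 0], [-0.0339, 0.0324, 0], [0, 0, 0.0022]])
        mu1, mu2 = el.poisson_ratios(DH)
        assert round(mu1, 4) == -0.3133
        assert round(mu2, 4) == -1.0463

    def test_isotropic_recovers_nu(self):
        D = el.base_elasticity(el.BaseMaterial(E=1.0, nu=0.3))
        assert el.poisson_ratios(D) == pytest.approx((0.3, 0.3))

    def test_zero_offdiagonal(self):
        assert el.poisson_ratios(np.diag([1.0, 2.0, 0.5])) == (0.0, 0.0)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            el.poisson_ratios(np.diag([0.0, 1.0, 1.0]))


class TestSensitivity:
    def _setup(self, nx=16):
        knots = ls.KnotGrid.regular(nx)
        design = ls.initialize_design(knots, [((0.5, 0.5), 0.3)])
        mesh = el.MicroMesh2D(nx, nx)
        Bc = ls.basis_matrix(knots, mesh.element_centers)
        width = 2.0 / nx
        phi = np.asarray(Bc @ design.alpha).ravel()
        dens = ls.smoothed_heaviside(phi, width)
        mat = el.BaseMaterial()
        eff = el.homogenize_elasticity(dens, mat, mesh)
        return design, mesh, Bc, width, dens, mat, eff

    def test_matches_finite_differences(self):
        design, mesh, Bc, width, dens, mat, eff = self._setup()
        sens = el.elasticity_sensitivity(eff.fields, dens, design, mesh, Bc)
        top = np.argsort(-np.abs(sens[:, 0, 0]))[:10]
        h = 1e-4
        for n in top:
            a = design.alpha.copy()
            a[n] += h
            Dp = el.homogenize_elasticity(
                ls.smoothed_heaviside(np.asarray(Bc @ a).ravel(), width), mat, mesh
            ).DH
            a = design.alpha.copy()
            a[n] -= h
            Dm = el.homogenize_elasticity(
                ls.smoothed_heaviside(np.asarray(Bc @ a).ravel(), width), mat, mesh
            ).DH
            fd = (Dp - Dm) / (2 * h)
            assert np.abs(sens[n] - fd).max() <= 0.03 * np.abs(fd).max()

    def test_zero_away_from_interface(self):
        design, mesh, Bc, width, dens, mat, eff = self._setup()
        sens = el.elasticity_sensitivity(eff.fields, dens, design, mesh, Bc)
        # knot in the far solid corner: its support misses the Dirac band
        corner = np.argmin(np.linalg.norm(design.knots.positions - [0.0, 0.0], axis=1))
        assert np.abs(sens[corner]).max() == 0.0

    def test_offdiagonal_symmetry(self):
        design, mesh, Bc, width, dens, mat, eff = self._setup()
        sens = el.elasticity_sensitivity(eff.fields, dens, design, mesh, Bc)
        assert np.allclose(sens[:, 0, 1], sens[:, 1, 0], atol=1e-14)
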