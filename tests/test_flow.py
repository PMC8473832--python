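"""Darcy-Stokes solver and MFP tensor against closed-form flow oracles."""

import numpy as np
import pytest

from auxstent import flow as fl
from auxstent import levelset as ls
from conftest import duct_series_profile


def open_channel(res=8):
    geom = fl.DomainGeometry()
    dom = fl.build_domain(np.zeros((res, res)), geom, res)
    params = fl.FlowParams()
    sol = fl.solve_flow(fl.assemble_system(dom, params))
    return dom, params, sol


class TestBuildDomain:
    def test_all_fluid(self):
        dom = fl.build_domain(np.zeros((8, 8)), fl.DomainGeometry(), 8)
        assert np.all(dom.Hf == 1.0)

    def test_default_element_count(self):
        dom = fl.build_domain(np.zeros((8, 8)), fl.DomainGeometry(), 8)
        assert dom.n_elements == 24 * 8 * 4 == 768

    def test_solid_column_maps_through_thickness(self):
        H = np.zeros((8, 8))
        H[4, 4] = 1.0
        dom = fl.build_domain(H, fl.DomainGeometry(), 8)
        Hf = dom.Hf.reshape(24, 8, 4)
        assert np.all(Hf[12, 4, :2] == 0.0)  # stent layer stack
        assert np.all(Hf[12, 4, 2:] == 1.0)  # top blood layer above it

    def test_resolution_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fl.build_domain(np.zeros((8, 8)), fl.DomainGeometry(stent_thickness=0.3), 8)


class TestAssembly:
    def test_pure_fluid_has_no_darcy_term(self):
        # with H^f = 1 the system is pure stabilized Stokes: independent of k
        geom = fl.DomainGeometry()
        dom = fl.build_domain(np.zeros((8, 8)), geom, 8)
        A1 = fl.assemble_system(dom, fl.FlowParams(k_solid=1e-5))
        A2 = fl.assemble_system(dom, fl.FlowParams(k_solid=1e-6))
        assert (A1.K - A2.K).nnz == 0 or abs((A1.K - A2.K)).max() < 1e-14
        assert abs((A1.M - A2.M)).max() < 1e-14

    def test_coupling_block_transpose_structure(self):
        from scipy import sparse

        dom, params, _ = open_channel()
        sys_ = fl.assemble_system(dom, params)
        A = sparse.bmat([[sys_.K, -sys_.G], [sys_.G.T, sys_.M]]).tocsr()
        n = dom.n_nodes
        upper = A[: 3 * n, 3 * n :]
        lower = A[3 * n :, : 3 * n]
        assert abs(upper + lower.T).max() < 1e-14

    def test_energy_dissipation_positive(self):
        dom, params, sol = open_channel()
        sys_ = fl.assemble_system(dom, params)
        u = sol.u.ravel()
        assert u @ (sys_.K @ u) > 0


class TestSolve:
    def test_global_mass_conservation(self):
        dom, params, sol = open_channel()
        assert fl.mass_conservation_error(sol, dom) < 1e-6

    def test_no_slip_exact_on_walls(self):
        dom, params, sol = open_channel()
        xyz = dom.node_coords()
        g = dom.geometry
        wall = (
            (xyz[:, 1] < 1e-12)
            | (xyz[:, 1] > g.width - 1e-12)
            | (xyz[:, 2] < 1e-12)
            | (xyz[:, 2] > g.height - 1e-12)
        )
        assert np.abs(sol.u[wall]).max() == 0.0

    def test_linearity_in_inlet_speed(self):
        geom = fl.DomainGeometry()
        dom = fl.build_domain(np.zeros((8, 8)), geom, 8)
        s1 = fl.solve_flow(fl.assemble_system(dom, fl.FlowParams(inlet_speed=1.0)))
        s2 = fl.solve_flow(fl.assemble_system(dom, fl.FlowParams(inlet_speed=2.0)))
        assert np.allclose(s2.u, 2 * s1.u, atol=1e-8 * np.abs(s1.u).max())
        assert np.allclose(s2.p, 2 * s1.p, atol=1e-8 * np.abs(s1.p).max())

    def test_duct_profile_matches_series_solution(self, duct_case):
        dom = duct_case["domain"]
        sol = duct_case["solution"]
        u = sol.u.reshape(dom.nx + 1, dom.ny + 1, dom.nz + 1, 3)
        prof = u[dom.nx // 2, dom.ny // 2, :, 0]
        z = np.linspace(-0.5, 0.5, dom.nz + 1)
        ana = duct_series_profile(z, 0.5, duct_case["pressure_gradient"])
        assert np.abs(prof - ana).max() <= 0.05 * ana.max()

    def test_uniform_darcy_slab_obeys_darcy_law(self):
        geom = fl.DomainGeometry()
        base = fl.build_domain(np.zeros((8, 8)), geom, 8)
        dom = fl.ComputationalDomain3D(
            geometry=geom, resolution=8, Hf=np.zeros(base.n_elements), region=base.region
        )
        params = fl.FlowParams()
        drop = 100.0
        sol = fl.solve_flow(fl.assemble_system(dom, params), pressure_drop=drop)
        u = sol.u.reshape(dom.nx + 1, dom.ny + 1, dom.nz + 1, 3)
        interior = u[6:19, 1:-1, 1:-1, 0]
        expected = params.k_solid / params.mu * drop / geom.length
        assert interior.mean() == pytest.approx(expected, rel=0.01)

    def test_blocking_wall_leaves_only_penalty_leakage(self):
        geom = fl.DomainGeometry()
        base = fl.build_domain(np.zeros((8, 8)), geom, 8)
        Hf = np.ones((base.nx, base.ny, base.nz))
        Hf[11:13, :, :] = 0.0  # wall across the whole cross-section
        dom = fl.ComputationalDomain3D(
            geometry=geom, resolution=8, Hf=Hf.ravel(), region=base.region
        )
        params = fl.FlowParams()
        drop = 100.0
        sol = fl.solve_flow(fl.assemble_system(dom, params), pressure_drop=drop)
        u = sol.u.reshape(dom.nx + 1, dom.ny + 1, dom.nz + 1, 3)
        downstream_mean = np.abs(u[16:, :, :, 0]).mean()
        assert downstream_mean <= 10 * params.k_solid / params.mu * drop


class TestExtraction:
    def test_plane_values_equal_3d_nodal_values(self):
        dom, params, sol = open_channel()
        w = fl.extract_design_plane_velocity(sol, dom)
        u3 = sol.u.reshape(dom.nx + 1, dom.ny + 1, dom.nz + 1, 3)
        assert np.array_equal(w.reshape(9, 9, 2), u3[8:17, :, 1, :2])

    def test_shape_matches_design_grid(self):
        dom, params, sol = open_channel()
        assert fl.extract_design_plane_velocity(sol, dom).shape == (81, 2)

    def test_solid_layer_interior_leakage_small(self):
        geom = fl.DomainGeometry()
        dom = fl.build_domain(np.ones((8, 8)), geom, 8)
        params = fl.FlowParams()
        sol = fl.solve_flow(fl.assemble_system(dom, params))
        w = fl.extract_design_plane_velocity(sol, dom).reshape(9, 9, 2)
        # away from the upstream/downstream solid faces the Darcy penalty
        # keeps the in-plane speed at leakage scale
        p_scale = sol.p.max() - sol.p.min()
        bound = 10 * params.k_solid / params.mu * p_scale
        assert np.abs(w[2:-2, 2:-2]).max() <= bound


class TestMFP:
    def test_symmetric_design_has_zero_offdiagonal(self):
        dom, params, sol = open_channel()
        w = fl.extract_design_plane_velocity(sol, dom)
        dens = ls.DensityField(H=np.zeros(64), delta=np.zeros(64), smoothing_width=0.1)
        K = fl.mfp_tensor(w, dens, params)
        assert abs(K.K2D[0, 1]) <= 1e-3 * max(K.K11, K.K22)

    def test_flow_direction_dominates_for_open_strut_design(self):
        # struts aligned with the flow: x-permeability far above transverse
        res = 8
        H = np.zeros((res, res))
        H[:, 1:3] = 1.0
        H[:, 5:7] = 1.0
        geom = fl.DomainGeometry()
        dom = fl.build_domain(H, geom, res)
        params = fl.FlowParams()
        sol = fl.solve_flow(fl.assemble_system(dom, params))
        w = fl.extract_design_plane_velocity(sol, dom)
        dens = ls.DensityField(H=H.ravel(), delta=np.zeros(64), smoothing_width=0.1)
        K = fl.mfp_tensor(w, dens, params)
        assert K.K11 > K.K22 > 0

    def test_transverse_bar_decreases_k22_nested(self):
        # nested designs: growing a transverse blocker cuts transverse motion
        res = 8
        geom = fl.DomainGeometry()
        params = fl.FlowParams()
        k22s = []
        base = np.zeros((res, res))
        base[2:4, 2:6] = 1.0  # deflector that generates transverse flow
        for extra in (0, 1, 2):
            H = base.copy()
            if extra >= 1:
                H[5:7, 1:7] = 1.0
            if extra >= 2:
                H[5:7, :] = 1.0
            dom = fl.build_domain(H, geom, res)
            sol = fl.solve_flow(fl.assemble_system(dom, params))
            w = fl.extract_design_plane_velocity(sol, dom)
            dens = ls.DensityField(H=H.ravel(), delta=np.zeros(64), smoothing_width=0.1)
            k22s.append(fl.mfp_tensor(w, dens, params).K22)
        assert k22s[0] > k22s[1] > k22s[2]


class TestMFPSensitivity:
    def _pipeline(self, Bc, width, res, geom, params):
        def run(alpha):
            phi = np.asarray(Bc @ alpha).ravel()
            df = ls.smoothed_heaviside(phi, width)
            dom = fl.build_domain(df.H.reshape(res, res), geom, res)
            system = fl.assemble_system(dom, params)
            sol = fl.solve_flow(system)
            w = fl.extract_design_plane_velocity(sol, dom)
            return fl.mfp_tensor(w, df, params), sol, system, df

        return run

    def test_adjoint_gradient_matches_finite_differences(self, hole_design):
        res = 8
        geom = fl.DomainGeometry()
        params = fl.FlowParams()
        Bc = ls.basis_matrix(hole_design.knots, fl.plane_element_centers(res))
        width = 2.0 / res
        run = self._pipeline(Bc, width, res, geom, params)
        K, sol, system, df = run(hole_design.alpha)
        g = fl.mfp_sensitivity_adjoint(sol, system, df, hole_design, params, Bc=Bc)
        h = 1e-3
        for n in np.argsort(-np.abs(g))[:5]:
            a = hole_design.alpha.copy()
            a[n] += h
            Kp = run(a)[0].K22
            a = hole_design.alpha.copy()
            a[n] -= h
            Km = run(a)[0].K22
            fd = (Kp - Km) / (2 * h)
            assert g[n] == pytest.approx(fd, rel=0.10)

    def test_frozen_form_is_a_descent_direction(self, hole_design):
        # the first-order (frozen-velocity) form agrees with the exact
        # adjoint gradient in direction, which is what the update needs
        res = 8
        geom = fl.DomainGeometry()
        params = fl.FlowParams()
        Bc = ls.basis_matrix(hole_design.knots, fl.plane_element_centers(res))
        width = 2.0 / res
        run = self._pipeline(Bc, width, res, geom, params)
        K, sol, system, df = run(hole_design.alpha)
        w = fl.extract_design_plane_velocity(sol, system.domain)
        g_frozen = fl.mfp_sensitivity(w, df, hole_design, params, Bc=Bc)
        g_exact = fl.mfp_sensitivity_adjoint(sol, system, df, hole_design, params, Bc=Bc)
        cos = g_frozen @ g_exact / (np.linalg.norm(g_frozen) * np.linalg.norm(g_exact))
        assert cos > 0.0  # moving along -g_frozen decreases K22
        top = np.argsort(-np.abs(g_frozen))[:5]
        assert np.all(np.sign(g_frozen[top]) == np.sign(g_exact[top]))

    def test_zero_away_from_interface(self):
        # a knot whose compact support misses the Dirac band contributes 0
        res = 16
        params = fl.FlowParams()
        knots = ls.KnotGrid.regular(res)  # support radius 3/16
        design = ls.initialize_design(knots, [((0.5, 0.5), 0.2)])
        Bc = ls.basis_matrix(knots, fl.plane_element_centers(res))
        phi = np.asarray(Bc @ design.alpha).ravel()
        df = ls.smoothed_heaviside(phi, 2.0 / res)
        w = np.ones(((res + 1) ** 2, 2))
        g = fl.mfp_sensitivity(w, df, design, params, Bc=Bc)
        corner = np.argmin(np.linalg.norm(knots.positions - [0.0, 0.0], axis=1))
        assert g[corner] == 0.0
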