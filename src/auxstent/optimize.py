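"""Multi-objective design loop: auxetic + flow-obstruction + stiffness.

Each iteration evaluates the three objectives on the current implicit
design

    J = W1 * J_A + W2 * J_P + W3 * J_MA,
    J_A  = (Mu1 + 1)^2 + (Mu2 + 1)^2      (push both Poisson ratios to -1)
    J_P  = K^H_2D(2,2)                     (transverse flow obstruction)
    J_MA = macro strain energy             (stenting compliance)

subject to the material volume constraint V <= V_max.  The constraint is
enforced by a proportional-integral controller against a scheduled
volume target that descends at the rate the interface can actually
follow; the integral part plays the role of a Lagrange multiplier and
decays quickly once the design is feasible, so the restoring force stays
commensurate with the objective gradients and cannot wind up.  All three
gradients are scaled to unit max magnitude before weighting so the
weights compare like with like, and (optionally) the objective values
are divided by the largest magnitude seen so far for the same reason.
The coefficient update is projected steepest descent with a backtracking
step limited so the interface moves at most about one design cell per
iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import elasticity as _el
from . import flow as _fl
from . import levelset as _ls
from . import macro as _mc
from .config import Config

__all__ = [
    "Weights",
    "OptimizationState",
    "auxetic_objective",
    "volume_fraction",
    "normalize_sensitivity",
    "combined_gradient",
    "run_optimization",
]


@dataclass(frozen=True)
class Weights:
    """Objective weights: W1 auxetic, W2 MFP, W3 macro compliance."""

    w1: float = 0.35
    w2: float = 0.35
    w3: float = 0.30

    def __post_init__(self):
        if min(self.w1, self.w2, self.w3) < 0 or self.w1 + self.w2 + self.w3 <= 0:
            raise ValueError("weights must be nonnegative with positive sum")


def auxetic_objective(Mu1: float, Mu2: float) -> tuple[float, tuple[float, float]]:
    """J_A = (Mu1+1)^2 + (Mu2+1)^2 and its chain-rule factors dJ/dMu."""
    if not (np.isfinite(Mu1) and np.isfinite(Mu2)):
        raise ValueError("Poisson ratios must be finite")
    J = (Mu1 + 1.0) ** 2 + (Mu2 + 1.0) ** 2
    return float(J), (2.0 * (Mu1 + 1.0), 2.0 * (Mu2 + 1.0))


def volume_fraction(
    density: _ls.DensityField, Bc=None, design: _ls.LevelSetDesign | None = None
) -> tuple[float, np.ndarray | None]:
    """Solid fraction V = mean(H) and its shape gradient.

    dV/dalpha_n = int phi_n delta(Phi) dOmega / |Omega|; returns (V, None)
    when no basis matrix / design is supplied.
    """
    H = np.asarray(density.H, float).ravel()
    V = float(H.mean())
    if Bc is None and design is None:
        return V, None
    if Bc is None:
        raise ValueError("pass the basis matrix evaluated at the density's elements")
    delta = np.asarray(density.delta, float).ravel()
    grad = np.asarray(Bc.T @ delta).ravel() / delta.size
    return V, grad


def normalize_sensitivity(g: np.ndarray) -> np.ndarray:
    """Scale to unit max magnitude; zero vector stays zero (1e-12 guard)."""
    g = np.asarray(g, float)
    m = np.abs(g).max() if g.size else 0.0
    if not np.isfinite(m) or m < 1e-12:
        return np.zeros_like(g)
    return g / m


def combined_gradient(
    grads: dict[str, np.ndarray], weights: Weights, constraint_term: np.ndarray | None = None
) -> np.ndarray:
    """Weighted sum of the normalized objective gradients plus the
    (already scaled) volume-constraint term."""
    g = (
        weights.w1 * normalize_sensitivity(grads["auxetic"])
        + weights.w2 * normalize_sensitivity(grads["mfp"])
        + weights.w3 * normalize_sensitivity(grads["macro"])
    )
    if constraint_term is not None:
        g = g + constraint_term
    return g


@dataclass
class OptimizationState:
    """Final design plus the per-iteration record of the run."""

    design: _ls.LevelSetDesign
    iteration: int
    J: float
    J_A: float
    J_P: float
    J_MA: float
    Mu1: float
    Mu2: float
    K11: float
    K22: float
    volume: float
    multiplier: float
    penalty: float
    converged: bool
    history: pd.DataFrame = field(repr=False)
    message: str = ""


class _Evaluator:
    """Precomputed operators shared by every objective evaluation."""

    def __init__(self, config: Config):
        self.config = config
        d = config.design
        self.nx = d.nx
        self.h = 1.0 / d.nx
        self.width = d.smoothing_cells * self.h
        self.knots = _ls.KnotGrid.regular(d.nx, support_cells=d.support_cells)
        self.mesh = _el.MicroMesh2D(d.nx, d.nx)
        self.Bc_micro = _ls.basis_matrix(self.knots, self.mesh.element_centers)
        f = config.flow
        self.geometry = _fl.DomainGeometry(
            inlet_length=f.inlet_length,
            outlet_length=f.outlet_length,
            stent_thickness=f.stent_thickness,
            top_thickness=f.top_thickness,
        )
        self.params = _fl.FlowParams(
            mu=f.mu,
            rho=f.rho,
            inlet_speed=f.inlet_speed,
            k_solid=f.k_solid,
            stab_const=f.stab_const,
        )
        self.resolution = f.resolution
        self.Bc_plane = _ls.basis_matrix(
            self.knots, _fl.plane_element_centers(f.resolution)
        )
        # element-averaged H^f: when the design grid refines the flow grid,
        # every flow-plane element takes the mean solid fraction of the
        # design cells it covers, so struts thinner than a flow element are
        # still felt by the Darcy blending (midpoint sampling misses them)
        self.plane_average = None
        if d.nx % f.resolution == 0:
            from scipy import sparse as _sp

            m = d.nx // f.resolution
            rows = []
            for ex in range(f.resolution):
                for ey in range(f.resolution):
                    sub = [
                        (ex * m + i) * d.nx + (ey * m + j)
                        for i in range(m)
                        for j in range(m)
                    ]
                    rows.append(sub)
            ridx = np.repeat(np.arange(f.resolution**2), m * m)
            cidx = np.concatenate(rows)
            vals = np.full(ridx.size, 1.0 / (m * m))
            self.plane_average = _sp.csr_matrix(
                (vals, (ridx, cidx)), shape=(f.resolution**2, d.nx**2)
            )
        self.material = _el.BaseMaterial(
            E=config.material.E, nu=config.material.nu, ersatz=config.material.ersatz
        )
        self.macro_model = _mc.MacroModel(
            nx=config.macro.nx, ny=config.macro.ny, stretch=config.macro.stretch
        )

    def initial_design(self) -> _ls.LevelSetDesign:
        d = self.config.design
        holes = []
        if d.holes_nx and d.holes_ny and d.hole_radius > 0:
            for i in range(d.holes_nx):
                for j in range(d.holes_ny):
                    cx = (i + 0.5) / d.holes_nx
                    cy = (j + 0.5) / d.holes_ny
                    holes.append(((cx, cy), d.hole_radius))
        bound = d.alpha_bound
        return _ls.initialize_design(self.knots, holes, alpha_bounds=(-bound, bound))

    def objectives(self, alpha: np.ndarray, with_gradients: bool = False) -> dict:
        """Evaluate all objectives (and optionally gradients) at ``alpha``."""
        out: dict = {}
        phi_m = np.asarray(self.Bc_micro @ alpha).ravel()
        dens_m = _ls.smoothed_heaviside(phi_m, self.width)
        eff = _el.homogenize_elasticity(dens_m, self.material, self.mesh)
        out["Mu1"], out["Mu2"] = eff.Mu1, eff.Mu2
        out["J_A"], dJA_dMu = auxetic_objective(eff.Mu1, eff.Mu2)
        msol = _mc.macro_compliance(eff, self.macro_model)
        out["J_MA"] = msol.compliance
        out["V"] = float(np.asarray(dens_m.H).mean())

        if self.plane_average is not None:
            Hp = np.asarray(self.plane_average @ dens_m.H).ravel()
            dens_p = _ls.DensityField(
                H=Hp, delta=np.zeros_like(Hp), smoothing_width=self.width
            )
        else:
            phi_p = np.asarray(self.Bc_plane @ alpha).ravel()
            dens_p = _ls.smoothed_heaviside(phi_p, self.width)
        dom = _fl.build_domain(
            dens_p.H.reshape(self.resolution, self.resolution),
            self.geometry,
            self.resolution,
        )
        system = _fl.assemble_system(dom, self.params)
        sol = _fl.solve_flow(system)
        w2d = _fl.extract_design_plane_velocity(sol, dom)
        K = _fl.mfp_tensor(w2d, dens_p, self.params)
        out["K11"], out["K22"] = K.K11, K.K22
        out["J_P"] = K.K22

        if not with_gradients:
            return out

        design = _ls.LevelSetDesign(
            knots=self.knots,
            alpha=alpha,
            alpha_bounds=(-self.config.design.alpha_bound, self.config.design.alpha_bound),
        )
        dDH = _el.elasticity_sensitivity(eff.fields, dens_m, design, self.mesh, self.Bc_micro)
        DH = eff.DH
        dMu1 = (dDH[:, 0, 1] * DH[0, 0] - DH[0, 1] * dDH[:, 0, 0]) / DH[0, 0] ** 2
        dMu2 = (dDH[:, 0, 1] * DH[1, 1] - DH[0, 1] * dDH[:, 1, 1]) / DH[1, 1] ** 2
        out["g_A"] = dJA_dMu[0] * dMu1 + dJA_dMu[1] * dMu2
        out["g_MA"] = _mc.compliance_sensitivity(msol, dDH)
        dH_plane = None
        if self.plane_average is not None:
            from scipy import sparse as _sp

            dH_plane = self.plane_average @ self.Bc_micro.multiply(
                dens_m.delta[:, None]
            )
        if self.config.optimization.use_adjoint_mfp:
            out["g_P"] = _fl.mfp_sensitivity_adjoint(
                sol, system, dens_p, design, self.params,
                Bc=self.Bc_plane, dH_dalpha=dH_plane,
            )
        else:
            out["g_P"] = _fl.mfp_sensitivity(
                w2d, dens_p, design, self.params,
                Bc=self.Bc_plane, dH_dalpha=dH_plane,
            )
        _, out["g_V"] = volume_fraction(dens_m, Bc=self.Bc_micro, design=design)
        return out


def run_optimization(
    config: Config,
    callback: Callable[[int, dict], None] | None = None,
    checkpoint_dir: str | None = None,
) -> OptimizationState:
    """Run the full multiscale loop to convergence.

    Stops when the relative change of the weighted objective stays below
    ``tol`` over ``tol_window`` consecutive iterations with the volume
    constraint satisfied to 1%, or at ``max_iter`` (flagged).
    """
    ev = _Evaluator(config)
    opt = config.optimization
    weights = Weights(config.weights.w1, config.weights.w2, config.weights.w3)
    design = ev.initial_design()

    lam = 0.0  # integral (multiplier) part of the volume controller
    scales: dict[str, float] | None = None
    hist: list[dict] = []
    stagnant = 0
    converged = False
    message = "max_iter reached"

    def scaled(res: dict) -> tuple[float, float, float, float]:
        sA = scales["J_A"] if scales else 1.0
        sP = scales["J_P"] if scales else 1.0
        sM = scales["J_MA"] if scales else 1.0
        jA, jP, jM = res["J_A"] / sA, res["J_P"] / sP, res["J_MA"] / sM
        return jA, jP, jM, weights.w1 * jA + weights.w2 * jP + weights.w3 * jM

    res = ev.objectives(design.alpha, with_gradients=True)
    if opt.normalize_values:
        # running-max scaling: each objective is divided by the largest
        # magnitude seen so far, so a term that starts near zero (the MFP
        # typically does on a mostly solid cell) cannot blow up the
        # weighted sum once it grows
        scales = {k: max(abs(res[k]), 1e-8) for k in ("J_A", "J_P", "J_MA")}

    # the volume constraint is enforced against a scheduled target that
    # descends from the initial fraction at the rate the CFL-limited
    # interface can actually follow; the restoring force is proportional
    # to the excess over the target plus a slowly integrated multiplier
    V0 = res["V"]

    def volume_target(iteration: int) -> float:
        return max(opt.volume_max, V0 - opt.volume_step_cap * iteration)

    def merit(res: dict, target: float) -> float:
        # the macro term enters with a negative sign: under the prescribed-
        # displacement loading, raising the stored energy is what stiffens
        # the stent, so the loop maximizes it while minimizing J_A and J_P.
        # The volume is tracked as an equality at the scheduled target (the
        # optimized designs ride the volume limit), so the quadratic term
        # is two-sided.
        jA, jP, jM, _ = scaled(res)
        return (
            weights.w1 * jA
            + weights.w2 * jP
            - weights.w3 * jM
            + lam * (res["V"] - opt.volume_max)
            + 0.5 * opt.volume_gain_p * (res["V"] - target) ** 2
        )

    it = 0
    for it in range(opt.max_iter):
        if scales is not None:
            for k in ("J_A", "J_P", "J_MA"):
                scales[k] = max(scales[k], abs(res[k]))
        jA, jP, jM, J = scaled(res)
        hist.append(
            dict(
                iteration=it,
                J=J,
                J_A=jA,
                J_P=jP,
                J_MA=jM,
                Mu1=res["Mu1"],
                Mu2=res["Mu2"],
                K11=res["K11"],
                K22=res["K22"],
                V=res["V"],
                multiplier=lam,
                target=volume_target(it),
                step=np.nan,
            )
        )
        if callback is not None:
            callback(it, hist[-1])
        every = opt.checkpoint_every
        if checkpoint_dir and every and it % every == 0:
            from pathlib import Path

            from .io import serialize_design

            Path(checkpoint_dir).mkdir(parents=True, exist_ok=True)
            serialize_design(design, Path(checkpoint_dir) / f"design_it{it:04d}.txt")

        if len(hist) > 1:
            dJ = abs(hist[-1]["J"] - hist[-2]["J"]) / max(abs(hist[-2]["J"]), 1e-12)
            ok_volume = res["V"] <= opt.volume_max + 0.01
            stagnant = stagnant + 1 if (dJ < opt.tol and ok_volume) else 0
            if stagnant >= opt.tol_window:
                converged = True
                message = "objective stationary with feasible volume"
                break

        # descent direction: weighted normalized gradients + constraint force;
        # the proportional term tracks the scheduled target, the integral
        # term (multiplier) removes the residual excess over V_max, and the
        # cap keeps the force commensurate with the objective gradients
        target = volume_target(it)
        force = float(
            np.clip(
                opt.volume_gain_p * (res["V"] - target) + lam,
                -opt.constraint_force_cap,
                opt.constraint_force_cap,
            )
        )
        sA = scales["J_A"] if scales else 1.0
        sP = scales["J_P"] if scales else 1.0
        sM = scales["J_MA"] if scales else 1.0
        g = combined_gradient(
            {"auxetic": res["g_A"] / sA, "mfp": res["g_P"] / sP, "macro": -res["g_MA"] / sM},
            weights,
            constraint_term=force * normalize_sensitivity(res["g_V"]),
        )
        direction = -g
        dphi = np.asarray(ev.Bc_micro @ direction).ravel()
        dmax = np.abs(dphi).max()
        if dmax < 1e-14:
            converged = True
            message = "vanishing descent direction"
            break
        # scale so the level-set field moves at most ~step_cells * h * |grad phi|
        phi_m = np.asarray(ev.Bc_micro @ design.alpha).ravel()
        gscale = _interface_gradient_scale(phi_m, ev.nx, ev.width)
        step0 = opt.step_cells * ev.h * gscale / dmax
        dV_rate = abs(float(res["g_V"] @ direction))
        if dV_rate > 1e-14:
            step0 = min(step0, opt.volume_step_cap / dV_rate)

        # filter-style acceptance: a step is taken when it improves the
        # merit OR makes clear progress toward the volume target (the
        # latter lets the loop traverse objective barriers -- e.g. the
        # transverse-MFP spike when a strut is first broken -- that a pure
        # merit line search refuses to cross)
        merit0 = merit(res, target)
        gap0 = abs(res["V"] - target)
        step = step0
        accepted = None
        for _ in range(opt.max_halvings + 1):
            trial, stagnated = _ls.update_coefficients(design, direction, step)
            if stagnated:
                break
            trial_res = ev.objectives(trial.alpha, with_gradients=False)
            improves_merit = merit(trial_res, target) < merit0 + 1e-12
            improves_volume = abs(trial_res["V"] - target) < gap0 - 1e-4
            if (improves_merit or improves_volume) and (
                abs(trial_res["V"] - res["V"]) <= 2 * opt.volume_step_cap
            ):
                accepted = (trial, trial_res, step)
                break
            step *= 0.5
        if accepted is None:
            viol = max(0.0, res["V"] - opt.volume_max)
            if viol <= 0.01:
                converged = True
                message = "no improving step at the feasible design"
                break
            # infeasible: take the smallest step, the constraint force drives it
            trial, stagnated = _ls.update_coefficients(design, direction, step)
            if stagnated:
                message = "stagnated at coefficient bounds"
                break
            accepted = (trial, ev.objectives(trial.alpha, with_gradients=False), step)
        design, res, step_taken = accepted
        hist[-1]["step"] = step_taken
        res = ev.objectives(design.alpha, with_gradients=True)

        # signed multiplier update: converges to the force that balances the
        # objectives' net push on the volume at the limit
        lam = float(
            np.clip(
                lam + opt.volume_gain_i * (res["V"] - volume_target(it + 1)),
                -opt.constraint_force_cap,
                opt.constraint_force_cap,
            )
        )

    history = pd.DataFrame(hist)
    jA, jP, jM, J = scaled(res)
    return OptimizationState(
        design=design,
        iteration=it,
        J=J,
        J_A=jA,
        J_P=jP,
        J_MA=jM,
        Mu1=res["Mu1"],
        Mu2=res["Mu2"],
        K11=res["K11"],
        K22=res["K22"],
        volume=res["V"],
        multiplier=lam,
        penalty=opt.volume_gain_p,
        converged=converged,
        history=history,
        message=message,
    )


def _interface_gradient_scale(phi: np.ndarray, nx: int, width: float) -> float:
    """Median |grad Phi| inside the interface band, for a CFL-like step limit."""
    P = phi.reshape(nx, nx)
    gx = np.gradient(P, 1.0 / nx, axis=0)
    gy = np.gradient(P, 1.0 / nx, axis=1)
    gn = np.hypot(gx, gy)
    band = np.abs(P) < width
    vals = gn[band] if band.any() else gn.ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return 1.0
    m = float(np.median(vals))
    return m if m > 1e-8 else 1.0
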