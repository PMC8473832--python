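"""Shared fixtures: expensive solves are session-scoped and reused."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from auxstent import flow as fl
from auxstent import levelset as ls
from auxstent.config import Config
from auxstent.optimize import run_optimization


def duct_series_profile(z, a, G, mu=1.0, nterms=80):
    """Analytic fully developed velocity in a square duct of half-width a.

    Classic Fourier series for -mu * lap(u) = G with no-slip walls at
    |y| = |z| = a, evaluated on the centerline y = 0.
    """
    s = np.zeros_like(z, dtype=float)
    for n in range(1, 2 * nterms, 2):
        k = n * np.pi / (2 * a)
        s += ((-1) ** ((n - 1) // 2) / n**3) * (1 - np.cosh(k * z) / np.cosh(k * a))
    return (16 * G * a**2 / (mu * np.pi**3)) * s


@pytest.fixture(scope="session")
def duct_case():
    """Pressure-driven Stokes flow in a square 1x1 duct, 12 elements across."""
    res = 12
    geom = fl.DomainGeometry(stent_thickness=0.5, top_thickness=0.5)
    base = fl.build_domain(np.zeros((res, res)), geom, res)
    domain = fl.ComputationalDomain3D(
        geometry=geom, resolution=res, Hf=np.ones(base.n_elements), region=base.region
    )
    params = fl.FlowParams()
    drop = 30.0
    sol = fl.solve_flow(fl.assemble_system(domain, params), pressure_drop=drop)
    return {
        "domain": domain,
        "params": params,
        "solution": sol,
        "pressure_gradient": drop / geom.length,
    }


@pytest.fixture(scope="session")
def small_run():
    """A small but complete optimization run for trace/bookkeeping checks."""
    cfg = Config.model_validate(
        {
            "design": {"nx": 16},
            "flow": {"resolution": 8},
            "macro": {"nx": 8, "ny": 8},
            "optimization": {"max_iter": 30, "volume_max": 0.30},
        }
    )
    return cfg, run_optimization(cfg)


@pytest.fixture(scope="session")
def case7_run():
    """Reduced-mesh run at the printed study conditions: 40x40 design grid,
    weights 0.35/0.35/0.30, volume limit 30%."""
    cfg = Config.model_validate(
        {"optimization": {"max_iter": 150, "volume_max": 0.30}}
    )
    return cfg, run_optimization(cfg)


@pytest.fixture()
def hole_design():
    """Two-hole asymmetric design used by the sensitivity checks."""
    knots = ls.KnotGrid.regular(8)
    return ls.initialize_design(knots, [((0.35, 0.5), 0.2), ((0.7, 0.3), 0.15)])
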