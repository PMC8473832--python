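# auxstent

Multiscale level-set topology optimization of auxetic, flow-friendly
coronary-stent microstructures.

Coronary stents fail clinically through mechanical problems (fracture,
malapposition, foreshortening) and through the adverse hemodynamics their
struts induce: wall shear stress below ~0.5 Pa promotes in-stent
restenosis, above ~2.5 Pa it raises thrombosis risk. Both pressures point
the same way — toward repeating strut cells that are *auxetic* (negative
Poisson's ratio, for adaptive radial deformation and better
deliverability) and that *obstruct the near-wall blood flow as little as
possible*. `auxstent` is a research code for designing such cells. It is
aimed at computational-mechanics and stent-design researchers who want a
transparent, fully scriptable implementation of the coupled problem.

## The model

A single 2D unit cell is described implicitly by a level-set field
expanded in compactly supported radial basis functions (Wendland C2) at
fixed knots, `Phi(x) = sum_i phi_i(x) alpha_i`, with solid where
`Phi > 0`. The coefficient vector `alpha` is the design variable. Three
objectives are computed from each design:

- **Auxetic**: periodic homogenization of the cell (plane-stress Q4,
  periodic boundary conditions) gives the effective stiffness `DH` and
  the directional Poisson's ratios `Mu1 = D12/D11`, `Mu2 = D12/D22`;
  the objective `J_A = (Mu1+1)^2 + (Mu2+1)^2` drives both toward -1.
- **Hemodynamic**: the cell is extruded into a thin stent layer inside a
  3D channel and a stabilized Darcy-Stokes (Brinkman-penalized) system
  is solved — Stokes in blood, a low-permeability Darcy penalty in
  solid, no explicit interface conditions. The in-plane velocities on
  the stent layer's mid-plane condense into the modified fluid
  permeability `K^H_ij = (1/|Y|) w^(i)^T K_ds w^(j)`; minimizing the
  transverse entry `J_P = K22` suppresses flow deflected off the flow
  axis by the struts.
- **Structural**: a 20 x 20 sheet of cells with the homogenized material
  under a prescribed horizontal stretch; the stored energy
  `J_MA = (1/2) int eps^T DH eps` measures stenting stiffness.

The weighted sum (default weights 0.35/0.35/0.30) is driven by analytic
shape sensitivities — interface (Dirac-band) integrals for `DH` and the
volume, an adjoint-corrected gradient for the MFP — under a volume limit
(default 30% solid) tracked by a proportional-integral controller. See
`docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from auxstent import poisson_ratios, Config, run_optimization

# directional Poisson's ratios of a homogenized stiffness matrix
DH = np.array([[0.1082, -0.0339, 0.0],
               [-0.0339, 0.0324, 0.0],
               [0.0,     0.0,    0.0022]])
print(poisson_ratios(DH))
# (-0.31330868761552677, -1.0462962962962963)
#  -> Mu1 = -0.3133 along the flow direction, Mu2 = -1.0463 transverse:
#     both negative, i.e. an auxetic cell.

# full design run at the default study conditions (40x40 design grid,
# 30% volume limit, weights 0.35/0.35/0.30); a few minutes on one core
state = run_optimization(Config())
print(f"V={state.volume:.4f}  Mu1={state.Mu1:.4f}  Mu2={state.Mu2:.4f}")
print(f"K11={state.K11:.4g}  K22={state.K22:.4g}")
# V=0.2996  Mu1=-0.0022  Mu2=-0.9647
# K11=12.61  K22=1.5e-05
```

The run converges onto the 30% volume limit with both effective
Poisson's ratios negative (strongly so transversally) and a
flow-direction permeability that dominates the transverse one by orders
of magnitude: the material concentrates into struts aligned with the
blood flow, joined by thin flexing connectors. `state.history` holds the
per-iteration record (objectives, ratios, MFP entries, volume,
multiplier) as a DataFrame.

The same stages are scriptable from a shell:

```bash
auxstent optimize --config my_run.yaml --out-dir run/   # full loop
auxstent homogenize --design run/design.txt             # DH and Mu1/Mu2
auxstent flow --design run/design.txt --vtk fields.vtk  # 3D solve + MFP
auxstent export --design run/design.txt --stl cell.stl  # watertight STL
auxstent fixtures --out-dir fixtures/                   # canonical cells
```

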