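# Methods

`auxstent` designs the repeating 2D unit cell of a coronary-stent scaffold
so that the homogenized material is auxetic (both effective Poisson's
ratios negative), obstructs the near-wall blood flow as little as
possible, and keeps the assembled stent sheet stiff — three objectives
coupled on one implicit geometry and driven to a volume-constrained
optimum. This note records the model, the numerical choices, and what
the defaults do and do not represent.

## Design representation

The microstructure boundary is the zero contour of a level-set field
expanded in compactly supported radial basis functions (Wendland C2,
`(1-r)^4 (4r+1)` for normalized radius `r <= 1`). Knots sit at the nodes
of the design grid (default 40 x 40 elements on the unit cell) with a
support radius of 3 grid spacings — wide enough that the collocation
matrix is well conditioned and every point is covered by several knots,
narrow enough to stay sparse. Because the knots are fixed, boundary
motion reduces to an update of the expansion coefficients; no
Hamilton-Jacobi time stepping or reinitialization is performed.

Material is identified by a smoothed Heaviside of the level set: a cubic
polynomial `1/2 + (3/4)t - (1/4)t^3`, `t = phi/Delta`, over a band of
half-width `Delta` = 2 design cells. Its derivative concentrates every
shape sensitivity on the interface band. The initial design is a solid
sheet punctured by a 4 x 4 array of holes of radius 0.06 cell lengths
(solid fraction about 0.82): the run starts nearly solid, so the
transverse permeability starts near zero and the volume constraint does
the first phase of the work — the behavior the converged histories of
such studies show.

## Effective elasticity (auxetic objective)

Periodic homogenization on the fixed design grid, 4-node plane-stress
quadrilaterals, three unit test strains in Voigt order (11, 22, 12 with
engineering shear). Periodicity is imposed by folding slave nodes of the
right/top edges onto their masters; one node is pinned to remove rigid
translation. Element stiffness is scaled by `max(H, ersatz)` with an
ersatz floor of 1e-4 so void regions stay nonsingular. The effective
matrix is the energy average of the corrected fields,

    DH_ij = (1/|Y|) sum_e c_e (u0_i - chi_i)^T k_e (u0_j - chi_j),

and the directional Poisson's ratios are `Mu1 = D12/D11` (flow
direction) and `Mu2 = D12/D22` (transverse). The auxetic objective is
`J_A = (Mu1+1)^2 + (Mu2+1)^2`, minimal when both ratios reach -1.

The shape derivative of `DH` is the interface integral of the elementwise
energy density of the corrected fields times the basis value and the
smoothed Dirac; because the smoothed Heaviside makes the chain exact,
finite-difference checks agree to ~1e-7 relative.

The base solid is normalized (E = 1, nu = 0.3, plane stress). Poisson
ratios are scale-free, so this choice affects only the magnitude of the
stiffness entries, not the signs the design targets.

## Flow model and the modified fluid permeability (MFP)

Near the artery wall the flow is slow, so blood is modeled as steady
incompressible Stokes flow (normalized viscosity 1). The 3D domain is a
box: inlet and outlet blood regions (length 1 each) flanking the unit
cell, a stent layer of thickness 0.25 holding the extruded 2D design
(constant cross-section), and a free blood layer of 0.25 above it.
Uniform plug inflow on the left face, no-slip on every other exterior
surface, and a traction-free (do-nothing) outlet that imposes near-zero
outlet pressure weakly. The do-nothing outlet is what makes the discrete
global mass balance exact (~1e-14): a strong pressure Dirichlet would
delete continuity rows and break it.

Solid and fluid coexist on one fixed grid through Brinkman penalization:
the viscous operator is kept everywhere and solid elements add a lumped
Darcy absorption `(mu/k) u` with `k = 1e-5`, driving the velocity toward
zero and enforcing approximate no-slip on the implicit interface with no
explicit interface conditions. A literal per-element swap to a pure
Darcy operator was tested and is unstable with equal-order trilinear
interpolation (pressure checkerboarding); keeping the viscous term
preserves inf-sup control while the penalty dominates it by three orders
of magnitude in solid elements. Mass lumping of the penalty term removes
the velocity oscillations the consistent form admits. Equal-order
velocity/pressure interpolation is stabilized by a pressure-Laplacian
term with the regime-blended coefficient
`tau = c (H^f h^2/mu + (1-H^f) k/mu)`, `c = 0.02` — the value balances
duct-flow accuracy (~1%) against the artificial continuity flux the
stabilization introduces.

Stent-layer elements take the element-averaged fluid fraction
`H^f = 1 - mean(H)` over the design cells they cover (block average when
the design grid refines the flow grid). Averaging matters: midpoint
sampling at the default flow resolution (8 elements per unit length)
misses struts thinner than a flow element entirely, making the flow
objective blind to exactly the thin members the optimizer produces.

The MFP condenses the 3D solve into a 2x2 tensor on the design plane
(the stent layer's horizontal mid-plane): with `w^(1), w^(2)` the
extracted in-plane velocity component fields and `A` the plane-restricted
blended viscosity operator,

    K^H_ij = (1/|Y_2D|) w^(i)^T A w^(j).

`K11` measures flow-aligned motion, `K22` transverse deflection; the flow
objective is `J_P = K22`. All flow quantities are normalized, so the
absolute magnitudes of `K^H` are scale-dependent; only orderings and
trends are meaningful.

Two gradients of `J_P` are provided. The first-order (frozen-velocity)
form varies only the plane operator, with the Dirac factor read as the
derivative of the fluid indicator (`dH^f/dPhi = -delta`); it is a descent
direction (positive alignment with the exact gradient, matching signs on
its largest entries) but not pointwise accurate, because the 3D velocity
field's own variation is not negligible. The adjoint-corrected gradient
adds that variation through one transposed solve and matches central
finite differences to ~1e-4 relative; the optimizer uses it by default
(`use_adjoint_mfp`).

## Macroscale stent sheet (stiffness objective)

The flattened stent is 20 x 20 uniform cells, one Q4 element per cell,
every element carrying the current `DH`. Vertical displacements are fixed
on the top and bottom edges and a unit relative horizontal stretch is
prescribed (-1/2 left, +1/2 right). `J_MA` is the stored strain energy.
Under displacement control, a stiffer structure stores *more* energy, so
the loop maximizes `J_MA` (minimizing it literally sheds all material and
empties the design — verified); the reported value is still the energy.
The frozen-displacement derivative through `dDH/dalpha` is exact for this
loading — the implicit displacement term vanishes by equilibrium — and
finite-difference checks confirm it to machine-level agreement.

## The design loop

Per iteration: homogenize, macro solve, build the 3D domain, solve the
flow, condense the MFP, assemble sensitivities. Each objective gradient
is normalized to unit maximum magnitude before weighting (default
weights 0.35 / 0.35 / 0.30 for auxetic / MFP / compliance), and each
objective value is divided by the largest magnitude seen so far
(running-max rather than first-iteration scaling: the MFP starts near
zero on a nearly solid cell and a first-iteration scale would let it
dominate everything once it grows).

The volume limit (default 30%) is enforced by a proportional-integral
controller against a scheduled target that descends from the initial
fraction at the per-iteration rate the interface can actually follow
(`volume_step_cap`, default 0.04). The target is tracked two-sidedly —
converged designs of this problem ride the volume limit — and the
integral term plays the multiplier's role. A classical augmented
Lagrangian with per-iteration multiplier updates was implemented first
and found to wind up: the multiplier integrates the violation faster
than the rate-limited interface can respond, then overshoots and strips
the design; the controller keeps the restoring force commensurate with
the (normalized) objective gradients.

Steps are projected steepest descent with backtracking (at most 8
halvings), the initial step chosen so the level-set field moves about
one design cell per iteration (using the median interface gradient as
the scale) and so the predicted volume change stays within the cap.
Acceptance is filter-style: a step is taken when it improves the merit
*or* clearly advances the volume toward its target. The second clause is
what lets the loop cross objective barriers — most importantly the
transverse-MFP spike when a strut is first broken open — that a pure
merit line search refuses to traverse. Convergence is declared when the
weighted objective changes by less than 1e-3 (relative) over 5
consecutive iterations with the volume within 1% of the limit, or when
no acceptable step exists at a feasible design.

Everything is deterministic: two runs from the same configuration produce
bitwise-identical histories.

## Default problem sizes

Design grid 40 x 40 (1681 knots), flow mesh 8 elements per unit length
(24 x 8 x 4 bricks, ~4500 unknowns), macro sheet 20 x 20 elements, at
most 150 iterations. At these sizes a full run takes a few minutes on
one core; all meshes are configurable.

## What the defaults do and do not represent

All quantities are normalized: unit cell length, unit viscosity, unit
inlet speed, unit solid modulus. The model assumes steady Stokes flow, a
rigid stent of constant cross-section, a flat (unrolled) macro sheet,
and linear elasticity. Passing tests therefore demonstrate internal
consistency and agreement with closed-form and brute-force oracles at
these conditions — not hemodynamic accuracy in a curved, pulsatile,
non-Newtonian artery, and not the behavior of a crimped or deployed
stent. At the default (coarse) resolutions the converged transverse
stiffness is small and the transverse Poisson's ratio is strongly
negative while the flow-direction ratio is only weakly negative; finer
grids resolve wider, more structured struts.

## Known limitations

- No level-set reinitialization: after many iterations the field's slope
  near the interface can drift from unity; the CFL-like step scale
  compensates by measuring the actual interface gradient.
- The MFP magnitudes depend on the (normalized) domain scales; comparing
  them across different geometries requires care.
- The frozen-velocity MFP gradient is directional only; the adjoint form
  should be used whenever pointwise accuracy matters.
- The plane-averaged fluid fraction requires the design grid to be a
  multiple of the flow grid; otherwise midpoint sampling is used and thin
  struts may be invisible to the flow objective.
- Objective magnitudes of zero at the start (e.g. the MFP on a fully
  solid cell) are handled by the running-max scaling, but a design whose
  level set leaves the smoothing band everywhere has identically zero
  shape gradients and the loop stops with a vanishing-direction message.
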