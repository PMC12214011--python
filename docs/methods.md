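# Methods

## Model

The package analyses a three-species reaction–diffusion model of solid
tumour immunotherapy: effector (cytotoxic immune) cells u, tumour cells v,
and IL-2 concentration w.  The kinetics combine tumour-stimulated effector
recruitment (α v), effector decay (μ_u), IL-2-stimulated effector
proliferation with saturation (ρ_u u w/(1+w)), logistic tumour growth with
saturating immune kill (u v/(γ_v+v)), tumour/effector-stimulated IL-2
production (ρ_w u v/(γ_w+v)), IL-2 decay (μ_w), and external treatment
inputs σ_u, σ_w.  Transport is Fickian diffusion; after nondimensionalising
time by the tumour growth rate, tumour density by the carrying capacity and
space by the tumour diffusion length, the tumour diffusivity is 1 and the
effector/IL-2 diffusivities δ_u, δ_w are the key mobility parameters.

Assumptions worth keeping in mind: linear diffusion is a crude model of
cell motility (an optional volume-filling form ∇·((1−v)²∇v) is provided);
kinetic parameters are identical between the well-mixed and spatial models,
which is a deliberate, crude comparison; and continuous densities are
meaningless below ~one cell — an optional "atto-fox" sink −H(10⁻¹⁵−v)v
removes such densities.

## Canonical parameters

`table1_nondim()` stores the published, *rounded* dimensionless values
(μ_u = 0.167, ρ_u = 0.692, γ_v = 0.1, μ_w = 55.56, ρ_w = 2.5, γ_w = 10⁻³).
The rounded values — not the exact dimensional ratios (e.g. m_E/r_T = 1/6)
— are the set against which all reference bifurcation locations reproduce;
the distinction matters at the fourth decimal of the Hopf dose.  The
bifurcation parameters α ∈ [0, 0.154], σ_u, σ_w, δ_u, δ_w ∈ [0.75, 8264]
are free arguments.  The dimensional table (with the Stokes–Einstein
effector-motility estimate ≈ 7×10⁻⁵ cm²/day and the division-walk tumour
estimate d_T = D²λ) exists for provenance and unit-facing work only.

## Equilibria and stability maps

The cancer-free state has a closed form; coexistence states (0 < v0 < 1)
are found two ways: (i) a dense sign scan plus Brent bracketing of the
scalar steady-state residual in v0 (default for single parameter sets), and
(ii) roots of the degree-5 polynomial obtained by exact coefficient-level
elimination of u0 and w0 (`numpy.polynomial` arithmetic), Newton-polished —
used inside plane scans for speed.  The two routes are required to agree to
1e-7 on root sets in the test suite.  Roots closer than 1e-8 are merged
(folds produce near-double roots).  Stability uses the dense 3×3 spectrum
with threshold Re λ < −1e-10; eigenvalues within ±1e-10 are flagged
marginal and excluded from "stable" counts, so classification near
boundaries is deterministic.

Stability-plane scans default to σ_u ∈ [0, 0.05], σ_w ∈ [0, 20] on 201×201
grids, which cover every reported feature (transcritical ≈ 0.0161, Hopf
≈ 0.0196 at σ_w = 0.5, IL-2 ramps up to σ_w = 20).  The largest α with
both bistability types (cancer-free+coexistence and two-coexistence) is
located by bisection with Δα = 10⁻³; the computed bound is ≈ 0.0831.

## Dispersion analysis

Growth rates of mode k about a homogeneous state are eigenvalues of
M_k = J − diag(δ_u, 1, δ_w) k², i.e. roots of the cubic
λ³ + a2 λ² + a1 λ + a0 with a0 = A k⁶ + B k⁴ + C k² + D.  The trace
coefficient is a2 = (δ_u + 1 + δ_w) k² − tr J (the tumour's unit
diffusivity appears explicitly; the k⁴ coefficient of a1,
δ_u + δ_u δ_w + δ_w, is the matching pairwise-product sum).  A
kinetics-stable state is Turing-unstable iff a0 < 0 at
k_c² = (−2B + √(4B² − 12AC))/(6A), the interior minimum of the a0 cubic.
k² is treated as continuous here (infinite-domain idealisation); finite
domains quantise k = nπ/L (Neumann), which the continuation and simulation
layers use.  Cancer-free states cannot pattern: v-perturbations are
inadmissible at v0 = 0 and the (u, w) subsystem is triangular.

Note that the *fastest-growing* wavenumber coincides with k_c only near
onset; deep inside the instability the argmax of Re λ_k and the argmin of
a0 separate.  Tests assert the coincidence at onset and band-membership
elsewhere.

## Continuation

Steady states of the 1D discretisation (3-point Neumann Laplacian) are
continued in σ_u or σ_w by pseudo-arclength: secant predictor, Newton
corrector on the bordered system with the previous tangent as the
normalisation, adaptive step in [1e-5, 1e-1].  Accepted points satisfy a
scaled residual < 1e-10.  Stability uses the dense spectrum for problems up
to 1600 unknowns and a shift-invert Arnoldi fallback above, with threshold
Re λ < −1e-8.  Folds are tagged at parameter-direction reversals and
refined by a local quadratic fit of the parameter along the branch; Hopf
points at complex-pair real-part crossings, refined by bisection (with the
state re-converged by Newton at each trial parameter).  On a degenerate
(3-node) domain the machinery reduces to the well-mixed 3×3 system, which
is how the homogeneous Hopf dose is refined to machine precision
(0.019608175 at α = 0.07, σ_w = 0.5).

Patterned branches are seeded in two ways.  `switch_branch` performs a
bordered Newton with the pattern amplitude (projection onto the critical
cos(nπx/L) eigenmode) pinned and the parameter free — plain Newton from a
small perturbation collapses onto the nearby homogeneous root.  The side on
which the pinned seed converges directly exhibits sub/supercriticality;
`classify_criticality` reads the same information from the branch's initial
parameter drift relative to the homogeneous-stable side.
`primary_patterned_state` instead grows the *discrete mode nearest the
continuous k_c* (mode n = 2 at L = 30) by stiff time relaxation and
Newton-polishes; this is the branch carrying the stable patterns.  Mode
selection matters: the marginally faster-growing mode 1 at the seeding
parameter leads to a different branch with a fold near σ_w = −1.92, while
the k_c-nearest mode reproduces the reference fold at σ_w ≈ −0.8455
(mesh-converged: m = 256 → 512 moves it by < 0.5%).  Treatment inputs are
allowed to go negative during continuation only — the fold lies at
unphysical σ_w < 0 — and the simulation layer rejects negative dosing.

Branch enumeration is capped (first 12 modes); completeness of the branch
census is not a goal.

## Simulation

Method of lines with the centred 3-point (1D) or compact 9-point (2D
squares; exact for quadratics) Laplacian, Neumann closure by ghost
reflection.  Discs use a masked Cartesian grid (nodes whose centres lie in
the circle) with the 5-point stencil and stair-step ghost reflection at the
rim; discs appear only in qualitative runs, where rim accuracy is not
quantitative.  Time integration is `scipy.integrate.solve_ivp` BDF with an
analytically assembled sparse Jacobian (diffusion blocks plus per-node
reaction 3×3 diagonals); the nonlinear-diffusion variant supplies a
sparsity pattern instead.  Dirichlet IL-2 boundary dosing w = B_w(t) keeps
rim nodes in the state vector with ẇ = B_w'(t) and zeroed diffusion rows —
exact for linear ramps, one solver path for everything.  The volume-filling
tumour flux uses a conservative face average of (1−v)² with ghost-reflection
weights at boundaries so it reduces exactly to the Neumann Laplacian as
v → 0.

Reference tolerances are 1e-11 (absolute and relative), used for all ODE
and 1D work.  The long 2D boundary-dosing runs use rtol = atol = 1e-6;
extinction times computed at 1e-6 and 1e-8 agree to 4 significant figures,
and halving the grid spacing (64² → 100² at δ_u = 10) moves the extinction
time by ~5%, within the stochastic-initial-condition spread.  Extinction is
an integrator event on max_x v crossing 1e-6 (≈ one cell at the
carrying-capacity scale of 10⁶ cells per unit length); `extinction_time`
falls back to linear interpolation of saved maxima for trajectories without
an event record.

## Synthetic inputs

Initial conditions are seeded multiplicative perturbations of a homogeneous
equilibrium, field = value·(1 + η ξ(x)), ξ i.i.d. standard normal,
η = 0.1 by default; noise fields are independent across species (switchable
— the published description only pins down the effector field), and
negative values are floored at 0.  Identical seed and spec give
bit-identical fields (`numpy` Generator with explicit seed, recorded in run
manifests).  Protocols implement the printed schedules: linear ramps in
σ_u or σ_w, the triangular IL-2 ramp (peak value as the argument; continuous
at the switch point, so the H(0) = 1/2 convention is immaterial), and the
boundary ramp B_w = 0.01 t.  The generator emulates small-amplitude
biological heterogeneity about a steady tumour; it does not model
macroscopic spatial structure, anisotropy, or parameter heterogeneity, so
passing tests demonstrate the *mechanism* (pattern-mediated resilience) and
not quantitative fidelity to any real tumour.

## Problem sizes and scaled runs

The reference study entry points (`immunores.studies`) use: the 3×3 ODE
system for Hopf and ramp-extinction quantities; m = 256 (L = 30) for the
patterned-branch fold with an m = 512 convergence check; 201×201 stability
scans for the α bound; 100×100 (side L = 300) for the δ_u = 10
boundary-dosing run and 64×64 for the ~5× longer δ_u = 1000 run.  The
test suite runs the three boundary-dosing comparisons at 64×64, and the
atto-fox invariance check on a 1D, m = 128, T = 500 triangular-ramp run at
the 1e-11 reference tolerances — at that fidelity the sink term engages and
changes saved fields by < 10⁻¹⁴, while at looser tolerances the
roundoff-level difference is amplified through the pattern instability (an
amplification property of the transient, not an effect of the term).

## Known limitations

- Quasi-static ramp results are rate-dependent (rate-induced delay of the
  collapse grows for faster ramps); extinction times under ramps are
  protocol-specific, not intrinsic.
- The extinction time of the slow effector ramp (T = 10⁵) is ≈ 3.47×10⁴,
  the ramp time to just past the subcritical Hopf dose (σ_u ≈ 0.0204).
- Approach to the cancer-free state is threshold-dependent: under the
  faster effector ramp (0.015 + 5×10⁻⁵ t) the tumour falls below 1% of
  carrying capacity at t ≈ 163 but below the 10⁻⁶ extinction threshold
  only at t ≈ 176.
- No two-parameter or 2D continuation; no normal-form criticality
  coefficients (criticality is read from branch geometry); no chemotaxis,
  haptotaxis or mechanics; no stochastic kinetics.
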