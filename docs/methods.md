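# Methods

## Scope and coordinates

`deantrack` simulates the lateral migration of rigid, neutrally buoyant
spheres in a rectangular-cross-section Archimedean spiral microchannel, one
way coupled: the fluid moves the particles, the particles do not disturb the
fluid, and particle–particle interactions are excluded (valid at the low
volume fractions used in practice).

The spiral centerline is `R(θ) = r0 + p·θ/2π` with pitch `p = w + s_gap`;
"turn spacing" is read as the wall-to-wall gap, so the centerline advances
by `w + s_gap` per turn. `r0` is taken as the centerline radius at the
inlet. Positions are cylindrical `(r, θ, z)`; the local cross-section frame
is `ξ = r − R(θ)` (positive toward the outer wall) and `ζ = z` (height off
the mid-plane). All internal units are SI; the configuration reader converts
µm, mm and mL/h.

The velocity scale is `U = 1.5·Q/(wh)` — the parallel-plate maximum-to-mean
ratio applied to the mean axial velocity. This single convention is used in
the channel Reynolds number `Re = ρUD_h/μ` and in the lift scaling; it is
the convention under which the printed Reynolds numbers of both study
channels (1.67–16.67 for the 100×50 µm spiral, ~50–150 for the 600×70 µm
one) are reproduced at their printed precision.

## Flow field

**Axial flow.** The exact rectangular-duct series (cosine expansion across
the shorter dimension, hyperbolic closure across the longer; 101 odd terms
by default, the `cosh` ratio evaluated in exponential form to avoid
overflow). The field is rescaled so its trapezoid-quadrature flow rate
equals `Q` exactly, and the wall rows are zeroed to make no-slip exact.
Checks: peak-to-mean ratio 2.0964 for a square duct and
`1.5/(1 − 0.630·h/w)` (lubrication closed form) for wide ducts — note this
is 1.519, not 1.500, at aspect ratio 50; the plane-Poiseuille 3/2 is only
reached in the limit (1.50 at aspect ratio 500).

**Dean secondary flow.** First-order perturbation: Stokes balance with the
centrifugal forcing of the axial flow,

    ∇²ω = −(ρ/(μR)) ∂(u²)/∂ζ,   ∇²ψ = −ω,
    v_ξ = ∂ψ/∂ζ,  v_ζ = −∂ψ/∂ξ,

with `ψ = 0` and Thom's wall-vorticity closure `ω_wall = −2ψ_adj/Δn²` on
all four walls. The vorticity equation, streamfunction equation and Thom
conditions are assembled as one sparse linear system and solved directly
(nondimensionalized by the half-height so the matrix is well conditioned);
an outer iteration on the wall vorticity is avoided because it does not
converge on fine grids. The solution is antisymmetrized in ζ (the
continuous problem is exactly odd) and the sign fixed so the mid-plane flow
points outward. Because the problem is linear with forcing ∝ 1/R, the field
bank solves at 8 radii spanning the spiral and interpolates componentwise
in 1/R — exact to rounding for this model. Net lateral flux at fixed ξ is
evaluated through the streamfunction (ψ at the top minus bottom wall),
which is identically zero; a quadrature of the differenced velocity would
carry O(grid) error instead.

Default grids: 121×61 (near-square cross-sections) and 241×41 (shallow,
width ≥ 4× height), chosen so the study particles span at least two cells;
doubling the resolution moves the peak secondary velocity by < 2%, and the
first-order amplitude scales exactly as 1/R.

**Spiral tangent projection.** The axial component is projected onto the
local spiral tangent: `u_r = v_ξ + u·R′/√(R′²+R²)`, `u_θ = u·R/√(R′²+R²)`
with `R′ = p/2π`. This small radial component (the fluid follows the
outward-winding channel) is essential: without it the channel centerline
slides outward under the particles at `u·p/(2πR)` ≈ 3 cm/s for the shallow
channel and every particle artificially collects on the inner wall.

## Inertial lift closures

The plane-Poiseuille net lift coefficient is a closed-form surrogate — a
Ho–Leal-type matched-asymptotics cubic

    f_L(s, Re) = C · s · (s_eq(Re)² − s²),   C = 22,
    s_eq(Re) = 0.6 + 0.15·(1 − e^{−Re/250}),

odd in the position fraction `s`, center-repelling inside `s_eq`,
wall-repelling outside, with the classical equilibrium at 0.6 of the
half-width at low Re shifting toward the wall as Re grows. The amplitude
sets the peak coefficient to ≈ 2.2 under the `F·D_h²/(ρU²a⁴)` normalization
used here, equivalent to ≈ 0.55 under the gap-squared normalization in
which the published matched-asymptotics curves peak near 0.5. Forces follow
`F = f_L·ρU²a⁴/D_h²`.

Three providers expose this over the cross-section:

* **superposed** — each wall pair acts as an independent plane channel
  (`F_ξ` from `2ξ/w`, `F_ζ` from `2ζ/h`); corner cross-coupling is
  deliberately ignored. In a square duct this gives 9 zeros: 4 stable on
  the diagonals, 4 on-axis saddles, an unstable center.
* **hood-style** — a synthetic field adding the quartic coupling
  `−2C·s_x·s_z²` (and symmetrically), which moves the stable zeros onto the
  symmetry axes and turns the diagonals into saddles, the topology reported
  for the asymptotic 3D-Poiseuille solution. It is a stand-in with that
  topology, not the published coefficients.
* **table** — bilinear interpolation of a plain-text grid
  (`# w= h= Re= a=` header, `ξ ζ F_ξ F_ζ` rows); the header must match the
  active channel within 1%.

Equilibria of any provider are found by sign-change bracketing on an 81²
scan of the admissible interior, polished with a 2D root solve, filtered to
residual < 1e-6 of the field maximum, and classified by the eigenvalues of
the mobility-scaled force Jacobian (centered differences, step 1e-4 of the
smaller duct dimension). Classification is cross-checked in the tests
against forward integration of the mobility dynamics from 8 surrounding
perturbations.

Lift acts only in the cross-section plane. The scenario ensembles use the
superposed provider: in the shallow channel it yields a single inner-wall
attractor consistent with the bench observations, whereas the synthetic
axis-stable variant (whose mid-plane points are ζ-stable) lets particles
strand on a mid-plane outer-wall balance point and split the ensemble.

## Particle dynamics

With densities matched and buoyancy dropped, the momentum balance is

    du_p/dt = G = (2/3M_p)(F_D + F_L + (M_p/2)·du_f/dt)
               + (u_{p,θ}²/r, −u_{p,r}u_{p,θ}/r, 0),

whose drag part is `(u_f − u_p)/τ` with `τ = ρR_p²/(3μ)` — the factor 3
(not 9/2·…) reflecting the virtual-mass-augmented effective inertia of a
neutrally buoyant sphere. The fluid acceleration along the trajectory is a
backward difference of the sampled fluid velocity at step k and a forward
difference at the predicted step k+1.

One step: explicit-Euler position predictor (clamped into the admissible
box for sampling); fluid velocity and lift sampled at the predicted
position; damped Newton solve of the trapezoidal velocity update
`v = v_k + (Δt/2)(G_k + G_{k+1}(v))` with the step-k velocity as initial
guess, an analytic Jacobian (`−I/τ` plus the centrifugal coupling block)
and residual-halving damping; trapezoidal position corrector with
`θ̇ = u_{p,θ}/r` evaluated at each end; wall projection (center clamped to
≥ R_p from every wall, wall-normal velocity zeroed on contact). The scalar
stepper retries a failed solve with a halved Δt (up to 5 times); in the
vectorized ensemble kernel a stalled particle is marked aborted instead.
The two code paths implement the identical scheme and are tested to agree
to ~1e-9 of the duct width at the outlet. Measured self-convergence order
of the full scheme is 2.0 ± 0.2; the trapezoidal rule is A-stable, so
Δt = 10τ remains bounded and accurate for the mean motion.

Defaults: Δt = 1e-4 s for the slow verification channel (Re ≤ 17) and
1e-5 s for the fast shallow channel — both resolve the Dean circulation and
axial transit by 10³–10⁵ steps; tolerances: Newton update norm < 1e-12 m/s,
≤ 30 iterations. Initial particle velocity equals the local fluid velocity
(consistent with the release assumption that makes Stokes drag acceptable
in the axial direction), and the backward difference is seeded with zero
fluid acceleration.

## Monte Carlo ensembles

Inlet positions are uniform over the rectangle inset by `R_p` from every
wall (the upper half only when the half-channel symmetry is exploited; the
mirror operation then appends ζ-negated copies, turning 100 released
particles into 200 records). Uniformity is an assumption — the study
protocol says only "random" — and is recorded in the run manifest together
with the seed. All particles advance together as one elementwise vectorized
batch; results are bitwise reproducible per seed and independent of
particle ordering. Integration stops at the outlet plane `θ = 2π·n_turns`
(outlet coordinates linearly interpolated in θ across the crossing step) or
at a time cap of 25 nominal transits; a run with more than 10% aborted
trajectories raises.

## Focusing metrics

Band center = median of the outlet coordinate; band width = 5th–95th
percentile span by default (full range and interquartile range are
selectable and recorded — the study never defines "width", so the
definition is explicit in every output); inner-wall distance =
`center + w/2`. Histograms use bins spanning the channel dimension exactly.
The flow-rate comparison table reports Q, Re, center, width and inner-wall
distance per run.

## What the generator does and does not emulate

The bundled scenarios reproduce the study conditions: the 100×50 µm, 3 mm,
5-turn verification spiral (1.9 and 7.2 µm particles, 0.3–3.0 mL/h) and the
600×70 µm shallow spiral (2, 10, 20 µm at 40–120 mL/h), water properties
ρ = 1000 kg/m³ and μ = 1 mPa·s, 100 particles per run.

Fidelity gaps, in decreasing order of consequence:

* **First-order Dean flow + straight-duct axial profile.** The real
  finite-De flow skews outward and its vortex cores shift; our cross-section
  fields are exactly ξ-symmetric. Near-tracer particles (1.9–2 µm, whose
  lift migration velocity is ~1e-8–1e-7 m/s) therefore circulate around
  centered vortices and pick up a slight *inner*-side dwell bias at the
  outlet, where the bench experiments report outer-wall accumulation.
* **Surrogate lift.** With the cubic surrogate at matched-asymptotics
  amplitude, the 7.2 µm verification case sits at a lift-to-Dean-drag ratio
  ~0.2: particles reach both `±s_eq` lateral bands and the weak inward Dean
  bias at their height equilibrium does not drain the outer band within
  five turns, so the outlet median is a near coin flip between the bands
  (≈ ±5–10 µm across seeds) rather than decisively inner as observed in the
  study. The size ordering is robust: the 7.2 µm interquartile spread is
  tighter than the 1.9 µm one.
* **Point attractor vs reported band width.** In the shallow channel the
  10 µm ensemble collapses onto a single attractor (53.7 µm from the inner
  wall; 5th–95th span 0.2–1.1 µm across seeds, < 0.1 µm with three extra
  turns). The study quotes a simulated width of "about 25 µm for all flow
  rates and for both particles" — a constancy consistent with a
  display-resolution floor over a collapsed distribution. We report the
  computed span without widening it.

Passing tests therefore demonstrate the internal correctness of the solver
chain and the robust qualitative physics (two-vortex secondary flow,
equilibrium topology and stability, inner-wall focusing of the large
shallow-channel particles, size-dependent spread ordering); they do not
certify outlet positions of near-tracer particles or absolute band widths
against fully resolved flow fields.

## Numerical details and degenerate inputs

Bilinear interpolation everywhere (exact at nodes, node-snap against
division roundoff); gradients for the Jacobians by centered differences;
equilibrium dedup radius of two scan cells; a lift query outside the
admissible box is clamped to it in ensemble mode and rejected in strict
mode; particle radius must be smaller than half the smaller duct dimension;
the Dean solve requires `R ≥ 2w` (small-curvature regime) and refuses
truncated series (< 10 terms) or grids coarser than 33 nodes per side.
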