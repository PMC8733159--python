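# Methods

`cardioloop` implements a sequential (cycle-to-cycle) fluid–structure
coupling for a cardiac chamber at desk scale.  The two physics solvers never
exchange data within a time step: the mechanics stage hands one settled
heart cycle of wall motion and boundary pressures to the fluid stage; the
fluid stage hands back one cycle of spatially resolved wall pressure,
condensed into a dimensionless pressure factor; the mechanics rerun with
that factor closes the loop.  Convergence is judged by the node-wise
Euclidean distance (ED) between the wall trajectories of successive
iterations.

## Geometry and discretization

The chamber is a 2D half-ellipse of unit depth: base plane at y = 0 with
half-width R = 25 mm, apex at y = −L with L = 70 mm, wall thickness
h0 = 10 mm, and wall parameter θ ∈ [0, π] sampled at 64 segments.  Two
straight port tubes attach at the base: the mitral inlet on the left half
(span fractions −0.625…−0.25 of the base half-width), the aortic outlet on
the right (0.25…0.5); each tube is four widths long so the port flow is
developed where the pressure boundary condition acts.  "Volume" throughout
means area × 1 m: the chamber holds ≈ 2.7 l, much more than a real left
ventricle.  We calibrate the activation and circulation so that the
*absolute* valve fluxes (tens to hundreds of ml/s) and chamber pressures
(≈ 1–8 kPa) lie in the physiological range, because the valve-opening law
thresholds (20 and 160 ml/s) act on absolute fluxes; the ejection
*fraction* of the 2D chamber is consequently small (a few percent) and is
not a target of the model.

The fluid grid is a structured fan of n_r × n_θ = 8 × 64 cells inside the
chamber (triangles in the innermost ring, which degenerates at the base
center) stitched node-exactly to Cartesian blocks in the ports, handled
uniformly as a polygonal finite-volume mesh (faces with owner/neighbour
cells).  Node and cell indices are frozen at build time; every coupling
iteration refers to the same material wall point by the same index, which
is what makes the ED metric well defined.

Mesh motion solves a Laplace problem per displacement component with
diffusivity γ = 1/max(δ, δ_floor)² — inverse squared distance δ to the
moving wall, floored at δ_floor = 1 mm.  Cells near the wall then follow it
almost rigidly while the far field absorbs the deformation.  The operator
is assembled and LU-factorized once on the reference configuration, so each
motion solve costs two triangular solves.  Boundary policy during a fluid
run: wall nodes follow the mechanics trace, base nodes outside the ports
slide along the base plane proportionally between the fixed port edge and
the moving base corner, port nodes and the fan origin stay fixed.

## Wall mechanics

Each of the 65 wall nodes carries one radial degree of freedom r_i along
its fixed ray.  The balance per unit wall area is

    m_eff a_i = (p_i − p_ext) − [T_pass(λ_i) + T_act(t) w_i]/r_i
                + κ (r_{i+1} − 2 r_i + r_{i−1}) − c_damp v_i ,

with λ_i = r_i/r0_i, surface density m_eff = ρ0 h0 (ρ0 = 1082 kg/m³),
neighbour regularization κ = 2·10⁵ Pa/m, damping c_damp = 2·10⁴ Pa·s/m
(strongly damped — the toy wall is meant to track its quasi-static balance,
not to ring), and one-sided stencils at the apex/base ends.

Passive tension comes from the transversely isotropic exponential
(Guccione) law W = C/2 (e^Q − 1) + K/2 (J − 1)², with the standard
ventricular constants C = 278 Pa, b_f = 12.0, b_t = 4.8, b_ft = 8.4,
K = 200 kPa, reduced to membrane kinematics (fiber circumferential,
plane-strain incompressible: E11 = (λ²−1)/2, E33 = (λ⁻²−1)/2, J = 1) and
differentiated analytically: T = h0 λ dW/dλ.  Atrial and surrounding
tissues carry Neo-Hooke presets (isochoric-split form) but only the
ventricular row drives the toy wall.

Active stress is the two-sigmoid ("double Hill") drive
a(τ) = T_peak g₁(τ) g₂(τ), τ the cycle phase, with shape constants
α₁ = 0.303, n₁ = 1.32, α₂ = 0.508, n₂ = 21.9 — classic systolic-twitch
values for this model family; the product form means the realized peak is
≈ 0.59 T_peak.  T_peak = 70 kPa puts the peak wall stress near 40 kPa.
The cycle period is T = 1.247 s.  The active stress tapers toward the base
corners as sin θ: the valve annulus of a real heart is far stiffer than the
free wall and barely contracts; numerically the taper also keeps the
near-base fluid cells from being crushed against the rigid port tubes.

The circulation is deliberately minimal: a constant atrial preload
(7.5 mmHg) behind a mitral diode (R_mv = 1.2·10⁶ Pa·s/m³), an aortic diode
(R_ao = 8·10⁵) into a two-element Windkessel (R_per = 1.9·10⁸,
C_art = 1.6·10⁻⁸ m³/Pa), chosen to give a classical pressure–volume loop
at the chamber's scale.  The chamber pressure is slaved to the volume
balance through a stiff artificial compliance,
dp/dt = K_c (Q_mv − Q_ao − V̇_wall)/V with K_c = 10⁸ Pa, updated backward
Euler.  Two numerical points matter here:

* The pressure solve includes the wall's one-step velocity response
  (admittance A_w = dt·perimeter/(m_eff + c_damp dt)): without it the
  stiff compliance and the explicit wall integrator form a feedback loop
  with gain |g·A_w| ≫ 1 at dt = 1 ms and the scheme explodes.  With the
  admittance (over-relaxed by a factor 2 so the residual halves per step)
  the pair is a damped quasi-Newton iteration on the volume constraint.
* The diode configuration is found by case analysis; the right-hand side
  is monotone in p so exactly one configuration is consistent.

Integration: RK4 at dt = 1 ms for the wall, with the wall pressure held
over the step; ten cycles reach a limit cycle (max node displacement
between cycles 9 and 10 is below 0.02 mm, well under the 0.1 mm
convergence tolerance used for the coupling).  The run is initialized at
the passive equilibrium stretch of the initial chamber pressure to shorten
the transient.  The last cycle is resampled onto 250 uniform phase points
(≈ 5 ms spacing; 1.247 s is not divisible by exactly 5 ms) — the shared
grid all stages use, so the factor needs no cross-grid mapping.

## Fluid stage

Incompressible Navier–Stokes in ALE form on the moving grid, solved by a
non-incremental pressure projection: explicit first-order upwind
convection on the relative face fluxes φ_f = U_f − V̇_mesh,f, explicit
compact viscous fluxes, implicit pointwise Darcy drag, then a pressure
Poisson solve that enforces ∑_f U_f = 0 per cell.  Blood: ρ = 1055 kg/m³,
μ = 0.004 Pa·s.

The mesh flux of each face is its exact swept volume per unit time; summed
around a cell these reproduce the cell volume change identically (discrete
geometric conservation), so a uniform velocity field survives arbitrary
mesh motion to round-off — verified to 10⁻¹⁰ in the tests.  Wall faces
carry exactly the mesh flux (no flow through a no-slip wall), making the
scalar advection conservative to round-off on closed domains.

Valves are porous zones at the port mouths (depth 6 mm).  The
Darcy–Forchheimer drag per unit mass is

    F_p = −(φ μ)/(ρ k_p L²) u_rel − 1.75 φ/√(150 k_p L²) |u_rel| u_rel ,

with porosity φ = 1, reference length L = the valve-zone depth (making
k_p L² a dimensional permeability), and the dimensionless permeability k_p
ramped with the instantaneous chamber volume-flux magnitude: blocked
(k_p = 10⁻⁷) below 20 ml/s, fully open above 160 ml/s, linear in between;
the same single curve is used for opening and closing (no hysteresis).
The mitral zone responds to filling (V̇ > 0), the aortic zone to ejection
(V̇ < 0).  The Darcy term is treated implicitly
(β = 1/(1 + dt(a + b|u_rel|))) and the same β scales the face-flux
corrections in the projection, so a blocked valve resists the pressure
solve too; a fully blocked zone passes < 10⁻³ of the open-valve flux under
the same pressure drop.  Cell velocities are corrected from the β-weighted
face-flux corrections through the Gauss reconstruction identity rather
than a raw pressure gradient — a cell next to a blocked zone must not see
the valve's pressure jump.

Time steps adapt to CFL ≤ 0.7 with the per-cell flux-based Courant number
(cell volume over half the summed |u_rel·S_f|), which remains meaningful
for the high-aspect cells near the fan center; further bounds: the
explicit-diffusion limit, 1.2× growth per step, a resolution cap
dt_max = 5 ms, and dt₀ = 1 ms for the first step.  Port-end pressures are
Dirichlet (the mechanics' atrial and arterial traces); the fluid starts at
rest and runs four cycles to a limit cycle (the L² cycle-to-cycle
difference of the wall pressure decreases monotonically).  Wall pressure
is sampled per wall segment from the wall-adjacent cell at every accepted
step and interpolated onto the shared 250-point phase grid.

Washout is tracked by a passive scalar (convection–diffusion with
D = 10⁻¹⁰ m²/s, a purely numerical diffusivity) initialized to 1 in the
chamber and 0 in the ports; first-order upwind keeps it in [0, 1] under
the CFL bound, and the residual volume is ∑ ψ_c V_c over chamber cells.

Solver verification: steady Poiseuille channel flow matches the closed
form to 0.01% at 32 cells across (the half-cell wall-flux treatment is
exact for a parabola), and the free-stream/GCL and scalar-conservation
checks hold to 10⁻¹⁰.

## The pressure factor

For each stored time the spatial statistics p_min, p_max, p_mean over the
chamber's wall elements (unweighted — elements count equally) define the
time-resolved scaling y_s = 2 (p_max − p_mean)/p_max, clipped to [−3, 3],
and the factor

    x_i = y_s (p_i − p_mean)/(p_max − p_min) + 1 .

The element mean of x is exactly one, so multiplying the circulation's
chamber pressure by x (p*_i = p_chamber x_i) redistributes the wall load
spatially without changing its mean — the circulation model stays in
balance.  With y_s = 1 the factor is bounded in [0, 2].  Degenerate inputs
follow two conventions that preserve both the mean-one property and the
identity behaviour: a spatially uniform field gives x ≡ 1, and p_max = 0
gives y_s = 0.  Note that this y_s does *not* make x·p_mean reconstruct
p_i exactly (that would require y = (p_max − p_min)/p_mean); the
definition is applied literally and no reconstruction is enforced.

Two robustness measures proved necessary at desk scale:

* After computing x we subtract the (round-off-sized) residual of the
  element mean, so the mean-one constraint holds to 10⁻¹² even for
  adversarial fields.
* The factor and the scaling trace are smoothed by a centered periodic
  moving average over a 60 ms window (`coupling.pf_smooth_s`).  The
  end-ejection pressure collapse (aortic closure drops the chamber
  pressure from ≈ 7.6 kPa to ≈ 1 kPa within ≈ 25 ms) otherwise imprints
  large single-sample deviations exactly where y_s is ill-conditioned
  (p_max near zero), and the coupling loop amplifies them from iteration
  to iteration until the mechanics diverges.  Smoothing is a convex
  combination per element, so the mean-one constraint, the clip bound,
  the x ∈ [0, 2] bound at y_s = 1, and the identity field all survive it
  exactly.  A time window of this kind is the natural stabilization for a
  coupling that exchanges data only once per cycle and is sensitive to
  the temporal alignment of fast valve events.

The factor is stored against cycle phase and linearly interpolated (with
periodic wrap) to mechanics time steps; the interpolation is written as
x₀ + w(x₁ − x₀) so the identity field reproduces exactly 1.0 in floating
point, and the mechanics run with x ≡ 1 is bitwise identical to the
uncoupled run — the fixed-point anchor of the whole scheme.  Mechanics
nodes receive the mean of their adjacent segments' factors.  By default
the factor acts only in the last mechanics cycle (`coupling.pf_window =
"last"`); setting `"all"` applies it throughout, which hands the fluid a
fully settled coupled motion — both contract on the default preset, the
last-cycle variant slightly faster.

## Coupling protocol and diagnostics

Iteration 0: 10 mechanics cycles uncoupled → 4 fluid cycles → factor.
Iteration j ≥ 1: 10 mechanics cycles with the factor → ED against the
previous iteration's last cycle → 4 fluid cycles → next factor.  The loop
stops when the maximum ED drops below tol (default 0.1 mm, motivated by
the sub-0.1 mm iteration-to-iteration changes observed once the loop has
contracted) or after max_iter = 3 iterations; a non-decreasing ED raises a
"coupling not contracting" warning in the report.  On the default preset
the maximum ED falls ≈ 0.62 → 0.19 → 0.12 mm over three iterations: the
first iteration does most of the work.

Diagnostics: ED fields and min/max/mean summaries (mm, per node group plus
overall); factor quantile bands per time (extrema, central 50% and 90%
envelopes, type-7 quantiles); residual-volume washout traces (ml); and PV
loops (ml vs mmHg, conversion 1 mmHg = 133.322 Pa).

## What the synthetic generator does and does not emulate

`make_synthetic_pressure_field` produces seeded element-pressure fields
with the observed structure of ventricular wall pressures: one dominant
smooth chamber waveform, localized systolic overpressure near the outlet
elements, an early-filling bump near the apex, and white measurement-like
noise (profiles: uniform / outlet-jet / apex-jet / noise).  It does not
emulate valve-closure transients, wall-motion feedback, or spatial
correlation beyond the single bump, so tests built on it validate the
factor pipeline's algebra and bookkeeping — not the hemodynamics; the
solver-level tests and the coupled run cover those.
`make_synthetic_wall_motion` produces the matching base-tapered periodic
contraction for running the fluid stage stand-alone.

## Known limitations

* 2D unit depth: no out-of-plane flow, no vortex-ring dynamics, volumes
  and ejection fraction are not physiological even though pressures and
  fluxes are.
* One chamber: the factor pipeline takes an element-set argument so
  several chambers are supported by bookkeeping, but the toy has only the
  ventricle.
* The fan grid degenerates at the base center; the flux-based CFL handles
  the high-aspect cells but local resolution there is poor.
* First-order upwind transport smears the washout front; the residual
  volume is reliable, sharp concentration gradients are not.
* The lumped circulation is a stand-in tuned for a classical PV loop, not
  a validated closed-loop model; absolute pressures should be read
  qualitatively.
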