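# Methods

This note documents the numerical methods, the defaults and the design
choices of flexmarine, module by module, including what the synthetic test
fixtures do and do not demonstrate about real applications.

## Mesh and dual geometry

A 2D mesh is a node table plus polygon connectivity (counter-clockwise).
The Voronoi point of each polygon is computed as the least-squares
circumcenter of its vertices — exact for cyclic polygons (triangles,
rectangles, regular hexagons), which covers every orthogonal tessellation
the framework targets. Orthogonality is verified as the angle between each
interior face and its dual edge; the default tolerance is 0.5°, and mesh
construction fails naming the worst face beyond it. Polygons whose Voronoi
point falls outside themselves are accepted but flagged
(`Mesh2D.voronoi_outside`), since the two-point flux approximation degrades
there; the user decides.

The vertical uses fixed z-layer interfaces starting at 0 (positive down).
A cell is wet if its layer top lies above the local bathymetry; the bottom
cell is clipped to the bathymetry (partial bottom cell) rather than
stair-stepped, so the wet volume of every column equals area × depth
exactly. Face layer thicknesses take the minimum of the two adjacent
columns, which closes flow at bathymetry steps.

Sections are built by intersecting a user polyline with interior faces;
the sign convention is "positive to the right of travel", so a
counter-clockwise loop measures outflow, and a face crossed twice in
opposite directions cancels. Meshes are stored in projected local-Cartesian
meters; an equirectangular lon/lat helper is provided for convenience but
spherical metrics are out of scope.

## Hydrodynamics

The solver is the hydrostatic predictor of the classic semi-implicit
C-grid family. Per step:

1. Smagorinsky viscosity ν = (C_s √A)²|S|, with |S| = √(2 S_ij S_ij) from
   least-squares gradients of cell-centre velocity vectors (themselves
   reconstructed from face-normal components by per-cell least squares —
   exact for uniform fields).
2. Explicit momentum tendency, AB2-combined (1.5 F^n − 0.5 F^{n−1}, first
   step forward Euler): upwind advection of the reconstructed cell
   vectors projected back to faces (the spatial operator is a
   framework choice; the mean of the adjacent values is used at exactly
   zero face flux), horizontal/vertical diffusion, Coriolis from the
   face-averaged reconstructed velocity, baroclinic pressure gradient from
   the hydrostatic integral of ρ(T, S) − ρ₀, wind stress on the surface
   layer and quadratic bottom drag C_b|u|u on the deepest wet layer.
   Vertical momentum advection is neglected (hydrostatic, thin-layer
   regime).
3. θ-weighted free-surface solve: eliminating u^{n+1} from continuity
   yields an SPD system for η^{n+1}, solved by Jacobi-preconditioned CG to
   a 1e-12 relative residual. After the velocity correction, η is
   recomputed from the discrete continuity equation itself, which makes
   volume conservation exact to round-off (verified over 10⁴ steps).
   Open-boundary cells may clamp η, open faces may clamp u (both,
   "clamped" boundaries); prescribing both on the same cell lets the η
   clamp absorb the flux, so throughflow setups prescribe u only.
4. Optional T/S transport and equation-of-state update (linear EOS by
   default, ρ = ρ₀(1 − α_T(T−T₀) + β_S(S−S₀)) with α_T = 2·10⁻⁴ K⁻¹,
   β_S = 7.6·10⁻⁴ PSU⁻¹; EOS-80 available as `mode="unesco"`).

The free surface is linearized: flux thicknesses are the undisturbed ones
while the surface-layer *volume* carries η, which is consistent with the
seiche dispersion test and keeps tracer constancy exact. θ = 0.5 is
second-order and least damped (the package verifies the damping ordering
0.5 < 0.75 < 1.0 on the seiche); energy at θ = 0.5 oscillates slightly
within a period between the staggered kinetic and potential reservoirs, so
the energy-decay check compares period means. The non-hydrostatic
corrector is not implemented (a `nonhydrostatic` flag is reserved);
wetting/drying, waves and sea ice are out of scope.

## Transport

Flux-form first-order upwind advection on the same θ-weighted face volume
fluxes the continuity equation used, plus two-point centered diffusion.
Because tracer and continuity share their discretization, a uniform tracer
remains uniform under any solver-produced flow, and closed-basin mass is
conserved to round-off. Vertical interface fluxes are diagnosed by
integrating layer continuity from the bottom; the residual is absorbed by
the free surface. Two schemes:

* explicit — both directions upwind/centered, guarded by a per-cell
  Courant check (sum of outflows × dt / volume ≤ 1) that raises with the
  maximum Courant number and a suggested dt;
* vertically semi-implicit — horizontal explicit, vertical advection
  (upwind) + diffusion solved fully implicitly per column (θ_v = 1; the
  tridiagonal operator is an M-matrix, hence unconditionally stable and
  free of new extrema). The two schemes agree to ≲1e-6 at small dt.

Open boundaries are clamped: inflow faces use the prescribed boundary
concentration in the upwind flux, outflow faces the interior value; a
missing boundary series for an advected variable is a configuration error
at load time. Negative concentrations from round-off are clipped with the
lost mass accumulated in the run log. Higher-order/flux-limited advection
is an extension point, not implemented.

## Equation systems

The DSL grammar (EBNF in `equations.py`) supports arithmetic, `^`
(right-associative), comparisons producing 0/1, `if(cond, a, b)` and the
function set exp/log/sqrt/min/max/abs/sin/cos/tanh/pow/step. Expressions
are parsed once into ASTs and evaluated with numpy over all active cells;
auxiliaries are topologically sorted (cycles are reported with the cycle
listed). Environment names available to equations: temp, salt, light,
depth, bottom_stress, time, x, y, z. Evaluation is strictly cell-local —
identical trajectories in 0D and in a 3D run with zero flow, which the
tests verify.

Time integration is forward Euler at the model step (RK4 optional); a
diagnostic warns when |dt·RHS/C| > 0.5. Stiff systems remain the user's
responsibility.

Vertical transfers are separate conservative operators:

* settling — upwind flux w_s·c between layers, internally sub-stepped when
  w_s dt exceeds the thinnest layer; bottom-cell flux deposits
  (c·w_s·dt per area) into the mapped benthic variable;
* resuspension — erosion E(τ/τ_cr − 1) into the bottom pelagic cell when
  the quadratic-drag bottom stress τ = ρ₀C_b|u_b|² exceeds τ_cr, capped by
  the available benthic inventory;
* interface exchange — flux k_ex(c_bottom − B/h_mix) per area, where
  h_mix is the benthic mixing depth defining the porewater-equivalent
  concentration. The linear pair is integrated with its exact exponential
  factor, so the discrete relaxation rate equals the analytic
  k_ex(1/h_p + 1/h_b) for any dt and the transfer never overshoots
  equilibrium.

The benthic model is a per-polygon layered stack (per-area units); lateral
benthic transport is not represented. Sediment-transport setups are just
equation systems with settling/resuspension parameters per grain-size
fraction (the shipped plume fixture uses Stokes velocities for 66 µm and
9 µm grains: 3.9·10⁻³ and 7.3·10⁻⁵ m/s).

## Heat budget

Fick mode applies k(T_air − T_surface) wholly to the surface layer (the
closed-basin e-folding time ρc_p h/k is verified to 1%). Flux mode uses:
clear-sky shortwave S₀ cosZ τ^(1/cosZ) from declination/hour-angle
geometry (τ = 0.7 default), reduced linearly by cloud (factor 1 − 0.62C)
and by the surface albedo (0.06); Berliand net longwave with vapor and
cloud corrections; sensible and latent fluxes proportional to wind speed
with transfer coefficients 1.1·10⁻³/1.3·10⁻³; humidity from relative
humidity or dew point via the Magnus formula.

In-water absorption uses one extinction scale: the flux decays to e⁻¹ of
its sub-surface value over the penetration depth (≈ Secchi depth; a single
shared parameter — a separate solar extinction was considered and left as
a possible extension). Shortwave reaching the bottom is reflected
(default reflectivity 1, keeping all heat in the column; the non-reflected
share heats the bottom layer) and re-absorbed on the way up; whatever
survives to the surface is spread uniformly per volume. The non-solar sum
follows the same downward law with its bottom remainder spread uniformly.
These reflect-and-redistribute rules close the budget identically, which
both the unit tests and the 10⁴-step heat-content check confirm. The
shortwave profile is exported as the `light` environment field.

ρc_p defaults to 4.09·10⁶ J m⁻³ K⁻¹; all coefficients are exposed in the
configuration.

## Agent-based module

Velocities are interpolated to agent positions by barycentric (area
coordinate) weights on the Delaunay triangulation of the Voronoi points,
applied to the reconstructed cell-centre vectors; this reproduces linear
velocity fields exactly inside the hull and collapses to the cell value at
a Voronoi point. Outside the hull (or on degenerate 1D meshes) the
containing cell's value is used. Vertical interpolation is linear between
layer centers.

Advection is RK2 midpoint per ABM sub-step (any integer multiple of the
global dt; Euler available for cross-checks). Diffusion is a uniform
directional random walk: horizontal step √(4 D dt) at a uniform angle,
vertical ±√(2 D_v dt) with reflection at surface and bottom. No
inhomogeneous-diffusivity (Visser) correction is applied, matching the
uniform-random-component design; the well-mixed test therefore uses
uniform diffusivity. Because the step length is fixed per dt, the vertical
walk is lattice-valued — long-run uniformity holds once initial depths are
spread, but users sampling fine vertical structure should start agents at
randomized depths.

Boundary handling uses the end-of-step position (an agent can in principle
jump across a thin wall in one very long sub-step — documented risk, kept
because sub-steps are short by construction): an agent ending outside the
wet domain returns to the Voronoi point of its last wet element at
unchanged depth (clipped to the local bathymetry); if the exit segment
crosses an open face and the boundary is a sink, the agent is deactivated
instead. Each agent owns a counter-based RNG stream keyed by
(seed, agent id), so trajectories are bit-reproducible and independent of
sub-step or population changes.

Downstream connectivity censuses final positions (default; a DSL
deactivation criterion supports settlement-style censusing): P[i][j] is
the fraction of agents released in region i censused in region j, with an
explicit "lost" column so rows always sum to 1; zero-release regions give
NaN rows with a warning.

## Offline hydrodynamics

Snapshots (face velocities, or per-layer speed/direction profiles
broadcast to faces, plus optional η, T, S, K_v) are interpolated linearly
in time; requesting a time outside coverage is an error (no
extrapolation). A per-cell divergence report is available for third-party
fields; fields produced by this package's own solver replay the coupled
tracer evolution exactly when every step is stored, and within linear
interpolation error otherwise. The wind-dependent vertical diffusivity is
a power law a·W^b + K₀ with defaults a = 10⁻⁴, b = 1, K₀ = 10⁻⁵ m² s⁻¹ —
the functional form is this package's choice. The offline file format is
this package's NetCDF layout (written with the NetCDF3/scipy backend).

## Runtime, configuration, outputs

The per-step module order is fixed and part of the contract: forcings →
hydrodynamic provider (full solver | offline | none — mutually exclusive)
→ heat → tracer transport → equation systems (react, settle, resuspend,
exchange, clip) → ABM → outputs. Setup files are XML; validation
aggregates *all* errors (alternative-provider conflicts, missing boundary
series for advected variables, output intervals that do not divide dt,
equation-system problems, …). Outputs are NetCDF for fields and
trajectories and delimited text for section fluxes and connectivity; state
checkpoints round-trip doubles bit-exactly. The run log records volume and
mass budgets per output interval, clipped-negativity totals and
provenance (config hash, seed, version). Everything is single-threaded
and deterministic given the seed.

## Synthetic fixtures: what they show and what they do not

The fixture generator builds orthogonal-by-construction rect and hex
meshes, analytic bathymetries, streamfunction gyres and uniform currents,
and six complete runnable recipes (box_npzd, seiche, channel, gyre_abm,
farm_depletion, sediment_plume), each sized to run in seconds on one CPU:
domains of 10²–10³ cells, idealized forcing, no real coastlines, tides or
observed meteorology. Passing tests on these fixtures demonstrates the
correctness of the numerics (conservation, analytic limits, scheme
consistency, statistical behaviour of the agents) and the qualitative
patterns of the application recipes (depletion strongest in and decaying
away from a farm block; coarse sediment depositing nearer the source than
fine). They do not validate real-world skill, which requires observed
boundary forcing, bathymetry and calibration beyond this package's scope.

## Problem sizes used by the shipped checks

The analytic-limit checks use a 50×1-cell seiche basin (dt 4 s, 800
steps), a single-cell inertial oscillation (two periods at dt 60 s), a
100-layer diffusion column (500 steps) and a 2000-step Newton-cooling
relaxation; the conservation checks run 10⁴ steps each on ≤25-cell
domains; the agent suite uses up to 10⁴ agents on a 1600-cell mesh. These
sizes were chosen so the full suite exercises every module in about a
minute while leaving all measured errors far from their acceptance
thresholds.
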