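# Methods

## Geometry and meshing

The vitreous chamber is the set {|x| ≤ r_v} ∩ {z ≤ z_h} minus the lens
sphere, in a right-handed frame with the z-axis pointing anterior and the
origin at the vitreous centre. All internal lengths are SI metres; times are
reported in days. Species parameters (vitreous radius, truncation plane,
lens centre/radius, injection-bolus origins, diffusion coefficient, Darcy
mobility) are the anatomical values tabulated in `geometry.SPECIES_PARAMS`,
`darcy.SPECIES_FLOW` and `transport.SPECIES_TRANSPORT`. Closed-form audits
(sphere minus two spherical caps for the volume; planar annulus for the
hyaloid area) reproduce the printed 1.44/4.79 mL volumes and 0.81/1.47 cm²
areas and anchor the mesh checks. A geometric curiosity worth knowing: with
these parameters the rabbit lens sphere passes exactly through the origin,
so (0,0,0) is a boundary point of the rabbit domain, not an interior one.

Meshing places nodes explicitly on every surface (Fibonacci lattice on the
outer sphere, concentric rings on the hyaloid annulus and the lens patch,
explicit rim circles where surfaces meet, and a guaranteed vertex at the
fovea), fills the interior with a jittered cubic lattice, Delaunay-
triangulates the cloud, and keeps the tetrahedra whose centroid lies inside
the domain. The jitter (deterministic per seed, ±0.22 of the local spacing)
exists solely to break the co-spherical degeneracies of a regular lattice.
Because boundary nodes interpolate the true surfaces, mesh volume and tagged
areas converge at second order; at the default element sizes (0.68 mm
rabbit, 0.95 mm human, ~35–45k cells) the volume error is ≈0.1% and the
hyaloid-area error ≈0.005%. Boundary facets are tagged HYALOID / LENS /
ANTERIOR_OUTER / POSTERIOR_OUTER by nearest surface, with the outer sphere
split at z = 0 and z = 0 assigned to the anterior side. Optional refinement
balls (used around the injection bolus by the study runner, factor 1.5)
shrink the local spacing. Meshes export as Gmsh MSH 2.2 and legacy VTK.
The default element count deliberately targets mesh-independent PK metrics,
not parity with any particular element count: the mesh/step-independence
test shows the half-life moves <1% between the default and a 0.8×-size,
half-step discretisation.

## Darcy flow

With ε = 1 and constant mobility κ/μ, continuity reduces to a pressure
Poisson problem. Boundary conditions: uniform normal inflow u_in on the
hyaloid (a single scalar, as the inlet is specified), p = 0 on the posterior
outer surface, zero normal flow on lens and anterior outer surface. The slow
inlet speed is derived as (3 μL/min) × (fraction entering the vitreous:
0.07 rabbit, 0.10 human) / hyaloid area → 4.3×10⁻⁸ and 3.4×10⁻⁸ m/s; the
fast regime uses 1.5×10⁻⁷ m/s. We use the physical sign convention
u = −(κ/μ)∇p (flow from high to low pressure). A primal P1 formulation is
used (Poisson for p, cellwise velocity by gradient recovery) rather than a
mixed method: only the velocity field is consumed downstream, and the
discrete boundary fluxes are recovered *consistently* — the prescribed
Neumann load on the hyaloid and the reaction residuals at the outlet nodes —
so the flux balance closes to machine precision even though the recovered
P0 velocity itself is only first-order accurate. Pressures are gauge
(relative to the outlet); the solved drops are ≈2 Pa (slow) and ≈9 Pa
(fast) in the human eye.

## Drug transport

P1 Galerkin with lumped mass; convection is assembled in the advective form
∫(u·∇C)φ with the cellwise-constant Darcy velocity. At the slow-convection
velocities and default element sizes the cell Péclet number is ≲0.5 (≈2 for
the fast case), so no stabilisation is applied by default. Time integration
is backward Euler with a two-block step schedule — 0.05 d for the first two
days while the bolus interface is sharp, 0.25 d afterwards — chosen for
unconditional stability next to absorbing boundaries; the schedule is our
own (validated by the step-halving independence test), and first-order
stepping biases the fastest-decaying cases slightly long (≈λ·Δt/2, i.e.
a few percent for half-lives under a day).

The sharp bolus initial condition is projected vertex-wise (C_i inside the
sphere, 0 outside) and rescaled so the lumped-mass integral equals the dose
exactly, rather than smoothed over a mollification length: the rule is
trivially reproducible and dose-exact. Fields are never clipped during
integration; only reported scalar series are floored at zero, and the worst
nodal undershoot is recorded (bounded by 10⁻³·C_i after the first day).

Boundary conditions per case: the hyaloid is always a perfect sink (C = 0);
lens and anterior outer surface always carry zero total flux; the posterior
outer surface is a sink in cases b. In case 1a the posterior surface is the
fluid outlet, and we let the convective drug flux leave with the fluid
(zero *diffusive* flux only). Treating it instead as strictly total-flux-
zero would make convection *lengthen* the case-1a half-life (the flow sweeps
drug posteriorly where nothing removes it — we measure ≈22 d for the human
middle injection), which contradicts the characteristic case ordering
2a > 1a > 1b and the strong shortening under fast convection; the outflow
treatment reproduces both. Discretely, the no-flux walls need no extra
boundary term: the recovered velocity field carries exactly zero weak flux
through them.

Mass accounting is exact by construction: sink losses are the reaction
residuals at Dirichlet nodes, and convective outflow is Σ qⱼCⱼ over outlet
nodes with qⱼ the nodal Darcy outflux — both conjugate to the discrete
operators — so the audit |mass + cumulative outflux − initial mass| /
initial mass closes to ~10⁻¹⁴ on every case, diffusion or convection.

## PK reductions

* **Half-life**: from a fixed baseline (3 d rabbit, 5 d human), the time for
  the vitreous-average concentration to halve, located by log-linear
  interpolation between samples (exact for exponential tails; the
  interpolation order is our choice).
* **In-vivo threshold**: 12.5 μg over the 4.79 mL human vitreous → 2.6 μg/mL
  (2 significant figures).
* **Duration of action**: last 0.5-day-resolved time before the average
  concentration permanently drops below the threshold, matching the 0.5-day
  precision of the reported tables.
* **Fovea concentration**: a point probe at (0,0,−r_v) for cases without a
  posterior sink. With a posterior sink the boundary value is identically
  zero, so the drug level just outside the vitreous is estimated from the
  consistent boundary flux at the fovea vertex: flux × macula area / macula
  volume gives a deposition rate, integrated over a trailing 1-day window
  (rectangle rule, earliest window truncated). The macula area uses the
  flat-disc approximation π(d/2)² (d = 5.5 mm human, 3.84 mm rabbit scaled).
  The window construction is a convention; the day-7 value for the 12.5 μg
  human case 2b lands within a factor ~1.4 of the reported 0.44 μg/mL, and
  we treat agreement only to within 2× as meaningful.
* **Dose scaling** exploits PDE linearity: one unit-dose run rescales to any
  dose to machine precision.

## Verification

* Absorbing sphere: remaining-mass fraction vs the eigenfunction series
  Σ 6/(n²π²)·exp(−Dn²π²t/a²), checked at t = a²/4D (and the series itself
  against an independent 10⁴-shell radial finite-difference solution).
  The comparison normalises by the true initial mass C₀V, counting the
  sink's instantaneous absorption of the boundary-vertex mass as absorbed.
* Manufactured solutions on the rabbit domain: a quadratic-in-space,
  exponential-in-time solution (with matching source and Dirichlet data on
  all surfaces) gives an observed spatial L2 order ≈1.9; a linear-in-space
  solution (exactly representable by P1) isolates the temporal error and
  gives order ≈1.0.
* A structured box-column mesh reproduces the closed-form 1D Darcy profile
  to solver precision.
* Monte-Carlo rejection sampling (fixed seed) confirms the closed-form
  volume within 3 standard errors.

## Synthetic PK curves

Digitised experimental curves from the literature are supported as user CSV
(`time_days, concentration`) but not bundled — they are figure-derived
third-party data. `synthesize_pk_curve` generates stand-ins: exponential
decay with multiplicative log-normal noise of given CV, deterministic per
seed. These emulate the sparse sampling (≈8 points) and ~20% scatter of
real vitreous PK measurements but none of their systematic features (assay
floors, inter-animal variability, non-exponential early phases), so tests
that pass on them demonstrate the reader/comparator machinery and estimator
robustness to noise — not agreement with any real dataset.

## Problem sizes and known limitations

Default production runs use ~35–45k cells and ~250–400 implicit steps; a
full human case runs in seconds on one CPU, and the acceptance script's six
simulations complete in well under a minute. Limitations: homogeneous,
non-liquefied vitreous (no Brinkman region); perfect-sink or zero-flux
boundaries only (no finite membrane permeabilities); no reaction/binding or
VEGF pharmacodynamics; single-bolus dosing only; the rabbit "macula" is a
proportional construct, as rabbits have a visual streak rather than a true
macula. The fast-convection cases sit at cell Péclet ≈2 without
stabilisation and are a few percent less accurate than the slow/no-flow
cases; fastest-decaying (case b) half-lives carry an additional few-percent
first-order time-stepping bias at the default schedule.
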