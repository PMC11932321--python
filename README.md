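# ivtpk — spatial pharmacokinetics of intravitreal bevacizumab

`ivtpk` simulates the fate of a bevacizumab bolus injected into the vitreous
of a rabbit or human eye. It is aimed at ocular-pharmacology modellers who
want a lightweight, scriptable alternative to commercial finite-element
packages for exploring how elimination routes, vitreous convection, and
injection placement shape intravitreal PK — vitreous half-life, duration of
action, and the drug level reaching the fovea, the therapeutic target in wet
age-related macular degeneration.

## Model

The vitreous is a truncated sphere of radius r_v (7.6 mm rabbit, 10.9 mm
human), cut by the hyaloid membrane plane z = z_h, with the lens sphere
subtracted; the fovea sits at the posterior pole (0, 0, −r_v). Aqueous humor
percolating through the vitreous (porosity ε = 1) obeys Darcy's law,

    u = −(κ/μ) ∇p,    ∇·u = 0,

with a uniform inflow speed u_in on the hyaloid membrane (derived from the
3 μL/min aqueous production rate) and gauge pressure p = 0 on the posterior
outer surface. Drug transport is convection–diffusion with no reaction,

    ∂C/∂t = ∇·(D ∇C) − u·∇C,

starting from a 0.05 mL spherical bolus at C_i = 0.167 mol/m³ (1.25 mg of a
149 kDa antibody). Four case studies combine convection (1 = yes, 2 = no)
with elimination routes (a = anterior sink C = 0 on the hyaloid only,
b = anterior + posterior sinks). Lens and anterior outer surfaces are
impermeable walls; in case 1a the posterior surface is the fluid outlet and
carries the convective drug flux out while its diffusive flux is zero.

Everything is discretised with linear (P1) tetrahedral finite elements on a
Delaunay-carve mesh of the domain, lumped mass, and backward-Euler time
stepping. Boundary fluxes are recovered consistently (reaction fluxes at
sink nodes, nodal Darcy outflux at the outlet), so the mass ledger closes to
solver precision and every run carries a mass audit.

## Worked example

```python
from ivtpk import (build_eye_geometry, generate_mesh, make_injection_site,
                   solve_darcy, simulate_transport, half_life,
                   duration_of_action, FlowParams, TransportParams, CaseSpec,
                   hyaloid_area, slow_inlet_speed)
from ivtpk.darcy import AQUEOUS_PRODUCTION_M3_S

eye = build_eye_geometry("human")
mesh = generate_mesh(eye)                      # ~40k cells at 0.95 mm
u_in = slow_inlet_speed(AQUEOUS_PRODUCTION_M3_S, 0.10, hyaloid_area(eye))
flow = solve_darcy(mesh, FlowParams(mobility=8.4e-11, inlet_speed=u_in))
series = simulate_transport(
    mesh, flow, TransportParams(diffusion=9.13e-11),
    CaseSpec("1a", "slow"), site=make_injection_site(eye, "middle"),
    t_end=50.0)
print(round(half_life(series.times, series.c_avg, base_time=5.0), 2))
print(duration_of_action(series.times, series.c_avg_ug_ml, threshold=2.6))
```

prints

```
5.34
36.0
```

i.e. with slow convection and anterior elimination only, the human vitreous
bevacizumab half-life (measured from a 5-day baseline) is ≈5.3 days and the
vitreous-average concentration stays above the 2.6 μg/mL in-vivo threshold
for 36 days. Dropping convection (`CaseSpec("2a")`, no flow) roughly doubles
the half-life to ≈10.2 days; adding the posterior sink (`"1b"`) collapses it
to ≈1.3 days.

The same sweep is available from the shell:

```sh
ivtpk study --config examples/study.yaml --out results/
ivtpk sensitivity --out results/          # half-life vs diffusion coefficient
ivtpk mesh --species rabbit --out results/   # MSH + VTK export
```

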