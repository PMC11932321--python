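"""Transient convection–diffusion of bevacizumab in the vitreous.

The drug obeys ∂C/∂t = ∇·(D∇C) − u·∇C (no reaction: metabolism and
degradation of the antibody in the eye are negligible), starting from a
spherical injection bolus of uniform concentration.  Elimination routes enter
through the boundary conditions:

* anterior elimination — perfect sink C = 0 on the hyaloid membrane (always);
* posterior elimination — perfect sink C = 0 on the posterior outer surface
  (cases "b" only);
* all other surfaces (and the posterior surface in cases "a") carry a
  total-flux-zero condition −n·(−D∇C + uC) = 0.

Discretisation: P1 finite elements with lumped mass and first-order implicit
(backward Euler) stepping, sharp by default near the bolus release (small
steps for the first two days, larger after).  Concentrations are mol/m³ and
times are days internally; reported series also carry μg/mL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem
from .darcy import FlowField
from .geometry import EyeGeometry, InjectionSite, SurfaceTag
from .meshing import VolumeMesh

__all__ = ["TransportParams", "CaseSpec", "ConcentrationSeries",
           "initial_bolus_field", "drug_boundary_conditions",
           "simulate_transport", "mass_audit", "SPECIES_TRANSPORT",
           "MOLECULAR_WEIGHT_G_MOL", "DEFAULT_DT_SCHEDULE"]

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86400.0

#: Bevacizumab molecular weight used for mol ↔ mass conversion.  The standard
#: 1.25 mg / 0.05 mL dose at 0.167 mol/m³ implies ≈149.7 kDa, consistent with
#: the nominal 149 kDa of the antibody.
MOLECULAR_WEIGHT_G_MOL = 149_000.0

#: Bevacizumab diffusion coefficients in the vitreous (m²/s).
SPECIES_TRANSPORT = {"rabbit": {"diffusion": 1.2e-10},
                     "human": {"diffusion": 9.13e-11}}

#: (t_until_days, dt_days): small steps while the bolus gradients are sharp.
DEFAULT_DT_SCHEDULE = ((2.0, 0.05), (None, 0.25))

VALID_CASES = ("1a", "1b", "2a", "2b")


def mol_m3_to_ug_ml(c: np.ndarray | float) -> np.ndarray | float:
    """mol/m³ → μg/mL (= g/m³) at the bevacizumab molecular weight."""
    return c * MOLECULAR_WEIGHT_G_MOL


@dataclass(frozen=True)
class TransportParams:
    """Drug-transport parameters (SI)."""

    diffusion: float                       # D, m²/s
    reaction_rate: float = 0.0             # R, mol/(m³·s); the model fixes 0
    molecular_weight: float = MOLECULAR_WEIGHT_G_MOL

    def __post_init__(self) -> None:
        if self.diffusion <= 0:
            raise ValueError("diffusion coefficient must be positive")
        if self.reaction_rate != 0.0:
            raise ValueError("the model assumes zero reaction rate")


@dataclass(frozen=True)
class CaseSpec:
    """One of the four elimination/convection case studies.

    Cases "1" include convection (slow or fast aqueous inflow); cases "2" are
    diffusion only.  Cases "b" add the posterior perfect-sink elimination.
    """

    case: str                              # 1a | 1b | 2a | 2b
    convection: str = "none"               # none | slow | fast
    injection: str = "middle"

    def __post_init__(self) -> None:
        if self.case not in VALID_CASES:
            raise ValueError(f"unknown case {self.case!r}; expected {VALID_CASES}")
        if self.convection not in ("none", "slow", "fast"):
            raise ValueError(f"unknown convection regime {self.convection!r}")
        if self.uses_convection and self.convection == "none":
            raise ValueError(f"case {self.case} requires a convection regime "
                             "(slow or fast)")
        if not self.uses_convection and self.convection != "none":
            raise ValueError(f"case {self.case} is diffusion-only; convection "
                             f"regime {self.convection!r} is inconsistent")

    @property
    def uses_convection(self) -> bool:
        return self.case.startswith("1")

    @property
    def posterior_elimination(self) -> bool:
        return self.case.endswith("b")


def drug_boundary_conditions(case: CaseSpec) -> dict[SurfaceTag, str]:
    """Map each surface to its drug boundary condition.

    'sink' — perfect sink C = 0; 'no_total_flux' — −n·(−D∇C + uC) = 0;
    'outflow' — zero diffusive flux, convective flux leaves with the fluid.
    The posterior surface in case 1a is the fluid outlet: the drug is carried
    out convectively there even though posterior *diffusive* elimination is
    off (this is what makes convection shorten the case-1a half-life).
    """
    if case.posterior_elimination:
        posterior = "sink"
    elif case.uses_convection:
        posterior = "outflow"
    else:
        posterior = "no_total_flux"
    return {
        SurfaceTag.HYALOID: "sink",
        SurfaceTag.LENS: "no_total_flux",
        SurfaceTag.ANTERIOR_OUTER: "no_total_flux",
        SurfaceTag.POSTERIOR_OUTER: posterior,
    }


def initial_bolus_field(mesh: VolumeMesh, site: InjectionSite,
                        min_cells: int = 8) -> np.ndarray:
    """Vertex indicator of the bolus sphere, rescaled to the exact dose mass.

    The sharp spherical initial condition is projected vertex-wise (C_i inside
    the sphere, 0 outside) and then rescaled so the lumped-mass integral equals
    C_i × dose volume exactly.
    """
    d = np.linalg.norm(mesh.points - site.center, axis=1)
    c = np.where(d <= site.radius, site.dose_concentration, 0.0)
    if site.dose_concentration == 0.0:
        return c
    n_inside = int(np.count_nonzero(c))
    if n_inside < min_cells:
        raise ValueError(
            f"bolus resolved by only {n_inside} mesh vertices "
            f"(< {min_cells}); refine the mesh near {site.center}"
        )
    target = site.dose_concentration * site.dose_volume
    have = float(mesh.lumped_volumes() @ c)
    return c * (target / have)


@dataclass
class ConcentrationSeries:
    """Scalar time series reduced from the concentration fields."""

    times: np.ndarray                     # days
    c_avg: np.ndarray                     # vitreous average, mol/m³
    c_fovea: np.ndarray                   # point value at the fovea, mol/m³
    fovea_flux: np.ndarray | None         # mol/(m²·day) at the fovea (cases b)
    outflux: dict                         # SurfaceTag -> cumulative mol leaving
    mass: np.ndarray                      # mol remaining in the domain
    initial_mass: float                   # mol
    case: CaseSpec | None = None
    species: str | None = None
    min_undershoot: float = 0.0           # most negative nodal value seen, mol/m³
    c_min: np.ndarray | None = None       # per-time minimum nodal value, mol/m³
    final_field: np.ndarray | None = None

    @property
    def c_avg_ug_ml(self) -> np.ndarray:
        return np.clip(mol_m3_to_ug_ml(self.c_avg), 0.0, None)

    @property
    def c_fovea_ug_ml(self) -> np.ndarray:
        return np.clip(mol_m3_to_ug_ml(self.c_fovea), 0.0, None)

    def scaled(self, factor: float) -> "ConcentrationSeries":
        """Rescale the dose (PDE linearity): concentrations, fluxes, masses."""
        if factor <= 0:
            raise ValueError("dose factor must be positive")
        return replace(
            self,
            c_avg=self.c_avg * factor,
            c_fovea=self.c_fovea * factor,
            fovea_flux=None if self.fovea_flux is None else self.fovea_flux * factor,
            outflux={k: v * factor for k, v in self.outflux.items()},
            mass=self.mass * factor,
            initial_mass=self.initial_mass * factor,
            min_undershoot=self.min_undershoot * factor,
            c_min=None if self.c_min is None else self.c_min * factor,
            final_field=None if self.final_field is None
            else self.final_field * factor,
        )


def _dt_blocks(t_end: float, dt) -> list[tuple[float, float]]:
    """Normalise a dt spec into [(block_end, dt), ...] covering (0, t_end]."""
    if dt is None:
        sched = DEFAULT_DT_SCHEDULE
    elif np.isscalar(dt):
        sched = ((None, float(dt)),)
    else:
        sched = tuple(dt)
    blocks, t_prev = [], 0.0
    for t_until, step in sched:
        if step <= 0:
            raise ValueError("dt must be positive")
        end = t_end if t_until is None else min(float(t_until), t_end)
        if end > t_prev:
            blocks.append((end, float(step)))
            t_prev = end
        if t_prev >= t_end:
            break
    if t_prev < t_end:
        blocks.append((t_end, blocks[-1][1] if blocks else 0.25))
    return blocks


def simulate_transport(mesh: VolumeMesh, flow: FlowField | None,
                       params: TransportParams, case: CaseSpec,
                       site: InjectionSite | None = None,
                       t_end: float = 40.0, dt=None,
                       c0: np.ndarray | None = None,
                       dirichlet_values: dict | None = None,
                       source=None,
                       min_bolus_cells: int = 8) -> ConcentrationSeries:
    """Integrate the drug-transport equation and reduce to scalar series.

    Parameters
    ----------
    flow : FlowField or None
        Steady Darcy field on the same mesh; required for cases with
        convection, ignored (may be None) otherwise.
    site : InjectionSite
        Bolus initial condition; alternatively pass a raw field ``c0``.
    t_end, dt
        Horizon in days and step spec: None (default schedule: 0.05 d for the
        first 2 days, then 0.25 d), a scalar, or [(t_until, dt), ...].
    dirichlet_values, source
        Verification hooks: override sink values with callables f(x, t) per
        tag, and add a volumetric source term f(x, t) (mol/m³/day).
    """
    if case.uses_convection:
        if flow is None:
            raise ValueError(f"case {case.case} needs a solved Darcy flow field")
        if flow.mesh is not mesh and flow.mesh.n_points != mesh.n_points:
            raise ValueError("flow field was solved on a different mesh")
        velocity = flow.velocity * SECONDS_PER_DAY          # m/day
    else:
        velocity = None

    if c0 is None:
        if site is None:
            raise ValueError("either an injection site or an initial field is required")
        c0 = initial_bolus_field(mesh, site, min_cells=min_bolus_cells)
    c = np.asarray(c0, dtype=float).copy()

    grads = fem.basis_gradients(mesh)
    D_day = params.diffusion * SECONDS_PER_DAY
    A = fem.stiffness_matrix(mesh, coeff=D_day, grads=grads)
    if velocity is not None:
        A = A + fem.convection_matrix(mesh, velocity, grads=grads)

    bc = drug_boundary_conditions(case)
    sink_tags = [t for t, kind in bc.items() if kind == "sink"]
    if dirichlet_values:
        # verification hook: any tag given explicit values becomes Dirichlet
        sink_tags = sorted(set(sink_tags) | set(dirichlet_values),
                           key=int)
    outflow_tags = [t for t, kind in bc.items() if kind == "outflow"]
    # No-total-flux walls need no operator term: the discrete Darcy velocity
    # carries exactly zero flux through them in the weak sense, and the
    # natural (do-nothing) condition supplies the zero diffusive flux.
    outflow_nodal_q = None
    if velocity is not None and outflow_tags:
        logger.info("drug outflow boundary on %s: convective flux leaves "
                    "with the fluid", [t.name for t in outflow_tags])
        # exact discrete convective outflux weights (m³/day per node),
        # restricted to the outflow surface's nodes
        q_day = flow.nodal_outflux * SECONDS_PER_DAY
        outflow_nodes = fem.tag_vertices(mesh, outflow_tags)
        outflow_nodal_q = np.zeros(mesh.n_points)
        outflow_nodal_q[outflow_nodes] = q_day[outflow_nodes]

    M = fem.lumped_mass(mesh)
    dirichlet = {tag: fem.tag_vertices(mesh, tag) for tag in sink_tags}
    dir_all = (np.unique(np.concatenate([v for v in dirichlet.values()]))
               if dirichlet else np.array([], dtype=int))
    dir_mask = np.zeros(mesh.n_points, dtype=bool)
    dir_mask[dir_all] = True

    def dir_value(tag, t):
        if dirichlet_values and tag in dirichlet_values:
            f = dirichlet_values[tag]
            return f(mesh.points[dirichlet[tag]], t)
        return 0.0

    # apply initial Dirichlet values
    for tag in sink_tags:
        c[dirichlet[tag]] = dir_value(tag, 0.0)

    initial_mass = float(M @ c)
    fovea_idx = (mesh.vertex_index_near(mesh.geometry.fovea_point)
                 if mesh.geometry is not None else 0)
    fovea_point = (mesh.geometry.fovea_point if mesh.geometry is not None
                   else mesh.points[0])
    vertex_areas = fem.vertex_boundary_areas(mesh)
    track_flux = case.posterior_elimination

    times = [0.0]
    total_volume = float(M.sum())
    c_avg = [initial_mass / total_volume]
    c_fov = [mesh.interpolate(c, fovea_point)]
    f_fov = [0.0]
    flux_tags = sink_tags + (outflow_tags if outflow_nodal_q is not None else [])
    cum = {tag: 0.0 for tag in flux_tags}
    outflux_hist = {tag: [0.0] for tag in flux_tags}
    mass_hist = [initial_mass]
    min_undershoot = float(min(c.min(), 0.0))
    c_min_hist = [float(c.min())]

    t = 0.0
    for block_end, step in _dt_blocks(t_end, dt):
        S = sp.csr_matrix(A, copy=True)
        S = S + sp.diags(M / step)
        S = S.tolil()
        for i in dir_all:
            S.rows[i], S.data[i] = [i], [1.0]
        lu = spla.splu(S.tocsc())
        n_steps = int(round((block_end - t) / step))
        for _ in range(n_steps):
            t_new = t + step
            rhs = M * c / step
            if source is not None:
                rhs = rhs + M * source(mesh.points, t_new)
            for tag in sink_tags:
                rhs[dirichlet[tag]] = dir_value(tag, t_new)
            c_prev = c
            c = lu.solve(rhs)
            if not np.all(np.isfinite(c)):
                raise RuntimeError(
                    f"transport solve diverged at t = {t_new:.3f} d "
                    f"(case {case.case}, dt = {step})")
            # consistent boundary fluxes at the sink nodes (reaction forces);
            # outward flux is minus the residual of the unconstrained equation
            resid = A @ c + M * (c - c_prev) / step
            if source is not None:
                resid = resid - M * source(mesh.points, t_new)
            for tag in sink_tags:
                cum[tag] -= float(resid[dirichlet[tag]].sum()) * step
            if outflow_nodal_q is not None:
                conv_rate = float(outflow_nodal_q @ c)
                for tag in outflow_tags:
                    cum[tag] += conv_rate * step
            t = t_new
            step_min = float(c[~dir_mask].min()) if (~dir_mask).any() else 0.0
            min_undershoot = min(min_undershoot, step_min)
            c_min_hist.append(step_min)
            times.append(t)
            mass_hist.append(float(M @ c))
            c_avg.append(mass_hist[-1] / total_volume)
            c_fov.append(mesh.interpolate(c, fovea_point))
            for tag in flux_tags:
                outflux_hist[tag].append(cum[tag])
            if track_flux:
                rate = -float(resid[fovea_idx])           # mol/day leaving the node
                f_fov.append(rate / vertex_areas[fovea_idx])
            else:
                f_fov.append(0.0)

    series = ConcentrationSeries(
        times=np.array(times),
        c_avg=np.array(c_avg),
        c_fovea=np.array(c_fov),
        fovea_flux=np.array(f_fov) if track_flux else None,
        outflux={tag: np.array(v) for tag, v in outflux_hist.items()},
        mass=np.array(mass_hist),
        initial_mass=initial_mass,
        case=case,
        species=mesh.geometry.species if mesh.geometry is not None else None,
        min_undershoot=min_undershoot,
        c_min=np.array(c_min_hist),
        final_field=c,
    )
    worst = mass_audit(series)
    logger.info("transport run complete: case %s, t_end %.1f d, worst mass "
                "imbalance %.2e", case.case, t_end, worst)
    return series


def mass_audit(series: ConcentrationSeries,
               initial_mass: float | None = None) -> float:
    """Worst relative mass imbalance: |mass + Σ outflux − m₀| / m₀ over time."""
    m0 = series.initial_mass if initial_mass is None else initial_mass
    if m0 == 0.0:
        return 0.0
    total_out = sum(series.outflux.values()) if series.outflux else 0.0
    drift = series.mass + total_out - m0
    return float(np.abs(drift).max() / m0)
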