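"""Steady Darcy flow of aqueous humor through the porous vitreous.

A fraction of the aqueous humor produced by the ciliary body permeates the
vitreous through the hyaloid membrane and leaves across the posterior outer
surface (the blood–retinal barrier side).  With unit porosity and constant
mobility κ/μ the problem reduces to a pressure Poisson equation:

    u = −(κ/μ) ∇p,   ∇·u = 0

with a prescribed uniform inflow speed on the hyaloid, gauge pressure p = 0 on
the posterior outer surface, and impermeable lens and anterior outer surfaces.
Pressures are gauge (relative to the posterior outlet).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem
from .geometry import SurfaceTag
from .meshing import VolumeMesh

__all__ = ["FlowParams", "FlowField", "slow_inlet_speed", "solve_darcy",
           "flow_diagnostics", "SPECIES_FLOW"]

#: Darcy mobility κ/μ in m²/(Pa·s) and slow/fast hyaloid inflow speeds in m/s.
#: The slow speeds derive from a 3 μL/min aqueous production rate with 7%
#: (rabbit) / 10% (human) entering the vitreous over the hyaloid area.
SPECIES_FLOW = {
    "rabbit": {"mobility": 5.8e-14 / 0.001, "density": 1000.0,
               "vitreous_fraction": 0.07},
    "human": {"mobility": 8.4e-11, "density": 1008.0,
              "vitreous_fraction": 0.10},
}

AQUEOUS_PRODUCTION_M3_S = 3e-9 / 60.0   # 3 μL/min
FAST_INLET_SPEED = 1.5e-7               # m/s


@dataclass(frozen=True)
class FlowParams:
    """Parameters of the Darcy solve (SI)."""

    mobility: float               # κ/μ, m²/(Pa·s)
    inlet_speed: float            # u_in ≥ 0, m/s, uniform over the hyaloid
    porosity: float = 1.0
    density: float = 1000.0       # kg/m³
    reference_pressure: float = 0.0

    def __post_init__(self) -> None:
        if self.mobility <= 0:
            raise ValueError("mobility must be positive")
        if self.inlet_speed < 0:
            raise ValueError("inlet speed must be non-negative")
        if self.porosity != 1.0:
            raise ValueError("the model assumes unit porosity")


def slow_inlet_speed(production_rate: float, vitreous_fraction: float,
                     hyaloid_area: float) -> float:
    """Uniform hyaloid inflow speed (m/s) from the aqueous production rate.

    ``production_rate`` in m³/s, ``vitreous_fraction`` the share entering the
    vitreous, ``hyaloid_area`` in m².
    """
    if hyaloid_area <= 0:
        raise ValueError("hyaloid area must be positive")
    if not 0.0 <= vitreous_fraction <= 1.0:
        raise ValueError("vitreous fraction must lie in [0, 1]")
    if production_rate < 0:
        raise ValueError("production rate must be non-negative")
    return production_rate * vitreous_fraction / hyaloid_area


@dataclass
class FlowField:
    """Solved steady Darcy field on a mesh."""

    mesh: VolumeMesh
    params: FlowParams
    pressure: np.ndarray          # (n_pts,) Pa, gauge
    velocity: np.ndarray          # (n_cells, 3) m/s
    tag_fluxes: dict              # SurfaceTag -> outward volumetric flux, m³/s
    nodal_outflux: np.ndarray     # (n_pts,) outward volumetric flux per node, m³/s
    divergence_residual: float    # ∞-norm of the free-node residual / inflow scale


def solve_darcy(mesh: VolumeMesh, params: FlowParams) -> FlowField:
    """Solve the pressure Poisson problem and recover the velocity field."""
    grads = fem.basis_gradients(mesh)
    K = fem.stiffness_matrix(mesh, coeff=params.mobility, grads=grads)
    hyaloid_mask = mesh.face_tags == int(SurfaceTag.HYALOID)
    areas, _ = mesh.face_areas_normals()
    b = fem.boundary_load(mesh, np.full(len(mesh.face_tags), params.inlet_speed),
                          hyaloid_mask)

    outlet = fem.tag_vertices(mesh, SurfaceTag.POSTERIOR_OUTER)
    if len(outlet) == 0:
        raise ValueError("no posterior outlet facets: pressure problem is singular")
    K = K.tolil()
    rhs = b.copy()
    for i in outlet:
        K.rows[i], K.data[i] = [i], [1.0]
        rhs[i] = 0.0
    p = spla.spsolve(K.tocsc(), rhs)

    velocity = -params.mobility * fem.cell_gradients(mesh, p, grads=grads)

    # consistent per-tag fluxes: prescribed inflow on the hyaloid, reaction
    # fluxes at the outlet nodes, weakly zero on the impermeable walls
    K_full = fem.stiffness_matrix(mesh, coeff=params.mobility, grads=grads)
    reactions = K_full @ p - b
    hyaloid_flux = -params.inlet_speed * float(areas[hyaloid_mask].sum())
    tag_fluxes = {
        SurfaceTag.HYALOID: hyaloid_flux,
        SurfaceTag.POSTERIOR_OUTER: float(-reactions[outlet].sum()),
        SurfaceTag.LENS: 0.0,
        SurfaceTag.ANTERIOR_OUTER: 0.0,
    }
    free = np.setdiff1d(np.arange(mesh.n_points), outlet)
    scale = max(abs(hyaloid_flux), 1e-300)
    residual = float(np.abs(reactions[free]).max()) / scale
    # outward nodal volumetric flux: exact discrete boundary flux of the
    # velocity field, concentrated at the outlet nodes (zero elsewhere up to
    # solver precision) — used by transport for conservative convective outflux
    return FlowField(mesh=mesh, params=params, pressure=p, velocity=velocity,
                     tag_fluxes=tag_fluxes, nodal_outflux=-reactions,
                     divergence_residual=residual)


def flow_diagnostics(flow: FlowField) -> dict:
    """Summary report: per-tag fluxes, pressure extrema, flux balance."""
    fluxes = {tag.name: q for tag, q in flow.tag_fluxes.items()}
    total = sum(flow.tag_fluxes.values())
    inflow = -flow.tag_fluxes[SurfaceTag.HYALOID]
    return {
        "tag_fluxes_m3_s": fluxes,
        "net_flux_m3_s": total,
        "flux_imbalance_rel": abs(total) / inflow if inflow > 0 else 0.0,
        "max_pressure_Pa": float(flow.pressure.max()),
        "min_pressure_Pa": float(flow.pressure.min()),
        "pressure_drop_Pa": float(flow.pressure.max() - flow.pressure.min()),
        "divergence_residual": flow.divergence_residual,
        "max_speed_m_s": float(np.linalg.norm(flow.velocity, axis=1).max()),
    }
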