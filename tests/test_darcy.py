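"""Darcy flow: inlet-speed derivation, 1D column oracle, conservation, pressure."""

import math

import numpy as np
import pytest

from ivtpk import darcy
from ivtpk.darcy import (FlowParams, flow_diagnostics, slow_inlet_speed,
                         solve_darcy)
from ivtpk.geometry import SurfaceTag, hyaloid_area
from ivtpk.meshing import VolumeMesh, _boundary_faces


def make_box_mesh(L=1.0e-2, W=0.5e-2, n=6):
    """Box column mesh (structured hexes split into tets): inflow tagged on
    x=0, outlet on x=L, walls elsewhere."""
    xs = np.linspace(0, L, 2 * n + 1)
    ys = np.linspace(0, W, n + 1)
    nx, ny = len(xs), len(ys)
    pts = np.stack(np.meshgrid(xs, ys, ys, indexing="ij"), axis=-1).reshape(-1, 3)
    h = xs[1] - xs[0]

    def vid(i, j, k):
        return (i * ny + j) * ny + k

    tet_pattern = [(0, 1, 3, 7), (0, 1, 7, 5), (0, 5, 7, 4),
                   (0, 3, 2, 7), (0, 2, 6, 7), (0, 6, 4, 7)]
    cells = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            for k in range(ny - 1):
                corners = [vid(i + a, j + b, k + c)
                           for c in (0, 1) for b in (0, 1) for a in (0, 1)]
                # corners order: index bit pattern a + 2b + 4c
                for t in tet_pattern:
                    cells.append([corners[v] for v in t])
    cells = np.asarray(cells)
    faces, owners = _boundary_faces(cells)
    cent = pts[faces].mean(axis=1)
    tags = np.full(len(faces), int(SurfaceTag.ANTERIOR_OUTER), dtype=np.int32)
    tags[cent[:, 0] < 1e-9] = int(SurfaceTag.HYALOID)
    tags[cent[:, 0] > L - 1e-9] = int(SurfaceTag.POSTERIOR_OUTER)
    return VolumeMesh(points=pts, cells=cells, boundary_faces=faces,
                      face_tags=tags, face_cells=owners, nominal_size=h,
                      geometry=None), L


@pytest.mark.parametrize("fraction, area_cm2, expected", [
    (0.07, 0.81, 4.3e-8),      # rabbit
    (0.10, 1.47, 3.4e-8),      # human
])
def test_slow_inlet_speed_from_aqueous_production(fraction, area_cm2, expected):
    u = slow_inlet_speed(darcy.AQUEOUS_PRODUCTION_M3_S, fraction,
                         area_cm2 * 1e-4)
    assert u == pytest.approx(expected, rel=0.02)   # printed to 2 sig figs


def test_inlet_speed_edge_cases():
    assert slow_inlet_speed(darcy.AQUEOUS_PRODUCTION_M3_S, 0.0, 1e-4) == 0.0
    with pytest.raises(ValueError):
        slow_inlet_speed(darcy.AQUEOUS_PRODUCTION_M3_S, 0.1, 0.0)
    with pytest.raises(ValueError):
        slow_inlet_speed(darcy.AQUEOUS_PRODUCTION_M3_S, 1.5, 1e-4)


def test_zero_inlet_gives_trivial_field(human_mesh_coarse):
    flow = solve_darcy(human_mesh_coarse,
                       FlowParams(mobility=8.4e-11, inlet_speed=0.0))
    np.testing.assert_allclose(flow.pressure, 0.0, atol=1e-20)
    np.testing.assert_allclose(flow.velocity, 0.0, atol=1e-20)
    report = flow_diagnostics(flow)
    assert all(abs(q) < 1e-25 for q in report["tag_fluxes_m3_s"].values())


def test_column_matches_one_dimensional_darcy_solution():
    mesh, L = make_box_mesh()
    mob, u_in = 8.4e-11, 3.4e-8
    flow = solve_darcy(mesh, FlowParams(mobility=mob, inlet_speed=u_in))
    expected = (u_in / mob) * (L - mesh.points[:, 0])
    np.testing.assert_allclose(flow.pressure, expected,
                               rtol=1e-8, atol=1e-8 * expected.max())
    np.testing.assert_allclose(flow.velocity,
                               np.tile([u_in, 0, 0], (mesh.n_cells, 1)),
                               atol=1e-6 * u_in)


def test_pressure_and_velocity_scale_linearly_with_inlet(human_mesh_coarse):
    p1 = solve_darcy(human_mesh_coarse,
                     FlowParams(mobility=8.4e-11, inlet_speed=3.4e-8))
    p2 = solve_darcy(human_mesh_coarse,
                     FlowParams(mobility=8.4e-11, inlet_speed=6.8e-8))
    np.testing.assert_allclose(p2.pressure, 2.0 * p1.pressure,
                               rtol=1e-10, atol=1e-12)
    np.testing.assert_allclose(p2.velocity, 2.0 * p1.velocity,
                               rtol=1e-10, atol=1e-20)


def test_flux_balance_and_divergence_residual(human_mesh_coarse, human_geometry):
    flow = solve_darcy(human_mesh_coarse,
                       FlowParams(mobility=8.4e-11, inlet_speed=3.4e-8))
    report = flow_diagnostics(flow)
    assert report["flux_imbalance_rel"] < 0.005
    assert flow.divergence_residual < 1e-8
    inflow = -flow.tag_fluxes[SurfaceTag.HYALOID]
    # hyaloid volumetric inflow = u_in x analytic hyaloid area (mesh area ~1%)
    assert inflow == pytest.approx(3.4e-8 * hyaloid_area(human_geometry),
                                   rel=0.01)
    assert flow.tag_fluxes[SurfaceTag.LENS] == 0.0
    assert flow.tag_fluxes[SurfaceTag.ANTERIOR_OUTER] == 0.0


def test_slow_convection_pressure_drop_band(human_mesh_coarse):
    flow = solve_darcy(human_mesh_coarse,
                       FlowParams(mobility=8.4e-11, inlet_speed=3.4e-8))
    drop = flow_diagnostics(flow)["pressure_drop_Pa"]
    assert 0.5 < drop < 5.0     # reported "around 2 Pa"


def test_pressure_extrema_on_the_boundary(human_mesh_coarse):
    m = human_mesh_coarse
    flow = solve_darcy(m, FlowParams(mobility=8.4e-11, inlet_speed=3.4e-8))
    boundary = np.unique(m.boundary_faces)
    interior_max = np.delete(flow.pressure, boundary).max()
    assert flow.pressure[boundary].max() >= interior_max - 1e-12


def test_invalid_flow_params():
    with pytest.raises(ValueError):
        FlowParams(mobility=0.0, inlet_speed=1e-8)
    with pytest.raises(ValueError):
        FlowParams(mobility=8.4e-11, inlet_speed=-1.0)
    with pytest.raises(ValueError):
        FlowParams(mobility=8.4e-11, inlet_speed=1e-8, porosity=0.5)
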