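"""Transport solver: initial bolus, boundary conditions, conservation, linearity."""

import math

import numpy as np
import pytest

from ivtpk.fixtures import analytic_sphere_decay
from ivtpk.geometry import SurfaceTag, build_eye_geometry, make_injection_site
from ivtpk.meshing import generate_sphere_mesh
from ivtpk.transport import (CaseSpec, ConcentrationSeries, TransportParams,
                             drug_boundary_conditions, initial_bolus_field,
                             mass_audit, mol_m3_to_ug_ml, simulate_transport,
                             MOLECULAR_WEIGHT_G_MOL)


def test_dose_concentration_consistent_with_molecular_weight():
    # 1.25 mg in 0.05 mL at ~149 kDa gives the standard 0.167 mol/m³
    c = 1.25e-3 / (MOLECULAR_WEIGHT_G_MOL * 0.05e-6)
    assert c == pytest.approx(0.167, rel=0.005)
    assert mol_m3_to_ug_ml(0.167) == pytest.approx(1.25e3 / 0.05, rel=0.005)


def test_initial_bolus_mass_matches_dose(human_mesh_coarse):
    g = human_mesh_coarse.geometry
    site = make_injection_site(g, "middle")
    c0 = initial_bolus_field(human_mesh_coarse, site)
    mass = human_mesh_coarse.lumped_volumes() @ c0
    assert mass == pytest.approx(0.167 * 0.05e-6, rel=1e-12)   # 8.35e-9 mol
    assert mass == pytest.approx(8.35e-9, rel=1e-6)


def test_zero_dose_gives_zero_field(human_mesh_coarse):
    g = human_mesh_coarse.geometry
    site = make_injection_site(g, "middle", dose_concentration=0.0)
    c0 = initial_bolus_field(human_mesh_coarse, site)
    assert np.all(c0 == 0.0)


def test_unresolved_bolus_raises(human_mesh_coarse):
    g = human_mesh_coarse.geometry
    site = make_injection_site(g, "middle")
    with pytest.raises(ValueError, match="refine"):
        initial_bolus_field(human_mesh_coarse, site, min_cells=10**6)


@pytest.mark.parametrize("case, convection, posterior", [
    ("2a", "none", "no_total_flux"),
    ("2b", "none", "sink"),
    ("1a", "slow", "outflow"),
    ("1b", "slow", "sink"),
])
def test_boundary_conditions_per_case(case, convection, posterior):
    bc = drug_boundary_conditions(CaseSpec(case, convection))
    assert bc[SurfaceTag.HYALOID] == "sink"
    assert bc[SurfaceTag.LENS] == "no_total_flux"
    assert bc[SurfaceTag.ANTERIOR_OUTER] == "no_total_flux"
    assert bc[SurfaceTag.POSTERIOR_OUTER] == posterior


def test_case_convection_consistency_enforced():
    with pytest.raises(ValueError, match="diffusion-only"):
        CaseSpec("2a", "fast")
    with pytest.raises(ValueError, match="requires a convection regime"):
        CaseSpec("1a", "none")
    with pytest.raises(ValueError, match="unknown case"):
        CaseSpec("3a", "none")


def test_closed_system_conserves_mass():
    # A sphere mesh has no hyaloid facets, so case 2a has no sink anywhere:
    # the system is closed and the mass must stay constant.
    mesh = generate_sphere_mesh(5e-3, element_size=1.2e-3, seed=0)
    c0 = np.where(np.linalg.norm(mesh.points, axis=1) < 2e-3, 1.0, 0.0)
    series = simulate_transport(mesh, None, TransportParams(diffusion=1e-10),
                                CaseSpec("2a"), c0=c0, t_end=2.0, dt=0.1)
    np.testing.assert_allclose(series.mass, series.initial_mass, rtol=1e-10)
    assert mass_audit(series) <= 1e-6


def test_absorbing_sphere_matches_eigenfunction_series():
    D, a = 1e-10, 5e-3
    t_check = a**2 / (4 * D) / 86400.0          # days
    mesh = generate_sphere_mesh(a, element_size=0.55e-3, seed=0)
    case = CaseSpec("2b")
    exact0 = lambda x, t: np.zeros(len(x))
    series = simulate_transport(
        mesh, None, TransportParams(diffusion=D), case,
        c0=np.ones(mesh.n_points), t_end=t_check, dt=t_check / 400,
        dirichlet_values={tag: exact0 for tag in SurfaceTag})
    # normalize by the true initial mass C0*V: the sink instantly absorbs the
    # boundary vertices' share, which counts as absorbed mass, not lost mass
    remaining = series.mass[-1] / (4 / 3 * math.pi * a**3)
    expected = analytic_sphere_decay(D, a, t_check * 86400.0)
    assert remaining == pytest.approx(expected, abs=0.01)


def test_dose_linearity_to_machine_precision(rabbit_mesh_coarse):
    g = rabbit_mesh_coarse.geometry
    params = TransportParams(diffusion=1.2e-10)
    base = make_injection_site(g, "middle")
    scaled = make_injection_site(g, "middle", dose_concentration=0.167 * 3)
    s1 = simulate_transport(rabbit_mesh_coarse, None, params, CaseSpec("2b"),
                            site=base, t_end=2.0, dt=0.1)
    s3 = simulate_transport(rabbit_mesh_coarse, None, params, CaseSpec("2b"),
                            site=scaled, t_end=2.0, dt=0.1)
    np.testing.assert_allclose(3.0 * s1.c_avg, s3.c_avg, rtol=1e-12)
    np.testing.assert_allclose(3.0 * s1.c_fovea[1:], s3.c_fovea[1:],
                               rtol=1e-9, atol=1e-16)
    np.testing.assert_allclose(3.0 * s1.fovea_flux[1:], s3.fovea_flux[1:],
                               rtol=1e-9, atol=1e-18)


def test_undershoot_bounded_after_first_day(human_mesh_coarse):
    g = human_mesh_coarse.geometry
    site = make_injection_site(g, "middle")
    series = simulate_transport(human_mesh_coarse, None,
                                TransportParams(diffusion=9.13e-11),
                                CaseSpec("2a"), site=site, t_end=5.0)
    late = series.c_min[series.times >= 1.0]
    assert late.min() >= -1e-3 * site.dose_concentration


def test_mass_audit_on_posterior_elimination_run(human_mesh_coarse):
    g = human_mesh_coarse.geometry
    site = make_injection_site(g, "middle")
    series = simulate_transport(human_mesh_coarse, None,
                                TransportParams(diffusion=9.13e-11),
                                CaseSpec("2b"), site=site, t_end=4.0)
    assert mass_audit(series) <= 0.01
    # sinks on both routes appear in the outflux ledger
    assert SurfaceTag.HYALOID in series.outflux
    assert SurfaceTag.POSTERIOR_OUTER in series.outflux


def test_zero_dose_audit_is_defined(human_mesh_coarse):
    g = human_mesh_coarse.geometry
    site = make_injection_site(g, "middle", dose_concentration=0.0)
    series = simulate_transport(human_mesh_coarse, None,
                                TransportParams(diffusion=9.13e-11),
                                CaseSpec("2a"), site=site, t_end=1.0, dt=0.5)
    assert mass_audit(series) == 0.0


def test_convection_case_requires_flow(human_mesh_coarse):
    g = human_mesh_coarse.geometry
    site = make_injection_site(g, "middle")
    with pytest.raises(ValueError, match="Darcy"):
        simulate_transport(human_mesh_coarse, None,
                           TransportParams(diffusion=9.13e-11),
                           CaseSpec("1a", "slow"), site=site, t_end=1.0)


def test_invalid_transport_params():
    with pytest.raises(ValueError):
        TransportParams(diffusion=0.0)
    with pytest.raises(ValueError):
        TransportParams(diffusion=1e-10, reaction_rate=1e-9)
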