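"""Closed-form geometric audits of the vitreous domain."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ivtpk.geometry import (EyeGeometry, SurfaceTag, bolus_radius,
                            build_eye_geometry, classify_surface_point,
                            hyaloid_area, make_injection_site,
                            signed_distance, vitreous_volume,
                            DOSE_VOLUME_M3)

MM = 1e-3


@pytest.mark.parametrize("species, r_v, z_h, lens_z, r_l, volume_ml, area_cm2", [
    ("rabbit", 7.6, 4.0, 4.0, 4.0, 1.44, 0.81),
    ("human", 10.9, 7.0, 8.0, 4.9, 4.79, 1.47),
])
def test_species_geometry_reproduces_anatomical_values(
        species, r_v, z_h, lens_z, r_l, volume_ml, area_cm2):
    g = build_eye_geometry(species)
    assert g.vitreous_radius == pytest.approx(r_v * MM)
    assert g.hyaloid_plane == pytest.approx(z_h * MM)
    assert g.lens_center[2] == pytest.approx(lens_z * MM)
    assert g.lens_radius == pytest.approx(r_l * MM)
    np.testing.assert_allclose(g.fovea_point, [0, 0, -r_v * MM])
    # printed vitreous volume (mL) and hyaloid area (cm²) to 3 significant figures
    assert vitreous_volume(g) * 1e6 == pytest.approx(volume_ml, abs=0.005)
    assert hyaloid_area(g) * 1e4 == pytest.approx(area_cm2, abs=0.005)


def test_human_lens_is_offset_one_mm_above_truncation_plane():
    g = build_eye_geometry("human")
    assert g.lens_center[2] - g.hyaloid_plane == pytest.approx(1.0 * MM)


def test_unknown_species_is_rejected():
    with pytest.raises(ValueError, match="unknown species"):
        build_eye_geometry("mouse")


def test_volume_approaches_full_sphere_without_lens_or_truncation():
    r_v = 7.6 * MM
    g = EyeGeometry(species="rabbit", vitreous_radius=r_v,
                    hyaloid_plane=r_v - 1e-7, lens_center=(0, 0, r_v - 1e-7),
                    lens_radius=1e-6)
    assert vitreous_volume(g) == pytest.approx(4 / 3 * math.pi * r_v**3,
                                               rel=1e-6)
    assert hyaloid_area(g) == pytest.approx(
        math.pi * (r_v**2 - g.hyaloid_plane**2), rel=1e-3)


def test_volume_matches_monte_carlo_rejection_sampling():
    g = build_eye_geometry("rabbit")
    rng = np.random.default_rng(12345)
    r_v, z_h = g.vitreous_radius, g.hyaloid_plane
    lo = np.array([-r_v, -r_v, -r_v])
    hi = np.array([r_v, r_v, z_h])
    box = float(np.prod(hi - lo))
    n_total, n_in = 0, 0
    for _ in range(10):
        pts = rng.uniform(lo, hi, size=(1_000_000, 3))
        n_in += int(np.sum(signed_distance(g, pts) < 0))
        n_total += len(pts)
    p = n_in / n_total
    estimate = p * box
    sigma = box * math.sqrt(p * (1 - p) / n_total)
    assert abs(estimate - vitreous_volume(g)) < 3 * sigma


def test_bolus_radius_closed_form_and_bisection_oracle():
    assert bolus_radius(4 * math.pi / 3) == pytest.approx(1.0)
    r = bolus_radius(DOSE_VOLUME_M3)
    assert r == pytest.approx(2.3 * MM, abs=0.05 * MM)   # printed 2.3 mm
    # independent bisection on V(r) = 4/3 pi r^3
    lo_r, hi_r = 0.0, 1.0
    for _ in range(80):
        mid = 0.5 * (lo_r + hi_r)
        if 4 / 3 * math.pi * mid**3 < DOSE_VOLUME_M3:
            lo_r = mid
        else:
            hi_r = mid
    assert r == pytest.approx(0.5 * (lo_r + hi_r), abs=1e-9)
    with pytest.raises(ValueError):
        bolus_radius(0.0)


@pytest.mark.parametrize("species, location, center_mm", [
    ("rabbit", "anterior", (0, 4.9, -0.3)),
    ("rabbit", "middle", (0, 2.5, -2.5)),
    ("rabbit", "posterior", (0, 0, -4.5)),
    ("human", "anterior", (0, 6, 3)),
    ("human", "middle", (0, 3, -0.5)),
    ("human", "posterior", (0, 0, -4)),
])
def test_injection_sites_match_anatomical_table(species, location, center_mm):
    g = build_eye_geometry(species)
    site = make_injection_site(g, location)
    np.testing.assert_allclose(site.center, np.array(center_mm) * MM)
    assert site.dose_concentration == pytest.approx(0.167)
    assert site.dose_volume == pytest.approx(0.05e-6)


def test_escaping_bolus_is_rejected_naming_the_boundary(monkeypatch):
    from ivtpk import geometry as geo
    g = build_eye_geometry("rabbit")
    bad = dict(geo.SPECIES_PARAMS["rabbit"]["injection_centers"])
    bad["too_deep"] = (0.0, 0.0, -9.5 * MM)
    monkeypatch.setitem(geo.SPECIES_PARAMS["rabbit"], "injection_centers", bad)
    with pytest.raises(ValueError, match="outer sphere"):
        make_injection_site(g, "too_deep")
    with pytest.raises(ValueError, match="unknown injection location"):
        make_injection_site(g, "sideways")


def test_surface_classification_examples():
    g = build_eye_geometry("rabbit")
    tol = 1e-6
    assert classify_surface_point(g, (0, 0, -7.6 * MM), tol) \
        == SurfaceTag.POSTERIOR_OUTER
    assert classify_surface_point(g, (0, 5 * MM, 4 * MM), tol) \
        == SurfaceTag.HYALOID
    # z = 0 exactly on the outer sphere resolves to the anterior side
    assert classify_surface_point(g, (7.6 * MM, 0, 0), tol) \
        == SurfaceTag.ANTERIOR_OUTER
    # lens surface point (the rabbit lens bottom touches the origin)
    assert classify_surface_point(g, (0, 0, 0), tol) == SurfaceTag.LENS
    with pytest.raises(ValueError, match="not on the domain boundary"):
        classify_surface_point(g, (0, 1 * MM, -2 * MM), tol)
    with pytest.raises(ValueError, match="not on the domain boundary"):
        classify_surface_point(g, (0, 0, -20 * MM), tol)


@given(theta=st.floats(0.05, math.pi - 0.05), phi=st.floats(0, 2 * math.pi))
def test_outer_sphere_points_classify_by_hemisphere(theta, phi):
    g = build_eye_geometry("human")
    r = g.vitreous_radius
    p = np.array([r * math.sin(theta) * math.cos(phi),
                  r * math.sin(theta) * math.sin(phi),
                  r * math.cos(theta)])
    if p[2] > g.hyaloid_plane - 1e-4:
        return  # beyond the truncation: not part of the boundary
    tag = classify_surface_point(g, p, tol=1e-9)
    expected = (SurfaceTag.ANTERIOR_OUTER if p[2] >= 0
                else SurfaceTag.POSTERIOR_OUTER)
    assert tag == expected


def test_degenerate_lens_geometry_is_rejected():
    with pytest.raises(ValueError, match="intersect the hyaloid plane"):
        EyeGeometry(species="rabbit", vitreous_radius=7.6 * MM,
                    hyaloid_plane=4 * MM, lens_center=(0, 0, 10 * MM),
                    lens_radius=2 * MM)
    with pytest.raises(ValueError, match="z-axis"):
        EyeGeometry(species="rabbit", vitreous_radius=7.6 * MM,
                    hyaloid_plane=4 * MM, lens_center=(1 * MM, 0, 4 * MM),
                    lens_radius=4 * MM)
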