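"""Vitreous geometry: truncated sphere minus lens, with anatomical surface tags.

The vitreous chamber is modelled as a sphere of radius ``r_v`` centred at the
origin, truncated by the hyaloid membrane plane ``z = z_h`` (the anterior cut),
with the crystalline lens — a smaller sphere dipping below that plane —
subtracted.  The fovea sits at the posterior pole ``(0, 0, -r_v)``.  The z-axis
points anterior; all lengths are SI metres internally.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SurfaceTag",
    "EyeGeometry",
    "InjectionSite",
    "SPECIES_PARAMS",
    "build_eye_geometry",
    "vitreous_volume",
    "hyaloid_area",
    "bolus_radius",
    "make_injection_site",
    "classify_surface_point",
    "signed_distance",
]

MM = 1e-3

#: Standard intravitreal dose: 1.25 mg bevacizumab in 0.05 mL.
DOSE_VOLUME_M3 = 0.05e-6
DOSE_CONCENTRATION_MOL_M3 = 0.167
DOSE_MASS_MG = 1.25

#: Default slack for the bolus-containment check.  The rabbit anterior site
#: sits within ~0.24 mm of the lens, so strict containment would be brittle.
CONTAINMENT_TOL_M = 0.05e-3


class SurfaceTag(enum.IntEnum):
    """Anatomical boundary surfaces of the vitreous domain."""

    HYALOID = 1          # planar annulus at z = z_h, outside the lens disc
    LENS = 2             # lens-sphere patch below the hyaloid plane
    ANTERIOR_OUTER = 3   # outer sphere, z >= 0
    POSTERIOR_OUTER = 4  # outer sphere, z < 0


@dataclass(frozen=True)
class EyeGeometry:
    """Species-parameterised analytic description of the vitreous domain."""

    species: str
    vitreous_radius: float          # r_v, m
    hyaloid_plane: float            # z_h, m
    lens_center: np.ndarray         # (0, 0, z_l), m
    lens_radius: float              # r_l, m

    def __post_init__(self) -> None:
        object.__setattr__(self, "lens_center",
                           np.asarray(self.lens_center, dtype=float))
        r_v, z_h, r_l = self.vitreous_radius, self.hyaloid_plane, self.lens_radius
        if not (0.0 < z_h < r_v):
            raise ValueError(f"hyaloid plane z_h={z_h} must satisfy 0 < z_h < r_v={r_v}")
        if r_l <= 0.0:
            raise ValueError("lens radius must be positive")
        if abs(self.lens_center[0]) > 0 or abs(self.lens_center[1]) > 0:
            raise ValueError("lens center must lie on the z-axis")
        if abs(self.lens_center[2] - z_h) >= r_l:
            raise ValueError(
                "lens sphere must intersect the hyaloid plane "
                f"(|z_l - z_h| = {abs(self.lens_center[2] - z_h):.3e} >= r_l = {r_l:.3e})"
            )

    @property
    def fovea_point(self) -> np.ndarray:
        """Posterior pole (0, 0, -r_v): the therapeutic target location."""
        return np.array([0.0, 0.0, -self.vitreous_radius])

    @property
    def outer_rim_radius(self) -> float:
        """Radius of the circle where the hyaloid plane meets the outer sphere."""
        return math.sqrt(self.vitreous_radius**2 - self.hyaloid_plane**2)

    @property
    def inner_rim_radius(self) -> float:
        """Radius of the circle where the hyaloid plane meets the lens sphere."""
        dz = self.lens_center[2] - self.hyaloid_plane
        return math.sqrt(self.lens_radius**2 - dz**2)


#: Model parameters per species (SI).  Injection-bolus origins are labelled by
#: depth: anterior (nearest the hyaloid), middle, posterior (nearest the fovea).
SPECIES_PARAMS: dict[str, dict] = {
    "rabbit": {
        "vitreous_radius": 7.6 * MM,
        "hyaloid_plane": 4.0 * MM,
        "lens_center": (0.0, 0.0, 4.0 * MM),
        "lens_radius": 4.0 * MM,
        "injection_centers": {
            "anterior": (0.0, 4.9 * MM, -0.3 * MM),
            "middle": (0.0, 2.5 * MM, -2.5 * MM),
            "posterior": (0.0, 0.0, -4.5 * MM),
        },
    },
    "human": {
        "vitreous_radius": 10.9 * MM,
        "hyaloid_plane": 7.0 * MM,
        "lens_center": (0.0, 0.0, 8.0 * MM),
        "lens_radius": 4.9 * MM,
        "injection_centers": {
            "anterior": (0.0, 6.0 * MM, 3.0 * MM),
            "middle": (0.0, 3.0 * MM, -0.5 * MM),
            "posterior": (0.0, 0.0, -4.0 * MM),
        },
    },
}


def build_eye_geometry(species: str) -> EyeGeometry:
    """Construct the rabbit or human vitreous geometry.

    Parameters
    ----------
    species : {'rabbit', 'human'}
    """
    try:
        p = SPECIES_PARAMS[species]
    except KeyError:
        raise ValueError(
            f"unknown species {species!r}: supported species are "
            f"{sorted(SPECIES_PARAMS)}"
        ) from None
    return EyeGeometry(
        species=species,
        vitreous_radius=p["vitreous_radius"],
        hyaloid_plane=p["hyaloid_plane"],
        lens_center=np.array(p["lens_center"]),
        lens_radius=p["lens_radius"],
    )


def _cap_volume(r: float, h: float) -> float:
    """Volume of a spherical cap of height h cut from a sphere of radius r."""
    return math.pi * h * h * (3.0 * r - h) / 3.0


def vitreous_volume(geometry: EyeGeometry) -> float:
    """Closed-form vitreous volume in m³.

    Full sphere, minus the cap anterior of the hyaloid plane, minus the part
    of the lens sphere protruding below that plane.
    """
    r_v, z_h = geometry.vitreous_radius, geometry.hyaloid_plane
    z_l, r_l = geometry.lens_center[2], geometry.lens_radius
    lens_low, lens_high = z_l - r_l, z_l + r_l
    if lens_high <= z_h or lens_low >= z_h:
        raise ValueError("degenerate geometry: lens does not straddle the hyaloid plane")
    v_sphere = 4.0 / 3.0 * math.pi * r_v**3
    v_anterior_cap = _cap_volume(r_v, r_v - z_h)
    v_lens_below = _cap_volume(r_l, z_h - lens_low)
    return v_sphere - v_anterior_cap - v_lens_below


def hyaloid_area(geometry: EyeGeometry) -> float:
    """Closed-form hyaloid membrane area in m²: planar annulus between the
    outer-sphere rim and the lens cross-section at z = z_h."""
    return math.pi * (geometry.outer_rim_radius**2 - geometry.inner_rim_radius**2)


def bolus_radius(dose_volume: float) -> float:
    """Radius of a spherical injection bolus of the given volume (m³ → m)."""
    if dose_volume <= 0.0:
        raise ValueError("dose volume must be positive")
    return (3.0 * dose_volume / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class InjectionSite:
    """Spherical drug bolus placed inside the vitreous."""

    location: str
    center: np.ndarray                               # m
    radius: float                                    # m
    dose_concentration: float = DOSE_CONCENTRATION_MOL_M3   # mol/m³
    dose_volume: float = DOSE_VOLUME_M3              # m³

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        r_expect = bolus_radius(self.dose_volume)
        if abs(self.radius - r_expect) > 0.01 * r_expect:
            raise ValueError(
                f"bolus radius {self.radius:.4e} inconsistent with dose volume "
                f"(expected {r_expect:.4e} m)"
            )


def _boundary_clearances(geometry: EyeGeometry, center: np.ndarray,
                         radius: float) -> dict[str, float]:
    """Signed clearance of a bolus sphere to each bounding surface (≥0 = inside)."""
    c = np.asarray(center, dtype=float)
    return {
        "outer sphere": geometry.vitreous_radius - float(np.linalg.norm(c)) - radius,
        "hyaloid plane": geometry.hyaloid_plane - c[2] - radius,
        "lens": float(np.linalg.norm(c - geometry.lens_center))
                - geometry.lens_radius - radius,
    }


def make_injection_site(geometry: EyeGeometry, location: str,
                        dose_concentration: float = DOSE_CONCENTRATION_MOL_M3,
                        dose_volume: float = DOSE_VOLUME_M3,
                        containment_tol: float = CONTAINMENT_TOL_M) -> InjectionSite:
    """Place the standard 0.05 mL bolus at a named depth for the species.

    Raises if the bolus escapes the domain by more than ``containment_tol``,
    naming the violated boundary.
    """
    centers = SPECIES_PARAMS[geometry.species]["injection_centers"]
    if location not in centers:
        raise ValueError(
            f"unknown injection location {location!r}: expected one of "
            f"{sorted(centers)}"
        )
    center = np.array(centers[location], dtype=float)
    radius = bolus_radius(dose_volume)
    for name, clearance in _boundary_clearances(geometry, center, radius).items():
        if clearance < -containment_tol:
            raise ValueError(
                f"injection bolus at {location!r} escapes the {name} by "
                f"{-clearance * 1e3:.2f} mm (tolerance {containment_tol * 1e3:.2f} mm)"
            )
    return InjectionSite(location=location, center=center, radius=radius,
                         dose_concentration=dose_concentration,
                         dose_volume=dose_volume)


def signed_distance(geometry: EyeGeometry, points: np.ndarray) -> np.ndarray:
    """Approximate signed distance to the domain boundary (negative inside).

    The maximum of the three constituent surface distances: outside the outer
    sphere, anterior of the hyaloid plane, or inside the lens sphere all count
    as outside.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    d_outer = np.linalg.norm(p, axis=1) - geometry.vitreous_radius
    d_plane = p[:, 2] - geometry.hyaloid_plane
    d_lens = geometry.lens_radius - np.linalg.norm(p - geometry.lens_center, axis=1)
    d = np.maximum(np.maximum(d_outer, d_plane), d_lens)
    return d if np.asarray(points).ndim == 2 else d[0]


def classify_surface_point(geometry: EyeGeometry, point: np.ndarray,
                           tol: float = 1e-6) -> SurfaceTag:
    """Tag a point lying on the domain boundary (within ``tol``).

    The outer sphere splits at z = 0, with z = 0 assigned to the anterior
    side.  Interior or exterior points are rejected.
    """
    p = np.asarray(point, dtype=float)
    if abs(signed_distance(geometry, p)) > tol:
        raise ValueError(
            f"point {p} is not on the domain boundary (signed distance "
            f"{signed_distance(geometry, p):.3e} m, tol {tol:.3e} m)"
        )
    d_outer = abs(np.linalg.norm(p) - geometry.vitreous_radius)
    d_lens = abs(np.linalg.norm(p - geometry.lens_center) - geometry.lens_radius)
    # Hyaloid candidacy requires being near the plane *and* within the annulus.
    r_xy = math.hypot(p[0], p[1])
    on_annulus = (geometry.inner_rim_radius - tol <= r_xy
                  <= geometry.outer_rim_radius + tol)
    d_plane = abs(p[2] - geometry.hyaloid_plane) if on_annulus else math.inf
    best = min(d_plane, d_outer, d_lens)
    if d_plane == best:
        return SurfaceTag.HYALOID
    if d_lens < d_outer:
        return SurfaceTag.LENS
    return SurfaceTag.ANTERIOR_OUTER if p[2] >= 0.0 else SurfaceTag.POSTERIOR_OUTER
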