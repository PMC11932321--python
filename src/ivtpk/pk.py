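"""Pharmacokinetic reductions of the simulated concentration series.

Half-life (log-linear interpolation from a species-specific baseline time),
duration of action (days above the in-vivo threshold concentration), and the
two fovea/macula concentration readouts: a point probe for cases without
posterior elimination, and a flux-based rolling daily estimate for cases with
a posterior sink (where the boundary value is identically zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .transport import ConcentrationSeries, mol_m3_to_ug_ml

__all__ = ["MaculaSpec", "PKMetrics", "MACULA", "BASE_TIME_DAYS",
           "half_life", "in_vivo_threshold", "duration_of_action",
           "macula_concentration_from_flux", "fovea_point_series",
           "dose_scale", "IN_VIVO_THRESHOLD_UG_ML"]

#: Baseline times for the half-life interpolation (days).
BASE_TIME_DAYS = {"rabbit": 3.0, "human": 5.0}

#: In-vivo threshold: 12.5 μg effective dose over the 4.79 mL human vitreous.
IN_VIVO_THRESHOLD_UG_ML = 2.6


@dataclass(frozen=True)
class MaculaSpec:
    """Macula (or rabbit visual-streak equivalent) geometry.

    The surface area is approximated as the flat disc π(d/2)²; the rabbit
    values are scaled proportionally from the human macula.
    """

    diameter: float   # m
    volume: float     # m³

    @property
    def area(self) -> float:
        return math.pi * (self.diameter / 2.0) ** 2


MACULA = {
    "rabbit": MaculaSpec(diameter=3.84e-3, volume=2.55e-9),
    "human": MaculaSpec(diameter=5.5e-3, volume=8.49e-9),
}


@dataclass(frozen=True)
class PKMetrics:
    """Scalar PK summary of one simulated case."""

    half_life: float                 # days
    duration_of_action: float | None  # days at 0.5-day resolution
    peak_fovea_concentration: float | None  # μg/mL
    peak_fovea_time: float | None    # days
    threshold: float                 # μg/mL used for the duration


def half_life(times: np.ndarray, concentration: np.ndarray,
              base_time: float) -> float:
    """Time for the concentration to halve, measured from ``base_time``.

    The crossing C(t*) = C(base)/2 is located by log-linear interpolation
    between the bracketing samples (exact for exponential decay); returns
    t* − base_time.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentration, dtype=float)
    if base_time < t[0] or base_time > t[-1]:
        raise ValueError(f"base time {base_time} outside the sampled range")
    c_base = float(np.interp(base_time, t, c))
    if c_base <= 0:
        raise ValueError("concentration at the base time must be positive")
    target = c_base / 2.0
    after = (t > base_time)
    below = after & (c <= target)
    if not below.any():
        raise ValueError(
            f"concentration never falls to half its value at t={base_time} d "
            f"within the simulated horizon; extend t_end beyond {t[-1]} d")
    j = int(np.argmax(below))
    t1, t2, c1, c2 = t[j - 1], t[j], c[j - 1], c[j]
    if c2 <= 0 or c1 <= 0 or c1 == c2:
        t_star = t2
    else:
        t_star = t1 + (t2 - t1) * math.log(target / c1) / math.log(c2 / c1)
    return float(t_star - base_time)


def in_vivo_threshold(dose_mass_ug: float, vitreous_volume_ml: float) -> float:
    """Dose spread over the vitreous volume, to 2 significant figures (μg/mL)."""
    if dose_mass_ug < 0 or vitreous_volume_ml <= 0:
        raise ValueError("dose must be non-negative and volume positive")
    c = dose_mass_ug / vitreous_volume_ml
    if c == 0.0:
        return 0.0
    return float(round(c, 1 - int(math.floor(math.log10(abs(c))))))


def duration_of_action(times: np.ndarray, concentration: np.ndarray,
                       threshold: float) -> float:
    """Days the concentration stays above the threshold, at 0.5-day resolution.

    Returns the last 0.5-day-resolved time before the series first remains
    below the threshold for good; 0 if it never reaches the threshold.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentration, dtype=float)
    dt = np.diff(t)
    if len(dt) and dt.max() > 0.5 + 1e-9:
        raise ValueError("series must be sampled at <= 0.5-day spacing")
    above = c >= threshold
    if not above.any():
        return 0.0
    if above[-1]:
        raise ValueError(
            f"concentration still above the threshold at t={t[-1]} d; "
            "extend t_end")
    last_above = int(np.where(above)[0][-1])
    t1, t2 = t[last_above], t[last_above + 1]
    c1, c2 = c[last_above], c[last_above + 1]
    t_cross = t1 if c1 == c2 else t1 + (t1 - t2) * (threshold - c1) / (c1 - c2)
    return float(math.floor(t_cross / 0.5 + 1e-9) * 0.5)


def macula_concentration_from_flux(series: ConcentrationSeries,
                                   macula: MaculaSpec,
                                   window: float = 1.0) -> np.ndarray:
    """Rolling daily macula concentration (μg/mL) from the fovea boundary flux.

    For cases with posterior elimination the fovea boundary value is pinned at
    zero, so the concentration just outside the vitreous is estimated from the
    flux: area × flux / volume gives a deposition rate (concentration per
    time), integrated over a trailing window (default 1 day, rectangle rule;
    the earliest window truncates to the available history).
    """
    if series.fovea_flux is None:
        raise ValueError(
            "flux-based macula concentration requires a posterior-elimination "
            "case (1b/2b); use the point-probe fovea series for cases a")
    t = series.times
    rate = mol_m3_to_ug_ml(series.fovea_flux) * macula.area / macula.volume
    dt = np.diff(t, prepend=t[0])
    out = np.empty_like(rate)
    for i in range(len(t)):
        in_win = (t > t[i] - window) & (t <= t[i])
        out[i] = float(np.sum(rate[in_win] * dt[in_win]))
    return np.clip(out, 0.0, None)


def fovea_point_series(series: ConcentrationSeries) -> np.ndarray:
    """Point-probe fovea concentration (μg/mL) for cases without posterior
    elimination (for cases b the boundary value is identically zero)."""
    if series.case is not None and series.case.posterior_elimination:
        raise ValueError(
            "the fovea boundary value is identically zero under posterior "
            "elimination; use macula_concentration_from_flux instead")
    return series.c_fovea_ug_ml


def dose_scale(series: ConcentrationSeries, factor: float) -> ConcentrationSeries:
    """Rescale a simulated series to a different dose (PDE linearity)."""
    return series.scaled(factor)
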