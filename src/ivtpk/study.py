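"""Orchestration of the full case matrix and the diffusion-sensitivity study.

A study sweeps species × case × injection location × convection regime,
reducing each run to its PK metrics, and writes half-life and
duration-of-action tables (one row per injection/convection combination, one
column per case, one block per species).  Everything is deterministic given
the configuration; the seed only feeds the mesh-lattice jitter and any
Monte-Carlo audits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import darcy, fem, pk, transport
from .darcy import FlowParams, FlowField, slow_inlet_speed, solve_darcy
from .geometry import (EyeGeometry, SurfaceTag, build_eye_geometry,
                       hyaloid_area, make_injection_site)
from .meshing import RefinementBall, VolumeMesh, generate_mesh
from .pk import BASE_TIME_DAYS, IN_VIVO_THRESHOLD_UG_ML, PKMetrics
from .transport import (CaseSpec, ConcentrationSeries, TransportParams,
                        simulate_transport)

__all__ = ["StudyConfig", "CaseResult", "run_case", "run_study",
           "diffusion_sensitivity", "load_config"]

logger = logging.getLogger(__name__)

DEFAULT_T_END = {"rabbit": 40.0, "human": 90.0}


@dataclass
class StudyConfig:
    """Fully specifies a reproducible study run."""

    species: tuple = ("rabbit", "human")
    cases: tuple = ("1a", "1b", "2a", "2b")
    injections: tuple = ("anterior", "middle", "posterior")
    convection_regimes: tuple = ("slow", "fast")
    resolution: float = 1.0          # multiplies the default element size
    dt_schedule: tuple | None = None  # None -> transport default
    t_end: dict = field(default_factory=lambda: dict(DEFAULT_T_END))
    threshold: float = IN_VIVO_THRESHOLD_UG_ML   # μg/mL
    dose_mg: float = 1.25
    d_multipliers: tuple = (1.0, 1.5, 2.0, 3.0)
    refine_bolus: bool = True
    out_dir: str = "results"
    seed: int = 0

    def element_size(self, species: str) -> float:
        from .meshing import DEFAULT_ELEMENT_SIZE
        return DEFAULT_ELEMENT_SIZE[species] * self.resolution

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> StudyConfig:
    """Read a study configuration from a YAML file."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("species", "cases", "injections", "convection_regimes",
                "d_multipliers"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return StudyConfig(**raw)


@dataclass
class CaseResult:
    """Series, PK metrics, and provenance for one simulated case."""

    species: str
    case: CaseSpec
    series: ConcentrationSeries
    metrics: PKMetrics
    provenance: dict


class _StudyCache:
    """Reuse meshes and Darcy solves across the case matrix."""

    def __init__(self) -> None:
        self.meshes: dict = {}
        self.flows: dict = {}

    def mesh(self, config: StudyConfig, species: str,
             injection: str) -> VolumeMesh:
        key = (species, injection if config.refine_bolus else None,
               config.resolution, config.seed)
        if key not in self.meshes:
            geometry = build_eye_geometry(species)
            refinement = []
            if config.refine_bolus:
                site = make_injection_site(geometry, injection)
                refinement.append(RefinementBall(
                    center=tuple(site.center), radius=site.radius * 1.25,
                    factor=1.5))
            self.meshes[key] = generate_mesh(
                geometry, element_size=config.element_size(species),
                refinement=refinement, seed=config.seed)
        return self.meshes[key]

    def flow(self, config: StudyConfig, species: str, injection: str,
             regime: str) -> FlowField:
        key = (species, injection if config.refine_bolus else None,
               config.resolution, config.seed, regime)
        if key not in self.flows:
            mesh = self.mesh(config, species, injection)
            geometry = mesh.geometry
            sp_flow = darcy.SPECIES_FLOW[species]
            if regime == "slow":
                u_in = slow_inlet_speed(darcy.AQUEOUS_PRODUCTION_M3_S,
                                        sp_flow["vitreous_fraction"],
                                        hyaloid_area(geometry))
            elif regime == "fast":
                u_in = darcy.FAST_INLET_SPEED
            else:
                raise ValueError(f"unknown convection regime {regime!r}")
            self.flows[key] = solve_darcy(
                mesh, FlowParams(mobility=sp_flow["mobility"], inlet_speed=u_in,
                                 density=sp_flow["density"]))
        return self.flows[key]


def run_case(config: StudyConfig, species: str, case: str, injection: str,
             convection: str = "none", d_multiplier: float = 1.0,
             t_end: float | None = None,
             cache: _StudyCache | None = None) -> CaseResult:
    """Simulate one (species, case, injection, convection) combination.

    ``convection`` must be 'none' for the diffusion-only cases 2a/2b and
    'slow' or 'fast' for cases 1a/1b (the Table-2 consistency rule).
    """
    spec = CaseSpec(case=case, convection=convection, injection=injection)
    cache = cache or _StudyCache()
    mesh = cache.mesh(config, species, injection)
    geometry = mesh.geometry
    site = make_injection_site(geometry, injection)
    flow = (cache.flow(config, species, injection, convection)
            if spec.uses_convection else None)
    params = TransportParams(
        diffusion=transport.SPECIES_TRANSPORT[species]["diffusion"]
        * d_multiplier)
    horizon = t_end if t_end is not None else config.t_end[species]
    series = simulate_transport(mesh, flow, params, spec, site=site,
                                t_end=horizon, dt=config.dt_schedule)
    if config.dose_mg != 1.25:
        series = series.scaled(config.dose_mg / 1.25)

    hl = pk.half_life(series.times, series.c_avg, BASE_TIME_DAYS[species])
    try:
        dur = pk.duration_of_action(series.times, series.c_avg_ug_ml,
                                    config.threshold)
    except ValueError as exc:
        logger.warning("duration of action undefined for %s/%s/%s: %s",
                       species, case, injection, exc)
        dur = None
    if spec.posterior_elimination:
        fov = pk.macula_concentration_from_flux(series, pk.MACULA[species])
    else:
        fov = pk.fovea_point_series(series)
    peak_idx = int(np.argmax(fov))
    metrics = PKMetrics(half_life=hl, duration_of_action=dur,
                        peak_fovea_concentration=float(fov[peak_idx]),
                        peak_fovea_time=float(series.times[peak_idx]),
                        threshold=config.threshold)
    provenance = {
        "species": species, "case": case, "injection": injection,
        "convection": convection, "d_multiplier": d_multiplier,
        "geometry_hash": hashlib.sha256(
            json.dumps({k: v for k, v in sorted(vars(geometry).items())},
                       default=str).encode()).hexdigest()[:16],
        "mesh": {"n_cells": mesh.n_cells, "n_points": mesh.n_points,
                 "nominal_size_m": mesh.nominal_size,
                 "hash": mesh.stats_hash()},
        "t_end_days": horizon,
        "dt_schedule": config.dt_schedule or transport.DEFAULT_DT_SCHEDULE,
        "mass_imbalance": transport.mass_audit(series),
    }
    return CaseResult(species=species, case=spec, series=series,
                      metrics=metrics, provenance=provenance)


def _matrix_rows(config: StudyConfig):
    """(row label, injection, convection-for-case-1) combinations, Table style."""
    rows = []
    for inj in config.injections:
        if inj == "middle":
            for regime in config.convection_regimes:
                rows.append((f"Middle vitreous ({regime} convection)",
                             inj, regime))
        else:
            rows.append((f"{inj.capitalize()} vitreous", inj, "slow"))
    return rows


def run_study(config: StudyConfig,
              out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Run the full case matrix and write half-life/duration CSV tables.

    Returns ``{"half_life": df, "duration": df}``; failed cells are left
    blank and the failure is logged, the run continues.
    """
    cache = _StudyCache()
    frames = {}
    records_h, records_d = [], []
    for species in config.species:
        for label, inj, regime in _matrix_rows(config):
            row_h = {"species": species, "row": label}
            row_d = {"species": species, "row": label}
            for case in config.cases:
                conv = regime if case.startswith("1") else "none"
                try:
                    res = run_case(config, species, case, inj, conv,
                                   cache=cache)
                    row_h[f"case_{case}"] = round(res.metrics.half_life, 2)
                    dur = res.metrics.duration_of_action
                    row_d[f"case_{case}"] = ("" if dur is None else dur)
                except Exception as exc:
                    logger.error("case %s/%s/%s/%s failed: %s",
                                 species, case, inj, conv, exc)
                    row_h[f"case_{case}"] = ""
                    row_d[f"case_{case}"] = ""
            records_h.append(row_h)
            records_d.append(row_d)
    frames["half_life"] = pd.DataFrame(records_h)
    frames["duration"] = pd.DataFrame(records_d)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frames["half_life"].to_csv(out / "half_life_days.csv", index=False)
        frames["duration"].to_csv(out / "duration_of_action_days.csv",
                                  index=False)
    return frames


def diffusion_sensitivity(config: StudyConfig,
                          multipliers=None) -> pd.DataFrame:
    """Half-life of the human slow-convection case 1a (middle injection) as
    the diffusion coefficient is scaled by each multiplier."""
    multipliers = tuple(multipliers or config.d_multipliers)
    cache = _StudyCache()
    rows = []
    for mult in multipliers:
        res = run_case(config, "human", "1a", "middle", "slow",
                       d_multiplier=mult,
                       t_end=min(30.0, config.t_end["human"]), cache=cache)
        rows.append({"d_multiplier": mult,
                     "diffusion_m2_s":
                         transport.SPECIES_TRANSPORT["human"]["diffusion"] * mult,
                     "half_life_days": res.metrics.half_life})
    return pd.DataFrame(rows)
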