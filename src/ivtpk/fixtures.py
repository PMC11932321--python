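"""Verification oracles and synthetic PK data.

Everything here is independent of the finite-element path it checks:

* an eigenfunction-series solution for diffusion out of an absorbing sphere,
  plus a radial finite-difference fallback oracle;
* a method-of-manufactured-solutions convergence study on the rabbit domain;
* synthetic digitized-PK curves (noisy exponential decay) standing in for
  figure-derived experimental data, with a CSV reader and a log-scale
  comparison metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla

__all__ = ["DigitizedPKCurve", "analytic_sphere_decay",
           "radial_fd_remaining_mass", "manufactured_solution_check",
           "synthesize_pk_curve", "read_pk_csv", "compare_to_model"]


def analytic_sphere_decay(D: float, a: float, t: float,
                          n_terms: int = 200) -> float:
    """Remaining mass fraction for pure diffusion in an absorbing sphere.

    Uniform initial concentration in a sphere of radius ``a`` with C = 0 on
    the surface: the fraction of the initial mass remaining at time ``t`` is
    Σₙ (6/(n²π²))·exp(−D n²π² t / a²).
    """
    if D <= 0 or a <= 0 or t < 0:
        raise ValueError("D, a must be positive and t non-negative")
    n = np.arange(1, n_terms + 1)
    lam = (n * math.pi / a) ** 2 * D
    return float(np.sum(6.0 / (n * math.pi) ** 2 * np.exp(-lam * t)))


def radial_fd_remaining_mass(D: float, a: float, t: float,
                             n_shells: int = 10_000,
                             n_steps: int = 2_000) -> float:
    """Brute-force radial finite-difference oracle for the absorbing sphere.

    Crank–Nicolson in time on the spherically symmetric diffusion equation
    ∂c/∂t = D(c'' + 2c'/r), with c'(0) = 0 and c(a) = 0.
    """
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    r = np.linspace(0.0, a, n_shells + 1)
    h = r[1] - r[0]
    n = n_shells + 1
    ri = r[1:-1]
    rows, cols, vals = [], [], []
    # r = 0: symmetry c'(0)=0; the limit of the operator is 3D c''(0)
    rows += [0, 0]
    cols += [0, 1]
    vals += [-6.0 * D / h**2, 6.0 * D / h**2]
    for k, rr in enumerate(ri, start=1):
        rows += [k, k, k]
        cols += [k - 1, k, k + 1]
        vals += [D * (1.0 / h**2 - 1.0 / (h * rr)), -2.0 * D / h**2,
                 D * (1.0 / h**2 + 1.0 / (h * rr))]
    L = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    dt = t / n_steps
    I = sp.identity(n, format="csr")
    A = (I - 0.5 * dt * L).tolil()
    A.rows[-1], A.data[-1] = [n - 1], [1.0]      # Dirichlet c(a) = 0
    B = (I + 0.5 * dt * L).tolil()
    B.rows[-1], B.data[-1] = [n - 1], [0.0]
    lu = spla.splu(A.tocsc())
    Bc = B.tocsr()
    c = np.ones(n)
    c[-1] = 0.0
    for _ in range(n_steps):
        c = lu.solve(Bc @ c)
    mass = np.trapezoid(4.0 * math.pi * r**2 * c, r)
    return float(mass / (4.0 / 3.0 * math.pi * a**3))


def manufactured_solution_check(mesh_levels=(2.4e-3, 1.7e-3, 1.2e-3),
                                dt_levels=(0.02, 0.01),
                                seed: int = 0) -> dict:
    """Convergence orders of the transport solver on the rabbit domain.

    Space: exact solution q(x)·e^(−t) with quadratic q, Dirichlet values and
    a source chosen so the diffusion equation holds exactly; the observed L2
    order over the mesh levels should approach 2.  Time: a spatially linear
    exact solution (representable exactly by P1) isolates the backward-Euler
    error; halving dt should show order ≈ 1.
    """
    from .geometry import SurfaceTag, build_eye_geometry
    from .meshing import generate_mesh
    from .transport import (CaseSpec, SECONDS_PER_DAY, TransportParams,
                            simulate_transport)

    geometry = build_eye_geometry("rabbit")
    D = 1.2e-10
    D_day = D * SECONDS_PER_DAY
    L = geometry.vitreous_radius

    def exact_quad(x, t):
        q = (x[:, 0] ** 2 + 2.0 * x[:, 1] ** 2 + 3.0 * x[:, 2] ** 2) / L**2
        return (1.0 + q) * math.exp(-t)

    def source_quad(x, t):
        # ∂c/∂t − DΔc with Δq = 12/L²
        return -exact_quad(x, t) - D_day * 12.0 / L**2 * math.exp(-t)

    def exact_lin(x, t):
        return (1.0 + (x[:, 0] + 2.0 * x[:, 1] + 3.0 * x[:, 2]) / L) \
            * math.exp(-t)

    def source_lin(x, t):
        return -exact_lin(x, t)

    params = TransportParams(diffusion=D)
    case = CaseSpec("2b")        # base case; all tags become Dirichlet below

    def run(mesh, dt, t_end, exact, source):
        dv = {tag: exact for tag in SurfaceTag}
        series = simulate_transport(
            mesh, None, params, case, c0=exact(mesh.points, 0.0),
            t_end=t_end, dt=dt, dirichlet_values=dv, source=source)
        w = mesh.lumped_volumes()
        err = series.final_field - exact(mesh.points, t_end)
        ref = exact(mesh.points, t_end)
        return math.sqrt(float(w @ err**2)) / math.sqrt(float(w @ ref**2))

    t_end = 0.2
    spatial_err = [run(generate_mesh(geometry, h, seed=seed), 0.005, t_end,
                       exact_quad, source_quad) for h in mesh_levels]
    h = np.asarray(mesh_levels)
    spatial_order = float(np.polyfit(np.log(h), np.log(spatial_err), 1)[0])

    mesh = generate_mesh(geometry, mesh_levels[1], seed=seed)
    temporal_err = [run(mesh, dt, t_end, exact_lin, source_lin)
                    for dt in dt_levels]
    temporal_order = float(
        math.log(temporal_err[0] / temporal_err[-1])
        / math.log(dt_levels[0] / dt_levels[-1]))
    return {"spatial_errors": spatial_err, "spatial_order": spatial_order,
            "temporal_errors": temporal_err, "temporal_order": temporal_order}


@dataclass(frozen=True)
class DigitizedPKCurve:
    """A (possibly figure-digitized) PK curve: concentration vs time."""

    times: np.ndarray            # days, strictly increasing
    concentrations: np.ndarray   # μg/mL (or dimensionless if normalized)
    source: str = "synthetic"
    normalized: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if len(t) != len(c) or len(t) == 0:
            raise ValueError("times and concentrations must match and be non-empty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if self.normalized and abs(c.max() - 1.0) > 1e-9:
            raise ValueError("normalized curve must peak at 1.0")


def synthesize_pk_curve(c0: float, half_life: float, sample_times,
                        noise_cv: float = 0.0,
                        seed: int | None = 0) -> DigitizedPKCurve:
    """Synthetic stand-in for a digitized experimental PK curve.

    Exponential decay from ``c0`` with the given half-life, multiplied by
    log-normal noise of coefficient of variation ``noise_cv``; deterministic
    under a fixed seed.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    t = np.asarray(sample_times, dtype=float)
    c = c0 * np.power(2.0, -t / half_life)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        c = c * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(t))
    return DigitizedPKCurve(times=t, concentrations=c, source="synthetic")


def read_pk_csv(path, normalized: bool = False) -> DigitizedPKCurve:
    """Read a PK curve CSV with columns ``time_days, concentration``."""
    df = pd.read_csv(path)
    required = {"time_days", "concentration"}
    if not required.issubset(df.columns):
        raise ValueError(f"PK CSV must have columns {sorted(required)}; "
                         f"got {list(df.columns)}")
    t = df["time_days"].to_numpy(dtype=float)
    c = df["concentration"].to_numpy(dtype=float)
    bad = np.where(np.diff(t) <= 0)[0]
    if len(bad):
        raise ValueError(f"times not strictly increasing at row {bad[0] + 1}")
    neg = np.where(c < 0)[0]
    if len(neg):
        raise ValueError(f"negative concentration at row {neg[0]}")
    return DigitizedPKCurve(times=t, concentrations=c,
                            source=str(path), normalized=normalized)


def compare_to_model(curve: DigitizedPKCurve, model_times, model_conc) -> float:
    """Log10-scale RMSE between a PK curve and a model series.

    The model series is interpolated at the curve's sample times on a log10
    concentration scale; a factor-of-10 offset gives an RMSE of exactly 1.
    """
    mt = np.asarray(model_times, dtype=float)
    mc = np.asarray(model_conc, dtype=float)
    m_at = np.interp(curve.times, mt, mc)
    eps = 1e-300
    diff = np.log10(np.maximum(curve.concentrations, eps)) \
        - np.log10(np.maximum(m_at, eps))
    return float(np.sqrt(np.mean(diff**2)))
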