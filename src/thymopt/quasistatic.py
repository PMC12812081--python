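"""Optimal naive T cell production under rapid peripheral turnover.

When peripheral clones turn over quickly, the clone count tracks the
thymic output, N(t) ≈ h(t)/u, and the host can minimize the
instantaneous cost

    Psi(t) = n g(t) K u / h + m h

independently at each age.  The minimizer is the closed-form schedule

    h(t) = sqrt( (K u n / m) g(t) ),

an exponential in t when all strains share one encounter rate and a
power law (1 + f̄ t/a)^{-(a+1)/2} when rates are Gamma-distributed —
the model's account of exponential vs power-law thymic involution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .encounter import EncounterModel, novelty_intensity

__all__ = [
    "CostParams",
    "pointwise_cost",
    "optimal_production",
    "clone_count",
    "lifetime_production",
    "log_schedule_diagnostics",
]


@dataclass(frozen=True)
class CostParams:
    """Cost coefficients of the fighting/maintenance trade-off.

    K : magnitude of the fighting cost (cost K/N per novel infection),
    m : maintenance cost per unit naive T cell production rate,
    u : decay rate of naive T cell clones in the periphery.
    """

    K: float
    m: float
    u: float

    def __post_init__(self) -> None:
        for name in ("K", "m", "u"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def to_config(self) -> dict:
        return {"K": float(self.K), "m": float(self.m), "u": float(self.u)}

    @classmethod
    def from_config(cls, mapping: dict) -> "CostParams":
        unknown = set(mapping) - {"K", "m", "u"}
        if unknown:
            raise ValueError(f"unknown cost parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


def pointwise_cost(t, h, params: CostParams, model: EncounterModel):
    """Instantaneous cost Psi(t) = n g(t) K u / h + m h at production rate h.

    Uses the quasi-stationary substitution N = h/u; diverges as h -> 0,
    so non-positive h is rejected.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError("production rate h must be strictly positive")
    g = novelty_intensity(model, t)
    out = model.n * np.asarray(g) * params.K * params.u / h + params.m * h
    return float(out) if out.ndim == 0 else out


def optimal_production(t, params: CostParams, model: EncounterModel):
    """Cost-minimizing production rate h(t) = sqrt(K u n g(t) / m)."""
    g = novelty_intensity(model, t)
    out = np.sqrt(params.K * params.u * model.n * np.asarray(g) / params.m)
    return float(out) if out.ndim == 0 else out


def clone_count(t, params: CostParams, model: EncounterModel):
    """Quasi-stationary clone count N(t) = h(t)/u along the optimum."""
    out = np.asarray(optimal_production(t, params, model)) / params.u
    return float(out) if out.ndim == 0 else out


def lifetime_production(
    params: CostParams, model: EncounterModel, horizon: float = np.inf
) -> float:
    """Total lifetime output ∫ h(t) dt of the quasi-static optimum.

    With an infinite horizon, h must decay integrably: h ~ t^{-(a+1)/2}
    for Gamma models, so a <= 1 (and any lognormal/empirical tail that
    decays more slowly than 1/t) diverges and is reported as an error.
    For a common encounter rate the infinite-horizon integral has the
    closed form 2 sqrt(K u n / (m f̄)), which the quadrature reproduces.
    """
    if horizon < 0:
        raise ValueError("horizon must be positive (or infinite)")
    if horizon == 0:
        return 0.0
    if np.isinf(horizon):
        if model.kind == "gamma" and model.shape <= 1.0:
            raise ValueError(
                "lifetime production diverges: Gamma shape a <= 1 gives "
                "h ~ t^-(a+1)/2, not integrable on an infinite horizon"
            )
        if model.kind not in ("degenerate", "gamma"):
            raise ValueError(
                "infinite-horizon lifetime production is only supported for "
                "degenerate and Gamma (a > 1) models; pass a finite horizon"
            )
        # truncate where the integrand falls below 1e-12 of its peak
        h0 = optimal_production(0.0, params, model)
        fb = model.mean_rate
        if model.kind == "degenerate":
            upper = 2.0 * np.log(1e12) / fb
        else:
            a = model.shape
            upper = (a / fb) * (1e12 ** (2.0 / (a + 1.0)) - 1.0)
        val, err = integrate.quad(
            lambda t: optimal_production(t, params, model),
            0.0,
            upper,
            epsabs=1e-12 * h0 * upper,
            epsrel=1e-10,
            limit=500,
        )
        return float(val)
    val, err = integrate.quad(
        lambda t: optimal_production(t, params, model),
        0.0,
        horizon,
        epsrel=1e-10,
        limit=500,
    )
    return float(val)


def log_schedule_diagnostics(
    params: CostParams,
    model: EncounterModel,
    grid,
    tol: float = 1e-10,
) -> dict:
    """Finite-difference slope and curvature of log h(t) on a grid.

    The optimal log-schedule always has non-positive slope and
    non-negative curvature (a mixture of exponentials is log-convex),
    with zero curvature exactly when all strains share one rate.
    Returns interior-point slopes/curvatures plus the grid indices where
    either sign condition fails beyond ``tol``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 3:
        raise ValueError("grid must be a 1-D array with at least 3 points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    logh = np.log(optimal_production(grid, params, model))
    slope = np.gradient(logh, grid)
    # second difference on (possibly non-uniform) grid interior points
    h1 = grid[1:-1] - grid[:-2]
    h2 = grid[2:] - grid[1:-1]
    curv = 2.0 * (
        logh[:-2] / (h1 * (h1 + h2))
        - logh[1:-1] / (h1 * h2)
        + logh[2:] / (h2 * (h1 + h2))
    )
    slope_viol = np.nonzero(slope > tol)[0]
    curv_viol = np.nonzero(curv < -tol)[0] + 1
    return {
        "grid": grid,
        "log_h": logh,
        "slope": slope,
        "curvature": curv,
        "slope_violations": slope_viol,
        "curvature_violations": curv_viol,
    }
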