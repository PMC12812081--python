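"""Distributions of pathogen-strain encounter rates.

A host meets each of ``n`` pathogen strains as an independent Poisson
process with per-strain rate ``f_i``.  Everything the optimal production
schedule depends on is the *novelty-weighted encounter intensity*

    g(t) = E[ f e^{-f t} ]  =  (1/n) sum_i f_i e^{-f_i t},

the mean rate of meeting a strain that has never been met before, per
strain, at age ``t``.  Heterogeneity in ``f`` across strains turns the
exponential decay of g(t) into a heavier-tailed (power-law-like) decay,
which is the mechanism behind power-law thymic involution curves.

Supported rate laws: a single common rate (degenerate), Gamma, lognormal,
and an explicit empirical list of rates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EncounterModel",
    "novelty_intensity",
    "novel_fraction",
    "sample_rates",
]

logger = logging.getLogger(__name__)

_KINDS = ("degenerate", "gamma", "lognormal", "empirical")

#: Gauss–Hermite order for lognormal expectations; doubled for the
#: convergence check.  The integrand in z = log f is smooth, so the rule
#: converges spectrally.
_GH_NODES = 64
_GH_RTOL = 1e-8


@dataclass(frozen=True)
class EncounterModel:
    """Distribution of per-strain encounter rates plus the strain count.

    Parameters
    ----------
    kind
        One of ``degenerate``, ``gamma``, ``lognormal``, ``empirical``.
    n
        Number of distinct pathogen strains a host may encounter over
        its lifetime.
    mean_rate
        Mean encounter rate f-bar (per unit age).  Required for
        ``degenerate``; derived (and cross-checked if given) otherwise.
    shape, rate_param
        Gamma shape ``a`` and rate ``b`` (density ∝ f^(a-1) e^(-b f)),
        so the mean is a/b and variance/mean² = 1/a.
    log_mean, log_var
        Mean and variance of log f for the lognormal law; the mean rate
        is exp(log_mean + log_var/2).
    rates
        Explicit per-strain rates (empirical kind); length must be n.
    """

    kind: str
    n: int
    mean_rate: float | None = None
    shape: float | None = None
    rate_param: float | None = None
    log_mean: float | None = None
    log_var: float | None = None
    rates: tuple[float, ...] | None = None
    _rates_arr: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected one of {_KINDS}")
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError("n must be a positive integer")
        if self.kind == "degenerate":
            if self.mean_rate is None or self.mean_rate <= 0:
                raise ValueError("degenerate kind requires mean_rate > 0")
        elif self.kind == "gamma":
            if self.shape is None or self.rate_param is None:
                raise ValueError("gamma kind requires shape and rate_param")
            if self.shape <= 0 or self.rate_param <= 0:
                raise ValueError("gamma shape and rate_param must be positive")
            mean = self.shape / self.rate_param
            if self.mean_rate is None:
                object.__setattr__(self, "mean_rate", mean)
            elif not np.isclose(self.mean_rate, mean, rtol=1e-12):
                raise ValueError("gamma mean_rate must equal shape/rate_param")
            if self.n < 100:
                logger.warning(
                    "continuous Gamma approximation with n=%d strains; an "
                    "explicit empirical rate list is recommended for n < 100",
                    self.n,
                )
        elif self.kind == "lognormal":
            if self.log_mean is None or self.log_var is None:
                raise ValueError("lognormal kind requires log_mean and log_var")
            if self.log_var <= 0:
                raise ValueError("log_var must be positive")
            mean = float(np.exp(self.log_mean + self.log_var / 2.0))
            if self.mean_rate is None:
                object.__setattr__(self, "mean_rate", mean)
            elif not np.isclose(self.mean_rate, mean, rtol=1e-12):
                raise ValueError("lognormal mean_rate must equal exp(mu + sigma^2/2)")
        else:  # empirical
            if self.rates is None:
                raise ValueError("empirical kind requires rates")
            arr = np.asarray(self.rates, dtype=float)
            if arr.ndim != 1 or len(arr) != self.n:
                raise ValueError("rates must be a flat list of length n")
            if np.any(arr <= 0):
                raise ValueError("all rates must be strictly positive")
            object.__setattr__(self, "rates", tuple(float(r) for r in arr))
            mean = float(arr.mean())
            if self.mean_rate is None:
                object.__setattr__(self, "mean_rate", mean)
            elif not np.isclose(self.mean_rate, mean, rtol=1e-12):
                raise ValueError("empirical mean_rate must equal mean(rates)")
        if self.kind == "empirical":
            object.__setattr__(self, "_rates_arr", np.asarray(self.rates, float))

    # -- constructors --------------------------------------------------

    @classmethod
    def degenerate(cls, mean_rate: float, n: int) -> "EncounterModel":
        return cls(kind="degenerate", n=n, mean_rate=mean_rate)

    @classmethod
    def gamma(cls, shape: float, rate_param: float, n: int) -> "EncounterModel":
        return cls(kind="gamma", n=n, shape=shape, rate_param=rate_param)

    @classmethod
    def lognormal(cls, log_mean: float, log_var: float, n: int) -> "EncounterModel":
        return cls(kind="lognormal", n=n, log_mean=log_mean, log_var=log_var)

    @classmethod
    def empirical(cls, rates, n: int | None = None) -> "EncounterModel":
        rates = tuple(float(r) for r in rates)
        return cls(kind="empirical", n=n if n is not None else len(rates), rates=rates)

    # -- serialization --------------------------------------------------

    def to_config(self) -> dict:
        """Plain mapping suitable for YAML/JSON round-tripping."""
        out = {"kind": self.kind, "n": int(self.n)}
        if self.kind == "degenerate":
            out["mean_rate"] = float(self.mean_rate)
        elif self.kind == "gamma":
            out["shape"] = float(self.shape)
            out["rate_param"] = float(self.rate_param)
        elif self.kind == "lognormal":
            out["log_mean"] = float(self.log_mean)
            out["log_var"] = float(self.log_var)
        else:
            out["rates"] = [float(r) for r in self.rates]
        return out

    @classmethod
    def from_config(cls, mapping: dict) -> "EncounterModel":
        mapping = dict(mapping)
        kind = mapping.pop("kind")
        n = mapping.pop("n", None)
        allowed = {
            "degenerate": {"mean_rate"},
            "gamma": {"shape", "rate_param", "mean_rate"},
            "lognormal": {"log_mean", "log_var", "mean_rate"},
            "empirical": {"rates", "mean_rate"},
        }
        if kind not in allowed:
            raise ValueError(f"unknown encounter model kind {kind!r}")
        unknown = set(mapping) - allowed[kind]
        if unknown:
            raise ValueError(f"unknown keys for {kind} model: {sorted(unknown)}")
        if kind == "empirical" and n is None:
            n = len(mapping["rates"])
        return cls(kind=kind, n=int(n), **mapping)

    def rates_to_csv(self, path) -> None:
        if self.kind != "empirical":
            raise ValueError("only empirical models carry an explicit rate list")
        pd.DataFrame({"f": list(self.rates)}).to_csv(path, index=False)

    @classmethod
    def rates_from_csv(cls, path, n: int | None = None) -> "EncounterModel":
        df = pd.read_csv(path)
        if "f" not in df.columns:
            raise ValueError('rate CSV must have a column named "f"')
        return cls.empirical(df["f"].to_numpy(), n=n)


def _check_age(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age t must be non-negative")
    return t


def _gh_expectation(model: EncounterModel, t: np.ndarray, weighted: bool) -> np.ndarray:
    """E[e^{-f t}] (or E[f e^{-f t}]) under the lognormal law by
    Gauss-Hermite quadrature in z = log f, with a node-doubling check."""
    mu, sigma = model.log_mean, float(np.sqrt(model.log_var))

    def estimate(order: int) -> np.ndarray:
        x, w = np.polynomial.hermite.hermgauss(order)
        f = np.exp(mu + sigma * np.sqrt(2.0) * x)  # (order,)
        integ = f[None, :] if weighted else 1.0
        vals = integ * np.exp(-np.outer(t, f))
        return (vals @ w) / np.sqrt(np.pi)

    coarse = estimate(_GH_NODES)
    fine = estimate(2 * _GH_NODES)
    err = np.max(np.abs(fine - coarse) / np.maximum(np.abs(fine), 1e-300))
    if err > _GH_RTOL:
        raise RuntimeError(
            f"lognormal quadrature did not converge: relative change {err:.2e} "
            f"between {_GH_NODES} and {2 * _GH_NODES} Gauss-Hermite nodes"
        )
    return fine


def novelty_intensity(model: EncounterModel, t) -> float | np.ndarray:
    """Novelty-weighted encounter intensity g(t) = E[f e^{-f t}].

    Closed forms: f̄ e^{-f̄ t} (degenerate) and f̄ (1 + f̄ t/a)^{-(a+1)}
    (Gamma, from the derivative of the Gamma MGF); lognormal models use
    Gauss–Hermite quadrature; empirical models are exact strain sums.

    g is strictly positive and strictly decreasing in t.
    """
    tarr = _check_age(t)
    fb = model.mean_rate
    if model.kind == "degenerate":
        out = fb * np.exp(-fb * tarr)
    elif model.kind == "gamma":
        out = fb * (1.0 + fb * tarr / model.shape) ** (-(model.shape + 1.0))
    elif model.kind == "lognormal":
        out = _gh_expectation(model, np.atleast_1d(tarr), weighted=True)
        out = out.reshape(tarr.shape)
    else:
        f = model._rates_arr
        out = np.mean(f * np.exp(-np.multiply.outer(tarr, f)), axis=-1)
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def novel_fraction(model: EncounterModel, t) -> float | np.ndarray:
    """Per-strain probability E[e^{-f t}] of no encounter by age t.

    Equals 1 at t = 0 and decreases monotonically; for the Gamma law it
    is the MGF (1 + f̄ t/a)^{-a}.
    """
    tarr = _check_age(t)
    fb = model.mean_rate
    if model.kind == "degenerate":
        out = np.exp(-fb * tarr)
    elif model.kind == "gamma":
        out = (1.0 + fb * tarr / model.shape) ** (-model.shape)
    elif model.kind == "lognormal":
        out = _gh_expectation(model, np.atleast_1d(tarr), weighted=False)
        out = out.reshape(tarr.shape)
    else:
        f = model._rates_arr
        out = np.mean(np.exp(-np.multiply.outer(tarr, f)), axis=-1)
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def sample_rates(model: EncounterModel, count: int, seed) -> np.ndarray:
    """Reproducible draws of per-strain rates from the model's law.

    Empirical models return (a copy of) their own list; other kinds draw
    ``count`` i.i.d. rates with ``numpy.random.default_rng(seed)``.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if model.kind == "empirical":
        return np.asarray(model.rates, dtype=float).copy()
    rng = np.random.default_rng(seed)
    if model.kind == "degenerate":
        return np.full(count, model.mean_rate, dtype=float)
    if model.kind == "gamma":
        return rng.gamma(model.shape, 1.0 / model.rate_param, size=count)
    return rng.lognormal(model.log_mean, float(np.sqrt(model.log_var)), size=count)
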