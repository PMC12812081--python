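"""Monte Carlo validation of the cost model.

Each pathogen strain is met as an independent Poisson process, so its
first-encounter age is exponential with the strain's rate; with perfect
lifelong immune memory only first encounters cost anything, each costing
K/N(age).  Averaging realized lifetime costs over many hosts must
reproduce the deterministic cost integral ∫ Psi(t) dt of the schedule
being simulated — the expectation structure behind the model's
fighting-cost term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .control import ControlProblem, PhaseSchedule, schedule_state, singular_control
from .oracle import GriddedControl, gridded_state
from .encounter import sample_rates

__all__ = ["LifeHistorySample", "simulate_lifetime_cost", "empirical_novelty_curve"]


@dataclass
class LifeHistorySample:
    """One host's realized life history.

    ``first_encounter_ages`` holds, per strain, the age of the first
    encounter, or ``inf`` for strains never met within [0, T].
    """

    first_encounter_ages: np.ndarray
    realized_fighting_cost: float
    production_cost: float

    @property
    def total_cost(self) -> float:
        return self.realized_fighting_cost + self.production_cost


def _production_cost(schedule, problem: ControlProblem) -> float:
    m = problem.cost.m
    if isinstance(schedule, GriddedControl):
        return m * float(np.dot(schedule.levels, np.diff(schedule.breakpoints)))
    total = 0.0
    for a, b, kind in schedule.segments(problem.T):
        if kind == "max":
            total += problem.h_max * (b - a)
        elif kind == "singular":
            val, _ = integrate.quad(
                lambda s: singular_control(s, problem, check_bounds=False), a, b,
                epsrel=1e-10, limit=200,
            )
            total += val
    return m * total


def _state_fn(schedule, problem: ControlProblem):
    if isinstance(schedule, GriddedControl):
        return lambda t: gridded_state(schedule, problem, t)
    return lambda t: schedule_state(schedule, problem, t)


def _host_rates(problem: ControlProblem, hosts: int, rng, freeze_rates: bool) -> np.ndarray:
    """Per-host, per-strain encounter rates, shape (hosts, n)."""
    model = problem.model
    n = model.n
    if model.kind in ("degenerate", "empirical"):
        base = sample_rates(model, n, seed=rng) if model.kind == "degenerate" else None
        row = base if base is not None else np.asarray(model.rates, dtype=float)
        return np.broadcast_to(row, (hosts, n))
    if freeze_rates:
        row = sample_rates(model, n, seed=rng)
        return np.broadcast_to(row, (hosts, n))
    return sample_rates(model, hosts * n, seed=rng).reshape(hosts, n)


def simulate_lifetime_cost(
    schedule,
    problem: ControlProblem,
    hosts: int,
    seed,
    freeze_rates: bool = False,
    return_samples: bool = False,
):
    """Simulate realized lifetime costs under a schedule.

    Per host, each strain's first-encounter age is drawn as an
    exponential time with its rate (later encounters are free: memory);
    the fighting cost K/N is accrued at each first encounter inside
    [0, T], and the deterministic production cost ∫ m h dt is added.
    For Gamma/lognormal models the per-strain rates are resampled per
    host by default; ``freeze_rates`` draws one rate vector shared by
    every host (the fixed-list reading of the strain sum).

    Returns ``(mean, se)`` over hosts, or ``(mean, se, samples)`` with
    ``return_samples``.
    """
    if hosts < 1:
        raise ValueError("hosts must be >= 1")
    rng = np.random.default_rng(seed)
    rates = _host_rates(problem, hosts, rng, freeze_rates)
    ages = rng.exponential(1.0, size=rates.shape) / rates
    hit = ages <= problem.T
    N_fn = _state_fn(schedule, problem)
    inv_n = np.zeros_like(ages)
    if np.any(hit):
        Nvals = np.asarray(N_fn(ages[hit]))
        if np.any(Nvals <= 0.0):
            raise ValueError("clone count is zero at a simulated encounter age")
        inv_n[hit] = 1.0 / Nvals
    fighting = problem.cost.K * inv_n.sum(axis=1)
    prod = _production_cost(schedule, problem)
    total = fighting + prod
    mean = float(total.mean())
    se = float(total.std(ddof=1) / np.sqrt(hosts)) if hosts > 1 else 0.0
    if not return_samples:
        return mean, se
    enc = np.where(hit, ages, np.inf)
    samples = [
        LifeHistorySample(
            first_encounter_ages=enc[i],
            realized_fighting_cost=float(fighting[i]),
            production_cost=prod,
        )
        for i in range(hosts)
    ]
    return mean, se, samples


def empirical_novelty_curve(samples: list[LifeHistorySample], grid) -> np.ndarray:
    """Fraction of (host, strain) pairs not yet encountered by each grid
    age — a Monte Carlo estimate of the novel fraction E[e^{-f t}]."""
    if not samples:
        raise ValueError("samples must be nonempty")
    ages = np.stack([s.first_encounter_ages for s in samples])
    grid = np.asarray(grid, dtype=float)
    return np.array([(ages > g).mean() for g in grid])
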