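"""Dynamic optimal control of naive T cell production.

With slow peripheral turnover the clone count obeys dN/dt = h(t) − u N,
N(0) = 0, and the host maximizes lifetime fitness

    phi = C − ∫_0^T [ K n g(t) / N(t) + m h(t) ] dt,   0 ≤ h ≤ h_max,

where g(t) is the novelty-weighted encounter intensity.  Pontryagin's
maximum principle with Hamiltonian H = −(K n g/N + m h) + λ(h − uN)
makes the control bang-bang except on singular arcs where the costate
λ(t) sticks to the marginal production cost m.  On such an arc the
stationarity condition K n g(t)/N² = u m pins N(t) to exactly the
quasi-static optimum; the candidate solution is

    three-phase:  h = h_max on [0, t1),  singular on [t1, t2),  0 after,
    two-phase:    h = h_max on [0, t3),  0 after  (arc infeasible),

with t1 the age at which the max-rate trajectory reaches the arc, t2
from backward integration of the costate from λ(T) = 0, and t3 from the
self-consistent switching condition λ(t3) = m.

Because the fighting cost K/N diverges at the prescribed initial state
N(0) = 0, all fitness evaluations start from a small regularizing clone
count N0 (identical for every schedule that is compared), by default
1e-6 times the singular-arc clone count at birth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate, optimize

from .encounter import EncounterModel, novelty_intensity
from .quasistatic import CostParams

__all__ = [
    "ControlProblem",
    "PhaseSchedule",
    "Trajectory",
    "singular_clone_count",
    "singular_control",
    "solve_t1",
    "solve_t2",
    "solve_t3",
    "assemble_schedule",
    "integrate_trajectory",
    "schedule_state",
    "fitness",
    "schedule_fitness",
    "pmp_certificate",
]


@dataclass(frozen=True)
class ControlProblem:
    """Specification of the finite-horizon production control problem.

    ``C`` is the baseline fitness in the absence of costs; ``N0`` the
    initial-state regularization (``None`` selects the default 1e-6 ×
    singular-arc clone count at t = 0); ``rel_tol``/``abs_tol`` are
    integration tolerances.
    """

    cost: CostParams
    model: EncounterModel
    T: float
    h_max: float
    C: float = 0.0
    N0: float | None = None
    rel_tol: float = 1e-10
    abs_tol: float = 1e-13

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("horizon T must be positive")
        if self.h_max <= 0:
            raise ValueError("h_max must be positive")
        if self.N0 is not None and self.N0 < 0:
            raise ValueError("N0 must be non-negative")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")

    @property
    def n0(self) -> float:
        """Effective initial clone count (regularized)."""
        if self.N0 is not None:
            return self.N0
        return 1e-6 * singular_clone_count(0.0, self)

    def with_n0(self, N0: float) -> "ControlProblem":
        return replace(self, N0=N0)


# ---------------------------------------------------------------------
# singular arc
# ---------------------------------------------------------------------


def _kn(problem: ControlProblem) -> float:
    return problem.cost.K * problem.model.n


def singular_clone_count(t, problem: ControlProblem):
    """Clone count N*(t) on the singular arc.

    Solves the stationarity condition K n g(t)/N² = u m, giving
    N*(t) = sqrt(K n g(t) / (u m)) — identical to the quasi-static
    optimum.  Closed forms for degenerate/Gamma models are special
    cases of this expression through the closed forms of g.
    """
    g = np.asarray(novelty_intensity(problem.model, t))
    out = np.sqrt(_kn(problem) * g / (problem.cost.u * problem.cost.m))
    return float(out) if out.ndim == 0 else out


def _dlog_g(problem: ControlProblem, t):
    """d log g / dt: closed form for degenerate/Gamma, central finite
    difference otherwise (smooth integrand, step 1e-6·(1+t))."""
    model = problem.model
    tarr = np.asarray(t, dtype=float)
    fb = model.mean_rate
    if model.kind == "degenerate":
        out = np.full_like(tarr, -fb)
    elif model.kind == "gamma":
        a = model.shape
        out = -(a + 1.0) * (fb / a) / (1.0 + fb * tarr / a)
    else:
        dt = 1e-6 * (1.0 + tarr)
        lo = np.maximum(tarr - dt, 0.0)
        hi = tarr + dt
        glo = np.log(novelty_intensity(model, lo))
        ghi = np.log(novelty_intensity(model, hi))
        out = (ghi - glo) / (hi - lo)
    return out


def singular_control(t, problem: ControlProblem, check_bounds: bool = True):
    """Production rate h*(t) = dN*/dt + u N* sustaining the singular arc.

    Degenerate closed form (u − f̄/2)·N*(t); Gamma closed form uses the
    power-law arc.  Values outside [0, h_max] mean the arc cannot be an
    admissible control at that age and raise unless ``check_bounds`` is
    disabled (used when probing feasibility).
    """
    tarr = np.asarray(t, dtype=float)
    nstar = np.asarray(singular_clone_count(tarr, problem))
    u = problem.cost.u
    # dN*/dt = (1/2) N* dlog g/dt
    h = (u + 0.5 * _dlog_g(problem, tarr)) * nstar
    if check_bounds:
        if np.any(h < -1e-12 * problem.h_max):
            tb = np.atleast_1d(tarr)[np.argmin(np.atleast_1d(h))]
            raise ValueError(f"singular arc infeasible at t={tb:.6g}: required production negative")
        if np.any(h > problem.h_max * (1.0 + 1e-12)):
            tb = np.atleast_1d(tarr)[np.argmax(np.atleast_1d(h))]
            raise ValueError(f"singular arc violates the production cap at t={tb:.6g}")
    out = np.asarray(h)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------
# switch times
# ---------------------------------------------------------------------


def _bang_state(t, problem: ControlProblem, N_start: float, h: float, t_start: float = 0.0):
    """Exact solution of dN/dt = h − uN from (t_start, N_start)."""
    u = problem.cost.u
    e = np.exp(-u * (np.asarray(t, dtype=float) - t_start))
    return (N_start - h / u) * e + h / u


def solve_t1(problem: ControlProblem) -> float:
    """Age at which the max-rate trajectory from N(0)=N0 meets the arc.

    Root of (h_max/u)(1 − e^{-u t}) + N0 e^{-u t} = N*(t), bracketed on
    a 1000-point scan of [0, T] and refined with Brent's method.
    """
    N0 = problem.n0

    def resid(t):
        return _bang_state(t, problem, N0, problem.h_max) - singular_clone_count(t, problem)

    ts = np.linspace(0.0, problem.T, 1001)
    r = resid(ts)
    if r[0] >= 0.0:
        return 0.0
    idx = np.nonzero((r[:-1] < 0.0) & (r[1:] >= 0.0))[0]
    if len(idx) == 0:
        raise ValueError("initial phase does not reach singular arc within [0, T]")
    i = idx[0]
    return float(optimize.brentq(resid, ts[i], ts[i + 1], xtol=1e-14, rtol=8.9e-16))


def _final_phase_costate(t2: float, problem: ControlProblem) -> float:
    """λ(t2) from backward integration of the costate over a final phase
    [t2, T] with h = 0 and N decaying from the arc value N*(t2).

    The linear costate equation integrates to
    λ(t2) = (u m / g(t2)) ∫_{t2}^{T} g(s) e^{u (s − t2)} ds,
    evaluated by adaptive quadrature.
    """
    u, m = problem.cost.u, problem.cost.m
    g2 = novelty_intensity(problem.model, t2)
    val, _ = integrate.quad(
        lambda s: novelty_intensity(problem.model, s) * np.exp(u * (s - t2)),
        t2,
        problem.T,
        epsrel=1e-12,
        limit=200,
    )
    return u * m * val / g2


def solve_t2(problem: ControlProblem) -> float:
    """Onset of the zero-production final phase.

    For a common encounter rate the backward costate integration has the
    closed form T − t2 = log(2 − f̄/u)/(u − f̄) (with removable limit
    1/u at u = f̄), defined only for u > f̄/2.  Other models solve the
    self-consistent condition λ(t2) = m numerically.
    """
    u, m = problem.cost.u, problem.cost.m
    if problem.model.kind == "degenerate":
        fb = problem.model.mean_rate
        if u <= fb / 2.0:
            raise ValueError("final-phase formula undefined for u <= f̄/2")
        if u == fb:
            span = 1.0 / u
        else:
            span = float(np.log1p((u - fb) / u) / (u - fb))
        t2 = problem.T - span
        if t2 < 0.0:
            raise ValueError("horizon too short for a final phase (t2 < 0)")
        return t2

    def resid(t2):
        return _final_phase_costate(t2, problem) - m

    ts = np.linspace(0.0, problem.T, 201)[::-1]  # scan from T downwards
    r_prev, t_prev = resid(ts[0] - 1e-12 * problem.T), ts[0]
    for t in ts[1:]:
        r = resid(t)
        if r_prev <= 0.0 <= r or r_prev >= 0.0 >= r:
            return float(optimize.brentq(resid, t, t_prev, xtol=1e-13))
        r_prev, t_prev = r, t
    raise ValueError("horizon too short for a final phase (no costate crossing)")


def solve_t3(problem: ControlProblem) -> float:
    """Switch age of the two-phase (bang-bang) candidate.

    Self-consistent PMP switching condition λ(t3) = m, where λ comes
    from backward costate integration along the trajectory induced by
    h = h_max on [0, t3), h = 0 after.  If several crossings exist the
    one with the best fitness is returned.
    """
    u, m = problem.cost.u, problem.cost.m
    N0 = problem.n0

    def resid(t3):
        N3 = _bang_state(t3, problem, N0, problem.h_max)
        val, _ = integrate.quad(
            lambda s: novelty_intensity(problem.model, s) * np.exp(u * (s - t3)),
            t3,
            problem.T,
            epsrel=1e-12,
            limit=200,
        )
        return _kn(problem) * val / N3**2 - m

    ts = np.linspace(problem.T * 1e-6, problem.T, 400)
    r = np.array([resid(t) for t in ts])
    roots = []
    for i in np.nonzero(np.sign(r[:-1]) * np.sign(r[1:]) <= 0.0)[0]:
        roots.append(float(optimize.brentq(resid, ts[i], ts[i + 1], xtol=1e-13)))
    if not roots:
        if np.all(r < 0.0):
            warnings.warn("production is never marginally valuable; single-phase h=0 schedule")
            return 0.0
        warnings.warn("costate exceeds m over the whole horizon; single-phase h=h_max schedule")
        return problem.T
    if len(roots) == 1:
        return roots[0]
    phis = [
        schedule_fitness(PhaseSchedule(structure="two_phase", t3=t3), problem) for t3 in roots
    ]
    return roots[int(np.argmax(phis))]


# ---------------------------------------------------------------------
# schedules and trajectories
# ---------------------------------------------------------------------


@dataclass
class PhaseSchedule:
    """Piecewise description of a candidate optimal control.

    ``three_phase``: h_max on [0, t1), the singular rule on [t1, t2),
    zero on [t2, T].  ``two_phase``: h_max on [0, t3), zero after.
    """

    structure: str
    t1: float | None = None
    t2: float | None = None
    t3: float | None = None
    phi: float | None = None

    def __post_init__(self) -> None:
        if self.structure not in ("three_phase", "two_phase"):
            raise ValueError("structure must be 'three_phase' or 'two_phase'")
        if self.structure == "three_phase":
            if self.t1 is None or self.t2 is None:
                raise ValueError("three_phase schedule requires t1 and t2")
            if not (0.0 <= self.t1 <= self.t2):
                raise ValueError("three_phase schedule requires 0 <= t1 <= t2")
        else:
            if self.t3 is None or self.t3 < 0.0:
                raise ValueError("two_phase schedule requires t3 >= 0")

    def segments(self, T: float) -> list[tuple[float, float, str]]:
        if self.structure == "three_phase":
            raw = [(0.0, self.t1, "max"), (self.t1, self.t2, "singular"), (self.t2, T, "off")]
        else:
            raw = [(0.0, self.t3, "max"), (self.t3, T, "off")]
        return [(a, b, kind) for a, b, kind in raw if b > a]

    def control(self, t, problem: ControlProblem):
        """Applied production rate h(t) under this schedule."""
        tarr = np.asarray(t, dtype=float)
        out = np.zeros_like(tarr)
        for a, b, kind in self.segments(problem.T):
            mask = (tarr >= a) & (tarr < b) if b < problem.T else (tarr >= a) & (tarr <= b)
            if kind == "max":
                out[mask] = problem.h_max
            elif kind == "singular":
                out[mask] = singular_control(tarr[mask], problem, check_bounds=False)
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        out = {"structure": self.structure}
        for key in ("t1", "t2", "t3", "phi"):
            val = getattr(self, key)
            if val is not None:
                out[key] = float(val)
        return out

    @classmethod
    def from_dict(cls, mapping: dict) -> "PhaseSchedule":
        return cls(**mapping)


def schedule_state(schedule: PhaseSchedule, problem: ControlProblem, t):
    """Exact clone count N(t) under a phase schedule.

    Constant segments use the closed-form linear-ODE solution.  On
    singular segments the singular control *rule* h*(t) is applied from
    the actual entry state: since N*(t) is a particular solution of
    dN/dt = h*(t) − uN, the state is N*(t) + (N_entry − N*(a)) e^{-u(t-a)},
    which collapses onto the arc when the entry state matches it (the
    assembled candidate) and stays well-defined for perturbed switch
    times."""
    u = problem.cost.u
    tarr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(tarr)
    N_entry = problem.n0
    for a, b, kind in schedule.segments(problem.T):
        mask = (tarr >= a) & (tarr <= b)
        if kind == "singular":
            dev = N_entry - float(singular_clone_count(a, problem))
            out[mask] = singular_clone_count(tarr[mask], problem) + dev * np.exp(
                -u * (tarr[mask] - a)
            )
            N_entry = float(singular_clone_count(b, problem)) + dev * np.exp(-u * (b - a))
        else:
            h = problem.h_max if kind == "max" else 0.0
            out[mask] = _bang_state(tarr[mask], problem, N_entry, h, t_start=a)
            N_entry = float(_bang_state(b, problem, N_entry, h, t_start=a))
    res = out.reshape(np.shape(t)) if np.ndim(t) else out[0]
    return res


@dataclass
class Trajectory:
    """Co-sampled state/costate/control arrays plus the fitness value."""

    ages: np.ndarray
    N: np.ndarray
    lam: np.ndarray
    h: np.ndarray
    psi: np.ndarray
    phi: float
    schedule: PhaseSchedule | None = field(default=None, repr=False)


def _segment_nodes(a: float, b: float, n_lin: int, refine_left: bool) -> np.ndarray:
    nodes = np.linspace(a, b, n_lin)
    if refine_left and b > a:
        geo = a + (b - a) * np.geomspace(1e-12, 1.0, 240)
        nodes = np.union1d(nodes, geo)
    return nodes


def _costate_on_grid(grid: np.ndarray, N_of_t, problem: ControlProblem) -> np.ndarray:
    """Backward solution of dλ/dt = uλ − K n g(t)/N(t)², λ(T) = 0, by
    exact per-panel integrating factors with 5-point Gauss–Legendre
    panel integrals (stable for any u·T)."""
    u = problem.cost.u
    kn = _kn(problem)
    x, w = np.polynomial.legendre.leggauss(5)
    a = grid[:-1]
    dt = np.diff(grid)
    # nodes: (panels, 5)
    s = a[:, None] + (x[None, :] + 1.0) * dt[:, None] / 2.0
    Q = kn * np.asarray(novelty_intensity(problem.model, s.ravel())).reshape(s.shape)
    Q /= np.asarray(N_of_t(s.ravel())).reshape(s.shape) ** 2
    # J_p = ∫_a^b e^{u (a - s)} Q(s) ds  (exponent ≤ 0, overflow-safe)
    J = ((np.exp(u * (a[:, None] - s)) * Q) @ w) * dt / 2.0
    lam = np.zeros_like(grid)
    for p in range(len(a) - 1, -1, -1):
        lam[p] = lam[p + 1] * np.exp(-u * dt[p]) + J[p]
    return lam


def integrate_trajectory(
    schedule: PhaseSchedule, problem: ControlProblem, points_per_segment: int = 600
) -> Trajectory:
    """Integrate state and costate along a phase schedule.

    The output grid contains every phase boundary exactly and refines
    geometrically toward t = 0, where the regularized fighting cost
    K n g / N has a sharp (integrable) spike.  The costate is integrated
    backward from λ(T) = 0 on the same grid.
    """
    segs = schedule.segments(problem.T)
    grids = []
    for i, (a, b, kind) in enumerate(segs):
        g = _segment_nodes(a, b, points_per_segment, refine_left=(i == 0))
        grids.append(g)
    grid = np.unique(np.concatenate(grids))
    N = schedule_state(schedule, problem, grid)
    if np.any(N <= 0.0):
        raise ValueError("clone count reached zero while the fighting cost is evaluated")
    h = schedule.control(grid, problem)
    psi = _kn(problem) * np.asarray(novelty_intensity(problem.model, grid)) / N + problem.cost.m * h
    lam = _costate_on_grid(grid, lambda s: schedule_state(schedule, problem, s), problem)
    phi = problem.C - float(np.trapezoid(psi, grid))
    return Trajectory(ages=grid, N=N, lam=lam, h=np.asarray(h), psi=psi, phi=phi, schedule=schedule)


def fitness(trajectory: Trajectory, problem: ControlProblem) -> float:
    """phi = C − ∫ Psi(t) dt by trapezoidal quadrature on the trajectory
    grid (accurate because the grid refines toward the t = 0 spike)."""
    if np.any(trajectory.N <= 0.0):
        raise ValueError("fitness undefined: clone count non-positive on the grid")
    return problem.C - float(np.trapezoid(trajectory.psi, trajectory.ages))


def schedule_fitness(schedule: PhaseSchedule, problem: ControlProblem) -> float:
    """phi of a phase schedule by adaptive quadrature per segment with
    closed-form N(t) — the high-accuracy evaluator used when comparing
    candidate schedules."""
    u, m = problem.cost.u, problem.cost.m
    kn = _kn(problem)
    total = 0.0
    N_entry = problem.n0
    for a, b, kind in schedule.segments(problem.T):
        if kind == "singular":
            dev = N_entry - float(singular_clone_count(a, problem))

            def integrand(s, dev=dev, a=a):
                N = singular_clone_count(s, problem) + dev * np.exp(-u * (s - a))
                return (
                    kn * novelty_intensity(problem.model, s) / N
                    + m * singular_control(s, problem, check_bounds=False)
                )

            N_entry = float(singular_clone_count(b, problem)) + dev * np.exp(-u * (b - a))
        else:
            h = problem.h_max if kind == "max" else 0.0
            Na = N_entry

            def integrand(s, Na=Na, h=h, a=a):
                N = _bang_state(s, problem, Na, h, t_start=a)
                return kn * novelty_intensity(problem.model, s) / N + m * h

            N_entry = float(_bang_state(b, problem, N_entry, h, t_start=a))
        val, _ = integrate.quad(integrand, a, b, epsrel=1e-11, limit=500)
        total += val
    return problem.C - total


def assemble_schedule(problem: ControlProblem, validate: bool = False) -> PhaseSchedule:
    """Construct the PMP candidate schedule.

    Attempts the three-phase structure first: t1 from the max-rate
    crossing, t2 from the backward costate, with the singular rule
    admissible (h* in [0, h_max]) throughout [t1, t2].  If t1 ≥ t2 or
    the arc is inadmissible, falls back to the bang-bang two-phase
    schedule with t3 from the λ(t3) = m switching condition; with
    ``validate`` the t3 root is cross-checked against a 1-D fitness
    scan (must agree to the scan resolution).
    """
    three = None
    try:
        t1 = solve_t1(problem)
        t2 = solve_t2(problem)
        if t1 < t2:
            arc = singular_control(np.linspace(t1, t2, 401), problem, check_bounds=False)
            if np.all(arc >= -1e-12) and np.all(arc <= problem.h_max * (1.0 + 1e-9)):
                three = PhaseSchedule(structure="three_phase", t1=t1, t2=t2)
    except ValueError:
        three = None
    if three is not None:
        three.phi = schedule_fitness(three, problem)
        return three
    t3 = solve_t3(problem)
    sched = PhaseSchedule(structure="two_phase", t3=t3)
    sched.phi = schedule_fitness(sched, problem)
    if validate:
        from .oracle import two_phase_scan

        scan = two_phase_scan(problem, grid_size=400)
        step = problem.T / 399
        if abs(scan["best_t3"] - t3) > step:
            warnings.warn(
                f"two-phase switch root t3={t3:.6g} differs from fitness-scan "
                f"argmax {scan['best_t3']:.6g} by more than one grid step"
            )
    return sched


# ---------------------------------------------------------------------
# PMP certificate
# ---------------------------------------------------------------------


def _switching_second_derivative(t: float, h: float, problem: ControlProblem) -> float:
    """d²/dt² of the switching function σ = λ − m, evaluated on the
    singular arc (λ = m, N = N*) as a function of the applied control h."""
    u, m = problem.cost.u, problem.cost.m
    kn = _kn(problem)
    N = singular_clone_count(t, problem)
    g = novelty_intensity(problem.model, t)
    gp = g * float(np.asarray(_dlog_g(problem, t)))
    lam_dot = u * m - kn * g / N**2  # = 0 on the arc
    Ndot = h - u * N
    return u * lam_dot - kn * (gp / N**2 - 2.0 * g * Ndot / N**3)


def pmp_certificate(
    trajectory: Trajectory,
    problem: ControlProblem,
    singular_rtol: float = 1e-4,
    sign_slack: float = 1e-6,
) -> dict:
    """Numerically certify the maximum-principle conditions.

    Checks (i) sign consistency of the costate against the applied
    control — λ > m wherever h = h_max, λ < m wherever h = 0, λ = m
    (within ``singular_rtol`` relative) on singular segments; (ii) the
    terminal condition λ(T) = 0; (iii) the generalized Legendre–Clebsch
    sign condition along the singular segment, via a finite-difference
    estimate of ∂/∂h of the second time-derivative of the switching
    function (must be ≥ 0 for a maximizing singular arc).  Violations
    are reported, never raised.
    """
    m = problem.cost.m
    t, lam, h = trajectory.ages, trajectory.lam, trajectory.h
    hmax = problem.h_max
    slack = sign_slack * m

    on_max = h >= hmax * (1.0 - 1e-9)
    on_off = h <= hmax * 1e-12
    on_sing = ~(on_max | on_off)

    bang_viol = float(np.max((m - lam[on_max]).clip(min=0.0), initial=0.0))
    off_viol = float(np.max((lam[on_off] - m).clip(min=0.0), initial=0.0))
    sing_dev = float(np.max(np.abs(lam[on_sing] - m) / m, initial=0.0))

    terminal_value = float(lam[-1])
    terminal_ok = abs(terminal_value) <= 1e-8 * max(1.0, float(np.max(np.abs(lam))))

    glc_min = np.inf
    if trajectory.schedule is not None and trajectory.schedule.structure == "three_phase":
        t1, t2 = trajectory.schedule.t1, trajectory.schedule.t2
        delta = 1e-6 * max(1.0, hmax)
        for ts in np.linspace(t1 + 1e-9, t2 - 1e-9, 21):
            hs = singular_control(ts, problem, check_bounds=False)
            hi = _switching_second_derivative(ts, hs + delta, problem)
            lo = _switching_second_derivative(ts, hs - delta, problem)
            glc_min = min(glc_min, (hi - lo) / (2.0 * delta))
    glc_ok = (not np.isfinite(glc_min)) or glc_min >= -1e-10

    sign_ok = bang_viol <= slack and off_viol <= slack and sing_dev <= singular_rtol
    return {
        "sign_ok": bool(sign_ok),
        "max_bang_violation": bang_viol,
        "max_off_violation": off_viol,
        "max_singular_deviation": sing_dev,
        "terminal_ok": bool(terminal_ok),
        "terminal_value": terminal_value,
        "legendre_clebsch_ok": bool(glc_ok),
        "legendre_clebsch_min": float(glc_min) if np.isfinite(glc_min) else None,
        "ok": bool(sign_ok and terminal_ok and glc_ok),
    }
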