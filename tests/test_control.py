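"""Maximum-principle construction of the dynamic production schedule."""

import warnings

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from thymopt import (
    ControlProblem,
    CostParams,
    EncounterModel,
    PhaseSchedule,
    assemble_schedule,
    clone_count,
    fitness,
    integrate_trajectory,
    novelty_intensity,
    optimal_production,
    pmp_certificate,
    schedule_fitness,
    schedule_state,
    singular_clone_count,
    singular_control,
    solve_t1,
    solve_t2,
    solve_t3,
)


def make_problem(fbar=0.275, u=1.0, K=0.001, m=1.0, n=1000, T=10.0, h_max=3.0, **kw):
    return ControlProblem(
        cost=CostParams(K=K, m=m, u=u),
        model=EncounterModel.degenerate(fbar, n),
        T=T,
        h_max=h_max,
        **kw,
    )


class TestSingularArc:
    def test_arc_equals_quasistatic_clone_count(self, three_phase_problem):
        p = three_phase_problem
        ts = np.linspace(0.0, 10.0, 41)
        assert np.allclose(
            singular_clone_count(ts, p),
            clone_count(ts, p.cost, p.model),
            rtol=1e-12,
        )

    @pytest.mark.parametrize(
        "model",
        [
            EncounterModel.degenerate(0.275, 1000),
            EncounterModel.gamma(shape=2.0, rate_param=10.0, n=1000),
            EncounterModel.lognormal(log_mean=-2.0, log_var=0.3, n=1000),
        ],
        ids=lambda m: m.kind,
    )
    def test_stationarity_residual_vanishes(self, model):
        p = ControlProblem(cost=CostParams(K=0.001, m=1.0, u=1.0), model=model,
                           T=10.0, h_max=3.0)
        for t in (0.0, 2.5, 8.0):
            N = singular_clone_count(t, p)
            resid = -p.cost.K * model.n * novelty_intensity(model, t) / N**2 \
                + p.cost.u * p.cost.m
            assert abs(resid) < 1e-12 * p.cost.u * p.cost.m * 10

    def test_gamma_large_shape_limit_recovers_degenerate(self):
        deg = make_problem(fbar=0.1)
        gam = ControlProblem(
            cost=deg.cost,
            model=EncounterModel.gamma(shape=1e4, rate_param=1e5, n=1000),
            T=10.0, h_max=3.0,
        )
        ts = np.linspace(0.0, 10.0, 21)
        assert np.allclose(
            singular_clone_count(ts, gam), singular_clone_count(ts, deg), rtol=1e-2
        )
        assert np.allclose(
            singular_control(ts, gam, check_bounds=False),
            singular_control(ts, deg, check_bounds=False),
            rtol=1e-2,
        )


class TestSingularControl:
    def test_smaller_than_quasistatic_production(self, three_phase_problem):
        p = three_phase_problem
        ts = np.linspace(0.0, 10.0, 41)
        assert np.all(
            np.asarray(singular_control(ts, p, check_bounds=False))
            < np.asarray(optimal_production(ts, p.cost, p.model))
        )

    def test_vanishes_when_decay_is_half_mean_rate(self):
        p = make_problem(fbar=0.275, u=0.1375)
        assert np.allclose(
            singular_control(np.linspace(0, 10, 5), p, check_bounds=False), 0.0, atol=1e-15
        )

    def test_matches_finite_difference_of_arc(self, three_phase_problem):
        p = three_phase_problem
        dt = 1e-6
        for t in (0.5, 3.0, 8.0):
            dN = (singular_clone_count(t + dt, p) - singular_clone_count(t - dt, p)) / (2 * dt)
            expected = dN + p.cost.u * singular_clone_count(t, p)
            assert singular_control(t, p) == pytest.approx(expected, rel=1e-6)

    def test_infeasible_arc_raises(self):
        p = make_problem(fbar=0.275, u=0.1)  # u < f̄/2: required production negative
        with pytest.raises(ValueError, match="infeasible"):
            singular_control(5.0, p)
        p2 = make_problem(h_max=0.01)  # arc needs more than the cap
        with pytest.raises(ValueError, match="cap"):
            singular_control(0.0, p2)


class TestSwitchTimes:
    def test_t1_defining_equation(self, three_phase_problem):
        p = three_phase_problem
        t1 = solve_t1(p)
        lhs = (p.h_max / p.cost.u) * (1.0 - np.exp(-p.cost.u * t1))
        rhs = singular_clone_count(t1, p)
        assert lhs == pytest.approx(rhs, rel=1e-10, abs=p.n0 * 1.01)

    def test_t1_matches_forward_integration_crossing(self, three_phase_problem):
        p = three_phase_problem

        def event(t, y):
            return y[0] - singular_clone_count(t, p)

        event.direction = 1.0
        sol = solve_ivp(
            lambda t, y: [p.h_max - p.cost.u * y[0]],
            (0.0, p.T),
            [p.n0],
            events=event,
            rtol=1e-12,
            atol=1e-14,
        )
        assert abs(solve_t1(p) - sol.t_events[0][0]) < 1e-8

    def test_t1_vanishes_for_huge_cap(self):
        assert solve_t1(make_problem(h_max=1e9)) < 1e-8

    def test_t1_unreachable_arc_reported(self, two_phase_problem):
        with pytest.raises(ValueError, match="does not reach"):
            solve_t1(two_phase_problem)

    def test_t2_closed_form_value(self):
        p = make_problem(fbar=0.5, u=1.0, T=10.0)
        assert p.T - solve_t2(p) == pytest.approx(2.0 * np.log(1.5), rel=1e-12)

    def test_t2_matches_backward_costate_integration(self):
        p = make_problem(fbar=0.5, u=1.0, T=10.0)
        t2 = solve_t2(p)
        N2 = singular_clone_count(t2, p)
        kn = p.cost.K * p.model.n

        def rhs(t, y):
            N = N2 * np.exp(-p.cost.u * (t - t2))
            return [p.cost.u * y[0] - kn * novelty_intensity(p.model, t) / N**2]

        sol = solve_ivp(rhs, (p.T, t2), [0.0], rtol=1e-12, atol=1e-14)
        assert sol.y[0, -1] == pytest.approx(p.cost.m, rel=1e-8)

    def test_t2_removable_singularity_at_u_equals_fbar(self):
        p = make_problem(fbar=1.0, u=1.0, T=10.0)
        assert p.T - solve_t2(p) == pytest.approx(1.0, rel=1e-12)
        p_near = make_problem(fbar=1.0, u=1.0 + 1e-8, T=10.0)
        assert p.T - solve_t2(p_near) == pytest.approx(1.0, abs=1e-6)

    def test_final_phase_lengthens_as_u_decreases(self):
        spans = [
            make_problem(fbar=0.275, u=u).T - solve_t2(make_problem(fbar=0.275, u=u))
            for u in (2.0, 1.0, 0.5, 0.2)
        ]
        assert np.all(np.diff(spans) > 0)

    def test_t2_undefined_for_slow_decay(self):
        with pytest.raises(ValueError, match="undefined"):
            solve_t2(make_problem(fbar=0.275, u=0.1))

    def test_t2_numeric_gamma_agrees_with_backward_integration(self):
        p = ControlProblem(
            cost=CostParams(K=0.001, m=1.0, u=1.0),
            model=EncounterModel.gamma(shape=5.0, rate_param=5.0 / 0.275, n=1000),
            T=10.0, h_max=3.0,
        )
        t2 = solve_t2(p)
        N2 = singular_clone_count(t2, p)
        kn = p.cost.K * p.model.n

        def rhs(t, y):
            N = N2 * np.exp(-p.cost.u * (t - t2))
            return [p.cost.u * y[0] - kn * novelty_intensity(p.model, t) / N**2]

        sol = solve_ivp(rhs, (p.T, t2), [0.0], rtol=1e-12, atol=1e-14)
        assert sol.y[0, -1] == pytest.approx(p.cost.m, rel=1e-7)


class TestAssembleSchedule:
    def test_three_phase_structure(self, three_phase_problem):
        sched = assemble_schedule(three_phase_problem)
        assert sched.structure == "three_phase"
        assert 0.0 < sched.t1 < sched.t2 < three_phase_problem.T

    def test_two_phase_structure_under_tight_cap(self, two_phase_problem):
        sched = assemble_schedule(two_phase_problem, validate=True)
        assert sched.structure == "two_phase"
        assert 0.0 < sched.t3 < two_phase_problem.T

    def test_no_singular_segment_for_slow_decay(self):
        # u <= f̄/2: production is concentrated early, no singular arc
        p = make_problem(fbar=0.275, u=0.12, h_max=3.0)
        sched = assemble_schedule(p)
        assert sched.structure == "two_phase"

    def test_t3_root_agrees_with_fitness_scan(self, two_phase_problem):
        from thymopt import two_phase_scan

        t3 = solve_t3(two_phase_problem)
        scan = two_phase_scan(two_phase_problem, grid_size=400)
        step = two_phase_problem.T / 399
        assert abs(scan["best_t3"] - t3) <= step + 1e-12


class TestTrajectory:
    def test_constant_control_matches_linear_ode_solution(self, three_phase_problem):
        p = three_phase_problem.with_n0(0.05)
        sched = PhaseSchedule(structure="two_phase", t3=p.T)  # h = h_max throughout
        traj = integrate_trajectory(sched, p)
        u, h = p.cost.u, p.h_max
        expected = 0.05 * np.exp(-u * traj.ages) + (h / u) * (1 - np.exp(-u * traj.ages))
        assert np.allclose(traj.N, expected, rtol=1e-12)

    def test_costate_sticks_to_m_on_singular_segment(self, three_phase_problem):
        p = three_phase_problem
        sched = assemble_schedule(p)
        traj = integrate_trajectory(sched, p)
        mid = (traj.ages > sched.t1 + 1e-9) & (traj.ages < sched.t2 - 1e-9)
        assert np.max(np.abs(traj.lam[mid] - p.cost.m) / p.cost.m) < 1e-4

    def test_zero_control_decays_from_n0(self, three_phase_problem):
        p = three_phase_problem.with_n0(0.3)
        sched = PhaseSchedule(structure="two_phase", t3=0.0)
        traj = integrate_trajectory(sched, p)
        assert np.allclose(traj.N, 0.3 * np.exp(-p.cost.u * traj.ages), rtol=1e-12)
        assert np.allclose(traj.h, 0.0)
        fight = p.cost.K * p.model.n * np.asarray(
            novelty_intensity(p.model, traj.ages)
        ) / traj.N
        assert np.allclose(traj.psi, fight, rtol=1e-12)

    def test_state_continuous_at_switches(self, three_phase_problem):
        sched = assemble_schedule(three_phase_problem)
        eps = 1e-9
        for s in (sched.t1, sched.t2):
            left = schedule_state(sched, three_phase_problem, s - eps)
            right = schedule_state(sched, three_phase_problem, s + eps)
            assert left == pytest.approx(right, rel=1e-6)

    def test_terminal_costate_zero(self, three_phase_problem):
        traj = integrate_trajectory(assemble_schedule(three_phase_problem), three_phase_problem)
        assert abs(traj.lam[-1]) < 1e-10


class TestFitness:
    def test_no_production_closed_form(self):
        p = make_problem(fbar=0.5, u=1.0, T=5.0).with_n0(0.2)
        sched = PhaseSchedule(structure="two_phase", t3=0.0)
        kn = p.cost.K * p.model.n
        fb, u = 0.5, 1.0
        closed = p.C - (kn * fb / 0.2) * (np.exp((u - fb) * p.T) - 1.0) / (u - fb)
        assert schedule_fitness(sched, p) == pytest.approx(closed, rel=1e-9)
        traj = integrate_trajectory(sched, p)
        # grid-trapezoid evaluator agrees at its discretization accuracy
        assert fitness(traj, p) == pytest.approx(closed, rel=1e-4)

    def test_additive_baseline_shift(self, three_phase_problem):
        sched = assemble_schedule(three_phase_problem)
        base = schedule_fitness(sched, three_phase_problem)
        from dataclasses import replace

        shifted = replace(three_phase_problem, C=2.5)
        assert schedule_fitness(sched, shifted) == pytest.approx(base + 2.5, rel=1e-12)

    def test_candidate_beats_perturbed_switch_times(self, three_phase_problem):
        p = three_phase_problem
        sched = assemble_schedule(p)
        phi0 = schedule_fitness(sched, p)
        for factor in (0.95, 1.05):
            pert = PhaseSchedule(structure="three_phase", t1=sched.t1 * factor, t2=sched.t2)
            assert schedule_fitness(pert, p) <= phi0 + 1e-12
            pert2 = PhaseSchedule(structure="three_phase", t1=sched.t1, t2=sched.t2 * factor)
            assert schedule_fitness(pert2, p) <= phi0 + 1e-12

    def test_candidate_dominates_random_piecewise_schedules(self, three_phase_problem, rng):
        from thymopt import GriddedControl, gridded_fitness

        p = three_phase_problem
        phi0 = schedule_fitness(assemble_schedule(p), p)
        bp = np.linspace(0.0, p.T, 21)
        for _ in range(100):
            levels = rng.uniform(0.0, p.h_max, size=20)
            phi = gridded_fitness(GriddedControl(bp, levels), p)
            assert phi <= phi0 + 1e-9 * abs(phi0)


class TestCertificate:
    def test_valid_three_phase_certificate_passes(self, three_phase_problem):
        traj = integrate_trajectory(assemble_schedule(three_phase_problem), three_phase_problem)
        cert = pmp_certificate(traj, three_phase_problem)
        assert cert["ok"]
        assert cert["legendre_clebsch_min"] > 0  # maximizing singular arc

    def test_swapped_switches_flagged(self, three_phase_problem):
        p = three_phase_problem
        sched = assemble_schedule(p)
        wrong = PhaseSchedule(structure="two_phase", t3=sched.t2)  # produce through the arc
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = integrate_trajectory(wrong, p)
        cert = pmp_certificate(traj, p)
        assert not cert["sign_ok"]

    def test_always_max_production_flagged(self, three_phase_problem):
        p = three_phase_problem
        traj = integrate_trajectory(PhaseSchedule(structure="two_phase", t3=p.T), p)
        cert = pmp_certificate(traj, p)
        assert not cert["sign_ok"]
        assert cert["max_bang_violation"] > 0  # λ < m while h = h_max near T
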