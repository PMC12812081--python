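"""When the singular phase disappears: the two-phase schedule.

With a tight production cap (h_max = 0.1) the max-rate trajectory can
never reach the singular arc, so the optimum is bang-bang: produce at
the cap until t3, then stop.  The switch is found from the condition
that the costate crosses the marginal production cost m exactly at t3,
and cross-checked against a brute-force fitness scan.
"""

from thymopt import assemble_schedule, resolve_scenario, two_phase_scan

problem = resolve_scenario("fig4b", {"u": 1.0}).control_problem()
schedule = assemble_schedule(problem)
scan = two_phase_scan(problem, grid_size=400)

print("structure:", schedule.structure)
print(f"switch age t3 (costate crossing) = {schedule.t3:.4f}")
print(f"switch age t3 (fitness scan)     = {scan['best_t3']:.4f}")
print(f"fitness phi = {schedule.phi:.5f}")
print()
print("The scan maximum and the root of lambda(t3) = m agree to the scan")
print("resolution: the switching condition is the optimality condition.")
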