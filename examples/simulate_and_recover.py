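"""Recover known repair parameters from a stochastic population simulation.

Simulates 20 genomic regions as independent cells x dipyrimidine-positions
grids (Bernoulli lesions, Bernoulli(theta) repair competence, Weibull(m, tau)
repair times), converts the remaining-lesion counts at 0/20/60/120 min into
rectified repair fractions, fits every region, and prints the median
absolute/relative errors of the recovered parameters.
"""

import numpy as np

from repairkinetics import SimulationConfig, fit
from repairkinetics.simulate import random_region_specs, simulate_time_courses

rng = np.random.default_rng(42)
specs = random_region_specs(20, rng)  # m ~ U[0.8,3], tau ~ U[30,150] min
cfg = SimulationConfig(regions=specs, n_cells=2000, n_positions=200, seed=42)

courses, _ = simulate_time_courses(cfg)
truth = {s.region_id: s for s in specs}

err_m, err_tau, err_theta = [], [], []
for rid, course in courses.items():
    p = fit(course, theta_min=0.4)
    s = truth[rid]
    err_m.append(abs(p.m - s.m))
    err_tau.append(abs(p.tau - s.tau) / s.tau)
    err_theta.append(abs(p.theta - s.theta))

print(f"{len(courses)} regions, 2000 cells x 200 positions each")
print(f"median |m_hat - m|        = {np.median(err_m):.3f}")
print(f"median |tau_hat - tau|/tau = {np.median(err_tau):.3f}")
print(f"median |theta_hat - theta| = {np.median(err_theta):.3f}")
print()
print("three time points suffice to recover all three parameters because")
print("the theta grid search reduces each candidate fit to a 2-parameter")
print("line in double-log space.")
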