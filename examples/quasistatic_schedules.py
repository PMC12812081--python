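"""Exponential vs power-law thymic involution in the rapid-turnover limit.

Builds two encounter-rate models with the same mean rate — one where
every pathogen strain is met equally often, one with exponentially
distributed (highly variable) rates — and prints the optimal naive
T cell production rate h(t) at a few ages.
"""

import numpy as np

from thymopt import CostParams, EncounterModel, lifetime_production, optimal_production

params = CostParams(K=10.0, m=1.0, u=1.0)  # K·u·n/m = 1e4 with n = 1000
common = EncounterModel.degenerate(0.1, 1000)
variable = EncounterModel.gamma(shape=1.0, rate_param=10.0, n=1000)  # same mean 0.1

print("age   h(t) common-rate   h(t) variable-rate")
for t in (0.0, 10.0, 20.0, 40.0):
    print(f"{t:4.0f}   {optimal_production(t, params, common):14.3f}   "
          f"{optimal_production(t, params, variable):16.3f}")

print()
print("Both schedules start at sqrt(K u n f̄ / m) =",
      f"{optimal_production(0.0, params, common):.3f},",
      "but the common-rate optimum halves every",
      f"{2 * np.log(2) / 0.1:.1f} age units (exponential decay)",
      "while rate heterogeneity slows the late decline to a power law")
print("Lifetime production, common rate:",
      f"{lifetime_production(params, common, np.inf):.1f} clones",
      "(closed form 2·sqrt(Kun/(m f̄)))")
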