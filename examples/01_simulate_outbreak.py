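"""Simulate one measles outbreak in a synthetic town.

Builds a ~1000-agent town, measures the contact rate on a disease-free
rehearsal, derives the per-contact infection probability from R0 = 12, and
runs a single outbreak with 50% vaccination and no isolation.
"""

import numpy as np

from epicalib import DiseaseConfig, TownConfig, simulate_outbreak

town = TownConfig().scaled(1000 / 9547)
disease = DiseaseConfig(vaccination_rate=0.5, isolation_rate=0.0)

trace = simulate_outbreak(town, disease, seed=1, scenario="S4_I0_V50")

print(f"contact-derived infection probability p = {trace.meta['p']:.4f}")
print(f"outbreak length: {trace.n_days} days")
print(f"final size (cases beyond the index case): {trace.final_size}")
print(f"peak daily incidence: {trace.incidence.max()} on day {trace.incidence.argmax() + 1}")
print(f"agents never infected: {trace.S[-1]} of {trace.n_agents}")

# The trace is the 'ground truth' an SVEIR model is later calibrated to:
# daily counts of susceptible, exposed, infectious, recovered agents and
# new infectious cases per day.
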