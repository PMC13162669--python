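"""Is the interaction score an artifact of the 25 µm radius choice?

Recomputes the score at 15, 30 and 50 µm over a 40-region cohort spanning
the full clustering range and reports the Spearman rank agreement with the
25 µm reference.
"""

import numpy as np

from immunoprox import SimulationConfig, radius_sensitivity, simulate_region

rng = np.random.default_rng(2)
regions = []
for k, pi in enumerate([0.0, 0.25, 0.5, 0.75, 1.0] * 8):
    cfg = SimulationConfig(attraction_pi=pi)
    regions.append(simulate_region(cfg, f"P{k}", f"R{k}", rng))

res = radius_sensitivity(regions)
for r in (15.0, 30.0, 50.0):
    print(f"iv at {r:4.0f} µm vs 25 µm:  Spearman rho = {res.rho[r]:.3f}"
          f"  (p = {res.p_value[r]:.2e})")
print("\nHigh rank correlation means region ranking — hence any median split —")
print("is stable across plausible interaction radii.")
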