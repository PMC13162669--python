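"""ROC discrimination of 1-year progression-free survival with bootstrap
optimism correction, plus the Youden operating point.

Patients censored before the 1-year horizon have unknown status and are
excluded from the binary label.
"""

import numpy as np
import pandas as pd

from immunoprox import (
    SimulationConfig,
    binary_outcome_at_horizon,
    bootstrap_optimism_auc,
    bootstrap_optimism_cindex,
    roc_auc,
    simulate_survival,
    youden_cutoff,
)

rng = np.random.default_rng(4)
cfg = SimulationConfig(beta_iv=-0.15)
n = 150
iv = rng.uniform(5, 55, n)
time, event = simulate_survival(iv, cfg, rng)

labels, usable = binary_outcome_at_horizon(time, event, horizon=365.0)
print(f"{int(usable.sum())} of {n} patients usable for the 1-year label "
      f"({int((~usable).sum())} censored before 1 year, excluded)")

roc = roc_auc(iv[usable], labels[usable])
cut = youden_cutoff(roc)
print(f"apparent AUC = {roc.auc:.3f}")
print(f"Youden cutoff: iv >= {cut.threshold:.1f}  "
      f"(J = {cut.youden_j:.2f}, sens = {cut.sensitivity:.2f}, "
      f"spec = {cut.specificity:.2f})")

auc_val = bootstrap_optimism_auc(iv[usable], labels[usable],
                                 n_boot=1000, seed=4)
c_val = bootstrap_optimism_cindex(time, event, pd.DataFrame({"iv": iv}),
                                  n_boot=1000, seed=4)
print(f"\nbootstrap (1000 iterations):")
print(f"  AUC      apparent {auc_val.apparent:.3f} -> corrected "
      f"{auc_val.corrected:.3f} (optimism {auc_val.optimism:+.4f})")
print(f"  C-index  apparent {c_val.apparent:.3f} -> corrected "
      f"{c_val.corrected:.3f} (optimism {c_val.optimism:+.4f})")
print("\nA one-covariate model barely overfits, so the optimism is tiny;")
print("richer models show a real apparent -> corrected drop.")
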