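# immunoprox

Spatial immune-proximity analysis for multiplexed immunohistochemistry
(mIHC) cell maps of tumor biopsies, built around the question: *does the
spatial interaction between PD-L1(+) tumor-associated macrophages (TAMs)
and CD8(+) T cells — rather than the abundance of either population —
predict outcome under immunotherapy?*

It is written for translational researchers working with inForm/phenoptr-
style cell-segmentation exports (one row per cell: centroid in µm plus
marker positivity flags for CD8, CD68, CD163, PD-L1, GZMB, TIM3) and
patient-level clinical tables from hepatocellular-carcinoma cohorts treated
with atezolizumab plus bevacizumab, but nothing in the code is specific to
that disease setting.

## The score and the analysis chain

For one imaged region, with `n_CD8` CD8(+) T cells, `n_TAM` PD-L1(+) TAMs
(macrophage gate: CD68 and/or CD163, plus PD-L1), and
`n_within(r)` the number of distinct CD8 cells whose nearest PD-L1(+) TAM
lies within radius `r` (25 µm by default — one to two cell diameters),
the **interaction variable** is

```
iv(r) = 100 · n_within(r) / (n_CD8 + n_TAM)
```

The normalization makes the score a relative frequency of interacting
cells, decoupled from raw density. Around it the package provides:

- nearest-neighbor distance profiles (CD8 counts in 5 µm bins of distance
  to the nearest TAM, cumulative fractions, median TAM→CD8 distance);
- patient-level aggregation over multiple biopsy cores (pooled counts or
  mean of per-core scores) and radius-sensitivity analysis at 15/30/50 µm
  with Spearman rank agreement against the 25 µm reference;
- median dichotomization, Kaplan–Meier curves, two-group log-rank tests,
  and Cox proportional-hazards screening (univariate gate at p < 0.05, then
  one multivariate model) with Efron or Breslow tie handling;
- ROC discrimination of 1-year progression-free survival, Youden-index
  cutoff selection, and Harrell-style bootstrap optimism correction of the
  AUC and the concordance index (1000 iterations by default);
- the ALBI liver-function score and modified ALBI grade;
- a synthetic-data generator (Thomas-like parent–offspring point process
  plus an exponential proportional-hazards outcome model) that produces
  cohorts with known spatial and survival ground truth for every stage.

## Worked example

```python
import numpy as np
from immunoprox import (SimulationConfig, simulate_region,
                        interaction_variable, distance_profile)

rng = np.random.default_rng(1)
for label, pi in [("dispersed", 0.0), ("clustered", 1.0)]:
    cfg = SimulationConfig(attraction_pi=pi, sigma=10.0)
    region = simulate_region(cfg, "P1", f"R_{label}", rng)
    res = interaction_variable(region)
    prof = distance_profile(region)
    print(label, res.n_tam, res.n_cd8, res.n_cd8_within,
          round(res.iv, 1), round(prof.median_nn_distance, 1))
```

prints

```
dispersed 72 137 39 18.7 27.2
clustered 62 137 134 67.3 7.3
```

— two regions with near-identical cell counts, but in the clustered one
134 of 137 CD8 cells sit within 25 µm of a PD-L1(+) TAM (iv 67.3 vs 18.7)
and the median TAM→CD8 distance collapses from 27 µm to 7 µm. The
`examples/` directory walks through each capability the same way
(cohort simulation, scoring, radius sensitivity, survival screening,
internal validation, ALBI grading); each script prints the numbers it
computes and a line on what they mean. The thin `immunoprox` CLI
(`simulate`, `score`, `survive`, `validate`, `albi`) exposes the same
pipeline for shell use.

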