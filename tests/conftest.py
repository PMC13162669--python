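from __future__ import annotations

import numpy as np
import pytest

from immunoprox import (
    Cell,
    Phenotype,
    RegionCellMap,
    assign_phenotypes,
)


def make_region(
    tam_xy=(), cd8_xy=(), other_xy=(), width=200.0, height=200.0,
    region_id="R1", patient_id="P1",
):
    """Hand-placed region with phenotypes derived from consistent flags."""
    cells = []
    k = 0
    for x, y in tam_xy:
        cells.append(Cell(f"c{k}", x, y, frozenset({"CD68", "PDL1"})))
        k += 1
    for x, y in cd8_xy:
        cells.append(Cell(f"c{k}", x, y, frozenset({"CD8"})))
        k += 1
    for x, y in other_xy:
        cells.append(Cell(f"c{k}", x, y, frozenset()))
        k += 1
    region = RegionCellMap(region_id=region_id, patient_id=patient_id,
                           width=width, height=height, cells=cells)
    return assign_phenotypes(region)


def random_region(rng, n_tam, n_cd8, n_other=0, width=200.0, height=200.0,
                  region_id="R1", patient_id="P1"):
    """Uniform random region with given phenotype counts."""
    def pts(n):
        return rng.uniform((0, 0), (width, height), size=(n, 2))
    return make_region(
        tam_xy=pts(n_tam), cd8_xy=pts(n_cd8), other_xy=pts(n_other),
        width=width, height=height, region_id=region_id, patient_id=patient_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def brute_force_nn(src_xy: np.ndarray, tgt_xy: np.ndarray) -> np.ndarray:
    """O(n^2) nearest-neighbor distances; NaN when no target exists."""
    src_xy = np.asarray(src_xy, float).reshape(-1, 2)
    tgt_xy = np.asarray(tgt_xy, float).reshape(-1, 2)
    if src_xy.shape[0] == 0:
        return np.empty(0)
    if tgt_xy.shape[0] == 0:
        return np.full(src_xy.shape[0], np.nan)
    out = np.empty(src_xy.shape[0])
    for i, (x, y) in enumerate(src_xy):
        d2 = (tgt_xy[:, 0] - x) ** 2 + (tgt_xy[:, 1] - y) ** 2
        out[i] = np.sqrt(d2.min())
    return out


def mann_whitney_auc(scores, labels) -> float:
    """Brute-force concordant-pair fraction with half-credit for ties."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    total = conc = 0.0
    for a in pos:
        for b in neg:
            total += 1
            if a > b:
                conc += 1
            elif a == b:
                conc += 0.5
    return conc / total


def brute_force_count_within(cd8_xy, tam_xy, radius) -> int:
    """Distinct CD8 cells with squared distance <= radius^2 of any TAM."""
    cd8_xy = np.asarray(cd8_xy, float).reshape(-1, 2)
    tam_xy = np.asarray(tam_xy, float).reshape(-1, 2)
    if cd8_xy.shape[0] == 0 or tam_xy.shape[0] == 0:
        return 0
    r2 = radius * radius
    n = 0
    for x, y in cd8_xy:
        d2 = (tam_xy[:, 0] - x) ** 2 + (tam_xy[:, 1] - y) ** 2
        if (d2 <= r2).any():
            n += 1
    return n
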