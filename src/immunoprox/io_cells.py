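"""Cell-segmentation tables, marker flags, and composite phenotype calls.

The data model mirrors the per-cell exports of multiplex-IHC analysis
software (inForm / phenoptr style): one row per segmented cell carrying the
centroid in micrometres and boolean positivity flags for a six-marker panel
(CD8, CD68, CD163, PD-L1, GZMB, TIM3).  Cells belong to rectangular imaged
regions (biopsy cores), several of which may come from one patient.

Composite phenotypes are assigned by an explicit, ordered rule:

* ``PDL1_TAM`` — a tumor-associated macrophage, (CD68 or CD163) positive,
  that also expresses PD-L1;
* ``CD8_T``   — a CD8(+) T cell;
* ``OTHER``   — everything else.

A cell matching several predicates takes the first label in the precedence
list, so classification is total and deterministic for every one of the 64
possible flag combinations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Marker panel, in the column order used by cell tables.
MARKERS: tuple[str, ...] = ("CD8", "CD68", "CD163", "PDL1", "GZMB", "TIM3")

_TRUTHY = {"1", "true", "t", "yes", "y", "pos", "positive"}
_FALSY = {"0", "false", "f", "no", "n", "neg", "negative", ""}

_CELL_COLUMNS = ["patient_id", "region_id", "cell_id", "x_um", "y_um", *MARKERS]

#: Expected columns of a patient-level clinical table.
PATIENT_COLUMNS = [
    "patient_id", "arm", "age", "sex", "etiology", "afp", "dcp",
    "max_tumor_size_cm", "tumor_number", "vascular_invasion",
    "extrahepatic_metastasis", "bclc", "child_pugh", "albumin_g_dl",
    "bilirubin_mg_dl", "size_change_pct", "pfs_days", "pfs_event",
    "os_days", "os_event",
]


class Phenotype(str, Enum):
    PDL1_TAM = "PDL1_TAM"
    CD8_T = "CD8_T"
    OTHER = "OTHER"


class CellTableFormatError(ValueError):
    """A required column is missing or a table is structurally invalid."""


class CellTableParseError(ValueError):
    """A row-level value could not be parsed; carries the row index."""


class RegionBoundsError(ValueError):
    """A cell coordinate lies outside its region's declared rectangle."""


class RuleCoverageError(ValueError):
    """A phenotype rule failed to assign a label to some flag combination."""


@dataclass(frozen=True)
class Cell:
    """One segmented cell: centroid in µm plus marker positivity flags."""

    cell_id: str
    x: float
    y: float
    markers: frozenset[str]
    phenotype: Phenotype | None = None

    def __post_init__(self) -> None:
        unknown = self.markers - set(MARKERS)
        if unknown:
            raise ValueError(f"unknown markers: {sorted(unknown)}")
        if not (self.x >= 0 and self.y >= 0):
            raise ValueError(f"cell {self.cell_id}: negative coordinate")


@dataclass
class RegionCellMap:
    """All cells of one imaged rectangular region (biopsy core)."""

    region_id: str
    patient_id: str
    width: float
    height: float
    cells: list[Cell] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("region width and height must be positive")
        for c in self.cells:
            if not (0 <= c.x <= self.width and 0 <= c.y <= self.height):
                raise RegionBoundsError(
                    f"cell {c.cell_id} at ({c.x}, {c.y}) outside region "
                    f"{self.region_id} ({self.width} x {self.height} um)"
                )

    def __len__(self) -> int:
        return len(self.cells)

    def coordinates(self, phenotype: Phenotype | None = None) -> np.ndarray:
        """(n, 2) array of centroids, optionally restricted to a phenotype."""
        pts = [
            (c.x, c.y)
            for c in self.cells
            if phenotype is None or c.phenotype == phenotype
        ]
        return np.asarray(pts, dtype=float).reshape(-1, 2)

    def count(self, phenotype: Phenotype) -> int:
        return sum(1 for c in self.cells if c.phenotype == phenotype)


Predicate = Callable[[frozenset], bool]


@dataclass(frozen=True)
class PhenotypeRule:
    """Ordered (label, predicate) pairs plus a default label.

    The first matching predicate wins; cells matching none take ``default``,
    so every flag combination maps to exactly one phenotype.
    """

    rules: tuple[tuple[Phenotype, Predicate], ...]
    default: Phenotype | None = Phenotype.OTHER

    def classify(self, markers: frozenset) -> Phenotype:
        for label, pred in self.rules:
            if pred(markers):
                return label
        if self.default is None:
            raise RuleCoverageError(f"no rule covers markers {sorted(markers)}")
        return self.default


def default_phenotype_rule(tam_requires_both: bool = False) -> PhenotypeRule:
    """The standard panel rule.

    PD-L1(+) TAM = macrophage marker(s) plus PD-L1; CD8 T cell = CD8.  The
    macrophage gate is CD68 OR CD163 by default (``tam_requires_both`` makes
    it an AND gate).  Double-positive cells resolve to PD-L1(+) TAM first.
    """

    def is_tam(m: frozenset) -> bool:
        mac = ("CD68" in m and "CD163" in m) if tam_requires_both \
            else ("CD68" in m or "CD163" in m)
        return mac and "PDL1" in m

    return PhenotypeRule(
        rules=(
            (Phenotype.PDL1_TAM, is_tam),
            (Phenotype.CD8_T, lambda m: "CD8" in m),
        ),
        default=Phenotype.OTHER,
    )


def assign_phenotypes(
    region: RegionCellMap, rule: PhenotypeRule | None = None
) -> RegionCellMap:
    """Return a copy of ``region`` with every cell labelled by ``rule``.

    Idempotent: re-applying the same rule reproduces the same labels.
    Cells positive for both CD8 and macrophage markers are resolved by the
    rule's precedence order and logged.
    """
    rule = rule or default_phenotype_rule()
    cells = []
    n_ambiguous = 0
    for c in region.cells:
        label = rule.classify(c.markers)
        if "CD8" in c.markers and ("CD68" in c.markers or "CD163" in c.markers):
            n_ambiguous += 1
        cells.append(replace(c, phenotype=label))
    if n_ambiguous:
        logger.info(
            "region %s: %d cell(s) positive for CD8 and macrophage markers; "
            "resolved by rule precedence", region.region_id, n_ambiguous,
        )
    return RegionCellMap(
        region_id=region.region_id,
        patient_id=region.patient_id,
        width=region.width,
        height=region.height,
        cells=cells,
    )


def phenotype_counts(region: RegionCellMap) -> dict[Phenotype, int]:
    counts = {p: 0 for p in Phenotype}
    for c in region.cells:
        if c.phenotype is not None:
            counts[c.phenotype] += 1
    return counts


def _parse_flag(value, column: str, row: int) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY or s == "nan":
        return False
    raise CellTableParseError(
        f"row {row}: cannot parse {column}={value!r} as a positivity flag"
    )


def read_cell_table(path: str | Path, sep: str | None = None) -> list[RegionCellMap]:
    """Read a delimited cell table into one :class:`RegionCellMap` per region.

    Accepts comma- or tab-delimited files (``sep=None`` sniffs); marker flags
    may be 0/1, true/false or yes/no.  Cells keep file order within a region.
    Region geometry is taken from optional ``region_width_um`` /
    ``region_height_um`` columns, else inferred as the ceiling of the largest
    coordinate in the region.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     dtype=str, keep_default_na=False)
    missing = [c for c in _CELL_COLUMNS if c not in df.columns]
    if missing:
        raise CellTableFormatError(f"missing required column(s): {missing}")

    for col in ("x_um", "y_um"):
        # float() is correctly rounded, so full-precision text round-trips
        # bit-exactly (pd.to_numeric's fast parser is not)
        vals = np.empty(len(df))
        for i, raw in enumerate(df[col].to_numpy()):
            try:
                vals[i] = float(raw)
            except ValueError:
                raise CellTableParseError(
                    f"row {i}: non-numeric {col}={raw!r}"
                ) from None
        df[col] = vals

    has_geom = "region_width_um" in df.columns and "region_height_um" in df.columns
    has_pheno = "phenotype" in df.columns

    regions: list[RegionCellMap] = []
    for region_id, grp in df.groupby("region_id", sort=False):
        patient_ids = grp["patient_id"].unique()
        if len(patient_ids) > 1:
            raise CellTableFormatError(
                f"region {region_id} maps to several patients: {list(patient_ids)}"
            )
        if has_geom:
            width = float(grp["region_width_um"].iloc[0])
            height = float(grp["region_height_um"].iloc[0])
        else:
            width = float(np.ceil(grp["x_um"].max())) or 1.0
            height = float(np.ceil(grp["y_um"].max())) or 1.0
        cells = []
        for row_idx, row in grp.iterrows():
            markers = frozenset(
                m for m in MARKERS if _parse_flag(row[m], m, int(row_idx))
            )
            pheno = None
            if has_pheno and str(row["phenotype"]).strip():
                pheno = Phenotype(str(row["phenotype"]).strip())
            cells.append(Cell(
                cell_id=str(row["cell_id"]),
                x=float(row["x_um"]), y=float(row["y_um"]),
                markers=markers, phenotype=pheno,
            ))
        regions.append(RegionCellMap(
            region_id=str(region_id), patient_id=str(patient_ids[0]),
            width=width, height=height, cells=cells,
        ))
    return regions


def cells_to_frame(regions: Iterable[RegionCellMap]) -> pd.DataFrame:
    rows = []
    for r in regions:
        for c in r.cells:
            row = {
                "patient_id": r.patient_id, "region_id": r.region_id,
                "cell_id": c.cell_id, "x_um": c.x, "y_um": c.y,
                "region_width_um": r.width, "region_height_um": r.height,
            }
            for m in MARKERS:
                row[m] = int(m in c.markers)
            row["phenotype"] = c.phenotype.value if c.phenotype else ""
            rows.append(row)
    cols = _CELL_COLUMNS[:5] + ["region_width_um", "region_height_um"] \
        + list(MARKERS) + ["phenotype"]
    return pd.DataFrame(rows, columns=[
        "patient_id", "region_id", "cell_id", "x_um", "y_um",
        "region_width_um", "region_height_um", *MARKERS, "phenotype",
    ]) if rows else pd.DataFrame(columns=cols)


def write_cell_table(
    regions: Iterable[RegionCellMap], path: str | Path, sep: str = ","
) -> None:
    """Write regions as a delimited cell table.

    Coordinates are written at full float precision so that
    ``read_cell_table(write_cell_table(x))`` reproduces ``x`` exactly
    (flags bit-exact, coordinates to the last ulp).
    """
    cells_to_frame(regions).to_csv(path, sep=sep, index=False)


def read_patient_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a patient clinical table; validates the expected columns."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise CellTableFormatError(f"missing required column(s): {missing}")
    return df


def write_patient_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)
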