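"""Quantification of segmented-cell tables from smFISH/IF imaging.

Input is one row per segmented cell — section id, phenotype call, nuclear
area, puncta count of a total-RNA probe — as exported by image-analysis
software.  This module applies the benchmark's filters (section quality
grades, oversized-nucleus removal) and produces per-section cell-type
proportions and per-type cell-size metrics usable as size factors in
deconvolution.

Proportions use the *total* number of segmented cells in a section as the
denominator, so unlabeled cells appear in an explicit ``other`` column and
rows still sum to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data_model import DataModelError
from .deconvolution import ProportionTable

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("section_id", "phenotype", "nuclear_area", "puncta_count")
GRADES = ("Low", "Okay", "High")
OTHER_LABEL = "other"

#: column name remapping for reading third-party CSV exports
DEFAULT_COLUMN_MAP = {
    "section_id": "section_id",
    "phenotype": "phenotype",
    "nuclear_area": "nuclear_area",
    "puncta_count": "puncta_count",
}


def read_cells_table(path: str | Path,
                     column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a segmented-cell CSV, renaming columns via ``column_map``.

    ``column_map`` maps canonical names (``section_id``, ``phenotype``,
    ``nuclear_area``, ``puncta_count``, optionally ``radius`` and
    ``combination``) to the column names used in the export.
    """
    column_map = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    table = pd.read_csv(path)
    rename = {src: canon for canon, src in column_map.items() if src in table.columns}
    table = table.rename(columns=rename)
    return validate_cells_table(table)


def validate_cells_table(cells: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in cells.columns]
    if missing:
        raise DataModelError(f"cells table missing columns: {missing}")
    if cells["section_id"].isna().any() or (cells["section_id"] == "").any():
        raise DataModelError("empty section ids")
    area = cells["nuclear_area"].to_numpy(dtype=float)
    if np.any(~np.isfinite(area)):
        raise DataModelError("non-finite nuclear areas")
    if np.any(area < 0):
        raise DataModelError("negative nuclear areas")
    return cells


def radius_filter(cells: pd.DataFrame,
                  max_radius: float = 5.0) -> tuple[pd.DataFrame, int]:
    """Drop cells whose nuclear radius strictly exceeds ``max_radius`` (um).

    When a ``radius`` column is absent, radius is derived from the nuclear
    area assuming a circular nucleus, ``r = sqrt(area / pi)``.  Returns the
    filtered table and the number of removed cells.  Idempotent.
    """
    if max_radius <= 0:
        raise DataModelError("max_radius must be positive")
    validate_cells_table(cells)
    if "radius" in cells.columns:
        radius = cells["radius"].to_numpy(dtype=float)
    else:
        radius = np.sqrt(cells["nuclear_area"].to_numpy(dtype=float) / np.pi)
    keep = radius <= max_radius
    n_removed = int((~keep).sum())
    logger.info("radius_filter: removed %d / %d cells (max_radius=%g um)",
                n_removed, len(cells), max_radius)
    return cells.loc[keep].reset_index(drop=True), n_removed


def qc_filter(cells: pd.DataFrame, qc: Mapping[str, str],
              min_grade: str = "Okay") -> pd.DataFrame:
    """Keep cells from sections graded at least ``min_grade`` (Low<Okay<High)."""
    if min_grade not in GRADES:
        raise DataModelError(f"unknown grade {min_grade!r}")
    sections = set(cells["section_id"].astype(str))
    ungraded = sections - set(map(str, qc))
    if ungraded:
        raise DataModelError(f"ungraded sections: {sorted(ungraded)[:5]}")
    level = {g: i for i, g in enumerate(GRADES)}
    for s, g in qc.items():
        if g not in level:
            raise DataModelError(f"invalid grade {g!r} for section {s!r}")
    keep_sections = {s for s in sections if level[qc[s]] >= level[min_grade]}
    out = cells[cells["section_id"].astype(str).isin(keep_sections)]
    return out.reset_index(drop=True)


def section_proportions(cells: pd.DataFrame,
                        unlabeled: Iterable[str] = ("", "nan", "None",
                                                    OTHER_LABEL)) -> ProportionTable:
    """Per-section cell-type proportions over *all* segmented cells.

    The denominator is the total number of segmented cells in a section;
    cells with no phenotype call (missing, or a label listed in
    ``unlabeled``) are pooled into an ``other`` column so that every row
    sums to exactly 1.
    """
    validate_cells_table(cells)
    if len(cells) == 0:
        raise DataModelError("empty cells table")
    unlabeled = set(unlabeled)
    phen = cells["phenotype"].astype(str).where(~cells["phenotype"].isna(),
                                                OTHER_LABEL)
    phen = phen.map(lambda x: OTHER_LABEL if x in unlabeled else x)
    counts = pd.crosstab(cells["section_id"].astype(str), phen)
    if OTHER_LABEL not in counts.columns:
        counts[OTHER_LABEL] = 0
    # put labeled types first, 'other' last
    cols = [c for c in counts.columns if c != OTHER_LABEL] + [OTHER_LABEL]
    counts = counts[cols]
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise DataModelError("section with zero cells")
    props = counts.div(totals, axis=0)
    return ProportionTable(props, method="rnascope")


def cell_size_metrics(cells: pd.DataFrame,
                      exclude: Iterable[str] = (OTHER_LABEL,),
                      ) -> dict[str, dict[str, float]]:
    """Per-type median size metrics from retained labeled cells.

    Returns three size tables keyed ``area``, ``puncta`` and
    ``area_x_puncta``: the per-type medians of nuclear area, of puncta count,
    and of the *per-cell product* of the two (not the product of the
    medians), pooling cells across sections.  Types with zero cells are
    omitted with a log warning.
    """
    validate_cells_table(cells)
    exclude = set(exclude)
    labeled = cells[~cells["phenotype"].isna()
                    & ~cells["phenotype"].astype(str).isin(exclude)]
    out: dict[str, dict[str, float]] = {"area": {}, "puncta": {},
                                        "area_x_puncta": {}}
    for ct, grp in labeled.groupby(labeled["phenotype"].astype(str)):
        if len(grp) == 0:
            logger.warning("cell type %s has no cells; omitted", ct)
            continue
        area = grp["nuclear_area"].to_numpy(dtype=float)
        puncta = grp["puncta_count"].to_numpy(dtype=float)
        out["area"][ct] = float(np.median(area))
        out["puncta"][ct] = float(np.median(puncta))
        out["area_x_puncta"][ct] = float(np.median(area * puncta))
    return out


def write_cell_sizes(sizes: Mapping[str, Mapping[str, float]],
                     path: str | Path) -> None:
    frame = pd.DataFrame(sizes)
    frame.index.name = "cell_type"
    frame.to_csv(path, sep="\t")
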