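"""Intensity measurement and tidy-table export.

All intensities are measured on the raw (un-enhanced) average GFP
projection — never on rescaled or background-subtracted intermediates —
so values stay in acquisition units.  The image is the replicate unit for
localization: pct_nuclear pools puncta across the cells of one field
rather than averaging per-cell fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .compartments import CompartmentSet
from .core_images import LabelMask
from .puncta import PunctumRecord

PUNCTA_COLUMNS = [
    "field_id", "punctum_id", "cell_id", "compartment",
    "centroid_row", "centroid_col", "area_px2", "equivalent_diameter_px",
    "mean_intensity", "max_intensity", "integrated_intensity",
]
CELL_COLUMNS = [
    "field_id", "cell_id", "nucleus_area_px2", "cell_area_px2",
    "n_puncta_total", "n_puncta_nuclear", "n_puncta_cytoplasmic",
    "mean_intensity_cell", "mean_intensity_nucleus", "mean_intensity_cytoplasm",
    "mean_puncta_intensity",
]
IMAGE_COLUMNS = [
    "field_id", "condition", "construct", "n_cells", "mean_puncta_per_cell",
    "pct_nuclear", "pct_cytoplasmic", "mean_puncta_intensity",
]

_KEYS = {
    "puncta": ["field_id", "punctum_id"],
    "cells": ["field_id", "cell_id"],
    "images": ["field_id"],
}
_COLUMNS = {"puncta": PUNCTA_COLUMNS, "cells": CELL_COLUMNS, "images": IMAGE_COLUMNS}


@dataclass
class CellRecord:
    """Per-cell geometry, puncta counts and compartment intensities."""

    field_id: str
    cell_id: int
    nucleus_area_px2: int
    cell_area_px2: int
    n_puncta_total: int
    n_puncta_nuclear: int
    n_puncta_cytoplasmic: int
    mean_intensity_cell: float
    mean_intensity_nucleus: float
    mean_intensity_cytoplasm: float  # NaN when the cytoplasm is empty
    mean_puncta_intensity: float     # NaN when the cell has no puncta


@dataclass
class ImageSummary:
    """Per-field summary; pct fields are NaN when the field has no puncta."""

    field_id: str
    condition: str
    construct: str
    n_cells: int
    mean_puncta_per_cell: float
    pct_nuclear: float
    pct_cytoplasmic: float
    mean_puncta_intensity: float


@dataclass
class MeasurementTable:
    """A tidy measurement table of one kind with a stable column order."""

    data: pd.DataFrame
    kind: str  # "puncta" | "cells" | "images"

    def __post_init__(self) -> None:
        if self.kind not in _KEYS:
            raise ValueError(f"unknown table kind {self.kind!r}")
        self.data = self.data.reindex(columns=_COLUMNS[self.kind])
        if self.data.duplicated(subset=_KEYS[self.kind]).any():
            raise ValueError("duplicate object rows")


def _label_means(image: np.ndarray, labels: np.ndarray, ids: np.ndarray) -> np.ndarray:
    if ids.size == 0:
        return np.array([])
    return np.asarray(ndi.mean(image, labels, ids), dtype=float)


def measure_intensities(
    records: list[PunctumRecord],
    puncta_mask: LabelMask,
    compartments: CompartmentSet,
    raw_gfp: np.ndarray,
    field_id: str | None = None,
) -> tuple[list[PunctumRecord], list[CellRecord]]:
    """Fill per-punctum intensities and build per-cell records.

    ``raw_gfp`` must be the un-enhanced average projection.  Per punctum:
    mean / max / integrated intensity over its pixels.  Per cell: mean over
    the cell, nucleus and cytoplasm masks; an empty cytoplasm or a cell
    without puncta yields NaN for the corresponding field.
    """
    raw = np.asarray(raw_gfp, dtype=np.float64)
    if raw.shape != puncta_mask.labels.shape:
        raise ValueError("shape mismatch")

    ids = puncta_mask.label_ids
    if ids.size:
        means = _label_means(raw, puncta_mask.labels, ids)
        maxs = np.asarray(ndi.maximum(raw, puncta_mask.labels, ids), dtype=float)
        sums = np.asarray(ndi.sum_labels(raw, puncta_mask.labels, ids), dtype=float)
        by_id = {int(i): (m, mx, s) for i, m, mx, s in zip(ids, means, maxs, sums)}
    else:
        by_id = {}
    for rec in records:
        m, mx, s = by_id[rec.punctum_id]
        rec.mean_intensity = float(m)
        rec.max_intensity = float(mx)
        rec.integrated_intensity = float(s)

    nuc, cel, cyt = (
        compartments.nuclei.labels,
        compartments.cells.labels,
        compartments.cytoplasm.labels,
    )
    cell_ids = compartments.nuclei.label_ids
    nuc_counts = np.bincount(nuc.ravel())
    cel_counts = np.bincount(cel.ravel())
    cyt_counts = np.bincount(cyt.ravel())
    mean_cell = _label_means(raw, cel, cell_ids)
    mean_nuc = _label_means(raw, nuc, cell_ids)

    per_cell_counts: dict[int, list[int]] = {int(i): [0, 0] for i in cell_ids}
    per_cell_int: dict[int, list[float]] = {int(i): [] for i in cell_ids}
    if field_id is None:
        field_id = records[0].field_id if records else ""
    for rec in records:
        slot = 0 if rec.compartment == "nuclear" else 1
        per_cell_counts[rec.cell_id][slot] += 1
        per_cell_int[rec.cell_id].append(rec.mean_intensity)

    cell_records: list[CellRecord] = []
    for i, cid in enumerate(cell_ids):
        cid = int(cid)
        n_nuc, n_cyt = per_cell_counts[cid]
        cyt_area = int(cyt_counts[cid]) if cid < cyt_counts.size else 0
        if cyt_area > 0:
            mean_cyt = float(ndi.mean(raw, cyt, cid))
        else:
            mean_cyt = math.nan
        vals = per_cell_int[cid]
        cell_records.append(
            CellRecord(
                field_id=field_id,
                cell_id=cid,
                nucleus_area_px2=int(nuc_counts[cid]),
                cell_area_px2=int(cel_counts[cid]),
                n_puncta_total=n_nuc + n_cyt,
                n_puncta_nuclear=n_nuc,
                n_puncta_cytoplasmic=n_cyt,
                mean_intensity_cell=float(mean_cell[i]),
                mean_intensity_nucleus=float(mean_nuc[i]),
                mean_intensity_cytoplasm=mean_cyt,
                mean_puncta_intensity=float(np.mean(vals)) if vals else math.nan,
            )
        )
    return records, cell_records


def summarize_image(
    cell_records: list[CellRecord],
    punctum_records: list[PunctumRecord],
    condition: str,
    construct: str,
    field_id: str = "",
) -> ImageSummary:
    """Pool one field into an ImageSummary.

    pct_nuclear = 100 * sum(n_nuclear) / sum(n_total) over the whole image;
    with zero puncta both localization fields are NaN and
    mean_puncta_per_cell is 0 (or NaN with no cells at all).
    """
    if not field_id and cell_records:
        field_id = cell_records[0].field_id
    n_cells = len(cell_records)
    totals = [c.n_puncta_total for c in cell_records]
    n_total = int(sum(totals))
    n_nuclear = int(sum(c.n_puncta_nuclear for c in cell_records))
    if n_total > 0:
        pct_nuc = 100.0 * n_nuclear / n_total
        pct_cyt = 100.0 - pct_nuc
    else:
        pct_nuc = pct_cyt = math.nan
    p_int = [r.mean_intensity for r in punctum_records]
    return ImageSummary(
        field_id=field_id,
        condition=condition,
        construct=construct,
        n_cells=n_cells,
        mean_puncta_per_cell=float(np.mean(totals)) if n_cells else math.nan,
        pct_nuclear=pct_nuc,
        pct_cytoplasmic=pct_cyt,
        mean_puncta_intensity=float(np.mean(p_int)) if p_int else math.nan,
    )


def puncta_table(records: list[PunctumRecord]) -> MeasurementTable:
    rows = []
    for r in records:
        d = asdict(r)
        cr, cc = d.pop("centroid_rc")
        d["centroid_row"], d["centroid_col"] = cr, cc
        rows.append(d)
    return MeasurementTable(pd.DataFrame(rows, columns=PUNCTA_COLUMNS), kind="puncta")


def cells_table(records: list[CellRecord]) -> MeasurementTable:
    return MeasurementTable(
        pd.DataFrame([asdict(r) for r in records], columns=CELL_COLUMNS), kind="cells"
    )


def images_table(summaries: list[ImageSummary]) -> MeasurementTable:
    return MeasurementTable(
        pd.DataFrame([asdict(s) for s in summaries], columns=IMAGE_COLUMNS),
        kind="images",
    )


def export_csv(table: MeasurementTable, path) -> None:
    """UTF-8 CSV, header row, fixed column order, missing values empty."""
    table.data.to_csv(path, index=False, encoding="utf-8")


def import_csv(path, kind: str) -> MeasurementTable:
    """Inverse of :func:`export_csv`; empty fields come back as NaN."""
    df = pd.read_csv(path, encoding="utf-8", dtype={"field_id": str})
    return MeasurementTable(df, kind=kind)
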