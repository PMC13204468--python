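"""Per-field nuclei, cell-body and cytoplasm segmentation.

The fidelity path for nuclei is an externally produced label TIFF (e.g. from
a trained nuclear-segmentation network); :func:`segment_nuclei_classical` is
a self-contained classical fallback so the pipeline runs without one.

Cell bodies are grown from nuclear seeds into a foreground defined by
three-class Otsu thresholding of the combined GFP+RFP image: the middle and
upper classes are foreground, i.e. the lower of the two Otsu boundaries,
multiplied by a correction factor (default 0.5), is the applied threshold.
Cytoplasm is the tertiary compartment cell \\ nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.morphology import disk, opening
from skimage.segmentation import watershed

from .core_images import LabelMask, Projection, rescale_to_unit
from .errors import DegenerateHistogram, ParentLinkageBroken


@dataclass
class SegmentationParams:
    """Segmentation settings with their pipeline defaults.

    ``min_nucleus_area_px2`` — nuclei smaller than this (strictly) are
    dropped before any downstream analysis.  ``secondary_correction``
    multiplies the lower three-class Otsu boundary to give the cell-body
    threshold.  ``combine_mode`` sets how the unit-rescaled GFP and RFP
    channels are merged before boundary detection.
    """

    min_nucleus_area_px2: int = 1200
    secondary_otsu_classes: int = 3
    secondary_foreground: str = "middle_and_upper"
    secondary_correction: float = 0.5
    combine_mode: str = "mean"  # or "sum_clipped"
    pre_smooth_sigma: float = 1.0
    nucleus_split_min_distance_px: int = 10

    def __post_init__(self) -> None:
        if self.min_nucleus_area_px2 < 0:
            raise ValueError("min_nucleus_area_px2 must be >= 0")
        if self.secondary_correction <= 0:
            raise ValueError("secondary_correction must be > 0")
        if self.secondary_otsu_classes not in (2, 3):
            raise ValueError("secondary_otsu_classes must be 2 or 3")
        if self.combine_mode not in ("mean", "sum_clipped"):
            raise ValueError(f"unknown combine_mode {self.combine_mode!r}")


@dataclass
class CompartmentSet:
    """Nuclei, cells and cytoplasm masks for one field, linked by shared
    integer ids."""

    nuclei: LabelMask
    cells: LabelMask
    cytoplasm: LabelMask

    def validate(self) -> None:
        """Check the compartment algebra: nucleus(l) ⊆ cell(l),
        cytoplasm(l) = cell(l) \\ nucleus(l), shared label sets."""
        nuc, cel, cyt = self.nuclei.labels, self.cells.labels, self.cytoplasm.labels
        ids = set(self.nuclei.label_ids.tolist())
        if set(self.cells.label_ids.tolist()) != ids:
            raise ParentLinkageBroken("parent linkage broken: cells vs nuclei")
        if not set(self.cytoplasm.label_ids.tolist()) <= ids:
            raise ParentLinkageBroken("parent linkage broken: cytoplasm vs nuclei")
        inside = nuc > 0
        if np.any(cel[inside] != nuc[inside]):
            raise ParentLinkageBroken("nucleus not contained in its cell")
        expected_cyt = np.where(inside, 0, cel)
        if np.any(cyt != expected_cyt):
            raise ParentLinkageBroken("cytoplasm != cell \\ nucleus")


def otsu_thresholds(
    image: np.ndarray, n_classes: int, n_bins: int = 256
) -> list[float]:
    """Multilevel Otsu thresholds of a unit-scaled image.

    Maximizes the between-class variance over an ``n_bins`` histogram on
    [0, 1] and returns the ``n_classes - 1`` boundaries as bin upper-edge
    values, ties broken toward the smallest threshold(s).  Implemented with
    cumulative zeroth/first moments so every boundary (or boundary pair) is
    scored in one vectorized pass.
    """
    if n_classes not in (2, 3):
        raise ValueError("n_classes must be 2 or 3")
    image = np.asarray(image, dtype=np.float64)
    hist, edges = np.histogram(np.clip(image, 0.0, 1.0), bins=n_bins, range=(0.0, 1.0))
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogram("degenerate histogram")
    p = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    W = np.cumsum(p)                # zeroth moment up to and including bin k
    M = np.cumsum(p * centers)      # first moment

    def cls_term(w: np.ndarray, m: np.ndarray) -> np.ndarray:
        # w * mu^2 with empty classes contributing zero
        out = np.zeros_like(w)
        nz = w > 0
        out[nz] = m[nz] ** 2 / w[nz]
        return out

    if n_classes == 2:
        k = np.arange(n_bins - 1)
        w1, m1 = W[k], M[k]
        w2, m2 = 1.0 - w1, M[-1] - m1
        score = cls_term(w1, m1) + cls_term(w2, m2)
        best = int(np.argmax(score))  # first max -> smallest threshold
        return [float(edges[best + 1])]

    # three classes: score all boundary pairs k1 < k2 at once
    k = np.arange(n_bins - 1)
    w_lo, m_lo = W[k], M[k]
    w1 = w_lo[:, None] * np.ones_like(w_lo)[None, :]
    m1 = m_lo[:, None] * np.ones_like(m_lo)[None, :]
    w2 = w_lo[None, :] - w_lo[:, None]
    m2 = m_lo[None, :] - m_lo[:, None]
    w3 = 1.0 - w_lo[None, :] * np.ones_like(w_lo)[:, None]
    m3 = M[-1] - m_lo[None, :] * np.ones_like(m_lo)[:, None]
    score = cls_term(w1, m1) + cls_term(w2, m2) + cls_term(w3, m3)
    score[np.tril_indices(n_bins - 1)] = -np.inf  # require k1 < k2
    flat = int(np.argmax(score))  # row-major first max -> lexicographically smallest
    k1, k2 = divmod(flat, n_bins - 1)
    return [float(edges[k1 + 1]), float(edges[k2 + 1])]


def segment_nuclei_classical(dapi: np.ndarray, params: SegmentationParams) -> LabelMask:
    """Classical nuclear segmentation from a DAPI projection.

    Smooth (sigma = ``pre_smooth_sigma``), rescale to [0, 1], two-class Otsu,
    fill holes, then split touching nuclei by a distance-transform watershed.
    Deterministic; a degenerate (blank) field yields an empty mask.
    """
    dapi = np.asarray(dapi, dtype=np.float64)
    smooth = ndi.gaussian_filter(dapi, params.pre_smooth_sigma)
    if smooth.max() == smooth.min():
        return LabelMask(np.zeros(dapi.shape, dtype=np.int32), kind="nuclei")
    unit = (smooth - smooth.min()) / (smooth.max() - smooth.min())
    try:
        t = otsu_thresholds(unit, 2)[0]
    except DegenerateHistogram:
        return LabelMask(np.zeros(dapi.shape, dtype=np.int32), kind="nuclei")
    binary = ndi.binary_fill_holes(unit > t)
    if not binary.any():
        return LabelMask(np.zeros(dapi.shape, dtype=np.int32), kind="nuclei")
    comp, n_comp = ndi.label(binary, structure=np.ones((3, 3)))
    dist = ndi.distance_transform_edt(binary)
    coords = peak_local_max(
        dist,
        min_distance=params.nucleus_split_min_distance_px,
        labels=comp,
        exclude_border=False,
    )
    markers = np.zeros(dapi.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    # guarantee every component keeps at least one seed
    seeded = set(np.unique(comp[markers > 0]).tolist())
    next_id = int(markers.max()) + 1
    for lbl in range(1, n_comp + 1):
        if lbl not in seeded:
            masked = np.where(comp == lbl, dist, -1.0)
            r, c = np.unravel_index(np.argmax(masked), masked.shape)
            markers[r, c] = next_id
            next_id += 1
    labels = watershed(-dist, markers, mask=binary)
    return LabelMask(labels.astype(np.int32), kind="nuclei")


def filter_labels_by_area(mask: LabelMask, min_area_px2: int) -> LabelMask:
    """Drop labels with pixel count strictly below ``min_area_px2``.

    Surviving labels keep their original ids; idempotent and monotone in
    the threshold.
    """
    counts = np.bincount(mask.labels.ravel())
    keep = counts >= min_area_px2
    keep[0] = False
    out = np.where(keep[mask.labels], mask.labels, 0)
    return LabelMask(out.astype(np.int32), kind=mask.kind)


def combine_gfp_rfp(
    gfp: np.ndarray, rfp: np.ndarray, params: SegmentationParams
) -> np.ndarray:
    """Merge the unit-rescaled GFP and RFP channels for boundary detection,
    then Gaussian-smooth (sigma = ``pre_smooth_sigma``).  Output in [0, 1]."""
    gfp = np.asarray(gfp, dtype=np.float64)
    rfp = np.asarray(rfp, dtype=np.float64)
    if gfp.shape != rfp.shape:
        raise ValueError("shape mismatch")
    if params.combine_mode == "mean":
        combined = 0.5 * (gfp + rfp)
    else:
        combined = np.clip(gfp + rfp, 0.0, 1.0)
    return np.clip(ndi.gaussian_filter(combined, params.pre_smooth_sigma), 0.0, 1.0)


def cell_body_threshold(
    combined: np.ndarray, params: SegmentationParams
) -> tuple[float, float]:
    """Return (applied threshold, raw Otsu boundary) for cell-body foreground.

    With three classes the lower boundary is used — taking the middle class
    as foreground means middle + upper classes are above threshold — scaled
    by ``secondary_correction``.
    """
    ts = otsu_thresholds(combined, params.secondary_otsu_classes)
    t1 = ts[0]
    return params.secondary_correction * t1, t1


def segment_cell_bodies(
    combined: np.ndarray, nuclei: LabelMask, params: SegmentationParams
) -> LabelMask:
    """Partition thresholded foreground among nuclear seeds by watershed.

    Foreground is ``combined >= secondary_correction * t1``.  Each foreground
    connected region containing nuclei is split among them by watershed on
    inverted intensity seeded at the nuclei; regions with no nucleus are
    discarded; every cell is forced to contain its full nucleus.  One cell
    per nucleus, same id.

    The watershed relief is a grayscale opening of the combined image
    (disk radius 5), so bright diffraction-scale reporter puncta sitting
    near a shared boundary cannot drag the dividing line into the wrong
    cell — boundaries follow the cell-wide intensity, not the spots.
    """
    if nuclei.n_objects == 0:
        return LabelMask(np.zeros(nuclei.labels.shape, dtype=np.int32), kind="cells")
    combined = np.asarray(combined, dtype=np.float64)
    if combined.shape != nuclei.labels.shape:
        raise ValueError("shape mismatch")
    try:
        applied, _ = cell_body_threshold(combined, params)
        fg = combined >= applied
    except DegenerateHistogram:
        fg = np.zeros(combined.shape, dtype=bool)
    mask = fg | (nuclei.labels > 0)
    relief = opening(combined, footprint=disk(5))
    cells = watershed(-relief, markers=nuclei.labels, mask=mask)
    return LabelMask(cells.astype(np.int32), kind="cells")


def derive_cytoplasm(cells: LabelMask, nuclei: LabelMask) -> LabelMask:
    """Tertiary compartment: per label, cytoplasm = cell minus nucleus."""
    if not set(cells.label_ids.tolist()) <= set(nuclei.label_ids.tolist()):
        raise ParentLinkageBroken("parent linkage broken")
    cyt = np.where(nuclei.labels > 0, 0, cells.labels)
    return LabelMask(cyt.astype(np.int32), kind="cytoplasm")


def segment_field(
    projection: Projection,
    params: SegmentationParams,
    external_nuclei: LabelMask | None = None,
) -> CompartmentSet:
    """Full compartment chain for one field.

    Uses an externally supplied nuclear mask when given (the fidelity path),
    otherwise the classical DAPI segmenter; area-filters nuclei, combines
    GFP+RFP, grows cell bodies, derives cytoplasm.
    """
    if external_nuclei is not None:
        nuclei = external_nuclei
    else:
        nuclei = segment_nuclei_classical(projection.channels["dapi"], params)
    nuclei = filter_labels_by_area(nuclei, params.min_nucleus_area_px2)
    gfp_u = rescale_to_unit(projection.channels["gfp"])
    rfp_u = rescale_to_unit(projection.channels["rfp"])
    combined = combine_gfp_rfp(gfp_u, rfp_u, params)
    cells = segment_cell_bodies(combined, nuclei, params)
    cytoplasm = derive_cytoplasm(cells, nuclei)
    cs = CompartmentSet(nuclei=nuclei, cells=cells, cytoplasm=cytoplasm)
    cs.validate()
    return cs
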