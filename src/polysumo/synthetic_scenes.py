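"""Synthetic fluorescence fields with exact ground truth.

Each scene emulates a three-channel confocal field: DAPI-stained elliptical
nuclei, an RFP/membrane counterstain filling the surrounding cell bodies,
and a GFP reporter carrying diffuse signal plus diffraction-scale Gaussian
puncta.  Per-cell punctum counts are Poisson with a condition-dependent
rate; each punctum is nuclear with a tunable probability and placed
uniformly inside its compartment with a small margin.  Fields get a smooth
background gradient, Poisson shot noise and Gaussian read noise, and are
quantized to 16 bit.  A thin z-stack (default 3 slices with mild defocus
blur) makes the average projection meaningful.  Everything is a pure
function of the seed.

Condition presets are qualitative stand-ins: their numeric rates are
invented, only their ordering mirrors the biology (polySUMO-chain removal
depletes puncta, SUMO2 overexpression or arsenic stress induces them, the
binding-dead mutant construct shows essentially none).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import disk

from .core_images import FieldImage, LabelMask, write_label_mask
from .errors import PlacementFailed

MAX_16BIT = 2**16 - 1


@dataclass
class SceneSpec:
    """Simulator inputs for one field.  Intensities are raw 16-bit units."""

    field_shape: tuple[int, int] = (1024, 1024)
    n_nuclei: int = 12
    nucleus_radii_px: tuple[float, float] = (22.0, 34.0)  # ellipse semi-axes
    cell_dilation_px: int = 18
    puncta_per_cell_lambda: float = 5.0
    nuclear_fraction: float = 0.9
    punctum_sigma_px: tuple[float, float] = (0.8, 2.0)
    punctum_peak: tuple[float, float] = (1200.0, 3000.0)
    diffuse_gfp_level: float = 300.0
    background_gradient_amp: float = 100.0
    read_noise_sd: float = 20.0
    photon_scale: float = 0.25  # photons per intensity unit
    n_z: int = 3
    seed: int = 0
    min_spot_separation_px: float = 4.0
    punctum_margin_px: int = 2
    dapi_level: float = 3000.0
    rfp_level: float = 1500.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.nuclear_fraction <= 1.0):
            raise ValueError("nuclear_fraction must be in [0, 1]")
        for name in ("puncta_per_cell_lambda", "diffuse_gfp_level",
                     "background_gradient_amp", "read_noise_sd", "photon_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Truth tables (and masks) every recovery test compares against."""

    nuclei: pd.DataFrame   # id, center_row, center_col, axis_r, axis_c, angle, area
    cells: pd.DataFrame    # id, area
    puncta: pd.DataFrame   # id, cell_id, compartment, row, col, sigma, peak, integrated
    condition: str = ""
    nuclei_mask: LabelMask | None = None
    cells_mask: LabelMask | None = None

    def per_cell_counts(self) -> pd.Series:
        """True punctum count per cell id (cells with none included as 0)."""
        counts = self.puncta.groupby("cell_id").size() if len(self.puncta) else pd.Series(dtype=int)
        return counts.reindex(self.cells["id"], fill_value=0)

    def pct_nuclear(self) -> float:
        if len(self.puncta) == 0:
            return float("nan")
        return 100.0 * float((self.puncta["compartment"] == "nuclear").mean())


@dataclass
class ConditionPreset:
    """Condition label with its invented puncta rate, nuclear fraction and
    punctum brightness scale (GFP quenching under oxidative stress is a
    global peak scale < 1)."""

    name: str
    puncta_per_cell_lambda: float
    nuclear_fraction: float
    punctum_peak_scale: float = 1.0


PRESETS: dict[str, ConditionPreset] = {
    p.name: p
    for p in [
        ConditionPreset("control", 5.0, 0.90),
        ConditionPreset("senp6_oe", 1.5, 0.90),
        ConditionPreset("sumo2_oe", 12.0, 0.92),
        ConditionPreset("as2o3", 15.0, 0.92),
        ConditionPreset("as2o3_recovery", 6.0, 0.90),
        ConditionPreset("serum_starvation", 14.0, 0.80),
        ConditionPreset("h2o2_low", 10.0, 0.60, punctum_peak_scale=0.7),
        ConditionPreset("h2o2_high", 10.0, 0.85, punctum_peak_scale=0.6),
        ConditionPreset("doxorubicin", 13.0, 0.92),
        ConditionPreset("heat_shock", 2.0, 0.90),
        ConditionPreset("mt_construct", 0.1, 0.90),
    ]
}


def spec_from_preset(preset: ConditionPreset | str, **overrides) -> SceneSpec:
    """SceneSpec for a condition preset, with optional field overrides."""
    if isinstance(preset, str):
        preset = PRESETS[preset]
    lo, hi = SceneSpec.punctum_peak if "punctum_peak" not in overrides else overrides.pop("punctum_peak")
    spec = SceneSpec(
        puncta_per_cell_lambda=preset.puncta_per_cell_lambda,
        nuclear_fraction=preset.nuclear_fraction,
        punctum_peak=(lo * preset.punctum_peak_scale, hi * preset.punctum_peak_scale),
        **overrides,
    )
    return spec


def _place_nuclei(spec: SceneSpec, rng: np.random.Generator) -> list[dict]:
    h, w = spec.field_shape
    r_lo, r_hi = spec.nucleus_radii_px
    margin = r_hi + spec.cell_dilation_px + 2
    placed: list[dict] = []
    for i in range(spec.n_nuclei):
        for _ in range(2000):
            cr = rng.uniform(margin, h - margin)
            cc = rng.uniform(margin, w - margin)
            ar = rng.uniform(r_lo, r_hi)
            ac = rng.uniform(r_lo, r_hi)
            angle = rng.uniform(0.0, np.pi)
            r_max = max(ar, ac)
            ok = all(
                np.hypot(cr - p["center_row"], cc - p["center_col"])
                > r_max + max(p["axis_r"], p["axis_c"]) + 4.0
                for p in placed
            )
            if ok:
                placed.append(
                    dict(id=i + 1, center_row=cr, center_col=cc,
                         axis_r=ar, axis_c=ac, angle=angle)
                )
                break
        else:
            raise PlacementFailed("placement failed")
    return placed


def _compartment_pixels(mask: np.ndarray, margin: int) -> np.ndarray:
    """(n, 2) pixel coordinates of mask eroded by a disk of given radius;
    falls back to the un-eroded mask when erosion empties it."""
    if margin > 0:
        eroded = ndi.binary_erosion(mask, structure=disk(margin))
        if eroded.any():
            mask = eroded
    return np.argwhere(mask)


def generate_scene(spec: SceneSpec) -> tuple[FieldImage, GroundTruth]:
    """Render one field and its ground truth, fully determined by the seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_shape

    nuclei_rows = _place_nuclei(spec, rng)
    nuclei_mask = np.zeros((h, w), dtype=np.int32)
    for row in nuclei_rows:
        rr, cc = draw_ellipse(
            row["center_row"], row["center_col"], row["axis_r"], row["axis_c"],
            shape=(h, w), rotation=row["angle"],
        )
        nuclei_mask[rr, cc] = row["id"]
        row["area"] = int(rr.size)

    # cell bodies: nuclei dilated by cell_dilation_px, clipped at the
    # nearest-nucleus partition so neighbours never overlap
    dist, (ir, ic) = ndi.distance_transform_edt(nuclei_mask == 0, return_indices=True)
    owner = nuclei_mask[ir, ic]
    cells_mask = np.where(dist <= spec.cell_dilation_px, owner, 0).astype(np.int32)

    cell_ids = [row["id"] for row in nuclei_rows]
    cell_areas = np.bincount(cells_mask.ravel(), minlength=max(cell_ids) + 1)

    # puncta: per-cell Poisson counts, Bernoulli compartment, uniform
    # placement with a margin and a minimum spot separation field-wide
    slices = ndi.find_objects(cells_mask)
    puncta_rows: list[dict] = []
    placed_rc: list[tuple[float, float]] = []
    peak_lo, peak_hi = spec.punctum_peak
    sig_lo, sig_hi = spec.punctum_sigma_px
    pid = 0
    for cid in cell_ids:
        sl = slices[cid - 1]
        nuc_local = nuclei_mask[sl] == cid
        cyt_local = (cells_mask[sl] == cid) & ~nuc_local
        nuc_px = _compartment_pixels(nuc_local, spec.punctum_margin_px)
        cyt_px = _compartment_pixels(cyt_local, spec.punctum_margin_px)
        off_r, off_c = sl[0].start, sl[1].start
        n = rng.poisson(spec.puncta_per_cell_lambda)
        for _ in range(n):
            nuclear = rng.random() < spec.nuclear_fraction
            pool = nuc_px if nuclear else cyt_px
            if pool.size == 0:
                pool, nuclear = nuc_px, True
                if pool.size == 0:
                    continue
            for _try in range(200):
                pr, pc = pool[rng.integers(pool.shape[0])]
                r = off_r + pr + rng.uniform(-0.49, 0.49)
                c = off_c + pc + rng.uniform(-0.49, 0.49)
                if all(
                    np.hypot(r - rr, c - cc2) >= spec.min_spot_separation_px
                    for rr, cc2 in placed_rc
                ):
                    break
            else:
                continue  # could not honour the separation; skip this punctum
            sigma = rng.uniform(sig_lo, sig_hi)
            peak = rng.uniform(peak_lo, peak_hi)
            pid += 1
            placed_rc.append((r, c))
            puncta_rows.append(
                dict(
                    id=pid, cell_id=cid,
                    compartment="nuclear" if nuclear else "cytoplasmic",
                    row=r, col=c, sigma=sigma, peak=peak,
                    integrated=peak * 2.0 * np.pi * sigma**2,
                )
            )

    # clean channel images
    theta = rng.uniform(0.0, 2.0 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    ramp = (np.cos(theta) * xx / w + np.sin(theta) * yy / h + 1.0) / 2.0
    background = spec.background_gradient_amp * ramp

    dapi_gain = {cid: rng.uniform(0.8, 1.2) for cid in cell_ids}
    rfp_gain = {cid: rng.uniform(0.8, 1.2) for cid in cell_ids}
    dapi_clean = np.zeros((h, w))
    rfp_clean = np.zeros((h, w))
    for cid in cell_ids:
        dapi_clean[nuclei_mask == cid] = spec.dapi_level * dapi_gain[cid]
        rfp_clean[cells_mask == cid] = spec.rfp_level * rfp_gain[cid]
    dapi_clean = ndi.gaussian_filter(dapi_clean, 1.0) + 0.3 * background
    rfp_clean = ndi.gaussian_filter(rfp_clean, 1.0) + 0.3 * background

    gfp_clean = spec.diffuse_gfp_level * (cells_mask > 0).astype(float)
    gfp_clean = ndi.gaussian_filter(gfp_clean, 1.0) + background
    for row in puncta_rows:
        _render_spot(gfp_clean, row["row"], row["col"], row["sigma"], row["peak"])

    channels: dict[str, np.ndarray] = {}
    for name, clean in (("dapi", dapi_clean), ("gfp", gfp_clean), ("rfp", rfp_clean)):
        stack = np.empty((spec.n_z, h, w), dtype=np.uint16)
        mid = (spec.n_z - 1) / 2.0
        for k in range(spec.n_z):
            defocus = 0.6 * abs(k - mid)
            plane = ndi.gaussian_filter(clean, defocus) if defocus > 0 else clean
            plane = np.clip(plane, 0.0, None)  # filter roundoff can dip below 0
            if spec.photon_scale > 0:
                plane = rng.poisson(plane * spec.photon_scale) / spec.photon_scale
            if spec.read_noise_sd > 0:
                plane = plane + rng.normal(0.0, spec.read_noise_sd, size=plane.shape)
            stack[k] = np.clip(np.round(plane), 0, MAX_16BIT).astype(np.uint16)
        channels[name] = stack

    truth = GroundTruth(
        nuclei=pd.DataFrame(
            nuclei_rows,
            columns=["id", "center_row", "center_col", "axis_r", "axis_c", "angle", "area"],
        ),
        cells=pd.DataFrame(
            {"id": cell_ids, "area": [int(cell_areas[c]) for c in cell_ids]}
        ),
        puncta=pd.DataFrame(
            puncta_rows,
            columns=["id", "cell_id", "compartment", "row", "col", "sigma", "peak", "integrated"],
        ),
        nuclei_mask=LabelMask(nuclei_mask, kind="nuclei"),
        cells_mask=LabelMask(cells_mask, kind="cells"),
    )
    fld = FieldImage(channels=channels, bit_depth=16)
    return fld, truth


def _render_spot(image: np.ndarray, r: float, c: float, sigma: float, peak: float) -> None:
    h, w = image.shape
    rad = int(np.ceil(4.0 * sigma)) + 1
    r0, r1 = max(0, int(r) - rad), min(h, int(r) + rad + 1)
    c0, c1 = max(0, int(c) - rad), min(w, int(c) + rad + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    image[r0:r1, c0:c1] += peak * np.exp(
        -((yy - r) ** 2 + (xx - c) ** 2) / (2.0 * sigma**2)
    )


def derive_seed(base_seed: int, index: int) -> int:
    """Per-scene seed: base ⊕ a hash-spread index, kept below 2^31."""
    spread = int.from_bytes(
        hashlib.sha256(index.to_bytes(8, "little")).digest()[:4], "little"
    )
    return (base_seed ^ spread) % (2**31)


def generate_experiment(
    presets: list[ConditionPreset | str],
    n_images_per_condition: int = 9,
    base_seed: int = 0,
    out_dir: str | Path | None = None,
    **spec_overrides,
) -> list[tuple[str, str, FieldImage, GroundTruth]]:
    """One scene per (condition, image index), seeded from ``base_seed``.

    Returns ``(condition, field_id, FieldImage, GroundTruth)`` tuples; when
    ``out_dir`` is given, also writes per-field channel TIFFs, truth-mask
    TIFFs, truth CSVs and a manifest YAML.
    """
    import tifffile

    results = []
    manifest: dict = {"base_seed": base_seed, "fields": []}
    index = 0
    for preset in presets:
        preset = PRESETS[preset] if isinstance(preset, str) else preset
        for img in range(n_images_per_condition):
            spec = spec_from_preset(preset, seed=derive_seed(base_seed, index), **spec_overrides)
            fld, truth = generate_scene(spec)
            truth.condition = preset.name
            field_id = f"{preset.name}_{img:02d}"
            results.append((preset.name, field_id, fld, truth))
            if out_dir is not None:
                fdir = Path(out_dir) / field_id
                fdir.mkdir(parents=True, exist_ok=True)
                for ch, arr in fld.channels.items():
                    tifffile.imwrite(fdir / f"{ch}.tif", arr, photometric="minisblack")
                write_label_mask(truth.nuclei_mask, fdir / "nuclei_truth.tif")
                write_label_mask(truth.cells_mask, fdir / "cells_truth.tif")
                truth.nuclei.to_csv(fdir / "truth_nuclei.csv", index=False)
                truth.cells.to_csv(fdir / "truth_cells.csv", index=False)
                truth.puncta.to_csv(fdir / "truth_puncta.csv", index=False)
                manifest["fields"].append(
                    {"field_id": field_id, "condition": preset.name, "seed": spec.seed}
                )
            index += 1
    if out_dir is not None:
        with open(Path(out_dir) / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    return results
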