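"""Image ingestion, z-projection, intensity rescaling, and label-mask I/O.

Conventions used throughout the package: arrays are indexed (row, col),
0-based, with pixel centers at integer coordinates; areas are in pixels^2.
All computation after projection happens in floating point, but the raw
integer-valued projections are retained for intensity measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .errors import (
    ChannelShapeMismatch,
    DegenerateDynamicRange,
    NotALabelImage,
    UnsupportedTiffDialect,
)

CHANNEL_NAMES = ("dapi", "gfp", "rfp")

MaskKind = str  # one of {"nuclei", "cells", "cytoplasm", "puncta"}


@dataclass
class FieldImage:
    """One microscopy field: per-channel (z, y, x) stacks or (y, x) planes.

    Parameters
    ----------
    channels
        Mapping from channel name (``dapi``, ``gfp``, ``rfp``) to a
        non-negative intensity array, either a z-stack ``(z, y, x)`` or a
        single plane ``(y, x)``.
    bit_depth
        Acquisition bit depth; stored values must not exceed
        ``2**bit_depth - 1``.
    pixel_size_um, z_step_um
        Optional acquisition metadata (microns).
    """

    channels: dict[str, np.ndarray]
    bit_depth: int = 16
    pixel_size_um: float | None = None
    z_step_um: float = 0.5

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        shapes = set()
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.ndim not in (2, 3):
                raise ValueError(f"channel {name!r} must be 2-D or 3-D")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} has non-finite values")
            if arr.min() < 0:
                raise ValueError(f"channel {name!r} has negative values")
            if arr.max() > 2**self.bit_depth - 1:
                raise ValueError(
                    f"channel {name!r} exceeds {self.bit_depth}-bit range"
                )
            shapes.add(arr.shape[-2:])
            self.channels[name] = arr
        if len(shapes) > 1:
            raise ChannelShapeMismatch("channel shape mismatch")

    @property
    def spatial_shape(self) -> tuple[int, int]:
        arr = next(iter(self.channels.values()))
        return arr.shape[-2:]


@dataclass
class Projection:
    """2-D per-channel images produced from a FieldImage."""

    channels: dict[str, np.ndarray]
    provenance: str = "average_z"  # or "as_acquired"

    def __post_init__(self) -> None:
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) > 1:
            raise ChannelShapeMismatch("channel shape mismatch")
        for name, arr in self.channels.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"projection {name!r} has non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class LabelMask:
    """2-D non-negative integer image; 0 is background, each positive
    integer one object."""

    labels: np.ndarray
    kind: MaskKind = "nuclei"

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if not np.issubdtype(arr.dtype, np.integer):
            if np.any(arr != np.round(arr)):
                raise NotALabelImage("not a label image")
            arr = arr.astype(np.int32)
        if arr.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = arr

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_objects(self) -> int:
        return int(self.label_ids.size)

    def areas(self) -> dict[int, int]:
        """Pixel count per positive label."""
        counts = np.bincount(self.labels.ravel())
        return {i: int(counts[i]) for i in range(1, counts.size) if counts[i] > 0}


def read_field(
    paths: Mapping[str, str | Path] | str | Path,
    channel_order: Sequence[str] = CHANNEL_NAMES,
    bit_depth: int | None = None,
    **metadata,
) -> FieldImage:
    """Read a field from per-channel TIFFs or one multi-page TIFF.

    ``paths`` is either a mapping ``{channel: path}`` or a single path to a
    multi-page TIFF whose pages (or leading axis) follow ``channel_order``.
    Integer values are preserved losslessly.
    """
    channels: dict[str, np.ndarray] = {}
    if isinstance(paths, (str, Path)):
        stack = tifffile.imread(paths)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim == 4:  # (c, z, y, x)
            planes = list(stack)
        elif stack.shape[0] == len(channel_order):
            planes = list(stack)
        else:
            raise UnsupportedTiffDialect(
                "unsupported TIFF dialect: cannot infer channel axis"
            )
        for name, plane in zip(channel_order, planes):
            channels[name] = _check_dtype(plane)
    else:
        for name, p in paths.items():
            channels[name] = _check_dtype(tifffile.imread(p))
    if bit_depth is None:
        bit_depth = 8 if all(a.dtype == np.uint8 for a in channels.values()) else 16
    return FieldImage(channels=channels, bit_depth=bit_depth, **metadata)


def _check_dtype(arr: np.ndarray) -> np.ndarray:
    if not np.issubdtype(arr.dtype, np.integer):
        raise UnsupportedTiffDialect(
            f"unsupported TIFF dialect: sample format {arr.dtype}"
        )
    return arr


def average_z_projection(fld: FieldImage) -> Projection:
    """Per-pixel arithmetic mean over z for each channel, in floating point.

    2-D channels pass through unchanged with provenance ``as_acquired``.
    """
    out: dict[str, np.ndarray] = {}
    any_stack = False
    for name, arr in fld.channels.items():
        if arr.ndim == 3:
            if arr.shape[0] == 0:
                raise ValueError("no slices")
            out[name] = arr.mean(axis=0, dtype=np.float64)
            any_stack = True
        else:
            out[name] = arr.astype(np.float64)
    return Projection(out, provenance="average_z" if any_stack else "as_acquired")


def rescale_to_unit(image: np.ndarray) -> np.ndarray:
    """Affine rescale to [0, 1]: (x - min) / (max - min).

    A constant image has no dynamic range; by convention it maps to all
    zeros and a :class:`DegenerateDynamicRange` warning is emitted, so blank
    negative-control fields still flow through the pipeline.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("non-finite values")
    lo, hi = image.min(), image.max()
    if hi == lo:
        warnings.warn("degenerate dynamic range", DegenerateDynamicRange)
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def read_label_mask(path: str | Path, kind: MaskKind = "nuclei") -> LabelMask:
    """Read a single-page label TIFF.

    Float TIFFs with integral values are accepted and cast; anything with a
    fractional value is rejected.
    """
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise NotALabelImage("not a label image: expected a single page")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr != np.round(arr)):
            raise NotALabelImage("not a label image")
        arr = arr.astype(np.int32)
    return LabelMask(labels=arr.astype(np.int32), kind=kind)


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a label mask as an integer TIFF (lossless roundtrip)."""
    labels = mask.labels
    dtype = np.uint16 if labels.max() < 2**16 else np.int32
    tifffile.imwrite(path, labels.astype(dtype))
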