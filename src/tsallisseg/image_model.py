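"""Grayscale image container, quantization, and PNG/NIfTI input-output.

All downstream histogramming and entropy math operates on discrete gray
levels, so every image entering the pipeline is represented as a
:class:`GrayImage`: an integer raster with values in ``[0, levels - 1]``.
Floating-point inputs (e.g. NIfTI volumes) are min-max quantized onto that
range; integer inputs already within range pass through verbatim.

Coordinate convention: 0-based indices, axis order ``(row, col)`` for 2D and
``(slice, row, col)`` for 3D.  Physical voxel spacing is carried as metadata
but plays no role in thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .errors import ContractError, FormatError, InputError

__all__ = ["GrayImage", "BinaryMask", "quantize", "load_image", "save_mask", "load_mask"]


@dataclass
class GrayImage:
    """A quantized grayscale raster.

    Parameters
    ----------
    data
        2D or 3D integer array with values in ``[0, levels - 1]``.
    levels
        Number of gray levels L (>= 2).  Defaults to 256.
    spacing
        Per-axis physical voxel size in mm; defaults to 1.0 per axis.
    constant_input
        True when the source raster was constant and quantization collapsed
        it to all zeros.
    affine
        Optional 4x4 affine carried from a NIfTI header, used to preserve
        geometry when writing masks.
    """

    data: np.ndarray
    levels: int = 256
    spacing: tuple[float, ...] | None = None
    constant_input: bool = False
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ContractError("GrayImage data must be an integer array")
        if self.data.ndim not in (2, 3) or min(self.data.shape) < 1:
            raise ContractError(
                f"GrayImage must be rank 2 or 3 with all dims >= 1, got shape {self.data.shape}"
            )
        if self.levels < 2:
            raise ContractError(f"levels must be >= 2, got {self.levels}")
        lo, hi = int(self.data.min()), int(self.data.max())
        if lo < 0 or hi > self.levels - 1:
            raise ContractError(
                f"values [{lo}, {hi}] exceed gray-level range [0, {self.levels - 1}]"
            )
        if self.spacing is None:
            self.spacing = (1.0,) * self.data.ndim
        elif len(self.spacing) != self.data.ndim:
            raise ContractError("spacing must have one entry per axis")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class BinaryMask:
    """A {0,1} raster aligned with a source :class:`GrayImage`."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if not np.all(np.isin(arr, (0, 1))):
            raise ContractError("mask values must be 0 or 1")
        self.data = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


def quantize(
    raw: np.ndarray,
    levels: int = 256,
    p_low: float | None = None,
    p_high: float | None = None,
) -> GrayImage:
    """Min-max quantize a real-valued raster onto ``[0, levels - 1]``.

    ``v -> round((v - min) / (max - min) * (levels - 1))``.  A constant
    raster maps to all zeros and sets ``constant_input``.  Optional
    percentile clipping ``(p_low, p_high)`` compresses intensity outliers
    before the linear map; by default no clipping is applied.
    """
    arr = np.asarray(raw, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise InputError("raster contains NaN or Inf")
    if levels < 2:
        raise ContractError(f"levels must be >= 2, got {levels}")
    if p_low is not None or p_high is not None:
        lo_p = 0.0 if p_low is None else p_low
        hi_p = 100.0 if p_high is None else p_high
        lo, hi = np.percentile(arr, [lo_p, hi_p])
        arr = np.clip(arr, lo, hi)
    vmin, vmax = arr.min(), arr.max()
    if vmax == vmin:
        data = np.zeros(arr.shape, dtype=np.int64)
        return GrayImage(data, levels=levels, constant_input=True)
    scaled = np.rint((arr - vmin) / (vmax - vmin) * (levels - 1)).astype(np.int64)
    return GrayImage(scaled, levels=levels)


def _load_png(path: Path) -> np.ndarray:
    img = Image.open(path)
    if img.mode in ("P", "RGB", "RGBA", "LA"):
        warnings.warn(
            f"{path.name}: non-grayscale PNG ({img.mode}) converted to luminance",
            stacklevel=3,
        )
        img = img.convert("L")
    return np.asarray(img)


def load_image(
    path: str | Path,
    levels: int = 256,
    p_low: float | None = None,
    p_high: float | None = None,
) -> GrayImage:
    """Load a PNG (2D) or NIfTI ``.nii``/``.nii.gz`` (3D) as a :class:`GrayImage`.

    Integer rasters already within ``[0, levels - 1]`` pass through verbatim;
    anything else (16-bit PNG, floating-point NIfTI) is min-max quantized.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    name = path.name.lower()
    affine = None
    spacing = None
    if name.endswith(".png"):
        try:
            arr = _load_png(path)
        except Exception as exc:  # pillow raises various subclasses
            raise FormatError(f"cannot read PNG {path}: {exc}") from exc
    elif name.endswith((".nii", ".nii.gz")):
        try:
            nii = nib.load(str(path))
            arr = np.asanyarray(nii.dataobj)
            affine = np.asarray(nii.affine)
            spacing = tuple(float(z) for z in nii.header.get_zooms()[: arr.ndim])
        except Exception as exc:
            raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc
    else:
        raise FormatError(f"unsupported image format: {path} (expected .png/.nii/.nii.gz)")

    if (
        np.issubdtype(arr.dtype, np.integer)
        and p_low is None
        and p_high is None
        and arr.min() >= 0
        and arr.max() <= levels - 1
    ):
        if arr.min() == arr.max():
            img = GrayImage(np.zeros(arr.shape, dtype=np.int64), levels=levels, constant_input=True)
        else:
            img = GrayImage(arr.astype(np.int64), levels=levels)
    else:
        img = quantize(arr, levels=levels, p_low=p_low, p_high=p_high)
    img.affine = affine
    if spacing is not None:
        img.spacing = spacing
    return img


def save_mask(mask: BinaryMask, path: str | Path, reference: GrayImage) -> None:
    """Write a mask as 0/255 PNG (2D) or uint8 NIfTI with reference geometry (3D)."""
    if mask.shape != reference.shape:
        raise ContractError(
            f"mask shape {mask.shape} does not match reference shape {reference.shape}"
        )
    path = Path(path)
    if mask.data.ndim == 2:
        Image.fromarray((mask.data * 255).astype(np.uint8), mode="L").save(path)
    else:
        affine = reference.affine if reference.affine is not None else np.eye(4)
        nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))


def load_mask(path: str | Path) -> BinaryMask:
    """Read back a mask written by :func:`save_mask` (any nonzero voxel -> 1)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    name = path.name.lower()
    if name.endswith(".png"):
        arr = _load_png(path)
    elif name.endswith((".nii", ".nii.gz")):
        arr = np.asanyarray(nib.load(str(path)).dataobj)
    else:
        raise FormatError(f"unsupported mask format: {path}")
    return BinaryMask((np.asarray(arr) > 0).astype(np.uint8))
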