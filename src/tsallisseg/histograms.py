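"""Gray-level histograms: the 1D marginal and the 2D (gray, local-mean) joint.

The 1D histogram is the probability distribution ``{p_1, ..., p_L}`` over
gray levels that the 1D Tsallis objective consumes.  The 2D histogram pairs
each pixel's gray level with the rounded arithmetic mean of its w x w
neighborhood (w x w x w in 3D, reflect-padded).  Interior pixels of
homogeneous regions land on the diagonal ``i == j`` of the joint
distribution, while noise spikes and region-boundary pixels fall off it —
which is exactly the structure the 2D threshold search exploits to suppress
noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ContractError
from .image_model import GrayImage

__all__ = [
    "Histogram1D",
    "Histogram2D",
    "histogram_1d",
    "neighborhood_mean",
    "histogram_2d",
]


@dataclass
class Histogram1D:
    """Counts and probabilities over L gray levels."""

    counts: np.ndarray
    p: np.ndarray
    levels: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.p = np.asarray(self.p, dtype=np.float64)
        if len(self.counts) != self.levels or len(self.p) != self.levels:
            raise ContractError("histogram length must equal number of levels")
        if np.any(self.p < 0) or abs(self.p.sum() - 1.0) > 1e-12:
            raise ContractError("probabilities must be nonnegative and sum to 1")

    def to_tsv(self, path: str | Path) -> None:
        """Export (level, count, probability) rows for inspection."""
        rows = np.column_stack([np.arange(self.levels), self.counts, self.p])
        np.savetxt(
            path,
            rows,
            fmt=("%d", "%d", "%.12g"),
            delimiter="\t",
            header="level\tcount\tprobability",
            comments="",
        )


@dataclass
class Histogram2D:
    """Joint probabilities p_ij over (gray level i, neighborhood-mean level j)."""

    p: np.ndarray
    window: int
    levels: int

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.shape != (self.levels, self.levels):
            raise ContractError("joint histogram must be L x L")
        if np.any(self.p < 0) or abs(self.p.sum() - 1.0) > 1e-12:
            raise ContractError("joint probabilities must be nonnegative and sum to 1")
        if self.window < 3 or self.window % 2 == 0:
            raise ContractError("window must be odd and >= 3")

    def marginal_gray(self) -> np.ndarray:
        """Marginal over the neighborhood axis; equals the 1D probabilities."""
        return self.p.sum(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        """Export nonzero (gray, mean, probability) triples."""
        i, j = np.nonzero(self.p)
        rows = np.column_stack([i, j, self.p[i, j]])
        np.savetxt(
            path,
            rows,
            fmt=("%d", "%d", "%.12g"),
            delimiter="\t",
            header="gray\tneighborhood_mean\tprobability",
            comments="",
        )


def histogram_1d(img: GrayImage) -> Histogram1D:
    """Count pixels per gray level and normalize to probabilities."""
    counts = np.bincount(img.data.ravel(), minlength=img.levels)
    return Histogram1D(counts=counts, p=counts / counts.sum(), levels=img.levels)


def neighborhood_mean(img: GrayImage, window: int = 3) -> GrayImage:
    """Rounded local arithmetic mean over a w x w (x w) reflect-padded window.

    Averaging cannot leave the convex hull of the input values, so the
    output stays within ``[0, L - 1]`` automatically; rounding is to the
    nearest integer level.
    """
    if window % 2 == 0 or window < 3:
        raise ContractError(f"window must be odd and >= 3, got {window}")
    mean = ndimage.uniform_filter(img.data.astype(np.float64), size=window, mode="reflect")
    data = np.clip(np.rint(mean).astype(np.int64), 0, img.levels - 1)
    return GrayImage(data, levels=img.levels, spacing=img.spacing, affine=img.affine)


def histogram_2d(img: GrayImage, window: int = 3) -> Histogram2D:
    """Joint distribution of (gray level, neighborhood-mean level)."""
    mean_img = neighborhood_mean(img, window=window)
    L = img.levels
    flat = img.data.ravel() * L + mean_img.data.ravel()
    counts = np.bincount(flat, minlength=L * L).reshape(L, L)
    return Histogram2D(p=counts / counts.sum(), window=window, levels=L)
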