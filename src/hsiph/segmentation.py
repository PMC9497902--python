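"""Foreground segmentation and equal-area region splitting.

A sausage is isolated from the dark background by thresholding one band of
the reflectance cube (default: reflectance > 0.075 at band 70, i.e. 695 nm)
and keeping the largest 4-connected component.  The mask is then cut into
``k`` regions of equal pixel count by slicing along its major principal
axis — the digital analogue of cutting a cylindrical sausage crosswise —
and the arithmetic mean spectrum of each region is extracted into a table
row alongside the sample code and reference pH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import Hypercube, SEGMENTATION_BAND, SEGMENTATION_THRESHOLD
from .io import make_spectra_table

__all__ = ["SegmentationMask", "RegionLabels", "segment", "split_regions",
           "extract_mean_spectra"]


@dataclass
class SegmentationMask:
    """Boolean foreground mask plus the thresholding rule that produced it."""

    mask: np.ndarray
    threshold: float = SEGMENTATION_THRESHOLD
    band_index: int = SEGMENTATION_BAND  # 1-based

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D image")

    @property
    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class RegionLabels:
    """Integer label image: 0 = background, 1..k = regions."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D image")
        if self.labels.max(initial=0) > self.k or self.labels.min(initial=0) < 0:
            raise ValueError("labels outside 0..k")

    def region_counts(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.k + 1)[1:]


def segment(cube: Hypercube, band_index: int = SEGMENTATION_BAND,
            threshold: float = SEGMENTATION_THRESHOLD,
            keep_largest: bool = True) -> SegmentationMask:
    """Threshold one band (strict ``>``) and keep the largest 4-connected blob.

    Pixels exactly at the threshold count as background.  Raises if no
    foreground pixel survives.
    """
    if cube.domain != "reflectance":
        raise ValueError(f"segmentation expects reflectance, got {cube.domain!r}")
    image = cube.band_image(band_index)
    mask = image > threshold
    if not mask.any():
        raise ValueError(
            f"no foreground pixels: no reflectance > {threshold} at band {band_index}"
        )
    if keep_largest:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
        labeled, n = ndimage.label(mask, structure=structure)
        if n > 1:
            sizes = np.bincount(labeled.ravel())[1:]
            mask = labeled == (int(np.argmax(sizes)) + 1)
    return SegmentationMask(mask, threshold=threshold, band_index=band_index)


def split_regions(mask: SegmentationMask, k: int = 5) -> RegionLabels:
    """Partition the mask into ``k`` contiguous equal-area slices.

    Pixels are sorted by their projection onto the mask's major principal
    axis (leading eigenvector of the pixel-coordinate covariance) and cut
    into ``k`` contiguous bins whose sizes differ by at most one pixel;
    remainder pixels go to the earliest bins.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = mask.count
    if n < k:
        raise ValueError(f"mask has {n} pixels, fewer than k={k}")
    coords = np.argwhere(mask.mask).astype(float)  # (n, 2) as (row, col)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / max(n - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, int(np.argmax(eigvals))]
    # deterministic orientation: positive along the first nonzero component
    lead = np.nonzero(np.abs(axis) > 1e-12)[0]
    if lead.size and axis[lead[0]] < 0:
        axis = -axis
    projection = centered @ axis
    order = np.argsort(projection, kind="stable")

    sizes = np.full(k, n // k)
    sizes[: n % k] += 1  # remainder to earliest bins
    labels = np.zeros(mask.mask.shape, dtype=int)
    start = 0
    rows = np.argwhere(mask.mask)
    for region, size in enumerate(sizes, start=1):
        sel = rows[order[start:start + size]]
        labels[sel[:, 0], sel[:, 1]] = region
        start += size
    return RegionLabels(labels, k)


def extract_mean_spectra(cube: Hypercube, labels: RegionLabels,
                         sample_code: str, ph_ref: float) -> pd.DataFrame:
    """One table row per region: the arithmetic mean spectrum over its pixels."""
    if labels.labels.shape != cube.values.shape[:2]:
        raise ValueError("label image does not match cube spatial shape")
    counts = labels.region_counts()
    empty = np.nonzero(counts == 0)[0]
    if empty.size:
        raise ValueError(f"empty region(s) {(empty + 1).tolist()}")
    spectra = np.empty((labels.k, cube.grid.n_bands))
    for region in range(1, labels.k + 1):
        sel = labels.labels == region
        spectra[region - 1] = cube.values[sel].mean(axis=0)
    return make_spectra_table(
        [sample_code] * labels.k,
        np.arange(1, labels.k + 1),
        [ph_ref] * labels.k,
        spectra,
        cube.grid,
    )
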