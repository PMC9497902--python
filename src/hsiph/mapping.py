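"""Pixel-wise pH prediction maps.

The hypercube is unfolded to a (pixels x feature-wavelengths) matrix at the
reduced model's wavelengths, multiplied by the model's coefficient vector
(plus intercept), and refolded to a 2-D image; background pixels carry a
no-data marker (NaN in memory, a sentinel in CSV export, transparency in
PNG).  Rendering uses a linear color scale with a color bar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Hypercube
from .feature_selection import LinearSpectralModel
from .segmentation import SegmentationMask

__all__ = ["PredictionMap", "predict_map", "render_map", "NO_DATA"]

#: sentinel written for background pixels in CSV export
NO_DATA = -999.0


@dataclass
class PredictionMap:
    """2-D predicted-pH image; finite exactly on the mask, NaN elsewhere."""

    values: np.ndarray
    mask: SegmentationMask
    scale: tuple | None = None   # (min, max) display range

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.mask.mask.shape:
            raise ValueError("map and mask shapes differ")
        if self.scale is None:
            finite = self.values[np.isfinite(self.values)]
            self.scale = (float(finite.min()), float(finite.max())) \
                if finite.size else (0.0, 1.0)

    def to_csv(self, path: str) -> None:
        out = np.where(np.isfinite(self.values), self.values, NO_DATA)
        np.savetxt(path, out, delimiter=",", fmt="%.6g")


def predict_map(cube: Hypercube, model: LinearSpectralModel,
                mask: SegmentationMask) -> PredictionMap:
    """Apply a reduced linear model to every masked pixel.

    Unfolds the masked pixels at the model's wavelengths, applies
    ``intercept + coef . reflectance`` in one matrix product, and refolds to
    an image with NaN outside the mask.
    """
    if cube.domain != model.domain:
        raise ValueError(
            f"cube domain {cube.domain!r} does not match model domain {model.domain!r}")
    if mask.mask.shape != cube.values.shape[:2]:
        raise ValueError("mask does not match cube spatial shape")
    if not mask.mask.any():
        raise ValueError("empty mask: nothing to predict")
    idx = cube.grid.indices_of_wavelengths(model.wavelengths_nm)
    unfolded = cube.values[mask.mask][:, idx]                      # (n_pix, k)
    ph = model.intercept + unfolded @ np.asarray(model.coefficients)
    values = np.full(mask.mask.shape, np.nan)
    values[mask.mask] = ph
    return PredictionMap(values, mask)


def render_map(pmap: PredictionMap, out_path: str, palette: str = "jet",
               scale: tuple | None = None, title: str | None = None) -> None:
    """Render the map to PNG with a linear color scale and color bar.

    No-data pixels are transparent.  Encoder settings are fixed so the same
    inputs always produce the same bytes.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmin, vmax = scale if scale is not None else pmap.scale
    if not vmin < vmax:
        raise ValueError(f"scale min {vmin} must be < max {vmax}")
    cmap = plt.get_cmap(palette).copy()
    cmap.set_bad(alpha=0.0)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(np.ma.masked_invalid(pmap.values), cmap=cmap,
                   vmin=vmin, vmax=vmax, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="predicted pH")
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=110, metadata={"Software": "hsiph"})
    plt.close(fig)


def rgb_composite(cube: Hypercube, bands_nm: tuple = (640, 550, 460)) -> np.ndarray:
    """Simple 3-band composite (values clipped to [0, 1]) for side-by-side
    display next to prediction maps."""
    idx = cube.grid.indices_of_wavelengths(bands_nm)
    return np.clip(cube.values[:, :, idx], 0.0, 1.0)
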