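"""Synthetic phantoms with the statistical structure the analysis assumes.

Three generators make every pipeline stage testable without measured data:

* :func:`generate_phantom_hypercube` — a reflectance hypercube holding an
  elliptical "sausage" on a dark background.  The sausage spectrum is a
  smooth baseline with Gaussian absorption dips at the heme-pigment bands
  (418 / 544 / 574 / 582 nm) and the O-H overtone water bands (780 / 980
  nm); dip depths are coupled linearly to a latent pH field, per-pixel
  multiplicative gain and additive offset emulate the scatter effects that
  MSC/SNV correct, and the background stays below the 0.075 segmentation
  threshold at 695 nm.  Ground truth (mask, region labels, per-region mean
  pH) is returned alongside.  The depth-pH coupling is a fixture
  convention, not a chemical model.

* :func:`generate_spectra_table` — random smooth reflectance spectra with
  pH generated from a known linear rule plus Gaussian noise, for PLSR and
  feature-selection recovery tests.

* :func:`generate_rsm_responses` — responses from a known quadratic surface
  over a CCD, for response-surface recovery tests.

Each generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .core import (DEFAULT_GRID, Hypercube, SEGMENTATION_BAND,
                   SEGMENTATION_THRESHOLD, WavelengthGrid)
from .feature_selection import LinearSpectralModel, evaluate_linear_model
from .io import make_spectra_table
from .rsm import CCDDesign, QuadraticSurface, evaluate_surface
from .segmentation import RegionLabels, SegmentationMask, split_regions

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom_hypercube",
           "generate_spectra_table", "generate_rsm_responses"]

#: (center nm, width nm, base depth, pH coupling slope per pH unit)
DEFAULT_FEATURE_BANDS = (
    (418.0, 12.0, 0.30, 0.10),   # heme Soret band
    (544.0, 10.0, 0.22, 0.12),   # oxymyoglobin / oxyhemoglobin alpha
    (574.0, 10.0, 0.18, 0.12),   # oxyhemoglobin beta
    (582.0, 8.0, 0.15, 0.12),    # oxymyoglobin
    (780.0, 22.0, 0.08, 0.04),   # O-H third overtone (water)
    (980.0, 28.0, 0.15, 0.04),   # O-H second overtone (water)
)

#: smooth meat-like reflectance baseline knots (nm, reflectance)
DEFAULT_BASELINE_KNOTS = ((350.0, 0.16), (450.0, 0.22), (560.0, 0.30),
                          (695.0, 0.42), (850.0, 0.52), (1000.0, 0.50),
                          (1100.0, 0.44))


@dataclass
class PhantomSpec:
    """Full description of one synthetic sausage scene."""

    shape: tuple = (64, 96)               # rows, cols
    ellipse_center: tuple | None = None   # defaults to image center
    ellipse_axes: tuple = (22.0, 40.0)    # semi-axes (rows, cols)
    background_reflectance: float = 0.04
    baseline_knots: tuple = DEFAULT_BASELINE_KNOTS
    feature_bands: tuple = DEFAULT_FEATURE_BANDS
    ph_value: float = 5.45                # constant field, or gradient:
    ph_gradient: tuple | None = None      # (ph_at_left, ph_at_right) on major axis
    ph_mid: float = 5.45                  # pH at which dips sit at base depth
    gain_sd: float = 0.03                 # per-pixel multiplicative scatter
    offset_sd: float = 0.01               # per-pixel additive scatter
    noise_sd: float = 0.003               # per-element spectral noise
    n_regions: int = 5
    seed: int = 0
    grid: WavelengthGrid = field(default_factory=lambda: DEFAULT_GRID)


@dataclass
class PhantomTruth:
    """Generator-side ground truth emitted with each phantom cube."""

    mask: SegmentationMask
    labels: RegionLabels
    ph_field: np.ndarray
    region_mean_ph: np.ndarray


def _sausage_spectrum(spec: PhantomSpec, ph: np.ndarray) -> np.ndarray:
    """Noise-free sausage reflectance for an array of pH values: (n, bands)."""
    wl = spec.grid.wavelengths
    knots = np.asarray(spec.baseline_knots)
    baseline = PchipInterpolator(knots[:, 0], knots[:, 1])(wl)
    ph = np.atleast_1d(np.asarray(ph, dtype=float))
    transmit = np.ones((ph.size, wl.size))
    for center, width, base_depth, slope in spec.feature_bands:
        depth = np.clip(base_depth * (1.0 + slope * (spec.ph_mid - ph)), 0.0, 0.95)
        gauss = np.exp(-0.5 * ((wl - center) / width) ** 2)
        transmit *= 1.0 - depth[:, None] * gauss[None, :]
    return baseline[None, :] * transmit


def generate_phantom_hypercube(spec: PhantomSpec):
    """Build one phantom scene; returns ``(Hypercube, PhantomTruth)``.

    Raises if the spec cannot separate sausage from background at the
    segmentation band (reflectance 0.075 at 695 nm).
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    cy, cx = spec.ellipse_center or ((rows - 1) / 2.0, (cols - 1) / 2.0)
    ay, ax = spec.ellipse_axes
    yy, xx = np.mgrid[0:rows, 0:cols]
    mask = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    if not mask.any():
        raise ValueError("ellipse produces an empty mask")

    # latent pH per sausage pixel: constant or linear along the major axis
    ph_field = np.full((rows, cols), np.nan)
    if spec.ph_gradient is None:
        ph_field[mask] = spec.ph_value
    else:
        lo, hi = spec.ph_gradient
        major = xx if ax >= ay else yy
        m = major[mask]
        t = (m - m.min()) / max(m.max() - m.min(), 1)
        ph_field[mask] = lo + t * (hi - lo)

    # separability check at the segmentation band, at the extreme pH
    seg_idx = SEGMENTATION_BAND - 1
    ph_extremes = np.array([np.nanmin(ph_field), np.nanmax(ph_field)])
    sausage_at_695 = _sausage_spectrum(spec, ph_extremes)[:, seg_idx]
    if spec.background_reflectance >= SEGMENTATION_THRESHOLD:
        raise ValueError(
            f"background reflectance {spec.background_reflectance} is not "
            f"below the segmentation threshold {SEGMENTATION_THRESHOLD}")
    if sausage_at_695.min() * (1 - 3 * spec.gain_sd) - 3 * spec.offset_sd \
            <= SEGMENTATION_THRESHOLD:
        raise ValueError(
            "sausage reflectance at 695 nm is not safely above the "
            f"segmentation threshold {SEGMENTATION_THRESHOLD}")

    values = np.full((rows, cols, spec.grid.n_bands),
                     spec.background_reflectance)
    spectra = _sausage_spectrum(spec, ph_field[mask])
    gain = rng.normal(1.0, spec.gain_sd, size=(int(mask.sum()), 1))
    offset = rng.normal(0.0, spec.offset_sd, size=(int(mask.sum()), 1))
    values[mask] = spectra * gain + offset
    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=values.shape)
    values = np.clip(values, 1e-4, 1.2)

    cube = Hypercube(values, spec.grid, domain="reflectance")
    seg_mask = SegmentationMask(mask)
    labels = split_regions(seg_mask, spec.n_regions)
    region_ph = np.array([ph_field[labels.labels == r].mean()
                          for r in range(1, spec.n_regions + 1)])
    return cube, PhantomTruth(seg_mask, labels, ph_field, region_ph)


def _smooth_random_spectra(n: int, grid: WavelengthGrid,
                           rng: np.random.Generator) -> np.ndarray:
    """Random smooth reflectance spectra in roughly (0.05, 0.9)."""
    wl = grid.wavelengths
    span = wl[-1] - wl[0]
    X = np.empty((n, grid.n_bands))
    for i in range(n):
        level = rng.uniform(0.2, 0.6)
        slope = rng.uniform(-0.15, 0.25) / span
        x = level + slope * (wl - wl[0])
        for _ in range(rng.integers(3, 7)):
            center = rng.uniform(wl[0], wl[-1])
            width = rng.uniform(20, 120)
            amp = rng.uniform(-0.12, 0.12)
            x += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
        X[i] = np.clip(x, 0.05, 0.9)
    return X


def generate_spectra_table(n_samples: int, true_model: LinearSpectralModel,
                           noise_sd: float = 0.0, seed: int = 0,
                           regions_per_sample: int = 5,
                           grid: WavelengthGrid | None = None):
    """Spectra table whose pH obeys a known linear rule plus noise.

    Each of ``n_samples * regions_per_sample`` rows gets an independent
    smooth random reflectance spectrum; its reference pH is the true model
    evaluated at the model's wavelengths plus ``N(0, noise_sd^2)``, clipped
    into the physically admissible (0, 14) range.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    grid = grid or DEFAULT_GRID
    rng = np.random.default_rng(seed)
    n_rows = n_samples * regions_per_sample
    X = _smooth_random_spectra(n_rows, grid, rng)
    idx = grid.indices_of_wavelengths(true_model.wavelengths_nm)
    ph = np.array([evaluate_linear_model(true_model, x[idx]) for x in X])
    if noise_sd > 0:
        ph = ph + rng.normal(0.0, noise_sd, size=n_rows)
    ph = np.clip(ph, 0.05, 13.95)
    codes = [f"S{1 + i // regions_per_sample:03d}" for i in range(n_rows)]
    regions = [1 + i % regions_per_sample for i in range(n_rows)]
    return make_spectra_table(codes, regions, ph, X, grid)


def generate_rsm_responses(surface: QuadraticSurface, design: CCDDesign,
                           noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Responses from a known surface over the design, plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    y = np.array([evaluate_surface(surface, run) for run in design.uncoded])
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(y))
    return y
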