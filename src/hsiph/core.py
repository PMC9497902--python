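"""Wavelength-grid arithmetic, reflectance calibration, and reflectance/absorbance conversion.

Band indexing is **1-based** throughout the public interface: band ``i`` sits at
``start_nm + (i - 1) * step_nm``.  On the default visible--NIR grid
(350--1100 nm, 5 nm step, 151 bands) band 70 is 695 nm, the band used for
foreground segmentation.

Absorbance uses the standard chemometric convention ``A = -log10(R)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WavelengthGrid",
    "Hypercube",
    "CalibrationPair",
    "CalibrationError",
    "build_wavelength_grid",
    "calibrate_reflectance",
    "to_absorbance",
    "to_reflectance",
]

#: log base of the absorbance transform (decadic, Beer-Lambert convention)
ABSORBANCE_LOG_BASE = 10


class CalibrationError(ValueError):
    """Raised when the white-minus-dark denominator is not strictly positive."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid with inclusive endpoints and 1-based band index."""

    start_nm: float
    step_nm: float
    n_bands: int

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError(f"step_nm must be > 0, got {self.step_nm}")
        if self.n_bands < 2:
            raise ValueError(f"n_bands must be >= 2, got {self.n_bands}")

    @property
    def stop_nm(self) -> float:
        return self.start_nm + (self.n_bands - 1) * self.step_nm

    @property
    def wavelengths(self) -> np.ndarray:
        """All band wavelengths in nm, ascending."""
        return self.start_nm + self.step_nm * np.arange(self.n_bands)

    def wavelength_of_band(self, band: int) -> float:
        """Wavelength (nm) of 1-based band index ``band``."""
        if not 1 <= band <= self.n_bands:
            raise IndexError(f"band {band} outside 1..{self.n_bands}")
        return self.start_nm + (band - 1) * self.step_nm

    def band_of_wavelength(self, nm: float) -> int:
        """1-based band index of an on-grid wavelength; raises if off-grid."""
        pos = (nm - self.start_nm) / self.step_nm
        band = int(round(pos)) + 1
        if not 1 <= band <= self.n_bands or abs(pos - round(pos)) > 1e-9:
            raise ValueError(f"{nm} nm is not on the grid {self}")
        return band

    def indices_of_wavelengths(self, nms) -> np.ndarray:
        """0-based array indices for a sequence of on-grid wavelengths."""
        return np.array([self.band_of_wavelength(w) - 1 for w in nms], dtype=int)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.start_nm}-{self.stop_nm} nm / {self.step_nm} nm ({self.n_bands} bands)"


def build_wavelength_grid(start_nm: float, stop_nm: float, step_nm: float) -> WavelengthGrid:
    """Build an inclusive grid; ``(stop - start)`` must be divisible by ``step``."""
    if stop_nm <= start_nm:
        raise ValueError(f"stop_nm ({stop_nm}) must exceed start_nm ({start_nm})")
    span = stop_nm - start_nm
    n_steps = span / step_nm
    if abs(n_steps - round(n_steps)) > 1e-9:
        remainder = span - round(span / step_nm - 0.5) * step_nm
        raise ValueError(
            f"range {start_nm}-{stop_nm} nm is not divisible by step {step_nm} nm "
            f"(remainder {remainder:g} nm)"
        )
    return WavelengthGrid(start_nm, step_nm, int(round(n_steps)) + 1)


#: the acquisition grid of the visible--NIR line-scan camera this package targets
DEFAULT_GRID = build_wavelength_grid(350.0, 1100.0, 5.0)

#: 1-based segmentation band (695 nm on the default grid) and its threshold
SEGMENTATION_BAND = 70
SEGMENTATION_THRESHOLD = 0.075


@dataclass
class Hypercube:
    """3-D spectral image: ``values[row, col, band]`` plus its wavelength grid.

    ``domain`` tags the physical meaning of the values: ``raw`` camera counts,
    calibrated ``reflectance``, or decadic ``absorbance``.
    """

    values: np.ndarray
    grid: WavelengthGrid
    domain: str = "reflectance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"hypercube must be 3-D, got shape {self.values.shape}")
        if self.values.shape[2] != self.grid.n_bands:
            raise ValueError(
                f"third dimension {self.values.shape[2]} != grid bands {self.grid.n_bands}"
            )
        if self.domain not in ("raw", "reflectance", "absorbance"):
            raise ValueError(f"unknown domain tag {self.domain!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("hypercube values must be finite")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def band_image(self, band: int) -> np.ndarray:
        """2-D image at a 1-based band index."""
        if not 1 <= band <= self.grid.n_bands:
            raise IndexError(f"band {band} outside 1..{self.grid.n_bands}")
        return self.values[:, :, band - 1]


@dataclass
class CalibrationPair:
    """Dark (0 %) and white (100 %) reference images or per-band vectors."""

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        if self.dark.shape != self.white.shape:
            raise ValueError(
                f"dark {self.dark.shape} and white {self.white.shape} shapes differ"
            )
        if self.dark.ndim not in (1, 3):
            raise ValueError("references must be per-band vectors (1-D) or cubes (3-D)")


def calibrate_reflectance(raw: Hypercube, cal: CalibrationPair) -> Hypercube:
    """Convert raw counts to reflectance with dark/white references.

    Per band (and pixel, for cube-shaped references)::

        R = (raw - dark) / (white - dark)

    1-D references broadcast across all pixels.  Any non-positive
    ``white - dark`` denominator raises :class:`CalibrationError` naming the
    first offending 1-based band.
    """
    if raw.domain != "raw":
        raise ValueError(f"expected a raw cube, got domain {raw.domain!r}")
    denom = cal.white - cal.dark
    bad = denom <= 0
    if np.any(bad):
        band_axis = 0 if denom.ndim == 1 else 2
        bad_bands = np.nonzero(np.any(bad, axis=tuple(i for i in range(denom.ndim) if i != band_axis)))[0]
        raise CalibrationError(
            f"white - dark not strictly positive at band(s) {(bad_bands + 1).tolist()}"
        )
    values = (raw.values - cal.dark) / denom
    return Hypercube(values, raw.grid, domain="reflectance")


def _neg_log10(values: np.ndarray, clip: bool, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if clip:
        values = np.clip(values, 1e-6, None)
    elif np.any(values <= 0):
        loc = tuple(int(i) for i in
                    np.unravel_index(int(np.argmax(values <= 0)), values.shape))
        raise ValueError(
            f"non-positive {what} at index {loc}; pass clip=True to floor at 1e-6"
        )
    return -np.log10(values)


def to_absorbance(cube_or_spectrum, clip: bool = False):
    """Decadic absorbance ``A = -log10(R)`` of a reflectance cube or array.

    By default non-positive reflectance is an error (with its location);
    ``clip=True`` floors reflectance at 1e-6 first.
    """
    if isinstance(cube_or_spectrum, Hypercube):
        if cube_or_spectrum.domain != "reflectance":
            raise ValueError(f"expected reflectance, got {cube_or_spectrum.domain!r}")
        return Hypercube(
            _neg_log10(cube_or_spectrum.values, clip, "reflectance"),
            cube_or_spectrum.grid,
            domain="absorbance",
        )
    return _neg_log10(cube_or_spectrum, clip, "reflectance")


def to_reflectance(cube_or_spectrum):
    """Inverse of :func:`to_absorbance`: ``R = 10 ** (-A)``."""
    if isinstance(cube_or_spectrum, Hypercube):
        if cube_or_spectrum.domain != "absorbance":
            raise ValueError(f"expected absorbance, got {cube_or_spectrum.domain!r}")
        return Hypercube(
            10.0 ** (-cube_or_spectrum.values), cube_or_spectrum.grid, domain="reflectance"
        )
    return 10.0 ** (-np.asarray(cube_or_spectrum, dtype=float))
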