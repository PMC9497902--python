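"""Spectral pretreatment operators and ordered pretreatment chains.

Implemented operators:

* **SNV** — standard normal variate: per-spectrum centering and scaling to
  unit sample (n-1) standard deviation.
* **MSC** — multiplicative scatter correction: each spectrum is regressed on
  a reference spectrum by ordinary least squares, ``x ~ a + b * ref``, and
  corrected to ``(x - a) / b``.  The reference defaults to the calibration
  set's mean spectrum and is frozen when transforming prediction rows.
* **normalization** — unit absolute area: ``x / sum(|x|)``.
* **1st/2nd derivative** — Savitzky-Golay derivatives (default window 7,
  polynomial order 2 for the first derivative, 3 for the second), same-length
  output with polynomial edge handling; the derivative step is one band.

A :class:`PretreatmentChain` is an ordered list of these steps applied left
to right, specified by strings such as ``"Normalization + 1st Derivative"``
(case-insensitive, ``+`` denotes composition).  Chains may be applied in the
reflectance or absorbance domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .core import WavelengthGrid
from .io import spectra_matrix, wavelength_columns

__all__ = [
    "snv", "msc", "normalize", "derivative",
    "PretreatmentChain", "parse_chain", "apply_chain",
    "STANDARD_CHAINS",
]

#: the ten pretreatment labels evaluated per spectral domain
STANDARD_CHAINS = [
    "Raw",
    "1st Derivative",
    "2nd Derivative",
    "MSC",
    "SNV",
    "Normalization",
    "Normalization + 1st Derivative",
    "1st Derivative + Normalization",
    "Normalization + 2nd Derivative",
    "2nd Derivative + Normalization",
]

_STEP_ALIASES = {
    "raw": None,
    "snv": "snv",
    "msc": "msc",
    "normalization": "normalization",
    "normalisation": "normalization",
    "1st derivative": "first_derivative",
    "first derivative": "first_derivative",
    "first_derivative": "first_derivative",
    "2nd derivative": "second_derivative",
    "second derivative": "second_derivative",
    "second_derivative": "second_derivative",
}


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: ``(x - mean) / sd`` with the n-1 sd."""
    x = np.asarray(spectrum, dtype=float)
    sd = x.std(ddof=1)
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("SNV undefined for a constant spectrum (zero variance)")
    return (x - x.mean()) / sd


def msc(spectra: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative scatter correction of a (n, bands) stack.

    Each row is regressed on ``reference`` (default: the stack's mean
    spectrum) by OLS, ``x = a + b * ref``, and corrected to ``(x - a) / b``.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom <= 0:
        raise ValueError("MSC reference spectrum has zero variance")
    out = np.empty_like(X)
    for i, x in enumerate(X):
        b = (x - x.mean()) @ ref_c / denom
        if abs(b) < 1e-12:
            raise ValueError(f"MSC slope ~ 0 for spectrum {i}; correction undefined")
        a = x.mean() - b * ref.mean()
        out[i] = (x - a) / b
    return out if np.asarray(spectra).ndim == 2 else out[0]


def normalize(spectrum: np.ndarray) -> np.ndarray:
    """Area normalization to unit absolute area: ``x / sum(|x|)``."""
    x = np.asarray(spectrum, dtype=float)
    area = np.abs(x).sum()
    if area <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return x / area


def derivative(spectrum: np.ndarray, order: int, window: int = 7,
               polyorder: int | None = None) -> np.ndarray:
    """Savitzky-Golay derivative (per band step), same length as the input."""
    if order not in (1, 2):
        raise ValueError(f"derivative order must be 1 or 2, got {order}")
    x = np.asarray(spectrum, dtype=float)
    if polyorder is None:
        polyorder = 2 if order == 1 else 3
    if x.shape[-1] < window:
        raise ValueError(f"spectrum length {x.shape[-1]} shorter than window {window}")
    return savgol_filter(x, window_length=window, polyorder=polyorder,
                         deriv=order, delta=1.0, mode="interp", axis=-1)


@dataclass
class PretreatmentChain:
    """Ordered pretreatment steps plus the spectral domain they act in.

    ``fit``/``transform`` follow the usual estimator contract: reference
    statistics (the MSC reference spectrum) are learned from the calibration
    block during :meth:`fit_transform` and frozen for later
    :meth:`transform` calls, so prediction rows never leak into them.
    """

    steps: list = field(default_factory=list)
    domain: str = "reflectance"
    label: str = "Raw"
    sg_window: int = 7
    _msc_references: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.domain not in ("reflectance", "absorbance"):
            raise ValueError(f"unknown chain domain {self.domain!r}")
        for step in self.steps:
            if step not in ("snv", "msc", "normalization",
                            "first_derivative", "second_derivative"):
                raise ValueError(f"unknown pretreatment step {step!r}")

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        self._msc_references = []
        return self._run(np.asarray(X, dtype=float), fitting=True)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self._run(np.asarray(X, dtype=float), fitting=False)

    def _run(self, X: np.ndarray, fitting: bool) -> np.ndarray:
        X = np.atleast_2d(X).copy()
        msc_slot = 0
        for step in self.steps:
            if step == "snv":
                X = np.vstack([snv(x) for x in X])
            elif step == "normalization":
                X = np.vstack([normalize(x) for x in X])
            elif step == "first_derivative":
                X = derivative(X, 1, window=self.sg_window)
            elif step == "second_derivative":
                X = derivative(X, 2, window=self.sg_window)
            elif step == "msc":
                if fitting:
                    self._msc_references.append(X.mean(axis=0))
                elif msc_slot >= len(self._msc_references):
                    raise RuntimeError("chain with MSC must be fit before transform")
                X = msc(X, self._msc_references[msc_slot])
                msc_slot += 1
        return X


def parse_chain(label: str, domain: str = "reflectance",
                sg_window: int = 7) -> PretreatmentChain:
    """Parse a chain label like ``"Normalization + 1st Derivative"``.

    Parsing is case-insensitive; ``+`` composes steps left to right and
    ``"Raw"`` denotes the empty chain.
    """
    steps = []
    for token in label.split("+"):
        key = token.strip().lower()
        if key not in _STEP_ALIASES:
            raise ValueError(f"unknown pretreatment {token.strip()!r} in chain {label!r}")
        step = _STEP_ALIASES[key]
        if step is not None:
            steps.append(step)
    return PretreatmentChain(steps, domain=domain, label=label.strip(),
                             sg_window=sg_window)


def apply_chain(table: pd.DataFrame, chain: PretreatmentChain,
                grid: WavelengthGrid,
                calibration_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Apply a chain to a spectra table, fitting references on calibration rows.

    ``calibration_mask`` marks the rows on which reference statistics (MSC
    reference) are learned; remaining rows are transformed with those frozen
    statistics.  With no mask, all rows are treated as calibration.
    """
    X = spectra_matrix(table, grid)
    cols = wavelength_columns(grid)
    out = table.copy()
    if calibration_mask is None:
        out[cols] = chain.fit_transform(X)
        return out
    calibration_mask = np.asarray(calibration_mask, dtype=bool)
    out.loc[calibration_mask, cols] = chain.fit_transform(X[calibration_mask])
    if (~calibration_mask).any():
        out.loc[~calibration_mask, cols] = chain.transform(X[~calibration_mask])
    return out
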