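"""Feature-wavelength selection from the PLSR coefficient profile.

Wavelengths carrying most of the predictive weight sit at the peaks and
valleys of the collapsed PLSR regression-coefficient vector.  Selection
finds local extrema of that vector (strict sign change of its first
difference), ranks them by absolute coefficient, greedily enforces a minimum
band separation, and keeps the top ``k``.  A reduced PLSR refit on those
bands is then collapsed to an explicit linear rule::

    pH = intercept + sum_j  c_j * x(lambda_j)

held by :class:`LinearSpectralModel`, which also powers pixel-wise
prediction maps.

A built-in preset (:data:`PRESET_FEATURE_WAVELENGTHS_NM`,
:func:`preset_reduced_model`) ships a published 12-wavelength sausage-pH
rule for demonstration and map rendering when no calibration data are at
hand.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics import PLSRModel, ModelMetrics, evaluate_chain_model, predict
from .core import WavelengthGrid
from .io import spectra_matrix, wavelength_columns
from .preprocessing import PretreatmentChain

__all__ = [
    "LinearSpectralModel",
    "select_feature_wavelengths",
    "build_reduced_model",
    "evaluate_linear_model",
    "PRESET_FEATURE_WAVELENGTHS_NM",
    "preset_reduced_model",
    "reduction_percent",
]

#: preset 12 feature wavelengths (nm) for sausage pH on the 350-1100 nm grid
PRESET_FEATURE_WAVELENGTHS_NM = (365, 385, 405, 475, 525, 580, 640, 725,
                                 875, 915, 1005, 1060)

_PRESET_INTERCEPT = 5.335
_PRESET_COEFFICIENTS = (7.243, -0.060, 7.461, -4.098, 3.594, 4.443,
                        -5.920, -4.083, -3.246, 4.495, 3.520, -9.730)


@dataclass
class LinearSpectralModel:
    """Explicit intercept + per-wavelength coefficient rule on reflectance.

    ``terms`` pair strictly increasing on-grid wavelengths (nm) with their
    coefficients (pH per unit reflectance).
    """

    intercept: float
    wavelengths_nm: tuple
    coefficients: tuple
    domain: str = "reflectance"
    chain_label: str = "Raw"

    def __post_init__(self) -> None:
        if len(self.wavelengths_nm) != len(self.coefficients):
            raise ValueError("wavelengths and coefficients differ in length")
        w = np.asarray(self.wavelengths_nm, dtype=float)
        if w.size and np.any(np.diff(w) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        self.wavelengths_nm = tuple(float(x) for x in self.wavelengths_nm)
        self.coefficients = tuple(float(x) for x in self.coefficients)

    @property
    def terms(self) -> list:
        return list(zip(self.wavelengths_nm, self.coefficients))

    def formula(self) -> str:
        """Human-readable one-line formula."""
        parts = [f"{self.intercept:.3f}"]
        for w, c in self.terms:
            parts.append(f"{'+' if c >= 0 else '-'} {abs(c):.3f}*x({w:g}nm)")
        return "pH = " + " ".join(parts)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({
                "intercept": self.intercept,
                "wavelengths_nm": list(self.wavelengths_nm),
                "coefficients": list(self.coefficients),
                "domain": self.domain,
                "chain": self.chain_label,
                "formula": self.formula(),
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "LinearSpectralModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["intercept"], tuple(d["wavelengths_nm"]),
                   tuple(d["coefficients"]), domain=d.get("domain", "reflectance"),
                   chain_label=d.get("chain", "Raw"))


def preset_reduced_model() -> LinearSpectralModel:
    """The built-in 12-wavelength reflectance-domain pH rule."""
    return LinearSpectralModel(_PRESET_INTERCEPT, PRESET_FEATURE_WAVELENGTHS_NM,
                               _PRESET_COEFFICIENTS, domain="reflectance",
                               chain_label="Raw")


def select_feature_wavelengths(model: PLSRModel, grid: WavelengthGrid,
                               k: int = 12,
                               min_separation_bands: int = 2) -> list:
    """Feature wavelengths at local extrema of the coefficient vector.

    Extrema are interior bands where the first difference of the coefficient
    vector strictly changes sign; they are ranked by absolute coefficient and
    kept greedily subject to a minimum index separation, then truncated to
    ``k`` and returned sorted ascending.  Fewer than ``k`` extrema triggers a
    warning and returns all found.
    """
    b = np.asarray(model.coef, dtype=float)
    if b.shape[0] != grid.n_bands:
        raise ValueError("model coefficient length does not match the grid")
    d = np.diff(b)
    interior = np.arange(1, b.size - 1)
    extrema = interior[d[interior - 1] * d[interior] < 0]
    kept: list = []
    for idx in sorted(extrema, key=lambda i: -abs(b[i])):
        if all(abs(idx - j) >= min_separation_bands for j in kept):
            kept.append(idx)
        if len(kept) == k:
            break
    if len(kept) < k:
        warnings.warn(
            f"only {len(kept)} coefficient extrema found, fewer than k={k}",
            stacklevel=2)
    return sorted(grid.wavelength_of_band(i + 1) for i in kept)


def build_reduced_model(cal: pd.DataFrame, wavelengths_nm, chain: PretreatmentChain,
                        grid: WavelengthGrid, n_latent: int,
                        pred: pd.DataFrame | None = None,
                        cv_scheme: str = "loo", cv_k: int | None = None,
                        cv_seed: int = 0):
    """Refit PLSR on a wavelength subset and collapse to a linear rule.

    Returns ``(LinearSpectralModel, ModelMetrics)``; the metric record has
    the same layout as the full-spectrum one so reduced and full models can
    be tabulated side by side.
    """
    wavelengths_nm = list(wavelengths_nm)
    if len(set(wavelengths_nm)) != len(wavelengths_nm):
        raise ValueError("duplicate wavelengths in the feature set")
    idx = grid.indices_of_wavelengths(wavelengths_nm)  # validates on-grid
    order = np.argsort(idx)
    idx, wavelengths_nm = idx[order], [wavelengths_nm[i] for i in order]

    sub_grid_cols = [wavelength_columns(grid)[i] for i in idx]
    reduced_cal = cal[["sample_code", "region_id", "pH_ref"] + sub_grid_cols]
    reduced_pred = None if pred is None else \
        pred[["sample_code", "region_id", "pH_ref"] + sub_grid_cols]

    sub_grid = _SubsetGrid(sub_grid_cols)
    model, metrics = evaluate_chain_model(
        reduced_cal, reduced_pred, chain, sub_grid,
        min(n_latent, len(idx)), cv_scheme=cv_scheme, cv_k=cv_k,
        cv_seed=cv_seed)
    linear = LinearSpectralModel(
        model.intercept, tuple(float(w) for w in wavelengths_nm),
        tuple(model.coef.tolist()), domain=chain.domain,
        chain_label=chain.label)
    return linear, metrics


class _SubsetGrid:
    """Duck-typed stand-in for WavelengthGrid over a wavelength subset."""

    def __init__(self, columns: list) -> None:
        self._columns = columns
        self.n_bands = len(columns)

    @property
    def wavelengths(self) -> np.ndarray:
        return np.array([float(c[1:]) for c in self._columns])


def evaluate_linear_model(model: LinearSpectralModel, reflectances) -> float:
    """``intercept + sum(coef * reflectance)`` for one spectrum at the model's
    wavelengths (in ascending wavelength order)."""
    x = np.asarray(reflectances, dtype=float).ravel()
    if x.size != len(model.coefficients):
        raise ValueError(
            f"expected {len(model.coefficients)} reflectances, got {x.size}")
    return float(model.intercept + x @ np.asarray(model.coefficients))


def reduction_percent(n_selected: int, n_total: int) -> int:
    """Percent of wavelengths removed, rounded to the nearest percent."""
    return int(round(100 * (1 - n_selected / n_total)))
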