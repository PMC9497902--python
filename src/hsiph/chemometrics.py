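"""Calibration/prediction splitting, NIPALS partial least squares regression,
prediction, and the R²/RMSE metric suite with cross-validation.

The regression model relates region-mean spectra ``X`` (rows × bands) to a
reference pH ``y``.  PLSR is fit with the classical NIPALS algorithm on
mean-centered data and collapsed to the linear form ``y_hat = b0 + X @ b``,
whose coefficient vector ``b`` over wavelengths is what feature-wavelength
selection later inspects.

Metrics follow the standard chemometric definitions::

    R^2  = 1 - sum((y_i - y_pred_i)^2) / sum((y_i - y_mean)^2)
    RMSE = sqrt(sum((y_i - y_pred_i)^2) / n)

where ``y_mean`` is the mean of the evaluated set itself (so calibration,
prediction and cross-validation R² each use their own group mean).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import spectra_matrix
from .preprocessing import PretreatmentChain

__all__ = [
    "PLSRModel", "ModelMetrics",
    "split_calibration_prediction", "fit_plsr", "predict",
    "compute_metrics", "cross_validate", "select_n_latent",
    "evaluate_chain_model", "is_good_model",
]


@dataclass
class PLSRModel:
    """NIPALS PLS1 model collapsed to intercept + coefficient form.

    ``weights`` (W), ``x_loadings`` (P) and ``y_loadings`` (q) hold one
    column/entry per latent variable; ``coef``/``intercept`` are the
    equivalent single linear rule ``y_hat = intercept + x @ coef``.
    """

    n_latent: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # (bands, n_latent)
    x_loadings: np.ndarray   # (bands, n_latent)
    y_loadings: np.ndarray   # (n_latent,)
    coef: np.ndarray         # (bands,)
    intercept: float
    chain_label: str = "Raw"
    scores: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_bands(self) -> int:
        return self.coef.shape[0]

    def to_json(self, path: str, extra: dict | None = None) -> None:
        payload = {
            "n_latent": self.n_latent,
            "chain": self.chain_label,
            "intercept": float(self.intercept),
            "coef": self.coef.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
        }
        if extra:
            payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class ModelMetrics:
    """One record of calibration / prediction / cross-validation figures."""

    Rc2: float = np.nan
    RMSEC: float = np.nan
    Rp2: float = np.nan
    RMSEP: float = np.nan
    Rcv2: float = np.nan
    RMSECV: float = np.nan

    def as_dict(self) -> dict:
        return asdict(self)


def split_calibration_prediction(table: pd.DataFrame, fraction: float = 2 / 3,
                                 seed: int = 0, by_sample: bool = False):
    """Random row-wise split into calibration (``ceil(fraction * n)``) and
    prediction groups; disjoint, exhaustive and seed-reproducible.

    ``by_sample=True`` groups rows by ``sample_code`` so all five region
    spectra of one sausage land in the same group.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if len(table) == 0:
        raise ValueError("cannot split an empty table")
    rng = np.random.default_rng(seed)
    if by_sample:
        codes = table["sample_code"].unique()
        n_cal = int(np.ceil(fraction * len(codes)))
        cal_codes = set(rng.permutation(codes)[:n_cal])
        cal_mask = table["sample_code"].isin(cal_codes).to_numpy()
    else:
        n_cal = int(np.ceil(fraction * len(table)))
        order = rng.permutation(len(table))
        cal_mask = np.zeros(len(table), dtype=bool)
        cal_mask[order[:n_cal]] = True
    return table.loc[cal_mask], table.loc[~cal_mask]


def fit_plsr(X: np.ndarray, y: np.ndarray, n_latent: int,
             tol: float = 1e-10, max_iter: int = 500) -> PLSRModel:
    """Fit PLS1 by NIPALS with deflation on mean-centered ``X`` and ``y``.

    Successive score vectors are mutually orthogonal; the latent-variable
    path and the collapsed ``intercept + X @ coef`` form give identical
    predictions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n or n < 2:
        raise ValueError(f"X has {n} rows but y has {len(y)} (need >= 2)")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance; PLSR undefined")
    max_rank = min(n - 1, p)
    if not 1 <= n_latent <= max_rank:
        raise ValueError(f"n_latent must be in 1..{max_rank}, got {n_latent}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.zeros((p, n_latent))
    P = np.zeros((p, n_latent))
    q = np.zeros(n_latent)
    T = np.zeros((n, n_latent))
    for a in range(n_latent):
        u = yc.copy()
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = Xc.T @ u
            norm = np.linalg.norm(w_new)
            if norm == 0:
                raise ValueError(f"X deflated to zero at latent variable {a + 1}")
            w_new /= norm
            t = Xc @ w_new
            tt = t @ t
            if tt == 0:
                raise ValueError(f"degenerate score vector at latent variable {a + 1}")
            q_a = (yc @ t) / tt
            u_new = yc * q_a
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w, u = w_new, u_new
        t = Xc @ w
        tt = t @ t
        p_a = Xc.T @ t / tt
        q_a = (yc @ t) / tt
        Xc = Xc - np.outer(t, p_a)
        yc = yc - q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t

    # collapse: b = W (P^T W)^{-1} q ; intercept = y_mean - x_mean . b
    coef = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - float(x_mean @ coef)
    return PLSRModel(n_latent, x_mean, y_mean, W, P, q, coef, intercept,
                     scores=T)


def predict(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    """``y_hat = intercept + X @ coef``; validates the band count."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_bands:
        raise ValueError(
            f"X has {X.shape[1]} bands but the model expects {model.n_bands}"
        )
    return model.intercept + X @ model.coef


def compute_metrics(y: np.ndarray, y_hat: np.ndarray):
    """Return ``(R2, RMSE)`` for one evaluated set (its own mean in R²)."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("y and y_hat must have equal length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: y has zero variance")
    ss_res = float(np.sum((y - y_hat) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / y.size))
    return r2, rmse


def _fold_indices(n: int, scheme: str, k: int | None, seed: int | None):
    if scheme == "loo":
        return [np.array([i]) for i in range(n)]
    if scheme == "kfold":
        if k is None or k < 2 or k > n:
            raise ValueError(f"kfold requires 2 <= k <= n, got k={k}, n={n}")
        order = np.random.default_rng(seed).permutation(n)
        return [order[i::k] for i in range(k)]
    raise ValueError(f"unknown CV scheme {scheme!r}")


def cross_validate(X: np.ndarray, y: np.ndarray, n_latent: int,
                   chain: PretreatmentChain | None = None,
                   scheme: str = "loo", k: int | None = None,
                   seed: int | None = 0, fold_callback=None):
    """Pooled out-of-fold ``(Rcv2, RMSECV)``.

    The full pipeline — pretreatment-chain statistics *and* the PLSR fit —
    is re-learned inside every fold, so cross-validation sees no statistic
    computed from its held-out rows.  ``fold_callback`` (if given) is called
    once per refit with the fold's test indices.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.empty_like(y)
    for test_idx in _fold_indices(len(y), scheme, k, seed):
        train = np.ones(len(y), dtype=bool)
        train[test_idx] = False
        X_train, X_test = X[train], X[test_idx]
        if chain is not None and chain.steps:
            X_train = chain.fit_transform(X_train)
            X_test = chain.transform(X_test)
        lv = min(n_latent, int(train.sum()) - 1, X.shape[1])
        model = fit_plsr(X_train, y[train], lv)
        y_hat[test_idx] = predict(model, X_test)
        if fold_callback is not None:
            fold_callback(test_idx)
    return compute_metrics(y, y_hat)


def select_n_latent(X: np.ndarray, y: np.ndarray, max_lv: int,
                    chain: PretreatmentChain | None = None,
                    scheme: str = "loo", k: int | None = None,
                    seed: int | None = 0) -> int:
    """Smallest latent-variable count whose RMSECV is within 2 % of the
    global minimum over ``1..max_lv`` (parsimony rule)."""
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    max_lv = min(max_lv, len(y) - 2, X.shape[1])
    rmsecvs = []
    for lv in range(1, max_lv + 1):
        _, rmsecv = cross_validate(X, y, lv, chain=chain, scheme=scheme,
                                   k=k, seed=seed)
        rmsecvs.append(rmsecv)
    best = min(rmsecvs)
    for lv, rmsecv in enumerate(rmsecvs, start=1):
        if rmsecv <= best * 1.02:
            return lv
    return len(rmsecvs)  # pragma: no cover - loop always returns


def evaluate_chain_model(cal: pd.DataFrame, pred: pd.DataFrame,
                         chain: PretreatmentChain, grid, n_latent: int,
                         cv_scheme: str = "loo", cv_k: int | None = None,
                         cv_seed: int = 0):
    """Fit one (chain, PLSR) configuration and fill a full metric record.

    Chain statistics are learned on the calibration rows and frozen for the
    prediction rows; cross-validation re-learns them per fold.
    """
    X_cal_raw = spectra_matrix(cal, grid)
    y_cal = cal["pH_ref"].to_numpy(dtype=float)
    X_cal = chain.fit_transform(X_cal_raw)
    lv = min(n_latent, len(y_cal) - 1, X_cal.shape[1])
    model = fit_plsr(X_cal, y_cal, lv)
    model.chain_label = chain.label
    rc2, rmsec = compute_metrics(y_cal, predict(model, X_cal))
    metrics = ModelMetrics(Rc2=rc2, RMSEC=rmsec)
    if pred is not None and len(pred):
        X_pred = chain.transform(spectra_matrix(pred, grid))
        y_pred = pred["pH_ref"].to_numpy(dtype=float)
        metrics.Rp2, metrics.RMSEP = compute_metrics(y_pred, predict(model, X_pred))
    metrics.Rcv2, metrics.RMSECV = cross_validate(
        X_cal_raw, y_cal, lv, chain=chain, scheme=cv_scheme, k=cv_k, seed=cv_seed)
    return model, metrics


def is_good_model(metrics: ModelMetrics, r2_min: float = 0.66,
                  rmse_max: float = 0.6, gap_max: float = 0.1) -> bool:
    """Quality gate: high R², low RMSE, and a small |RMSEC - RMSECV| gap."""
    gap = abs(metrics.RMSEC - metrics.RMSECV)
    return (metrics.Rc2 >= r2_min and metrics.RMSEC <= rmse_max
            and np.isfinite(gap) and gap <= gap_max)
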