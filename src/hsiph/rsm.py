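"""Central composite design and response-surface methodology for the
five-factor casing-modification experiment.

The design is a half-fraction 2^(5-1) factorial core (defining relation
``X5 = X1 * X2 * X3 * X4``), 10 axial runs at coded distance alpha = 2, and
replicated center runs (default 6), i.e. 32 runs in total.  The response
(sausage pH after storage) is modelled by the full quadratic polynomial

    y = b0 + sum_a b_a X_a + sum_a b_aa X_a^2 + sum_{a<b} b_ab X_a X_b

with 21 coefficients in uncoded factor units, fit by ordinary least squares.
The ANOVA decomposition uses adjusted (Type III, drop-term refit) sums of
squares and splits the residual into lack-of-fit and pure error (from the
center replicates), with F tests against the residual mean square.

Presets carry the five casing-modification factors (soy lecithin %, soy
oil %, orange extracts %, lactic acid mL/kg NaCl, treatment time min) and a
published fitted pH surface usable as ground truth in simulations.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FactorSpec", "CCDDesign", "QuadraticSurface",
    "generate_ccd", "code_transform", "fit_quadratic_surface",
    "anova_quadratic", "evaluate_surface", "contour_grid",
    "preset_factors", "preset_surface", "PRESET_TABLE_UNCODED",
]


@dataclass(frozen=True)
class FactorSpec:
    """One design factor with its affine coded <-> uncoded map."""

    name: str
    center: float
    halfrange: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.halfrange <= 0:
            raise ValueError(f"halfrange must be > 0 for {self.name}")

    def to_uncoded(self, coded: float) -> float:
        return self.center + coded * self.halfrange

    def to_coded(self, uncoded: float) -> float:
        return (uncoded - self.center) / self.halfrange


def code_transform(factor: FactorSpec, value: float, direction: str) -> float:
    """Affine coded/uncoded transform; ``direction`` is ``to_coded`` or
    ``to_uncoded``."""
    if direction == "to_coded":
        return factor.to_coded(value)
    if direction == "to_uncoded":
        return factor.to_uncoded(value)
    raise ValueError(f"direction must be to_coded|to_uncoded, got {direction!r}")


def preset_factors() -> list:
    """The five casing-modification factors (centers from the design's center
    runs, half-ranges from its +/-1 factorial levels)."""
    return [
        FactorSpec("X1", 3.16, 1.04, "% w/w soy lecithin"),
        FactorSpec("X2", 1.78, 0.60, "% w/w soy oil"),
        FactorSpec("X3", 0.26, 0.14, "% w/w orange extracts"),
        FactorSpec("X4", 19.50, 1.50, "mL/kg NaCl lactic acid"),
        FactorSpec("X5", 75.0, 15.0, "min treatment time"),
    ]


@dataclass
class CCDDesign:
    """Coded + uncoded run matrices of the central composite design."""

    factors: list
    alpha: float
    n_center: int
    coded: np.ndarray      # (n_runs, 5) in run order
    run_type: list         # "factorial" | "axial" | "center" per run

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def uncoded(self) -> np.ndarray:
        centers = np.array([f.center for f in self.factors])
        halves = np.array([f.halfrange for f in self.factors])
        return centers + self.coded * halves

    def to_frame(self) -> pd.DataFrame:
        names = [f.name for f in self.factors]
        frame = pd.DataFrame(self.coded, columns=[f"{n}_coded" for n in names])
        for j, n in enumerate(names):
            frame[n] = self.uncoded[:, j]
        frame.insert(0, "run", np.arange(1, self.n_runs + 1))
        frame.insert(1, "type", self.run_type)
        return frame


def generate_ccd(factors: list | None = None, alpha: float = 2.0,
                 n_center: int = 6, seed: int | None = None,
                 allow_non5: bool = False) -> CCDDesign:
    """Half-fraction CCD: 2^(5-1) factorial core with ``X5 = X1*X2*X3*X4``,
    10 axial runs at +/-alpha, and ``n_center`` center replicates (32 runs
    at the defaults).  ``seed`` shuffles the run order; ``None`` keeps
    standard order (factorial, axial, center)."""
    if factors is None:
        factors = preset_factors()
    n_fac = len(factors)
    if n_fac != 5 and not allow_non5:
        raise ValueError(
            f"this design is defined for 5 factors, got {n_fac} "
            "(pass allow_non5=True for a full-factorial core generalization)")
    rows = []
    types = []
    if n_fac == 5:
        for combo in itertools.product((-1.0, 1.0), repeat=4):
            rows.append(list(combo) + [float(np.prod(combo))])
            types.append("factorial")
    else:  # full factorial core for the generalization
        for combo in itertools.product((-1.0, 1.0), repeat=n_fac):
            rows.append(list(combo))
            types.append("factorial")
    for j in range(n_fac):
        for sign in (-1.0, 1.0):
            row = [0.0] * n_fac
            row[j] = sign * alpha
            rows.append(row)
            types.append("axial")
    for _ in range(n_center):
        rows.append([0.0] * n_fac)
        types.append("center")
    coded = np.array(rows)
    if seed is not None:
        order = np.random.default_rng(seed).permutation(len(rows))
        coded = coded[order]
        types = [types[i] for i in order]
    return CCDDesign(list(factors), alpha, n_center, coded, types)


_INTER_PAIRS = [(a, b) for a in range(5) for b in range(a + 1, 5)]


@dataclass
class QuadraticSurface:
    """21-coefficient quadratic response surface in uncoded factor units."""

    beta0: float
    beta_linear: np.ndarray            # (5,)
    beta_quad: np.ndarray              # (5,)
    beta_inter: np.ndarray             # (10,), pairs (1,2),(1,3)...(4,5)

    def __post_init__(self) -> None:
        self.beta_linear = np.asarray(self.beta_linear, dtype=float)
        self.beta_quad = np.asarray(self.beta_quad, dtype=float)
        self.beta_inter = np.asarray(self.beta_inter, dtype=float)
        if (self.beta_linear.shape, self.beta_quad.shape,
                self.beta_inter.shape) != ((5,), (5,), (10,)):
            raise ValueError("surface needs 5 linear, 5 quadratic, 10 interaction terms")

    def coefficients(self) -> np.ndarray:
        return np.concatenate(([self.beta0], self.beta_linear,
                               self.beta_quad, self.beta_inter))

    def to_json(self, path: str) -> None:
        names = (["beta0"] + [f"b{a+1}" for a in range(5)]
                 + [f"b{a+1}{a+1}" for a in range(5)]
                 + [f"b{a+1}{b+1}" for a, b in _INTER_PAIRS])
        with open(path, "w") as fh:
            json.dump(dict(zip(names, self.coefficients().tolist())), fh, indent=1)


def preset_surface() -> QuadraticSurface:
    """Published fitted pH surface over the five casing-modification factors
    (uncoded units); useful as simulation ground truth and for contouring."""
    return QuadraticSurface(
        beta0=59.0,
        beta_linear=[1.52, -9.07, -8.40, -3.84, -0.252],
        beta_quad=[-0.052, 0.426, 7.82, 0.0635, 0.0007],
        beta_inter=[0.0110, -3.27, -0.016, -0.0035, 2.07,
                    0.272, 0.0216, 1.00, -0.1109, 0.0086],
    )


def _basis(X: np.ndarray) -> np.ndarray:
    """(n, 21) quadratic basis: 1, X_a, X_a^2, X_a X_b (a < b)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cols = [np.ones(len(X))]
    cols += [X[:, a] for a in range(5)]
    cols += [X[:, a] ** 2 for a in range(5)]
    cols += [X[:, a] * X[:, b] for a, b in _INTER_PAIRS]
    return np.column_stack(cols)


def evaluate_surface(surface: QuadraticSurface, x) -> float:
    """Exact polynomial evaluation at one uncoded 5-vector."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != 5:
        raise ValueError(f"expected 5 factor values, got {x.size}")
    return float((_basis(x[None, :]) @ surface.coefficients())[0])


def fit_quadratic_surface(design: CCDDesign, responses) -> QuadraticSurface:
    """OLS fit of the 21-term quadratic basis in uncoded units."""
    y = np.asarray(responses, dtype=float).ravel()
    if len(y) != design.n_runs:
        raise ValueError(f"{len(y)} responses for {design.n_runs} runs")
    B = _basis(design.uncoded)
    if np.linalg.matrix_rank(B) < B.shape[1]:
        raise ValueError("design basis is rank-deficient; cannot fit 21 terms")
    beta, *_ = np.linalg.lstsq(B, y, rcond=None)
    return QuadraticSurface(float(beta[0]), beta[1:6], beta[6:11], beta[11:21])


def _sse(B: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(B, y, rcond=None)
    return float(np.sum((y - B @ beta) ** 2))


def anova_quadratic(design: CCDDesign, responses,
                    surface: QuadraticSurface | None = None) -> pd.DataFrame:
    """ANOVA table with adjusted (Type III) sums of squares.

    Rows: Model, Linear, each X_a, Square, each X_a^2, 2-Way Interaction,
    each X_a*X_b, Error, Lack-of-Fit, Pure Error, Total.  Each term's
    adjusted SS is the SSE increase from dropping that term (or term group)
    from the full 21-term model; F tests use the residual mean square.
    Lack-of-fit tests model adequacy against pure error from the center
    replicates; with no replicates those rows are omitted with a warning.
    """
    y = np.asarray(responses, dtype=float).ravel()
    n = len(y)
    if n != design.n_runs:
        raise ValueError(f"{n} responses for {design.n_runs} runs")
    B = _basis(design.uncoded)
    p = B.shape[1]
    sse_full = _sse(B, y)
    sst = float(np.sum((y - y.mean()) ** 2))
    df_model, df_error = p - 1, n - p
    mse = sse_full / df_error if df_error > 0 else np.nan

    # column indices of the basis: 0 intercept, 1..5 linear, 6..10 square,
    # 11..20 interactions
    factor_names = [f.name for f in design.factors]
    groups = [("Model", list(range(1, 21))),
              ("Linear", list(range(1, 6)))]
    groups += [(factor_names[a], [1 + a]) for a in range(5)]
    groups += [("Square", list(range(6, 11)))]
    groups += [(f"{factor_names[a]}*{factor_names[a]}", [6 + a]) for a in range(5)]
    groups += [("2-Way Interaction", list(range(11, 21)))]
    groups += [(f"{factor_names[a]}*{factor_names[b]}", [11 + k])
               for k, (a, b) in enumerate(_INTER_PAIRS)]

    rows = []
    for name, cols in groups:
        if name == "Model":
            ss = sst - sse_full
        else:
            keep = [c for c in range(p) if c not in cols]
            ss = _sse(B[:, keep], y) - sse_full
        df = len(cols)
        F = (ss / df) / mse if df_error > 0 else np.nan
        pval = float(stats.f.sf(F, df, df_error)) if df_error > 0 else np.nan
        rows.append((name, df, ss, F, pval))

    # replicate (pure error) decomposition from duplicated design points
    frame = pd.DataFrame(design.coded)
    rep_groups = frame.groupby(list(frame.columns), sort=False).indices.values()
    ss_pe = sum(float(np.sum((y[list(ix)] - y[list(ix)].mean()) ** 2))
                for ix in rep_groups if len(ix) > 1)
    df_pe = sum(len(ix) - 1 for ix in rep_groups if len(ix) > 1)

    error_rows = [("Error", df_error, sse_full, np.nan, np.nan)]
    if df_pe > 0:
        ss_lof = max(sse_full - ss_pe, 0.0)
        df_lof = df_error - df_pe
        if df_lof > 0 and ss_pe > 0:
            f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
            p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
        else:  # exact fit or no lack-of-fit dof: the F ratio is undefined
            f_lof, p_lof = np.nan, np.nan
        error_rows += [("Lack of Fit", df_lof, ss_lof, f_lof, p_lof),
                       ("Pure Error", df_pe, ss_pe, np.nan, np.nan)]
    else:
        import warnings
        warnings.warn("no replicated design points: lack-of-fit rows omitted",
                      stacklevel=2)
    error_rows.append(("Total", n - 1, sst, np.nan, np.nan))

    table = pd.DataFrame(rows + error_rows,
                         columns=["source", "df", "adj_SS", "F", "p"])
    table["significant"] = np.where(table["p"] < 0.05, "*", "")
    return table


def contour_grid(surface: QuadraticSurface, vary: tuple, hold: dict,
                 factors: list | None = None, grid_n: int = 61,
                 coded_span: float = 2.0):
    """Evaluate the surface over a 2-D grid of two varied factors.

    ``vary`` gives two factor names; ``hold`` maps the other three names to
    uncoded values.  The varied axes span ``+/- coded_span`` coded units
    around each factor's center.  Returns ``(x_values, y_values, grid)``
    with ``grid[i, j]`` at ``(y_values[i], x_values[j])``.
    """
    if factors is None:
        factors = preset_factors()
    names = [f.name for f in factors]
    fx, fy = vary
    if fx == fy or fx not in names or fy not in names:
        raise ValueError(f"vary must name two distinct factors from {names}")
    missing = set(names) - {fx, fy} - set(hold)
    if missing:
        raise ValueError(f"hold values missing for {sorted(missing)}")
    by_name = {f.name: f for f in factors}
    xs = np.linspace(by_name[fx].to_uncoded(-coded_span),
                     by_name[fx].to_uncoded(coded_span), grid_n)
    ys = np.linspace(by_name[fy].to_uncoded(-coded_span),
                     by_name[fy].to_uncoded(coded_span), grid_n)
    grid = np.empty((grid_n, grid_n))
    point = {name: hold[name] for name in names if name in hold}
    for i, yv in enumerate(ys):
        for j, xv in enumerate(xs):
            point[fx], point[fy] = xv, yv
            grid[i, j] = evaluate_surface(surface, [point[n] for n in names])
    return xs, ys, grid


def plot_contour(surface: QuadraticSurface, vary: tuple, hold: dict,
                 out_path: str, factors: list | None = None,
                 grid_n: int = 61) -> None:
    """Render labeled level curves of :func:`contour_grid` to a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if factors is None:
        factors = preset_factors()
    xs, ys, grid = contour_grid(surface, vary, hold, factors, grid_n)
    by_name = {f.name: f for f in factors}
    fig, ax = plt.subplots(figsize=(5, 4))
    cs = ax.contour(xs, ys, grid, levels=10)
    ax.clabel(cs, inline=True, fontsize=7)
    ax.set_xlabel(f"{vary[0]} ({by_name[vary[0]].units})")
    ax.set_ylabel(f"{vary[1]} ({by_name[vary[1]].units})")
    ax.set_title("response surface")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110, metadata={})
    plt.close(fig)


#: verbatim uncoded design table of the original casing-modification
#: experiment (runs x [X1, X2, X3, X4, X5]); printed with rounding quirks,
#: kept for tolerance comparisons against the exact affine design
PRESET_TABLE_UNCODED = np.array([
    [3.16, 1.78, 0.26, 19.50, 75],
    [3.16, 1.78, 0.26, 22.50, 75],
    [4.20, 1.18, 0.40, 18.00, 90],
    [3.16, 1.78, 0.26, 16.50, 75],
    [2.11, 2.38, 0.12, 21.00, 90],
    [3.16, 1.78, 0.26, 19.50, 75],
    [2.11, 2.38, 0.40, 21.00, 60],
    [1.07, 1.78, 0.26, 19.50, 75],
    [3.16, 1.78, 0.26, 19.50, 105],
    [3.16, 1.78, 0.26, 19.50, 45],
    [3.16, 1.78, 0.26, 19.50, 75],
    [2.11, 1.18, 0.40, 21.00, 90],
    [4.20, 2.38, 0.12, 21.00, 60],
    [4.20, 2.38, 0.40, 18.00, 60],
    [4.20, 1.18, 0.40, 21.00, 60],
    [2.11, 1.18, 0.12, 18.00, 90],
    [3.16, 2.93, 0.26, 19.50, 75],
    [4.20, 1.18, 0.12, 21.00, 90],
    [2.11, 1.18, 0.12, 21.00, 60],
    [4.20, 2.38, 0.40, 21.00, 90],
    [2.11, 1.18, 0.40, 18.00, 60],
    [4.20, 1.18, 0.12, 18.00, 60],
    [3.16, 1.78, 0.53, 19.50, 75],
    [5.16, 1.78, 0.26, 19.50, 75],
    [2.11, 2.38, 0.40, 18.00, 90],
    [3.16, 1.78, 0.26, 19.50, 75],
    [4.20, 2.38, 0.12, 18.00, 90],
    [3.16, 1.78, 0.26, 19.50, 75],
    [3.16, 1.78, 0.26, 19.50, 75],
    [2.11, 2.38, 0.12, 18.00, 60],
    [3.16, 1.78, 0.00, 19.50, 75],
    [3.20, 0.60, 0.26, 19.50, 75],
])
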