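"""Yield–nitrogen response curves and the economic optimum N rate (EONR).

Given yields measured (or simulated) at a small design of fertilizer N rates
— by default the five-rate design 0, 67, 134, 201, 268 kg N/ha — this module
fits the two standard agronomic response forms,

* quadratic:            y = a + b N + c N^2
* quadratic-plus-plateau: the same quadratic up to its smooth join point
  N0 = -b / (2c), constant at the quadratic's vertex value thereafter,

selects between them by residual sum of squares among fits that are
significant (regression F-test, p < 0.05, with concave curvature), and
derives the EONR by setting the first derivative of the selected curve equal
to the grain-equivalent price of fertilizer N (the price ratio, default 5.6
kg grain per kg N):

    EONR = (price_ratio - b) / (2 c),   clipped to [0, N_max].

YEONR is the fitted yield at the EONR. Nonsignificant responses yield
EONR = 0 with an explicit flag rather than a dropped observation, so every
ensemble member always contributes a defined value downstream.

:func:`profit_grid_eonr` is an independent brute-force check: it maximizes
the partial profit y(N) - price_ratio * N on a dense grid and is used in
tests to validate the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DEFAULT_N_RATES",
    "DEFAULT_PRICE_RATIO",
    "NResponseData",
    "FittedResponse",
    "EonrResult",
    "FitError",
    "fit_quadratic",
    "fit_quad_plateau",
    "select_model",
    "compute_eonr",
    "eonr_from_data",
    "profit_grid_eonr",
]

DEFAULT_N_RATES = (0.0, 67.0, 134.0, 201.0, 268.0)
DEFAULT_PRICE_RATIO = 5.6  # kg grain per kg N
SIGNIFICANCE_LEVEL = 0.05
#: curvature below this magnitude is treated as no concavity (flat/linear data)
CURVATURE_TOL = 1e-6


class FitError(ValueError):
    """The response data cannot support the requested fit."""


@dataclass(frozen=True)
class NResponseData:
    """Yields observed at a vector of N rates (kg N/ha, kg grain/ha)."""

    n_rates: np.ndarray
    yields: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.n_rates, dtype=float)
        y = np.asarray(self.yields, dtype=float)
        if n.shape != y.shape or n.ndim != 1:
            raise ValueError("n_rates and yields must be 1-D and equal length")
        if len(np.unique(n)) < 4:
            raise ValueError("need at least 4 distinct N rates")
        if np.any(y < 0):
            raise ValueError("yields must be >= 0")
        order = np.argsort(n)
        object.__setattr__(self, "n_rates", n[order])
        object.__setattr__(self, "yields", y[order])

    @property
    def n_max(self) -> float:
        return float(self.n_rates[-1])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"n_rate": self.n_rates, "yield": self.yields}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "NResponseData":
        df = pd.read_csv(path)
        return cls(df["n_rate"].to_numpy(), df["yield"].to_numpy())


@dataclass(frozen=True)
class FittedResponse:
    """One fitted yield–N curve with its goodness-of-fit statistics."""

    form: str            # "quadratic" | "quad_plateau"
    a: float             # intercept, kg/ha
    b: float             # linear slope, kg grain per kg N
    c: float             # curvature, kg grain per kg N^2
    sse: float
    r_squared: float
    p_value: float
    significant: bool
    join_n0: float | None = None  # quad_plateau only: -b/(2c)

    def predict(self, n: float | np.ndarray) -> float | np.ndarray:
        n = np.asarray(n, dtype=float)
        quad = self.a + self.b * n + self.c * n**2
        if self.form == "quad_plateau" and self.join_n0 is not None:
            plateau = self.a + self.b * self.join_n0 + self.c * self.join_n0**2
            quad = np.where(n <= self.join_n0, quad, plateau)
        return float(quad) if quad.ndim == 0 else quad

    def slope(self, n: float) -> float:
        if self.form == "quad_plateau" and self.join_n0 is not None and n > self.join_n0:
            return 0.0
        return self.b + 2.0 * self.c * n

    def to_row(self) -> dict:
        return {
            "form": self.form, "a": self.a, "b": self.b, "c": self.c,
            "join_n0": self.join_n0, "sse": self.sse,
            "r_squared": self.r_squared, "p_value": self.p_value,
            "significant": self.significant,
        }


@dataclass(frozen=True)
class EonrResult:
    """Economic optimum N rate and the yield there."""

    eonr: float          # kg N/ha, in [0, n_max]
    yeonr: float         # kg/ha, fitted yield at eonr
    price_ratio: float
    source_form: str
    boundary_flag: str   # interior | clipped_low | clipped_high | nonsignificant

    def to_row(self) -> dict:
        return {
            "eonr": self.eonr, "yeonr": self.yeonr,
            "price_ratio": self.price_ratio, "source_form": self.source_form,
            "boundary_flag": self.boundary_flag,
        }


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _fit_stats(y: np.ndarray, pred: np.ndarray, n_params: int) -> tuple[float, float, float]:
    """SSE, R^2 and the regression-F p-value against the mean-only model."""
    sse = float(np.sum((y - pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    df1 = n_params - 1
    df2 = len(y) - n_params
    if sst <= 0.0:
        return sse, 0.0, 1.0
    r2 = 1.0 - sse / sst
    if df2 <= 0:
        return sse, r2, 1.0
    if sse <= 1e-12 * sst:
        return sse, r2, 0.0
    f_stat = ((sst - sse) / df1) / (sse / df2)
    return sse, r2, float(stats.f.sf(f_stat, df1, df2))


def fit_quadratic(data: NResponseData) -> FittedResponse:
    """Ordinary least squares fit of y = a + b N + c N^2.

    Significance is the regression F-test (p < 0.05) and requires concave
    (c <= 0) curvature, since a convex "response" has no economic optimum.
    """
    n, y = data.n_rates, data.yields
    if len(np.unique(n)) < 3:
        raise FitError("quadratic fit needs at least 3 distinct N rates")
    X = np.column_stack([np.ones_like(n), n, n**2])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b, c = (float(v) for v in coef)
    sse, r2, p = _fit_stats(y, X @ coef, n_params=3)
    return FittedResponse(
        form="quadratic", a=a, b=b, c=c, sse=sse, r_squared=r2, p_value=p,
        significant=(p < SIGNIFICANCE_LEVEL and c <= 0.0),
    )


def _qp_residuals(params: np.ndarray, n: np.ndarray, y: np.ndarray) -> np.ndarray:
    a, b, c = params
    n0 = -b / (2.0 * c)
    pred = np.where(n <= n0, a + b * n + c * n**2, a - b**2 / (4.0 * c))
    return pred - y


def fit_quad_plateau(data: NResponseData) -> FittedResponse:
    """Nonlinear least squares fit of the quadratic-plus-plateau form.

    The plateau joins the quadratic smoothly at its vertex N0 = -b/(2c)
    (continuous value and zero slope), so the model has the same three free
    parameters as the quadratic. The optimizer is restarted from the
    quadratic solution and from vertex guesses at each interior design rate;
    the lowest-SSE solution wins, making the fit deterministic. If no
    concave solution exists (e.g. strictly linear data) the result is
    returned flagged nonsignificant.
    """
    n, y = data.n_rates, data.yields
    quad = fit_quadratic(data)

    starts: list[np.ndarray] = []
    c_start = quad.c if quad.c < -CURVATURE_TOL else -1e-3
    starts.append(np.array([quad.a, max(quad.b, 1e-3), c_start]))
    y0, ymax = float(y[0]), float(y.max())
    for n0_guess in n[1:-1]:
        if n0_guess <= 0:
            continue
        c0 = -(ymax - y0) / n0_guess**2 if ymax > y0 else -1e-3
        starts.append(np.array([y0, -2.0 * c0 * n0_guess, c0]))

    best: optimize.OptimizeResult | None = None
    bounds = ([-np.inf, -np.inf, -np.inf], [np.inf, np.inf, -1e-12])
    for x0 in starts:
        x0 = x0.copy()
        x0[2] = min(x0[2], -1e-9)
        try:
            res = optimize.least_squares(
                _qp_residuals, x0, args=(n, y), bounds=bounds, method="trf"
            )
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:  # pragma: no cover - all starts failed
        a, b, c = quad.a, quad.b, min(quad.c, -1e-9)
    else:
        a, b, c = (float(v) for v in best.x)
    n0 = -b / (2.0 * c)
    pred = np.where(n <= n0, a + b * n + c * n**2, a - b**2 / (4.0 * c))
    sse, r2, p = _fit_stats(y, pred, n_params=3)
    concave = c <= -CURVATURE_TOL
    return FittedResponse(
        form="quad_plateau", a=a, b=b, c=c, sse=sse, r_squared=r2, p_value=p,
        significant=(p < SIGNIFICANCE_LEVEL and concave), join_n0=n0,
    )


def select_model(quad: FittedResponse, qp: FittedResponse) -> FittedResponse:
    """Pick the better of the two fits on shared data.

    Among significant fits the smaller SSE wins (equivalently the larger R^2
    on the same data); an exact SSE tie goes to the quadratic-plus-plateau.
    If only one is significant it is returned; if neither, the quadratic is
    returned carrying its nonsignificant flag.
    """
    if quad.significant and qp.significant:
        if qp.sse <= quad.sse:
            return qp
        return quad
    if qp.significant:
        return qp
    if quad.significant:
        return quad
    return quad


# ---------------------------------------------------------------------------
# EONR
# ---------------------------------------------------------------------------


def compute_eonr(
    fit: FittedResponse,
    price_ratio: float = DEFAULT_PRICE_RATIO,
    n_max: float = DEFAULT_N_RATES[-1],
) -> EonrResult:
    """EONR from the first-order condition dy/dN = price_ratio.

    The interior solution N* = (price_ratio - b) / (2c) is clipped to the
    tested range [0, n_max] (extrapolating a fitted quadratic beyond the
    design is not defensible); the flag records clipping. A nonsignificant
    fit maps to EONR 0 with flag ``"nonsignificant"``.
    """
    if not fit.significant:
        return EonrResult(
            eonr=0.0, yeonr=float(fit.predict(0.0)), price_ratio=price_ratio,
            source_form=fit.form, boundary_flag="nonsignificant",
        )
    if fit.c == 0.0:
        if fit.b > price_ratio:
            eonr, flag = n_max, "clipped_high"
        else:
            eonr, flag = 0.0, "clipped_low"
    else:
        n_star = (price_ratio - fit.b) / (2.0 * fit.c)
        if n_star < 0.0:
            eonr, flag = 0.0, "clipped_low"
        elif n_star > n_max:
            eonr, flag = n_max, "clipped_high"
        else:
            eonr, flag = float(n_star), "interior"
    return EonrResult(
        eonr=eonr, yeonr=float(fit.predict(eonr)), price_ratio=price_ratio,
        source_form=fit.form, boundary_flag=flag,
    )


def eonr_from_data(
    data: NResponseData,
    price_ratio: float = DEFAULT_PRICE_RATIO,
    n_max: float | None = None,
) -> tuple[EonrResult, FittedResponse]:
    """Fit both response forms, select, and derive the EONR.

    This is the single entry point the forecast engine calls per ensemble
    member. Returns the EONR result together with the selected fit.
    """
    if n_max is None:
        n_max = data.n_max
    quad = fit_quadratic(data)
    qp = fit_quad_plateau(data)
    fit = select_model(quad, qp)
    return compute_eonr(fit, price_ratio, n_max), fit


def profit_grid_eonr(
    fit: FittedResponse,
    price_ratio: float = DEFAULT_PRICE_RATIO,
    n_max: float = DEFAULT_N_RATES[-1],
    step: float = 0.01,
) -> float:
    """Brute-force EONR: argmax of y(N) - price_ratio*N on a dense grid.

    An independent oracle for the closed form; accurate to ``step``.
    """
    grid = np.arange(0.0, n_max + step / 2, step)
    profit = np.asarray(fit.predict(grid)) - price_ratio * grid
    return float(grid[int(np.argmax(profit))])
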