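"""Estimators of pi0, the proportion of true null hypotheses.

Four estimators are provided, all built on the same idea: for p-values above
some point lambda the alternative contributes (almost) nothing, so the
density of p-values there reflects the null fraction alone.

* ``pi0_smoothing`` — Storey-Tibshirani: natural cubic spline through
  (lambda_r, pi0_hat(lambda_r)) on a grid, evaluated at lambda = 1.
* ``pi0_bootstrap`` — Storey: pick the lambda minimizing the bootstrap MSE of
  pi0_hat(lambda) around the plug-in minimum over the grid.
* ``pi0_lbe`` — location-based estimator using moments of -ln(1 - p); the
  moment order m is a step function of the family size S.
* ``pi0_sdpb`` — Meinshausen-Rice lower bound on the fraction of false nulls
  with the standard-deviation-proportional bounding function; pi0 = 1 - L.

``pi0_mode`` aggregates several estimates by binning them into intervals of
width 0.05 and averaging the most populated bin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Any, Sequence

import numpy as np

from .metatest import as_pvalue_set

logger = logging.getLogger("sgofplus")

__all__ = [
    "Pi0Estimate",
    "default_lambda_grid",
    "pi0_at_lambda",
    "pi0_smoothing",
    "pi0_bootstrap",
    "pi0_lbe",
    "pi0_sdpb",
    "pi0_mode",
]

# -ln(1-p) diverges at p = 1; the LBE clamps there.
_LBE_EPS = 1e-8

# Monte-Carlo calibration of the SDPB bounding sequence under the complete
# null: number of uniform replicates and the internal seed (fixed so the
# bounding sequence is a deterministic function of (S, alpha)).
_SDPB_CAL_REPLICATES = 2000
_SDPB_CAL_SEED = 20110909
_SDPB_CAL_CHUNK = 200


def default_lambda_grid() -> np.ndarray:
    """The default grid lambda_r = 0, 0.05, ..., 0.95."""
    return np.round(np.arange(0, 20) * 0.05, 10)


@dataclass(frozen=True)
class Pi0Estimate:
    """A pi0 estimate with its method label and tuning metadata."""

    value: float
    method: str
    tuning: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("pi0 estimate must be clipped into [0, 1]")

    def __float__(self) -> float:
        return self.value


def pi0_at_lambda(pvalues, lam: float) -> float:
    """Raw Storey estimator #{p_i > lambda} / (S * (1 - lambda)).

    Not clipped: values above 1 are possible (and expected near lambda = 1);
    clipping is the responsibility of the estimator that consumes it.
    """
    ps = as_pvalue_set(pvalues)
    if not 0.0 <= lam < 1.0:
        raise ValueError("lambda must lie in [0, 1)")
    return float(np.count_nonzero(ps.values > lam)) / (ps.S * (1.0 - lam))


def _pi0_curve(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """pi0_hat(lambda_r) for every grid point, vectorized."""
    S = values.size
    counts = S - np.searchsorted(np.sort(values), grid, side="right")
    return counts / (S * (1.0 - grid))


def _check_grid(grid) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size < 2 or np.any(np.diff(g) <= 0):
        raise ValueError("lambda grid must be strictly increasing")
    if g[0] < 0.0 or g[-1] >= 1.0:
        raise ValueError("lambda grid must lie within [0, 1)")
    return g


def _natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Design matrix of the natural cubic spline with the given knots.

    Truncated-power construction: columns are 1, x, and N_k(x) for
    k = 1..K-2, where N_k = d_k - d_{K-1} and
    d_k(x) = ((x - xi_k)+^3 - (x - xi_K)+^3) / (xi_K - xi_k).
    The fit is linear beyond the boundary knots, so evaluation at
    lambda = 1 extrapolates linearly.
    """
    knots = np.asarray(knots, dtype=float)
    K = knots.size
    x = np.asarray(x, dtype=float)

    def d(k: int) -> np.ndarray:
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - knots[-1], 0.0) ** 3
        return num / (knots[-1] - knots[k])

    cols = [np.ones_like(x), x]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


def _spline_knots(grid: np.ndarray, df: int) -> np.ndarray:
    """Boundary knots at the grid ends, df-1 internal knots at quantiles."""
    qs = np.linspace(0.0, 1.0, df + 1)
    return np.unique(np.quantile(grid, qs))


def _fit_spline_at_one(grid: np.ndarray, y: np.ndarray, df: int) -> tuple[float, float]:
    """Least-squares natural-spline fit; returns (value at 1, GCV score)."""
    knots = _spline_knots(grid, df)
    X = _natural_spline_basis(grid, knots)
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    n = grid.size
    denom = max(n - rank, 1)
    gcv = rss / (denom / n) ** 2 / n
    at_one = float((_natural_spline_basis(np.array([1.0]), knots) @ beta)[0])
    return at_one, gcv


def pi0_smoothing(pvalues, grid=None, df: "int | str" = 3) -> Pi0Estimate:
    """Smoothing estimator: spline through (lambda_r, pi0_hat(lambda_r)) at 1.

    ``df`` is the flexibility of the natural cubic spline (number of basis
    functions beyond the intercept); default 3.  ``df="gcv"`` selects df in
    {3, 4, 5, 6} by generalized cross-validation.
    """
    ps = as_pvalue_set(pvalues)
    grid = _check_grid(default_lambda_grid() if grid is None else grid)
    if grid.size < 4:
        raise ValueError("smoothing requires at least 4 lambda grid points")
    y = _pi0_curve(ps.values, grid)
    if df == "gcv":
        fits = {d: _fit_spline_at_one(grid, y, d) for d in (3, 4, 5, 6)}
        df_used = min(fits, key=lambda d: fits[d][1])
        raw = fits[df_used][0]
    else:
        df_used = int(df)
        raw, _ = _fit_spline_at_one(grid, y, df_used)
    value = float(np.clip(raw, 0.0, 1.0))
    return Pi0Estimate(value, "smoothing", {"df": df_used, "grid": grid, "raw": raw})


def pi0_bootstrap(pvalues, grid=None, n_boot: int = 100, seed: int | None = None) -> Pi0Estimate:
    """Bootstrap estimator: lambda minimizing the bootstrap MSE of pi0_hat.

    The MSE of pi0_hat(lambda) is estimated around the plug-in minimum
    min_lambda' pi0_hat(lambda') by resampling the p-values with
    replacement; ties in the MSE go to the smallest lambda.  Deterministic
    given ``seed``.
    """
    ps = as_pvalue_set(pvalues)
    grid = _check_grid(default_lambda_grid() if grid is None else grid)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    curve = _pi0_curve(ps.values, grid)
    target = float(np.min(curve))
    rng = np.random.default_rng(seed)
    mse = np.zeros(grid.size)
    for _ in range(n_boot):
        resample = rng.choice(ps.values, size=ps.S, replace=True)
        mse += (_pi0_curve(resample, grid) - target) ** 2
    mse /= n_boot
    best = int(np.argmin(mse))  # first minimum -> smallest lambda
    value = float(np.clip(curve[best], 0.0, 1.0))
    return Pi0Estimate(
        value,
        "bootstrap",
        {"lambda": float(grid[best]), "n_boot": n_boot, "grid": grid, "raw": float(curve[best])},
    )


def lbe_order(S: int) -> int:
    """Moment order m of the LBE as a step function of the family size.

    m = 1 for 2 <= S < 2000, m = 2 for 2000 <= S < 7500, m = 3 for
    S >= 7500 (breakpoints from the variance bound l = 0.05^2).
    """
    if S < 2:
        raise ValueError("LBE requires at least 2 p-values")
    if S < 2000:
        return 1
    if S < 7500:
        return 2
    return 3


def pi0_lbe(pvalues) -> Pi0Estimate:
    """Location-based estimator: (1/(S*m!)) * sum_i (-ln(1 - p_i))^m.

    Under uniformity E[(-ln(1-P))^m] = m!, so the estimator is unbiased for
    pi0 = 1 at every order.  p-values equal to 1 are clamped at 1 - 1e-8
    (the log diverges there) with a logged warning.
    """
    ps = as_pvalue_set(pvalues)
    m = lbe_order(ps.S)
    values = ps.values
    if np.any(values >= 1.0):
        logger.warning("LBE: clamping %d p-value(s) equal to 1 at 1 - 1e-8",
                       int(np.count_nonzero(values >= 1.0)))
        values = np.minimum(values, 1.0 - _LBE_EPS)
    raw = float(np.sum((-np.log1p(-values)) ** m) / (ps.S * math.factorial(m)))
    value = float(np.clip(raw, 0.0, 1.0))
    return Pi0Estimate(value, "lbe", {"m": m, "raw": raw})


@lru_cache(maxsize=256)
def _sdpb_beta(S: int, alpha: float, n_replicates: int = _SDPB_CAL_REPLICATES) -> float:
    """Bounding sequence beta_{S, alpha} by complete-null calibration.

    The (1-alpha) quantile of V_S = sup_t (F_hat(t) - t)/sqrt(t(1-t)) over
    ``n_replicates`` families of S Uniform(0,1) p-values, with the supremum
    taken over the same candidate set the estimator uses.  Fixed internal
    seed makes the sequence a deterministic function of (S, alpha).
    """
    rng = np.random.default_rng(_SDPB_CAL_SEED)
    sups = np.empty(n_replicates)
    done = 0
    while done < n_replicates:
        k = min(_SDPB_CAL_CHUNK, n_replicates - done)
        block = np.sort(rng.random((k, S)), axis=1)
        ecdf = np.arange(1, S + 1) / S
        stat = (ecdf[None, :] - block) / np.sqrt(block * (1.0 - block))
        sups[done:done + k] = np.max(stat, axis=1)
        done += k
    return float(np.quantile(sups, 1.0 - alpha))


def sdpb_beta_asymptotic(S: int) -> float:
    """Asymptotic rate sqrt(2 ln ln S / S) for the bounding sequence."""
    return float(np.sqrt(2.0 * np.log(np.log(S)) / S))


def pi0_sdpb(pvalues, alpha: float = 0.05, bounding: str = "calibrated") -> Pi0Estimate:
    """SDPB estimator: pi0 = 1 - L_hat, with L_hat a bound on false nulls.

    L_hat = sup_t (F_hat(t) - t - beta_{S,alpha} * sqrt(t(1-t))) / (1 - t),
    clipped at 0.  The supremum runs over the observed p-values plus the
    default lambda grid (F_hat is a step function, so this suffices).  With
    probability >= 1 - alpha under the complete null L_hat = 0, making the
    estimator a conservative (upward-biased) pi0 estimate.
    """
    ps = as_pvalue_set(pvalues)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if bounding == "calibrated":
        beta = _sdpb_beta(ps.S, alpha)
    elif bounding == "asymptotic":
        beta = sdpb_beta_asymptotic(ps.S)
    else:
        raise ValueError(f"unknown bounding sequence: {bounding!r}")
    ts = np.unique(np.concatenate([ps.values, default_lambda_grid()]))
    ts = ts[(ts > 0.0) & (ts < 1.0)]
    if ts.size == 0:
        L = 0.0
    else:
        ecdf = np.searchsorted(ps.sorted(), ts, side="right") / ps.S
        bound = (ecdf - ts - beta * np.sqrt(ts * (1.0 - ts))) / (1.0 - ts)
        L = max(float(np.max(bound)), 0.0)
    value = float(np.clip(1.0 - L, 0.0, 1.0))
    return Pi0Estimate(value, "sdpb", {"beta": beta, "bounding": bounding, "L": L, "alpha": alpha})


def pi0_mode(estimates: Sequence["Pi0Estimate | float"], bin_width: float = 0.05) -> float:
    """Modal-interval aggregation of several pi0 estimates.

    Estimates are binned into half-open intervals [k*w, (k+1)*w) anchored at
    0; the average of the estimates in the most populated bin is returned.
    Ties between equally populated bins go to the bin holding the larger
    values (the more conservative, higher-pi0 choice).
    """
    vals = np.asarray([float(e) for e in estimates], dtype=float)
    if vals.size == 0:
        raise ValueError("pi0_mode requires at least one estimate")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    bins = np.floor(vals / bin_width).astype(int)
    counts: dict[int, int] = {}
    for b in bins:
        counts[int(b)] = counts.get(int(b), 0) + 1
    best_count = max(counts.values())
    best_bin = max(b for b, c in counts.items() if c == best_count)
    return float(np.mean(vals[bins == best_bin]))
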