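"""Logit-space functional data analysis of probability curves.

Replicate curves P(Q) are interpolated (linearly in log Q) onto a common
logarithmic grid, clamped to [eps, 1 - eps] with eps = 1e-3, and mapped
through the logit.  The ensemble trend is the inverse logit of the
pointwise mean, with a one-standard-deviation band in logit space — this
keeps the trend and band inside [0, 1] while allowing asymmetric
uncertainty near the boundaries.  Diversity curves are averaged on their
original scale (no logit).

Shape scores quantify how saturating-monotone a P_I curve is and how
unimodal a P_M curve is.  Their exact definitions are this package's own
(rank-correlation x terminal-flatness; residual gain of the best up-down
isotonic fit over the best monotone fit) and are documented below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr
from sklearn.isotonic import IsotonicRegression

from .feasibility import ProbabilityCurve
from .network import NetworkInputError

__all__ = ["FDAResult", "fda_aggregate", "diversity_aggregate", "shape_scores",
            "common_log_grid"]

DEFAULT_EPSILON = 1e-3
DEFAULT_GRID_POINTS = 200


def _logit(p):
    return np.log(p / (1.0 - p))


def _inv_logit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class FDAResult:
    """Pointwise logit-space summary of an ensemble of probability curves."""

    Q: np.ndarray
    mean: np.ndarray            # central trend, inverse-logit of mu_lambda
    lower: np.ndarray           # inverse-logit of mu_lambda - sd_lambda
    upper: np.ndarray           # inverse-logit of mu_lambda + sd_lambda
    logit_mean: np.ndarray
    logit_sd: np.ndarray
    epsilon: float
    n_curves: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "Q": self.Q, "P_mean": self.mean, "P_lower": self.lower,
            "P_upper": self.upper, "logit_mean": self.logit_mean,
            "logit_sd": self.logit_sd,
        })


def common_log_grid(curves, n_points: int = DEFAULT_GRID_POINTS) -> np.ndarray:
    """Log-spaced grid over the intersection of the curves' Q ranges."""
    lo = max(float(c[0][0]) if isinstance(c, tuple) else float(c.Q[0]) for c in curves)
    hi = min(float(c[0][-1]) if isinstance(c, tuple) else float(c.Q[-1]) for c in curves)
    if hi <= lo:
        raise NetworkInputError("curves have no common Q range")
    return np.geomspace(lo, hi, n_points)


def _interp_curve(Q_grid, Q, p, label):
    if Q_grid[0] < Q[0] * (1 - 1e-12) or Q_grid[-1] > Q[-1] * (1 + 1e-12):
        raise NetworkInputError(
            f"curve {label} covers [{Q[0]:.4g}, {Q[-1]:.4g}] and cannot be "
            "interpolated onto the common grid (extrapolation refused)"
        )
    return np.interp(np.log(Q_grid), np.log(Q), p)


def fda_aggregate(
    curves,
    values: str = "p_mat",
    Q_grid: np.ndarray | None = None,
    n_points: int = DEFAULT_GRID_POINTS,
    epsilon: float = DEFAULT_EPSILON,
) -> FDAResult:
    """Aggregate replicate probability curves in logit space.

    ``curves`` is a list of :class:`ProbabilityCurve` (``values`` selects
    p_init or p_mat) or of ``(Q, p)`` tuples.  Order of operations:
    interpolate (linear in log Q), clamp to [eps, 1-eps], logit, pointwise
    mean and SD (n-1 denominator), inverse logit.
    """
    if len(curves) < 2:
        raise NetworkInputError("FDA needs at least 2 curves (SD undefined otherwise)")
    if Q_grid is None:
        Q_grid = common_log_grid(curves, n_points)
    rows = []
    for k, c in enumerate(curves):
        if isinstance(c, ProbabilityCurve):
            Q, p = c.Q, getattr(c, values)
            label = c.network_id or f"#{k}"
        else:
            Q, p = np.asarray(c[0], float), np.asarray(c[1], float)
            label = f"#{k}"
        rows.append(_interp_curve(Q_grid, Q, p, label))
    P = np.clip(np.vstack(rows), epsilon, 1.0 - epsilon)
    lam = _logit(P)
    mu = lam.mean(axis=0)
    sd = lam.std(axis=0, ddof=1)
    return FDAResult(
        Q=np.asarray(Q_grid, float),
        mean=_inv_logit(mu),
        lower=_inv_logit(mu - sd),
        upper=_inv_logit(mu + sd),
        logit_mean=mu,
        logit_sd=sd,
        epsilon=epsilon,
        n_curves=len(curves),
    )


def diversity_aggregate(curves, Q_grid: np.ndarray | None = None,
                        n_points: int = DEFAULT_GRID_POINTS):
    """Pointwise arithmetic mean of diversity curves on the original scale.

    ``curves`` is a list of ``(Q, D)`` tuples; NaN grid points (supply below
    every community's critical level) are averaged over the replicates that
    define them.  Returns ``(Q_grid, mean_curve)``.
    """
    if not curves:
        raise NetworkInputError("no curves to aggregate")
    if Q_grid is None:
        Q_grid = common_log_grid(curves, n_points)
    rows = [_interp_curve(Q_grid, np.asarray(Q, float), np.asarray(D, float), f"#{k}")
            for k, (Q, D) in enumerate(curves)]
    return np.asarray(Q_grid, float), np.nanmean(np.vstack(rows), axis=0)


def _isotonic_sse(x, y, increasing: bool) -> float:
    fit = IsotonicRegression(increasing=increasing).fit_transform(x, y)
    return float(np.sum((fit - y) ** 2))


def _updown_sse(x, y) -> float:
    """Best up-then-down fit: increasing isotonic on [0..k], decreasing on
    [k..end], minimized over the split point."""
    n = len(y)
    best = np.inf
    for k in range(n):
        sse = 0.0
        if k >= 1:
            sse += _isotonic_sse(x[: k + 1], y[: k + 1], True)
        if k <= n - 2:
            sse += _isotonic_sse(x[k:], y[k:], False)
        best = min(best, sse)
    return best


def shape_scores(curve, values: str = "p_mat") -> tuple[float, float]:
    """(saturation score, unimodality score) for one curve.

    Saturation score: Spearman rank correlation of p with Q times
    (1 - normalized terminal slope), where the terminal slope is the mean
    log-Q slope over the last 10% of the grid normalized by the maximum
    positive slope; near 1 for increasing-then-flat curves, <= 0 for
    decreasing ones.

    Unimodality score: 1 - SSE(best up-down isotonic fit) / SSE(best
    monotone isotonic fit); near 1 when a rise-then-fall shape explains the
    curve far better than any monotone one, ~0 for monotone curves.

    Constant curves return (0, 0).  These are diagnostic plumbing scores of
    this package, not published statistics.
    """
    if isinstance(curve, ProbabilityCurve):
        Q, p = curve.Q, getattr(curve, values)
    else:
        Q, p = np.asarray(curve[0], float), np.asarray(curve[1], float)
    if len(Q) < 5:
        raise NetworkInputError("shape scores need at least 5 grid points")
    if np.ptp(p) < 1e-12:
        return 0.0, 0.0
    x = np.log(Q)
    slopes = np.diff(p) / np.diff(x)
    max_slope = float(np.max(slopes))
    k_tail = max(1, len(slopes) // 10)
    term = float(np.mean(slopes[-k_tail:]))
    flatness = 1.0 - np.clip(term / max_slope, 0.0, 1.0) if max_slope > 0 else 0.0
    rho = float(spearmanr(Q, p).statistic)
    saturation = rho * flatness
    sse_mono = min(_isotonic_sse(x, p, True), _isotonic_sse(x, p, False))
    if sse_mono < 1e-15:
        unimodality = 0.0
    else:
        unimodality = 1.0 - _updown_sse(x, p) / sse_mono
    return saturation, unimodality
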