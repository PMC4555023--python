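"""Nonlinear correlation coefficient h2 with delay scan and direction.

The h2 coefficient measures how much of signal Y's variance is explained by
a (possibly nonlinear) function of signal X. The regression curve is a
piecewise-linear approximation of the scatterplot of Y against X: the
observed X range is cut into equal-width amplitude bins and the curve
passes through the per-bin means (mean x, mean y), linearly interpolated
between anchors and linearly extended beyond the terminal ones.

    h2 = 1 - var(Y - g(X)) / var(Y),   clamped to [0, 1]

h2 is asymmetric (a nonlinear map may be predictable one way only) and
invariant to affine rescaling of either signal. A delay scan shifts Y
forward by 0..max_delay samples; the larger of the two directed maxima and
the sign of its delay determine the direction of the coupling.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .config import DEFAULT_CONFIG, AnalysisConfig
from .regions import RegionRole

__all__ = [
    "PiecewiseCurve",
    "Direction",
    "DirectedEdgeEstimate",
    "DegenerateSignalError",
    "fit_piecewise_curve",
    "h2_coefficient",
    "h2_delay_scan",
    "directed_pair_estimate",
]

#: Two directed maxima closer than this are treated as a tie (undirected).
EQUAL_MAX_TOL = 1e-9


class DegenerateSignalError(ValueError):
    """The predictor (or response) is constant, so no curve can be fitted."""


class Direction(Enum):
    X_TO_Y = "X->Y"
    Y_TO_X = "Y->X"
    UNDIRECTED = "undirected"


@dataclass(frozen=True)
class PiecewiseCurve:
    """Piecewise-linear regression curve through per-bin mean anchors."""

    anchor_x: np.ndarray
    anchor_y: np.ndarray

    @property
    def n_anchors(self) -> int:
        return self.anchor_x.size

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return _evaluate(self.anchor_x, self.anchor_y, np.asarray(x, dtype=float))


@dataclass(frozen=True)
class DirectedEdgeEstimate:
    """One region pair's h2, best delay and inferred direction.

    ``delay_s`` is positive when X leads Y, negative when Y leads X.
    """

    pair: tuple[RegionRole, RegionRole] | None
    h2: float
    delay_s: float
    direction: Direction


def _anchors(x: np.ndarray, y: np.ndarray, n_bins: int):
    """Per-bin (mean x, mean y) anchors over equal-width bins of x's range.

    Empty bins contribute no anchor (equivalently, they are merged into
    their nearest non-empty neighbour). Bin membership orders the anchors
    strictly in x, as required for interpolation.
    """
    xmin = x.min()
    span = x.max() - xmin
    if span <= 0.0:
        raise DegenerateSignalError("constant predictor: amplitude range is empty")
    idx = np.minimum(((x - xmin) * (n_bins / span)).astype(np.int64), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    nz = counts > 0
    cnz = counts[nz]
    ax = np.bincount(idx, weights=x, minlength=n_bins)[nz] / cnz
    ay = np.bincount(idx, weights=y, minlength=n_bins)[nz] / cnz
    return ax, ay


def _evaluate(ax: np.ndarray, ay: np.ndarray, x: np.ndarray) -> np.ndarray:
    if ax.size == 1:
        return np.full(x.shape, ay[0])
    g = np.interp(x, ax, ay)
    lo = x < ax[0]
    if lo.any():
        s = (ay[1] - ay[0]) / (ax[1] - ax[0])
        g[lo] = ay[0] + s * (x[lo] - ax[0])
    hi = x > ax[-1]
    if hi.any():
        s = (ay[-1] - ay[-2]) / (ax[-1] - ax[-2])
        g[hi] = ay[-1] + s * (x[hi] - ax[-1])
    return g


def fit_piecewise_curve(x, y, n_bins: int = DEFAULT_CONFIG.n_bins) -> PiecewiseCurve:
    """Fit the piecewise-linear regression curve of y on x.

    Raises :class:`DegenerateSignalError` for a constant predictor; the
    pipeline maps that case to h2 = 0 (a flat channel is uninformative).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    ax, ay = _anchors(x, y, n_bins)
    return PiecewiseCurve(ax, ay)


def _h2(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """Fast path: h2 of centred vectors, 0.0 on degenerate input."""
    y = y - y.mean()
    ss_y = float(y @ y)
    if ss_y <= 0.0:
        return 0.0
    try:
        ax, ay = _anchors(x, y, n_bins)
    except DegenerateSignalError:
        return 0.0
    r = y - _evaluate(ax, ay, x)
    h2 = 1.0 - float(r @ r) / ss_y
    return min(max(h2, 0.0), 1.0)


def h2_coefficient(x, y, n_bins: int = DEFAULT_CONFIG.n_bins) -> float:
    """The nonlinear correlation coefficient h2 of y explained by x.

    Deterministic for fixed inputs; returns 0.0 when either signal is
    constant. Means are removed before fitting (no further detrending or
    filtering, matching an unfiltered acquisition).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    return _h2(x - x.mean(), y, n_bins)


def h2_delay_scan(
    x, y, cfg: AnalysisConfig = DEFAULT_CONFIG, rate: float | None = None
) -> tuple[float, int]:
    """Maximize h2 over non-negative shifts of y relative to x.

    For each delay tau in 0..round(max_delay_s * rate), h2 is computed
    between x(t) and y(t + tau) on the overlapping N - tau samples (X
    leading Y; no padding, which would bias h2 toward zero). Returns the
    maximum and its tau; ties go to the smallest tau.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    max_tau = cfg.max_delay_samples(rate)
    n = x.size
    if max_tau < 0 or n - max_tau < 4 * cfg.n_bins:
        raise ValueError(
            "delay scan range empty or signals too short for the bin count"
        )
    best_h2, best_tau = -1.0, 0
    for tau in range(max_tau + 1):
        h2 = _h2(x[: n - tau] if tau else x, y[tau:], cfg.n_bins)
        if h2 > best_h2 + EQUAL_MAX_TOL:
            best_h2, best_tau = h2, tau
    return best_h2, best_tau


def directed_pair_estimate(
    x,
    y,
    cfg: AnalysisConfig = DEFAULT_CONFIG,
    pair: tuple[RegionRole, RegionRole] | None = None,
    rate: float | None = None,
) -> DirectedEdgeEstimate:
    """Estimate the coupling between two signals with direction.

    Runs the delay scan in both directions and keeps the larger maximum;
    the sign of the winning delay defines the direction. If the two maxima
    agree to within 1e-9, or the winning delay is zero, the edge is
    undirected: it still carries connectivity weight but no direction.
    """
    r = rate if rate is not None else cfg.rate
    h2_xy, tau_xy = h2_delay_scan(x, y, cfg, rate=r)
    h2_yx, tau_yx = h2_delay_scan(y, x, cfg, rate=r)
    if abs(h2_xy - h2_yx) <= EQUAL_MAX_TOL:
        h2, tau, direction = max(h2_xy, h2_yx), tau_xy, Direction.UNDIRECTED
        delay_s = tau / r
    elif h2_xy > h2_yx:
        h2, tau, direction = h2_xy, tau_xy, Direction.X_TO_Y
        delay_s = tau / r
    else:
        h2, tau, direction = h2_yx, tau_yx, Direction.Y_TO_X
        delay_s = -tau / r
    if tau == 0:
        direction = Direction.UNDIRECTED
    return DirectedEdgeEstimate(pair=pair, h2=h2, delay_s=delay_s, direction=direction)
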