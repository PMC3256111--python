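"""Kernel-smoothed nonparametric IRT primitives.

The estimation chain is Ramsay-style kernel smoothing:

1. subjects are ranked by subscale summed score; mid-ranks are mapped
   through the standard-normal quantile function to latent scores
   ``theta_i = Phi^{-1}(r_i / (N + 1))``;
2. each option indicator is regressed on the latent scores with a
   Nadaraya-Watson estimator (Gaussian kernel, bandwidth h) evaluated on a
   fixed grid, giving option characteristic curves (OCCs);
3. item characteristic curves (expected item score), item information,
   the expected summed score, the score density and the summed-score
   standard error all derive from the OCCs by the moment identities below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde, norm, rankdata
from sklearn.isotonic import IsotonicRegression


#: Rank-normal latent scores are standard normal by construction, so the
#: central 1 - 2*DENSE_TRIM probability mass lies between the corresponding
#: normal quantiles; outside that band kernel estimates rest on a handful of
#: subjects and are noise-dominated.
DENSE_TRIM = 0.005

#: The median-option crossing for the slope diagnostic is searched within the
#: central 95% of patients; further out the window around the crossing would
#: consist only of sparse, noise-dominated grid points.
SLOPE_TRIM = 0.025


def dense_bounds(grid: "LatentGrid", trim: float = DENSE_TRIM) -> tuple[float, float]:
    """Latent range containing the central 1 - 2*trim of rank-normal scores,
    clipped to the grid."""
    lo = float(max(grid.lo, norm.ppf(trim)))
    hi = float(min(grid.hi, norm.ppf(1.0 - trim)))
    return lo, hi


@dataclass(frozen=True)
class LatentGrid:
    """Q equally spaced evaluation points on [lo, hi] (default 51 on [-3, 3])."""

    lo: float = -3.0
    hi: float = 3.0
    q: int = 51

    def __post_init__(self) -> None:
        if not (self.lo < self.hi and self.q >= 2):
            raise ValueError("grid needs lo < hi and at least 2 points")

    @property
    def points(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.q)


@dataclass
class LatentScores:
    """Per-subject summed score, mid-rank and rank-normal latent score."""

    summed: np.ndarray
    ranks: np.ndarray
    theta: np.ndarray


@dataclass
class OccSet:
    """Option characteristic curves of one item on a latent grid.

    ``probs[q, m]`` is the estimated probability of option ``option_codes[m]``
    at grid point q; rows sum to 1.
    """

    item: str
    grid: LatentGrid
    probs: np.ndarray
    option_codes: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.option_codes = np.asarray(self.option_codes)
        if self.probs.shape != (self.grid.q, len(self.option_codes)):
            raise ValueError("probs shape must be (Q, M)")


@dataclass
class IccCurve:
    """Expected item score ``e`` and conditional variance ``v`` over the grid."""

    item: str
    grid: LatentGrid
    e: np.ndarray
    v: np.ndarray


@dataclass
class SubscaleCurves:
    """Subscale-level curves: expected summed score T (isotonic), average
    item information, score density on the expected-score axis, and the
    summed-score standard error."""

    subscale: str
    grid: LatentGrid
    expected_score: np.ndarray
    information: np.ndarray
    density: np.ndarray
    se: np.ndarray


@dataclass
class ItemDiagnostics:
    item: str
    slope: float
    item_total_r: float


# ---------------------------------------------------------------------------
# latent scores and bandwidth


def latent_scores(summed: np.ndarray) -> LatentScores:
    """Rank-normal latent scores from summed scores.

    Mid-ranks average over ties, so tied summed scores share a latent
    score; ``theta = Phi^{-1}(rank / (N + 1))`` avoids infinite quantiles.
    """
    summed = np.asarray(summed, dtype=float)
    n = len(summed)
    if n == 0:
        raise ValueError("no subjects")
    ranks = rankdata(summed, method="average")
    theta = norm.ppf(ranks / (n + 1))
    return LatentScores(summed=summed, ranks=ranks, theta=theta)


def default_bandwidth(n: int) -> float:
    """h = 1.1 * N^(-1/5), the kernel-IRT convention for rank-normal scores."""
    if n < 2:
        raise ValueError("need at least 2 subjects")
    return 1.1 * n ** (-0.2)


# ---------------------------------------------------------------------------
# curve estimation


def estimate_occ(
    values: np.ndarray,
    scores: LatentScores,
    grid: LatentGrid,
    h: float,
    option_codes: np.ndarray,
    item: str = "",
) -> OccSet:
    """Nadaraya-Watson OCC estimate with a standard Gaussian kernel.

    ``P[q, m] = sum_i K((theta_q - theta_i)/h) 1[x_i = m] / sum_i K(...)``.
    """
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    values = np.asarray(values, dtype=float)
    option_codes = np.asarray(option_codes)
    if np.isnan(values).any():
        raise ValueError(f"item {item!r} has missing values")
    u = (grid.points[:, None] - scores.theta[None, :]) / h  # (Q, N)
    w = np.exp(-0.5 * u * u)
    denom = w.sum(axis=1)
    if np.any(denom <= 0):
        raise ZeroDivisionError("zero kernel mass at a grid point")
    indicator = values[None, :] == option_codes[:, None]  # (M, N)
    probs = (w @ indicator.T) / denom[:, None]
    return OccSet(item=item, grid=grid, probs=probs, option_codes=option_codes, bandwidth=h)


def icc_from_occ(occ: OccSet) -> IccCurve:
    """Moments of the option distribution at each grid point:
    ``e = sum_m m P[.,m]``, ``v = sum_m m^2 P[.,m] - e^2``."""
    codes = occ.option_codes.astype(float)
    e = occ.probs @ codes
    v = occ.probs @ codes**2 - e**2
    return IccCurve(item=occ.item, grid=occ.grid, e=e, v=np.maximum(v, 0.0))


def expected_subscale_score(iccs: list[IccCurve]) -> np.ndarray:
    """T[q] = sum_j e_j[q], projected to a nondecreasing function.

    The isotonic projection removes local decreases produced by sampling
    noise; a monotone T is required for summed-score inversion.
    """
    grids = {(c.grid.lo, c.grid.hi, c.grid.q) for c in iccs}
    if len(grids) != 1:
        raise ValueError("all ICCs must share the latent grid")
    t = np.sum([c.e for c in iccs], axis=0)
    theta = iccs[0].grid.points
    return IsotonicRegression(increasing=True).fit_transform(theta, t)


def _derivative(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Central differences in the interior, one-sided at the ends."""
    return np.gradient(y, x, edge_order=1)


def item_information(icc: IccCurve) -> np.ndarray:
    """I_j[q] = (e_j'[q])^2 / v_j[q]; defined as 0 where the item is
    degenerate (v = 0 forces a flat e, hence e' = 0)."""
    de = _derivative(icc.e, icc.grid.points)
    with np.errstate(divide="ignore", invalid="ignore"):
        info = np.where(icc.v > 1e-12, de**2 / np.where(icc.v > 1e-12, icc.v, 1.0), 0.0)
    return info


def average_information(iccs: list[IccCurve]) -> np.ndarray:
    return np.mean([item_information(c) for c in iccs], axis=0)


def summed_score_se(iccs: list[IccCurve]) -> np.ndarray:
    """Conditional SD of the summed score: sqrt(sum_j v_j[q]) (items treated
    as locally independent given severity)."""
    return np.sqrt(np.sum([c.v for c in iccs], axis=0))


def irt_se(iccs: list[IccCurve]) -> np.ndarray:
    """Alternative error curve on the latent metric: 1 / sqrt(J * Ibar)."""
    j = len(iccs)
    ibar = average_information(iccs)
    with np.errstate(divide="ignore"):
        return 1.0 / np.sqrt(np.maximum(j * ibar, 1e-300))


def score_density(
    scores: LatentScores, expected_score: np.ndarray, grid: LatentGrid
) -> np.ndarray:
    """Density of scores on the expected-score axis.

    A Gaussian KDE of the latent scores is transformed through the monotone
    map T by change of variables ``f_X(T(theta)) = f_theta(theta) / T'(theta)``
    and renormalised (trapezoid) to integrate to 1 over the achievable
    expected-score range.
    """
    t = np.asarray(expected_score, dtype=float)
    dt = _derivative(t, grid.points)
    if np.mean(dt <= 1e-9) > 0.2:
        raise ValueError(
            "expected-score function is flat on a substantial region; "
            "use a wider bandwidth"
        )
    dt = np.maximum(dt, 1e-9)
    f_theta = gaussian_kde(scores.theta)(grid.points)
    f_x = f_theta / dt
    area = np.trapezoid(f_x, t)
    if area <= 0:
        raise ValueError("degenerate score density")
    return f_x / area


# ---------------------------------------------------------------------------
# item diagnostics


def icc_slope_at_median(
    icc: IccCurve,
    median_option: float,
    halfwidth: float = 1.0,
    bounds: tuple[float, float] | None = None,
) -> float:
    """ICC slope de/dtheta at the median-option crossing.

    The crossing is the grid point where the ICC is nearest the median
    option code (ties broken toward lower theta).  The slope is a local
    least-squares fit of e on theta over a +-``halfwidth`` window around
    the crossing, weighted by the standard-normal density (the known law of
    rank-normal scores), so the data-sparse, noise-dominated grid edges
    contribute little.  Exact for linear ICCs; zero for curves symmetric
    about the crossing.  ``bounds`` restricts the crossing search to a
    latent range.
    """
    theta = icc.grid.points
    b_lo, b_hi = bounds if bounds is not None else (theta[0], theta[-1])
    inside = (theta >= b_lo) & (theta <= b_hi)
    candidates = np.where(inside, np.abs(icc.e - median_option), np.inf)
    q = int(np.argmin(candidates))
    window = (theta >= theta[q] - halfwidth) & (theta <= theta[q] + halfwidth)
    x, y = theta[window], icc.e[window]
    if len(x) < 2:
        return 0.0
    w = norm.pdf(x)
    xbar = np.average(x, weights=w)
    sxx = np.average((x - xbar) ** 2, weights=w)
    if sxx <= 0:
        return 0.0
    sxy = np.average((x - xbar) * (y - np.average(y, weights=w)), weights=w)
    return float(sxy / sxx)


def item_total_correlation(values: np.ndarray, totals: np.ndarray) -> float:
    """Pearson correlation between item score and subscale summed score.

    Returns NaN when either array is constant.
    """
    values = np.asarray(values, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if values.std() == 0 or totals.std() == 0:
        return float("nan")
    return float(np.corrcoef(values, totals)[0, 1])
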