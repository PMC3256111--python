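"""Summed-score linking between a short form and the full instrument.

Both forms are fitted on the same population, giving monotone expected
summed-score functions T_short(theta) and T_full(theta) on a common latent
grid.  Each achievable integer short-form score s is carried to the latent
axis by inverting T_short (linear interpolation; flat segments resolve to
their midpoint) and back down to the full-form metric through T_full,
rounded half-up to an integer.  The result is a monotone conversion table;
its accuracy is measured on held-out subjects as the mean difference
between the converted short-form score and the observed full-form score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import RatingsMatrix
from .scale import ScaleDefinition


@dataclass
class ScoreFunction:
    """Monotone (isotonic-projected) expected summed score on a theta grid."""

    theta: np.ndarray
    values: np.ndarray
    label: str = "full"
    subscale: str = ""

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.theta.shape != self.values.shape:
            raise ValueError("theta and values must have equal length")
        if np.any(np.diff(self.theta) <= 0):
            raise ValueError("theta grid must be strictly increasing")
        if np.any(np.diff(self.values) < -1e-9):
            raise ValueError("expected-score values must be nondecreasing")

    def __call__(self, theta: float | np.ndarray) -> np.ndarray:
        return np.interp(theta, self.theta, self.values)

    @property
    def score_range(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])


def invert_score_function(t: ScoreFunction, s: float) -> float:
    """theta with T(theta) = s by linear interpolation.

    Flat segments resolve to their midpoint; scores outside the achievable
    range are clamped to the nearer endpoint with a warning.
    """
    lo, hi = t.score_range
    if s < lo or s > hi:
        warnings.warn(
            f"summed score {s} outside achievable range [{lo:.3f}, {hi:.3f}]; clamped",
            stacklevel=2,
        )
        return float(t.theta[0] if s < lo else t.theta[-1])
    v, th = t.values, t.theta

    i = int(np.searchsorted(v, s, side="left"))
    if i == 0:
        theta_left = th[0]
    elif v[i] == v[i - 1]:
        theta_left = th[i]
    else:
        theta_left = th[i - 1] + (s - v[i - 1]) / (v[i] - v[i - 1]) * (th[i] - th[i - 1])

    j = int(np.searchsorted(v, s, side="right"))
    if j == len(v):
        theta_right = th[-1]
    elif v[j] == v[j - 1]:
        theta_right = th[j - 1]
    else:
        theta_right = th[j - 1] + (s - v[j - 1]) / (v[j] - v[j - 1]) * (th[j] - th[j - 1])

    return float(0.5 * (theta_left + theta_right))


@dataclass
class ConversionTable:
    """Monotone integer map short-form summed score -> full-form summed score."""

    subscale: str
    short_scores: np.ndarray
    full_scores: np.ndarray

    def __post_init__(self) -> None:
        self.short_scores = np.asarray(self.short_scores, dtype=int)
        self.full_scores = np.asarray(self.full_scores, dtype=int)
        if np.any(np.diff(self.short_scores) != 1):
            raise ValueError("short scores must be consecutive integers")
        if np.any(np.diff(self.full_scores) < 0):
            raise ValueError("mapped scores must be nondecreasing")

    def __call__(self, s: int | np.ndarray) -> np.ndarray:
        s = np.asarray(s)
        clipped = np.clip(s, self.short_scores[0], self.short_scores[-1])
        return self.full_scores[clipped - self.short_scores[0]]

    def n_clamped(self, s: np.ndarray) -> int:
        s = np.asarray(s)
        return int(((s < self.short_scores[0]) | (s > self.short_scores[-1])).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"short_score": self.short_scores, "full_score": self.full_scores}
        )


def build_conversion_table(
    t_short: ScoreFunction, t_full: ScoreFunction, subscale: str = ""
) -> ConversionTable:
    """Compose inversion of T_short with evaluation of T_full.

    Rows span the integers inside the short form's achievable
    expected-score range; mapped scores are rounded half-up.
    """
    if t_short.theta.shape != t_full.theta.shape or np.any(t_short.theta != t_full.theta):
        raise ValueError("score functions must share the theta grid")
    lo, hi = t_short.score_range
    short_scores = np.arange(math.ceil(lo - 1e-9), math.floor(hi + 1e-9) + 1)
    if len(short_scores) == 0:
        raise ValueError("no achievable integer scores in the short-form range")
    full = []
    for s in short_scores:
        theta_s = invert_score_function(t_short, float(s))
        full.append(math.floor(float(t_full(theta_s)) + 0.5))
    return ConversionTable(
        subscale=subscale or t_short.subscale,
        short_scores=short_scores,
        full_scores=np.asarray(full),
    )


@dataclass
class LinkingBias:
    """Converted-minus-observed full-form score on a validation sample."""

    subscale: str
    mean: float
    min: float
    max: float
    n: int
    n_clamped: int = 0

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValueError("min <= mean <= max violated")


def evaluate_linking(
    table: ConversionTable,
    validation: RatingsMatrix,
    full_scale: ScaleDefinition,
    short_scale: ScaleDefinition,
    subscale: str,
) -> LinkingBias:
    """Per-subject difference table(short sum) - full sum over a validation
    sample; the mean is reported to 3 decimals."""
    short_items = list(short_scale.subscales[subscale])
    full_items = list(full_scale.subscales[subscale])
    missing = [it for it in full_items if it not in validation.values.columns]
    if missing:
        raise ValueError(f"validation sample lacks full-form items: {missing}")
    short_sum = validation.values[short_items].sum(axis=1).to_numpy()
    full_sum = validation.values[full_items].sum(axis=1).to_numpy()
    n_clamped = table.n_clamped(short_sum)
    if n_clamped:
        warnings.warn(
            f"{n_clamped} validation subjects outside the conversion table range; "
            "nearest row used",
            stacklevel=2,
        )
    diff = table(short_sum.astype(int)) - full_sum
    return LinkingBias(
        subscale=subscale,
        mean=round(float(diff.mean()), 3),
        min=float(diff.min()),
        max=float(diff.max()),
        n=len(diff),
        n_clamped=n_clamped,
    )
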