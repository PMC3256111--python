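"""Graded-response-model cohort simulation.

The generator is the logistic graded response model (GRM): item *j* has a
discrimination ``a`` and strictly increasing cumulative thresholds
``b_2 <= ... <= b_M`` on the latent severity axis, and

    P(X >= m | theta) = L(a (theta - b_m)),   L the standard logistic,

so the probability of option ``m`` is the difference of adjacent cumulative
curves.  The GRM produces ordered, unimodal-region option curves (the
geometry of a well-behaved rating item) and gives closed-form oracle curves
for recovery tests of the kernel estimator.

Archetype constructors emulate the item pathologies seen in clinical rating
scales: genuinely flat (non-discriminating) items, items whose top option is
essentially never used, and items whose interior options are swamped by
their neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import skewnorm

from .data import RatingsMatrix
from .scale import ScaleDefinition


@dataclass(frozen=True)
class GrmItemParams:
    """Discrimination ``a >= 0`` and strictly increasing thresholds ``b``
    (length M-1 for an M-option item)."""

    a: float
    b: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("discrimination a must be >= 0")
        bb = np.asarray(self.b, dtype=float)
        if bb.ndim != 1 or len(bb) < 1:
            raise ValueError("need at least one threshold")
        if not np.all(np.diff(bb) > 0):
            raise ValueError(f"thresholds must be strictly increasing, got {self.b}")

    @property
    def n_options(self) -> int:
        return len(self.b) + 1


def grm_option_probs(
    theta: float | np.ndarray, item: GrmItemParams, n_options: int | None = None
) -> np.ndarray:
    """Option probabilities P(option m | theta), m = 1..M.

    Returns shape ``(M,)`` for scalar theta, else ``theta.shape + (M,)``.
    Rows are nonnegative and sum to 1.
    """
    if n_options is not None and n_options != item.n_options:
        raise ValueError(
            f"item has {item.n_options} options, caller expects {n_options}"
        )
    th = np.asarray(theta, dtype=float)
    b = np.asarray(item.b, dtype=float)
    # cumulative P(X >= m) for m = 2..M, with the m=1 curve identically 1
    cum = expit(item.a * (th[..., None] - b))
    upper = np.concatenate(
        [np.ones(th.shape + (1,)), cum, np.zeros(th.shape + (1,))], axis=-1
    )
    probs = upper[..., :-1] - upper[..., 1:]
    probs = np.clip(probs, 0.0, 1.0)
    if np.isscalar(theta) or th.ndim == 0:
        return probs.reshape(-1)
    return probs


def expected_item_score(
    theta: np.ndarray, item: GrmItemParams, option_min: int = 1
) -> np.ndarray:
    """Closed-form generator ICC: E[X | theta] on the option-code scale."""
    probs = grm_option_probs(np.asarray(theta, dtype=float), item)
    codes = option_min + np.arange(item.n_options)
    return probs @ codes


_ARCHETYPES = (
    "ideal",
    "flat",
    "ceiling_compressed",
    "disordered_regions",
    "range_restricted",
)


def make_archetype(kind: str, n_options: int = 7) -> GrmItemParams:
    """Named generator archetypes for an ``n_options``-level item.

    ideal
        Highly discriminating (a = 1.8) with thresholds equally spaced on
        [-2, 2]: every option owns a clean severity region.
    flat
        Barely discriminating (a = 0.1) with thresholds spread over [-6, 6]:
        every option curve stays low and nearly level across the observable
        severity range, so the item carries almost no information.
    ceiling_compressed
        Like ideal but the top threshold sits at 3.8, so the extreme option
        is practically never rated (P(top option | theta = 2) < 0.05).
    range_restricted
        Weakly discriminating (a = 0.4) with all thresholds pushed high
        (1 to 5): the item is rarely endorsed beyond the lowest options and
        its expected score never reaches the median option level.
    disordered_regions
        Moderate a with near-coincident interior thresholds: the interior
        options are dominated everywhere by their neighbours, producing
        empty modal regions (GRM thresholds stay ordered; the overlap comes
        from their closeness).
    """
    if n_options < 2:
        raise ValueError("need at least 2 options")
    k = n_options - 1  # number of thresholds
    if kind == "ideal":
        return GrmItemParams(a=1.8, b=tuple(np.linspace(-2.0, 2.0, k)))
    if kind == "flat":
        return GrmItemParams(a=0.1, b=tuple(np.linspace(-6.0, 6.0, k)))
    if kind == "ceiling_compressed":
        b = np.linspace(-2.0, 2.0, k)
        b[-1] = 3.8
        return GrmItemParams(a=1.8, b=tuple(b))
    if kind == "range_restricted":
        return GrmItemParams(a=0.4, b=tuple(np.linspace(1.0, 5.0, k)))
    if kind == "disordered_regions":
        if k == 1:
            return GrmItemParams(a=0.6, b=(0.0,))
        inner = np.linspace(-0.05, 0.05, k - 2) if k > 2 else np.array([])
        b = np.concatenate([[-1.5], inner, [1.5]])
        return GrmItemParams(a=0.6, b=tuple(np.sort(b)))
    raise ValueError(f"unknown archetype kind {kind!r}; choose from {_ARCHETYPES}")


# ---------------------------------------------------------------------------
# Cohort configuration


@dataclass
class SeverityDistribution:
    """Latent severity law: ``normal(mu, sigma)`` or
    ``skew_normal(location, scale, shape)``."""

    kind: str = "normal"
    params: tuple[float, ...] = (0.0, 1.0)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "normal":
            mu, sigma = self.params
            return rng.normal(mu, sigma, size=n)
        if self.kind == "skew_normal":
            loc, scale, shape = self.params
            return skewnorm.rvs(shape, loc=loc, scale=scale, size=n, random_state=rng)
        raise ValueError(f"unknown severity distribution {self.kind!r}")


def right_skewed_severity(shape: float = 4.0) -> SeverityDistribution:
    """Skew-normal severity standardised to mean 0, variance 1.

    Positive ``shape`` yields right skew: very severe patients are rarer
    than mildly ill ones, mirroring clinical trial baselines.
    """
    delta = shape / np.sqrt(1 + shape**2)
    mean = delta * np.sqrt(2 / np.pi)
    sd = np.sqrt(1 - 2 * delta**2 / np.pi)
    return SeverityDistribution("skew_normal", (-mean / sd, 1.0 / sd, shape))


@dataclass
class CohortConfig:
    """Everything needed to simulate one cross-sectional cohort."""

    scale: ScaleDefinition
    item_params: dict[str, GrmItemParams]
    n: int
    seed: int = 0
    severity: SeverityDistribution = field(default_factory=right_skewed_severity)
    covariate_generators: dict[str, Callable[[int, np.random.Generator], np.ndarray]] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        missing = [it for it in self.scale.items if it not in self.item_params]
        if missing:
            raise ValueError(f"missing GRM parameters for items: {missing}")
        for it, p in self.item_params.items():
            if it in self.scale.items and p.n_options != self.scale.n_options:
                raise ValueError(
                    f"item {it!r} has {p.n_options} options, scale expects "
                    f"{self.scale.n_options}"
                )


def default_covariate_generators() -> dict[str, Callable]:
    """Demographics resembling a schizophrenia trial population."""

    def age(n, rng):
        return np.clip(rng.normal(39.5, 12.2, n), 18, 80).round(0)

    def gender(n, rng):
        return rng.choice(["Male", "Female"], size=n, p=[0.665, 0.335])

    def diagnosis(n, rng):
        return rng.choice(["Schizophrenia", "Schizoaffective"], size=n, p=[0.955, 0.045])

    def race(n, rng):
        return rng.choice(
            ["Caucasian", "Black", "Asian", "Hispanic", "Other"],
            size=n,
            p=[0.672, 0.176, 0.070, 0.051, 0.031],
        )

    return {"age": age, "gender": gender, "diagnosis": diagnosis, "race": race}


def simulate_cohort(
    config: CohortConfig, extra_items: dict[str, GrmItemParams] | None = None
) -> RatingsMatrix:
    """Draw a cohort: theta_i from the severity law, then each item from its
    GRM option distribution.  Deterministic under ``config.seed``.

    ``extra_items`` are additional columns generated from the same latent
    draws but not part of the scale definition; they are returned in the
    covariates frame so candidate items can be scored against an anchor
    scale (see :mod:`ksirt.criteria`).
    """
    master = np.random.SeedSequence(config.seed)
    theta_seed, item_seed, cov_seed = master.spawn(3)
    theta = config.severity.sample(config.n, np.random.default_rng(theta_seed))

    rng_items = np.random.default_rng(item_seed)
    codes = np.arange(config.scale.option_min, config.scale.option_max + 1)
    values = {}
    for item_id in config.scale.items:
        probs = grm_option_probs(theta, config.item_params[item_id])
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng_items.random(config.n)
        values[item_id] = codes[(probs.cumsum(axis=1) < u[:, None]).sum(axis=1)]
    vals = pd.DataFrame(values, index=pd.RangeIndex(config.n, name="subject_id"))

    cov_frames = {}
    if extra_items:
        for item_id, params in extra_items.items():
            probs = grm_option_probs(theta, params)
            probs /= probs.sum(axis=1, keepdims=True)
            xcodes = config.scale.option_min + np.arange(params.n_options)
            u = rng_items.random(config.n)
            cov_frames[item_id] = xcodes[(probs.cumsum(axis=1) < u[:, None]).sum(axis=1)]
    if config.covariate_generators:
        rng_cov = np.random.default_rng(cov_seed)
        for name, gen in config.covariate_generators.items():
            cov_frames[name] = gen(config.n, rng_cov)
    cov = pd.DataFrame(cov_frames, index=vals.index) if cov_frames else None
    return RatingsMatrix(vals, config.scale, cov)


def panss_like_config(
    n: int = 7187,
    seed: int = 0,
    weak_items: dict[str, str] | None = None,
    severity: SeverityDistribution | None = None,
    with_covariates: bool = True,
) -> CohortConfig:
    """A PANSS-shaped cohort: 30 items x 7 options in subscales of 7/7/16.

    Sound items get discriminations spread over [1.0, 1.8] with thresholds
    spanning roughly [-2, 3.5] (the top threshold is pushed high so the
    extreme option is rare, as observed clinically).  ``weak_items`` maps
    item IDs to archetype kinds; by default the items the published study
    found Weak are generated from pathological archetypes.
    """
    from .scale import panss

    scale = panss()
    if weak_items is None:
        weak_items = {
            "P7": "disordered_regions",
            "N5": "range_restricted",
            "G1": "flat",
            "G2": "ceiling_compressed",
            "G3": "range_restricted",
            "G5": "disordered_regions",
            "G10": "flat",
            "G11": "disordered_regions",
            "G12": "range_restricted",
            "G15": "flat",
            "G16": "range_restricted",
        }
    rng = np.random.default_rng(np.random.SeedSequence((seed, 9121)))
    params: dict[str, GrmItemParams] = {}
    for item_id in scale.items:
        if item_id in weak_items:
            params[item_id] = make_archetype(weak_items[item_id], scale.n_options)
            continue
        a = float(rng.uniform(1.0, 1.8))
        lo = float(rng.uniform(-2.2, -1.6))
        hi = float(rng.uniform(1.6, 2.2))
        b = np.linspace(lo, hi, scale.n_options - 1)
        b[-1] = float(rng.uniform(3.0, 3.8))  # extreme option rarely rated
        params[item_id] = GrmItemParams(a=a, b=tuple(b))
    return CohortConfig(
        scale=scale,
        item_params=params,
        n=n,
        seed=seed,
        severity=severity or right_skewed_severity(),
        covariate_generators=default_covariate_generators() if with_covariates else None,
    )
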