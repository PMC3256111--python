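"""Operational item-selection criteria for rating-scale shortening.

Five criteria grade each item from its fitted curves:

1. **Options used** -- how many option levels the ICC actually reaches
   (Yes when the ICC maximum rounds to at least the 5th option level).
2. **Rapid increase** -- option curves should rise briskly with severity
   (No when every non-extreme option stays below ``p_flat`` or no curve
   ever doubles; Yes when a majority of the non-lowest options reach
   half-maximum at or below the midpoint of the expected-score range;
   Somewhat when the rises only happen above that midpoint).
3. **Region ordering** -- the severity regions where each option is modal
   should be ordered with the option codes (Yes: 0 violations,
   Somewhat: 1-4, No: >= 5; an option with no modal region is a violation).
4. **Span** -- options should cover the severity continuum (an option is
   displaced when its support ``P >= tau`` is empty, or sits entirely above
   the 25th percentile of the expected-score range for the two lowest
   options / entirely below the 75th percentile for the two highest; No
   when >= 4 options are displaced).
5. **Slope** -- ICC slope at the median option crossing >= 0.40.

Global rule: an item is *Very Good* with >= 4 Yes ratings, *Good* with
exactly 3, *Weak* otherwise ("Somewhat" carries no weight).  Items rated
Weak are dropped from the short form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernel import IccCurve, OccSet
from .scale import ScaleDefinition

YES, SOMEWHAT, NO = "Yes", "Somewhat", "No"
VERY_GOOD, GOOD, WEAK = "Very Good", "Good", "Weak"


@dataclass(frozen=True)
class CriteriaThresholds:
    """Tunable cut-offs of the operational criteria (defaults as documented)."""

    c1_min_options: int = 5      # Yes when >= this many option levels reached
    p_flat: float = 0.3          # criterion 2: flat ceiling for non-extreme options
    tau: float = 0.05            # criterion 4: support threshold
    c4_no_min: int = 4           # criterion 4: displaced options needed for No
    slope_cut: float = 0.40      # criterion 5
    c3_no_min: int = 5           # criterion 3: violations needed for No
    theta_trim: float = 0.005    # judge curves on the central 1 - 2*trim range


@dataclass(frozen=True)
class CriterionRating:
    index: int
    rating: str
    evidence: float | int | None = None

    def __post_init__(self) -> None:
        if self.index in (1, 4, 5) and self.rating == SOMEWHAT:
            raise ValueError(f"criterion {self.index} never takes Somewhat")


@dataclass
class ItemClassification:
    item: str
    ratings: tuple[CriterionRating, ...]
    yes_count: int = field(init=False)
    rating: str = field(init=False)

    def __post_init__(self) -> None:
        if len(self.ratings) != 5:
            raise ValueError("need all five criterion ratings")
        self.yes_count = sum(r.rating == YES for r in self.ratings)
        self.rating = classify_yes_count(self.yes_count)

    @property
    def retained(self) -> bool:
        return self.rating != WEAK


def classify_yes_count(yes_count: int) -> str:
    """>= 4 Yes -> Very Good; exactly 3 -> Good; <= 2 -> Weak."""
    if yes_count >= 4:
        return VERY_GOOD
    if yes_count == 3:
        return GOOD
    return WEAK


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


# ---------------------------------------------------------------------------
# individual criteria


def _grid_mask(grid, mask: np.ndarray | None) -> np.ndarray:
    if mask is None:
        return np.ones(grid.q, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (grid.q,) or not mask.any():
        raise ValueError("mask must select at least one grid point")
    return mask


def criterion1_options_used(
    icc: IccCurve,
    option_min: int = 1,
    thresholds: CriteriaThresholds | None = None,
    mask: np.ndarray | None = None,
) -> tuple[int, str]:
    """Number of option levels reached by the ICC maximum; Yes iff >= 5."""
    th = thresholds or CriteriaThresholds()
    m = _grid_mask(icc.grid, mask)
    count = _round_half_up(float(np.max(icc.e[m]))) - option_min + 1
    return count, (YES if count >= th.c1_min_options else NO)


def criterion2_rapid_increase(
    occ: OccSet,
    expected_score: np.ndarray,
    thresholds: CriteriaThresholds | None = None,
    mask: np.ndarray | None = None,
) -> str:
    """Do the option curves rise rapidly with severity?"""
    th = thresholds or CriteriaThresholds()
    m = _grid_mask(occ.grid, mask)
    p = occ.probs[m]
    t = np.asarray(expected_score, dtype=float)[m]
    grid_points = occ.grid.points[m]

    interior = slice(1, -1)  # non-extreme options
    flat = bool(np.all(p[:, interior].max(axis=0) <= th.p_flat))

    def doubles(col: np.ndarray) -> bool:
        peak_at = int(np.argmax(col))
        lead_in = col[: peak_at + 1]
        return bool(len(lead_in) > 1 and col[peak_at] >= 2.0 * lead_in.min())

    any_doubling = any(doubles(p[:, j]) for j in range(1, p.shape[1]))
    if flat or not any_doubling:
        return NO

    # theta at the midpoint of the achievable expected-score range
    t_mid = 0.5 * (t.min() + t.max())
    theta_mid = float(np.interp(t_mid, t, grid_points))

    rising = 0
    n_upper = p.shape[1] - 1  # options above the lowest code
    for j in range(1, p.shape[1]):
        col = p[:, j]
        half = 0.5 * col.max()
        reach = np.nonzero(col >= half)[0]
        if len(reach) and grid_points[reach[0]] <= theta_mid:
            rising += 1
    return YES if rising > n_upper / 2 else SOMEWHAT


def modal_locations(occ: OccSet, mask: np.ndarray | None = None) -> np.ndarray:
    """Midpoint of each option's modal region (theta where it is argmax);
    NaN for options that are never modal."""
    keep = _grid_mask(occ.grid, mask)
    modal = np.argmax(occ.probs[keep], axis=1)
    theta = occ.grid.points[keep]
    locs = np.full(occ.probs.shape[1], np.nan)
    for m in range(occ.probs.shape[1]):
        pts = theta[modal == m]
        if len(pts):
            locs[m] = 0.5 * (pts.min() + pts.max())
    return locs


def criterion3_region_ordering(
    occ: OccSet,
    thresholds: CriteriaThresholds | None = None,
    mask: np.ndarray | None = None,
) -> tuple[int, str]:
    """Count options whose modal region is empty or out of order."""
    th = thresholds or CriteriaThresholds()
    locs = modal_locations(occ, mask)
    violations = int(np.isnan(locs).sum())
    present = np.nonzero(~np.isnan(locs))[0]
    for k, m in enumerate(present):
        lo = locs[present[k - 1]] if k > 0 else -np.inf
        hi = locs[present[k + 1]] if k + 1 < len(present) else np.inf
        if not (lo <= locs[m] <= hi):
            violations += 1
    if violations == 0:
        rating = YES
    elif violations < th.c3_no_min:
        rating = SOMEWHAT
    else:
        rating = NO
    return violations, rating


def criterion4_span(
    occ: OccSet,
    expected_score: np.ndarray,
    thresholds: CriteriaThresholds | None = None,
    mask: np.ndarray | None = None,
) -> tuple[int, str]:
    """Count displaced options; No when >= 4 are displaced."""
    th = thresholds or CriteriaThresholds()
    keep = _grid_mask(occ.grid, mask)
    t = np.asarray(expected_score, dtype=float)[keep]
    probs = occ.probs[keep]
    t25 = t.min() + 0.25 * (t.max() - t.min())
    t75 = t.min() + 0.75 * (t.max() - t.min())
    n_opt = probs.shape[1]
    displaced = 0
    for m in range(n_opt):
        support = np.nonzero(probs[:, m] >= th.tau)[0]
        if len(support) == 0:
            displaced += 1
            continue
        t_support = t[support]
        if m <= 1 and t_support.min() > t25:
            displaced += 1
        elif m >= n_opt - 2 and t_support.max() < t75:
            displaced += 1
    return displaced, (NO if displaced >= th.c4_no_min else YES)


def criterion5_slope(
    slope: float, thresholds: CriteriaThresholds | None = None
) -> str:
    th = thresholds or CriteriaThresholds()
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    return YES if slope >= th.slope_cut else NO


def classify_item(ratings: list[CriterionRating] | tuple[CriterionRating, ...],
                  item: str = "") -> ItemClassification:
    return ItemClassification(item=item, ratings=tuple(ratings))


# ---------------------------------------------------------------------------
# applying the criteria to fitted results / fixtures


def classify_results(results, thresholds: CriteriaThresholds | None = None) -> pd.DataFrame:
    """Grade every item of a :class:`~ksirt.model.KernelIRTResults`.

    Returns a DataFrame with the per-criterion ratings, supporting
    evidence, Yes count, global rating and retained flag.
    """
    from scipy.stats import norm

    th = thresholds or CriteriaThresholds()
    scale = results.model.scale
    t = results.curves.expected_score
    slopes = {d.item: d.slope for d in results.diagnostics}
    # judge curves where the rank-normal scores actually live: the grid
    # edges hold almost no subjects and their estimates are noise-dominated
    grid_pts = results.grid.points
    mask = (grid_pts >= norm.ppf(th.theta_trim)) & (
        grid_pts <= norm.ppf(1.0 - th.theta_trim)
    )
    if not mask.any():
        mask = np.ones_like(grid_pts, dtype=bool)
    rows = []
    for item_id, occ in results.occ.items():
        icc = results.icc[item_id]
        c1_count, c1 = criterion1_options_used(icc, scale.option_min, th, mask)
        c2 = criterion2_rapid_increase(occ, t, th, mask)
        c3_viol, c3 = criterion3_region_ordering(occ, th, mask)
        c4_disp, c4 = criterion4_span(occ, t, th, mask)
        c5 = criterion5_slope(slopes[item_id], th)
        cls = classify_item(
            [
                CriterionRating(1, c1, c1_count),
                CriterionRating(2, c2),
                CriterionRating(3, c3, c3_viol),
                CriterionRating(4, c4, c4_disp),
                CriterionRating(5, c5, slopes[item_id]),
            ],
            item=item_id,
        )
        rows.append(
            {
                "item": item_id,
                "c1_count": c1_count,
                "c1": c1,
                "c2": c2,
                "c3": c3,
                "c3_violations": c3_viol,
                "c4": c4,
                "c4_displaced": c4_disp,
                "c5": c5,
                "slope": slopes[item_id],
                "yes_count": cls.yes_count,
                "rating": cls.rating,
                "retained": cls.retained,
            }
        )
    return pd.DataFrame(rows).set_index("item", drop=False)


def classify_fixture(fixture: pd.DataFrame) -> pd.DataFrame:
    """Apply the Yes-count rule to a printed criterion-rating table.

    ``fixture`` needs columns c1..c5; the derived rating and retained flag
    are appended (printed ratings, if present, are left untouched for
    comparison)."""
    out = fixture.copy()
    yes = sum((out[c] == YES).astype(int) for c in ("c1", "c2", "c3", "c4", "c5"))
    out["yes_count"] = yes
    out["derived_rating"] = yes.map(classify_yes_count)
    out["retained"] = out["derived_rating"] != WEAK
    return out


def select_short_form(
    classifications: pd.DataFrame, scale: ScaleDefinition
) -> ScaleDefinition:
    """Short-form definition keeping exactly the non-Weak items (subscale
    grouping and order preserved).  Raises if a subscale loses every item."""
    col = "derived_rating" if "derived_rating" in classifications else "rating"
    keep = [it for it in scale.items if classifications.loc[it, col] != WEAK]
    return scale.subset(keep)


def criterion_counts(
    classifications: pd.DataFrame,
    scale: ScaleDefinition,
    subscale: str,
    criterion: int,
) -> tuple[int, float]:
    """Yes-count and percentage for one criterion within one subscale."""
    items = [it for it in scale.subscales[subscale] if it in classifications.index]
    if not items:
        raise ValueError(f"no classified items in subscale {subscale!r}")
    col = f"c{criterion}"
    count = int((classifications.loc[items, col] == YES).sum())
    return count, round(100.0 * count / len(items), 2)


# ---------------------------------------------------------------------------
# archetype evaluation harness


def classify_archetype(
    kind: str,
    n: int = 3000,
    seed: int = 0,
    n_anchor: int = 7,
    thresholds: CriteriaThresholds | None = None,
) -> pd.Series:
    """Simulate a cohort and grade one archetype item against an ideal anchor.

    The anchor subscale (``n_anchor`` ideal items) defines the latent
    ranking; the candidate item is generated from the archetype's GRM
    parameters on the same latent draws and its curves are estimated
    against the anchor scores.  Scoring a candidate against an anchor
    rather than against a total that includes it keeps a noisy item's own
    variance from inflating its apparent discrimination.
    """
    from .grm import CohortConfig, SeverityDistribution, make_archetype, simulate_cohort
    from .model import KernelIRT

    anchor_ids = tuple(f"A{i + 1}" for i in range(n_anchor))
    scale = ScaleDefinition(
        items=anchor_ids, subscales={"Anchor": anchor_ids}, option_min=1, option_max=7
    )
    config = CohortConfig(
        scale=scale,
        item_params={it: make_archetype("ideal", 7) for it in anchor_ids},
        n=n,
        seed=seed,
        severity=SeverityDistribution("normal", (0.0, 1.0)),
    )
    cohort = simulate_cohort(config, extra_items={"X": make_archetype(kind, 7)})
    x = cohort.covariates["X"].to_numpy()
    results = KernelIRT(cohort, "Anchor", extra_items={"X": x}).fit()
    table = classify_results(results, thresholds=thresholds)
    return table.loc["X"]
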