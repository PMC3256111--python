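"""Kernel-IRT primitives: latent scores, OCC/ICC estimation, derived curves."""

import numpy as np
import pytest
from scipy.stats import norm

from ksirt.kernel import (
    IccCurve,
    LatentGrid,
    LatentScores,
    OccSet,
    default_bandwidth,
    estimate_occ,
    expected_subscale_score,
    icc_from_occ,
    icc_slope_at_median,
    item_information,
    item_total_correlation,
    latent_scores,
    score_density,
    summed_score_se,
)

GRID = LatentGrid()
CODES7 = np.arange(1, 8)


def make_icc(e, v=None, grid=GRID):
    e = np.asarray(e, dtype=float)
    v = np.zeros_like(e) if v is None else np.asarray(v, dtype=float)
    return IccCurve(item="x", grid=grid, e=e, v=v)


class TestLatentScores:
    def test_single_subject_at_median(self):
        assert latent_scores(np.array([10.0])).theta[0] == pytest.approx(0.0)

    def test_three_distinct_totals(self):
        th = latent_scores(np.array([5.0, 9.0, 7.0])).theta
        expected = norm.ppf([0.25, 0.75, 0.5])
        assert np.allclose(th, expected)
        assert th[0] == pytest.approx(-0.6745, abs=1e-4)

    def test_ties_share_theta(self):
        th = latent_scores(np.array([3.0, 5.0, 5.0, 8.0])).theta
        assert th[1] == th[2]

    def test_nondecreasing_in_summed_score(self):
        rng = np.random.default_rng(0)
        s = rng.integers(7, 50, size=200).astype(float)
        sc = latent_scores(s)
        order = np.argsort(s)
        assert np.all(np.diff(sc.theta[order]) >= 0)


class TestBandwidth:
    def test_formula(self):
        assert default_bandwidth(100) == pytest.approx(1.1 * 100 ** -0.2)
        assert default_bandwidth(3594) == pytest.approx(1.1 * 3594 ** -0.2)

    def test_shrinks_with_n(self):
        assert default_bandwidth(10_000) < default_bandwidth(100)


def brute_force_occ(values, theta, grid_points, h, codes):
    """Independent oracle: explicit loops over subjects and grid points."""
    out = np.zeros((len(grid_points), len(codes)))
    for qi, tq in enumerate(grid_points):
        weights = [np.exp(-0.5 * ((tq - t) / h) ** 2) for t in theta]
        denom = sum(weights)
        for mi, code in enumerate(codes):
            num = sum(w for w, x in zip(weights, values) if x == code)
            out[qi, mi] = num / denom
    return out


class TestEstimateOcc:
    def test_constant_response(self):
        scores = LatentScores(np.ones(4), np.ones(4), np.array([-1.0, 0.0, 0.5, 1.0]))
        occ = estimate_occ(np.full(4, 4.0), scores, GRID, 0.5, CODES7)
        assert np.allclose(occ.probs[:, 3], 1.0)
        assert np.allclose(occ.probs.sum(axis=1), 1.0)

    def test_symmetric_two_subjects(self):
        scores = LatentScores(np.ones(2), np.ones(2), np.array([-1.0, 1.0]))
        occ = estimate_occ(np.array([1.0, 7.0]), scores, LatentGrid(-1, 1, 3), 1.0, CODES7)
        assert occ.probs[1, 0] == pytest.approx(0.5)
        assert occ.probs[1, 6] == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self):
        theta = np.array([-1.2, 0.3, 0.9])
        values = np.array([2.0, 5.0, 5.0])
        scores = LatentScores(values, values, theta)
        grid = LatentGrid(-2, 2, 9)
        occ = estimate_occ(values, scores, grid, 0.5, CODES7)
        oracle = brute_force_occ(values, theta, grid.points, 0.5, CODES7)
        assert np.max(np.abs(occ.probs - oracle)) < 1e-12

    def test_bad_bandwidth(self):
        scores = LatentScores(np.ones(2), np.ones(2), np.zeros(2))
        with pytest.raises(ValueError):
            estimate_occ(np.array([1.0, 2.0]), scores, GRID, 0.0, CODES7)


class TestIccFromOcc:
    @pytest.mark.parametrize(
        "probs, e, v",
        [
            (np.eye(7)[3], 4.0, 0.0),                       # degenerate at option 4
            (np.array([0.5, 0, 0, 0, 0, 0, 0.5]), 4.0, 9.0),  # two-point
            (np.full(7, 1 / 7), 4.0, 4.0),                   # uniform
        ],
    )
    def test_moments(self, probs, e, v):
        occ = OccSet("x", GRID, np.tile(probs, (GRID.q, 1)), CODES7, 0.2)
        icc = icc_from_occ(occ)
        assert np.allclose(icc.e, e)
        assert np.allclose(icc.v, v)


class TestSubscaleCurves:
    def test_constant_items_floor_and_ceiling(self):
        t_floor = expected_subscale_score([make_icc(np.ones(GRID.q))] * 7)
        assert np.allclose(t_floor, 7.0)
        t_ceil = expected_subscale_score([make_icc(np.full(GRID.q, 7.0))] * 7)
        assert np.allclose(t_ceil, 49.0)

    def test_monotone_inputs_stay_increasing(self):
        e = 4 + 0.5 * GRID.points
        t = expected_subscale_score([make_icc(e)] * 7)
        assert np.all(np.diff(t) > 0)
        assert np.allclose(t, 7 * e)

    def test_isotonic_projection_removes_dips(self):
        e = 4 + 0.5 * GRID.points
        e[25] -= 0.4  # sampling dip
        t = expected_subscale_score([make_icc(e)])
        assert np.all(np.diff(t) >= -1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="share the latent grid"):
            expected_subscale_score(
                [make_icc(np.ones(GRID.q)), make_icc(np.ones(11), grid=LatentGrid(-3, 3, 11))]
            )


class TestInformation:
    def test_constant_icc_no_information(self):
        info = item_information(make_icc(np.full(GRID.q, 3.0), np.ones(GRID.q)))
        assert np.allclose(info, 0.0)

    def test_linear_icc_constant_information(self):
        icc = make_icc(4 + 0.5 * GRID.points, np.ones(GRID.q))
        assert np.allclose(item_information(icc), 0.25)

    def test_doubling_slope_quadruples_information(self):
        i1 = item_information(make_icc(4 + 0.5 * GRID.points, np.ones(GRID.q)))
        i2 = item_information(make_icc(4 + 1.0 * GRID.points, np.ones(GRID.q)))
        assert np.allclose(i2, 4 * i1)

    def test_degenerate_item_zero_not_nan(self):
        info = item_information(make_icc(np.full(GRID.q, 4.0), np.zeros(GRID.q)))
        assert np.allclose(info, 0.0)


class TestSummedScoreSe:
    def test_degenerate_zero(self):
        assert np.allclose(summed_score_se([make_icc(np.ones(GRID.q))] * 7), 0.0)

    def test_variance_additivity(self):
        iccs = [make_icc(np.ones(GRID.q), np.full(GRID.q, 9 / 7))] * 7
        assert np.allclose(summed_score_se(iccs), 3.0)

    def test_invariant_to_item_order(self):
        rng = np.random.default_rng(1)
        iccs = [make_icc(np.ones(GRID.q), rng.uniform(0, 2, GRID.q)) for _ in range(5)]
        assert np.allclose(summed_score_se(iccs), summed_score_se(iccs[::-1]))


class TestScoreDensity:
    def test_linear_map_of_normal_scores(self):
        rng = np.random.default_rng(4)
        theta = norm.ppf(np.arange(1, 5001) / 5001.0)
        scores = LatentScores(theta, theta, theta)
        t = 28 + 7 * GRID.points
        f = score_density(scores, t, GRID)
        expected = norm.pdf(t, loc=28, scale=7)
        expected /= np.trapezoid(expected, t)
        assert np.max(np.abs(f - expected)) < 0.004

    def test_integrates_to_one(self, ideal_cohort):
        from ksirt.model import KernelIRT

        res = KernelIRT(ideal_cohort, "S").fit()
        area = np.trapezoid(res.curves.density, res.curves.expected_score)
        assert abs(area - 1) < 1e-3

    def test_right_skewed_cohort_mode_left_of_midpoint(self):
        from ksirt.grm import (
            CohortConfig, make_archetype, right_skewed_severity, simulate_cohort,
        )
        from ksirt.model import KernelIRT
        from ksirt.scale import ScaleDefinition

        ids = tuple(f"I{k}" for k in range(7))
        scale = ScaleDefinition(items=ids, subscales={"S": ids})
        cfg = CohortConfig(
            scale=scale,
            item_params={it: make_archetype("ideal", 7) for it in ids},
            n=4000,
            seed=12,
            severity=right_skewed_severity(shape=4.0),
        )
        res = KernelIRT(simulate_cohort(cfg), "S").fit()
        t = res.curves.expected_score
        mode = t[np.argmax(res.curves.density)]
        assert mode < 0.5 * (t.min() + t.max())

    def test_flat_map_raises(self):
        theta = norm.ppf(np.arange(1, 101) / 101.0)
        scores = LatentScores(theta, theta, theta)
        with pytest.raises(ValueError, match="wider bandwidth"):
            score_density(scores, np.full(GRID.q, 10.0), GRID)


class TestSlope:
    def test_linear_case(self):
        assert icc_slope_at_median(make_icc(4 + 0.5 * GRID.points), 4.0) == pytest.approx(0.5)

    def test_symmetric_parabola_zero_slope(self):
        e = 4 + GRID.points**2
        assert icc_slope_at_median(make_icc(e), 4.0) == pytest.approx(0.0, abs=1e-9)

    def test_constant_curve(self):
        assert icc_slope_at_median(make_icc(np.full(GRID.q, 2.0)), 4.0) == 0.0


class TestItemTotalCorrelation:
    def test_single_item_subscale_self_correlation(self):
        x = np.array([1.0, 3.0, 5.0, 7.0])
        assert item_total_correlation(x, x) == pytest.approx(1.0)

    def test_matches_direct_pearson(self):
        rng = np.random.default_rng(2)
        x = rng.integers(1, 8, 500).astype(float)
        totals = x + rng.integers(6, 43, 500)
        direct = np.corrcoef(x, totals)[0, 1]
        assert item_total_correlation(x, totals) == pytest.approx(direct)

    def test_reversed_coding_negates(self):
        rng = np.random.default_rng(3)
        x = rng.integers(1, 8, 200).astype(float)
        totals = x + rng.normal(0, 2, 200)
        r = item_total_correlation(x, totals)
        assert item_total_correlation(8 - x, totals) == pytest.approx(-r)

    def test_zero_variance_undefined(self):
        assert np.isnan(item_total_correlation(np.ones(5), np.arange(5.0)))


class TestRecovery:
    def test_occ_and_icc_recover_generator_curves(self):
        """Kernel estimates converge to the generating GRM curves on an
        all-ideal cohort (N = 3000)."""
        from ksirt.grm import (
            CohortConfig, SeverityDistribution, expected_item_score,
            grm_option_probs, make_archetype, simulate_cohort,
        )
        from ksirt.model import KernelIRT
        from ksirt.scale import ScaleDefinition

        ids = tuple(f"I{k}" for k in range(16))
        scale = ScaleDefinition(items=ids, subscales={"S": ids})
        params = {it: make_archetype("ideal", 7) for it in ids}
        cfg = CohortConfig(
            scale=scale, item_params=params, n=3000, seed=42,
            severity=SeverityDistribution("normal", (0.0, 1.0)),
        )
        res = KernelIRT(simulate_cohort(cfg), "S").fit()
        grid = res.grid.points
        mask = (grid >= -2) & (grid <= 2)
        for it in ids:
            occ_err = np.abs(res.occ[it].probs - grm_option_probs(grid, params[it]))
            assert occ_err[mask].mean() < 0.03
            icc_err = np.abs(res.icc[it].e - expected_item_score(grid, params[it]))
            assert icc_err[mask].mean() < 0.1

    def test_flat_information_below_ideal(self):
        """A flat archetype carries pointwise less information than an
        ideal archetype across the central severity range."""
        from ksirt.grm import expected_item_score, grm_option_probs, make_archetype

        grid = GRID.points
        mask = (grid >= -2) & (grid <= 2)
        infos = {}
        for kind in ("ideal", "flat"):
            item = make_archetype(kind, 7)
            probs = grm_option_probs(grid, item)
            occ = OccSet(kind, GRID, probs, CODES7, 0.2)
            infos[kind] = item_information(icc_from_occ(occ))
        assert np.all(infos["flat"][mask] < infos["ideal"][mask])
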