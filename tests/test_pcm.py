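"""Partial credit model: probabilities, estimation, extremes, score tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import raschscale as rs

# ---------------------------------------------------------------------------
# independent reference implementation used as the oracle throughout:
# direct evaluation of the category-probability formula, plus bisection on
# the expected-score curve.  Deliberately naive and separate from the package.


def oracle_probs(beta, delta, taus):
    weights = []
    for x in range(len(taus) + 1):
        expo = -sum(taus[:x]) + x * (beta - delta)
        weights.append(math.exp(expo))
    total = sum(weights)
    return [w / total for w in weights]


def oracle_expected_total(beta, instrument):
    total = 0.0
    for item in instrument.items:
        p = oracle_probs(beta, item.delta, list(item.thresholds))
        total += sum(x * px for x, px in enumerate(p))
    return total


def oracle_beta(target, instrument, lo=-50.0, hi=50.0, iters=200):
    for _ in range(iters):
        mid = (lo + hi) / 2
        if oracle_expected_total(mid, instrument) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def make_instrument(deltas, taus_per_item):
    return rs.Instrument(
        tuple(
            rs.ItemCalibration(delta=d, thresholds=tuple(t))
            for d, t in zip(deltas, taus_per_item)
        )
    )


INSTRUMENT_GRID = [
    make_instrument([0.0], [[0.0]]),  # single dichotomous item
    make_instrument([-1.0, 0.0, 1.0], [[0.0]] * 3),  # dichotomous triplet
    make_instrument([0.0] * 4, [[-1.0, 0.0, 1.0]] * 4),  # centered polytomous
    make_instrument(
        [-1.5, -0.5, 0.5, 1.5],
        [[-0.8, 0.8], [-1.2, 0.0, 1.2], [0.0], [-0.5, -0.1, 0.6]],
    ),  # mixed category counts, off-center items
    rs.generate_instrument(rs.SimulationConfig()),  # ESS-shaped, L = 24
]


class TestCategoryProbabilities:
    def test_dichotomous_at_item_location(self):
        item = rs.ItemCalibration(delta=1.3, thresholds=(0.0,))
        np.testing.assert_allclose(
            rs.category_probabilities(1.3, item), [0.5, 0.5], atol=1e-12
        )

    def test_uniform_when_all_exponents_vanish(self):
        item = rs.ItemCalibration(delta=0.7, thresholds=(0.0, 0.0, 0.0))
        np.testing.assert_allclose(
            rs.category_probabilities(0.7, item), [0.25] * 4, atol=1e-12
        )

    def test_matches_term_by_term_oracle(self):
        item = rs.ItemCalibration(delta=0.0, thresholds=(-1.0, 0.0, 1.0))
        got = rs.category_probabilities(0.5, item)
        np.testing.assert_allclose(got, oracle_probs(0.5, 0.0, [-1, 0, 1]), atol=1e-12)

    @given(
        beta=st.floats(-30, 30),
        delta=st.floats(-5, 5),
        taus=st.lists(st.floats(-3, 3), min_size=1, max_size=5),
    )
    @settings(derandomize=True, max_examples=150)
    def test_normalization_and_positivity(self, beta, delta, taus):
        taus = [t - sum(taus) / len(taus) for t in taus]  # center
        item = rs.ItemCalibration(delta=delta, thresholds=tuple(taus))
        p = rs.category_probabilities(beta, item)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)

    def test_dichotomous_reduction_to_basic_rasch(self):
        """With one zero threshold the polytomous formula is the basic model."""
        for beta in np.linspace(-6, 6, 25):
            for delta in (-2.0, 0.0, 1.7):
                item = rs.ItemCalibration(delta=delta, thresholds=(0.0,))
                p1 = rs.category_probabilities(beta, item)[1]
                expected = math.exp(beta - delta) / (1 + math.exp(beta - delta))
                assert p1 == pytest.approx(expected, abs=1e-12)

    def test_extreme_beta_is_stable(self):
        item = rs.ItemCalibration(delta=0.0, thresholds=(-1.0, 1.0))
        p = rs.category_probabilities(500.0, item)
        assert np.isfinite(p).all() and p[-1] == pytest.approx(1.0)

    def test_uncentered_thresholds_rejected(self):
        with pytest.raises(ValueError, match="centered"):
            rs.ItemCalibration(delta=0.0, thresholds=(0.5, 0.2))


class TestExpectedScoreAndInformation:
    def test_symmetric_instrument_at_zero(self, ess_like_instrument):
        exp_score, info = rs.expected_score_and_information(0.0, ess_like_instrument)
        assert exp_score == pytest.approx(ess_like_instrument.L / 2, abs=1e-9)
        assert info > 0

    def test_limits(self, ess_like_instrument):
        lo, _ = rs.expected_score_and_information(-60.0, ess_like_instrument)
        hi, _ = rs.expected_score_and_information(60.0, ess_like_instrument)
        assert lo == pytest.approx(0.0, abs=1e-9)
        assert hi == pytest.approx(ess_like_instrument.L, abs=1e-9)

    @pytest.mark.parametrize("beta", [-2.0, -0.3, 0.0, 1.1, 3.0])
    def test_information_is_score_derivative(self, ess_like_instrument, beta):
        """Fisher information equals dE[total]/dbeta (finite differences)."""
        h = 1e-5
        up, _ = rs.expected_score_and_information(beta + h, ess_like_instrument)
        dn, _ = rs.expected_score_and_information(beta - h, ess_like_instrument)
        _, info = rs.expected_score_and_information(beta, ess_like_instrument)
        assert info == pytest.approx((up - dn) / (2 * h), rel=1e-5)


class TestEstimatePerson:
    def test_midpoint_of_symmetric_instrument(self, ess_like_instrument):
        loc = rs.estimate_person(12, ess_like_instrument)
        assert loc.beta == pytest.approx(0.0, abs=1e-8)
        assert not loc.is_extreme

    def test_unadjusted_extremes_are_nonfinite(self, ess_like_instrument):
        lo = rs.estimate_person(0, ess_like_instrument, adjust_extremes=False)
        hi = rs.estimate_person(24, ess_like_instrument, adjust_extremes=False)
        assert lo.beta == -math.inf and hi.beta == math.inf
        assert lo.is_extreme and hi.is_extreme
        assert math.isinf(lo.se)

    @pytest.mark.parametrize("instrument", INSTRUMENT_GRID)
    def test_agrees_with_bisection_oracle(self, instrument):
        for raw in range(1, instrument.L):
            got = rs.estimate_person(raw, instrument)
            assert got.beta == pytest.approx(
                oracle_beta(raw, instrument), abs=1e-6
            ), f"raw score {raw}"
            _, info = rs.expected_score_and_information(got.beta, instrument)
            assert got.se == pytest.approx(1 / math.sqrt(info))

    def test_beta_increases_with_raw_score(self, ess_like_instrument):
        betas = [
            rs.estimate_person(r, ess_like_instrument).beta
            for r in range(0, ess_like_instrument.L + 1)
        ]
        assert all(b > a for a, b in zip(betas, betas[1:]))

    def test_out_of_range_score_rejected(self, ess_like_instrument):
        with pytest.raises(ValueError):
            rs.estimate_person(25, ess_like_instrument)


class TestExtremeAdjustment:
    def test_floor_sits_below_first_measurable_score(self, ess_like_instrument):
        floor = rs.extreme_adjustment(0, ess_like_instrument, epsilon=0.3)
        assert math.isfinite(floor.beta) and floor.is_extreme
        assert floor.beta < rs.estimate_person(1, ess_like_instrument).beta

    def test_small_epsilon_like_published_runs(self, ess_like_instrument):
        loc = rs.extreme_adjustment(0, ess_like_instrument, epsilon=0.185)
        assert math.isfinite(loc.beta) and math.isfinite(loc.se)

    def test_monotone_in_epsilon(self, ess_like_instrument):
        betas = [
            rs.extreme_adjustment(0, ess_like_instrument, epsilon=e).beta
            for e in (0.1, 0.2, 0.3, 0.5, 0.8)
        ]
        assert all(b > a for a, b in zip(betas, betas[1:]))

    def test_rejects_interior_scores_and_bad_epsilon(self, ess_like_instrument):
        with pytest.raises(ValueError):
            rs.extreme_adjustment(5, ess_like_instrument)
        with pytest.raises(ValueError):
            rs.extreme_adjustment(0, ess_like_instrument, epsilon=1.5)


class TestScoreToLogitTable:
    def test_ess_shape_gives_25_rows(self, ess_like_instrument):
        table = rs.score_to_logit_table(ess_like_instrument)
        assert len(table.rows) == 25
        assert table.L == 24
        assert table.rows[0].is_extreme and table.rows[24].is_extreme

    def test_single_dichotomous_item(self):
        table = rs.score_to_logit_table(make_instrument([0.0], [[0.0]]))
        assert len(table.rows) == 2
        assert all(r.is_extreme for r in table.rows)

    def test_ogive_gaps_wider_at_the_ends(self, ess_like_instrument):
        table = rs.score_to_logit_table(ess_like_instrument)
        logits = table.logits
        end_gap = logits[1] - logits[0]
        mid_gap = logits[12] - logits[11]
        assert end_gap > mid_gap

    def test_se_pattern_larger_at_extremes(self, ess_like_instrument):
        table = rs.score_to_logit_table(ess_like_instrument)
        mid_se = table.rows[12].se
        assert table.rows[0].se > mid_se
        assert table.rows[24].se > mid_se

    def test_feeds_transform_pipeline(self, ess_like_instrument):
        table = rs.score_to_logit_table(ess_like_instrument)
        spec = rs.TransformSpec.resolve(table, "lmd")
        tt = rs.transform_table(table, spec)
        assert np.all(np.diff(tt.real_locations) > 0)
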