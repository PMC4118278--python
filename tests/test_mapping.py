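import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eqmap.design import DesignSpec
from eqmap.mapping import (
    DimensionProbabilities,
    ProbabilityError,
    expected_utility_closed_form,
    expected_utility_enumeration,
    map_cohort,
)
from eqmap.ppom import PPOMError, fit_ppom
from eqmap.tariff import DIMENSIONS


def brute_force_expectation(matrix: np.ndarray, tariff) -> float:
    """Independent oracle: iterate raw level tuples and re-derive each
    state's score from the coefficient table, without the package's
    scoring or enumeration helpers."""
    total = 0.0
    for levels in itertools.product((1, 2, 3), repeat=5):
        weight = 1.0
        score = tariff.full_health_value
        if max(levels) > 1:
            score -= tariff.constant_any_problem
        if max(levels) == 3:
            score -= tariff.any_level3_decrement
        for d, (dim, level) in enumerate(zip(DIMENSIONS, levels)):
            weight *= matrix[d, level - 1]
            if level == 2:
                score -= tariff.level2_decrement[dim]
            elif level == 3:
                score -= tariff.level3_decrement[dim]
        total += weight * score
    return total


def _random_probs(seed: int) -> DimensionProbabilities:
    rng = np.random.default_rng(seed)
    return DimensionProbabilities(rng.dirichlet(np.ones(3), size=5))


class TestExpectedUtility:
    def test_worked_example(self, uk_tariff):
        # every dimension at (0.70, 0.20, 0.10)
        probs = DimensionProbabilities.uniform_rows(0.7, 0.2, 0.1)
        oracle = brute_force_expectation(probs.matrix, uk_tariff)
        enum = expected_utility_enumeration(probs, uk_tariff)
        closed = expected_utility_closed_form(probs, uk_tariff)
        assert oracle == pytest.approx(0.61745548, abs=1e-8)
        assert enum == pytest.approx(oracle, abs=1e-9)
        assert abs(enum - closed) < 1e-12

    @pytest.mark.parametrize(
        "row, expected",
        [((1.0, 0.0, 0.0), 1.0), ((0.0, 0.0, 1.0), -0.594)],
    )
    def test_degenerate_rows_hit_the_anchors(self, uk_tariff, row, expected):
        probs = DimensionProbabilities.uniform_rows(*row)
        assert expected_utility_enumeration(probs, uk_tariff) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected_utility_closed_form(probs, uk_tariff) == pytest.approx(
            expected, abs=1e-12
        )

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6))
    def test_closed_form_equals_enumeration(self, uk_tariff, seed):
        probs = _random_probs(seed)
        enum = expected_utility_enumeration(probs, uk_tariff)
        closed = expected_utility_closed_form(probs, uk_tariff)
        assert abs(enum - closed) < 1e-12
        assert -0.594 - 1e-12 <= closed <= 1.0 + 1e-12

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6))
    def test_shifting_mass_to_extreme_never_helps(self, uk_tariff, seed):
        # moving probability from level 1 to level 3 in one dimension
        probs = _random_probs(seed)
        base = expected_utility_closed_form(probs, uk_tariff)
        for d in range(5):
            m = probs.matrix.copy()
            shift = m[d, 0] * 0.5
            m[d, 0] -= shift
            m[d, 2] += shift
            worse = expected_utility_closed_form(DimensionProbabilities(m), uk_tariff)
            assert worse <= base + 1e-12

    def test_affine_in_each_row(self, uk_tariff):
        # E[U] is affine in any single row's probability vector
        base = _random_probs(3).matrix
        row_a = np.array([0.8, 0.15, 0.05])
        row_b = np.array([0.2, 0.3, 0.5])
        lam = 0.37

        def value(row):
            m = base.copy()
            m[2] = row
            return expected_utility_closed_form(DimensionProbabilities(m), uk_tariff)

        mixed = value(lam * row_a + (1 - lam) * row_b)
        assert mixed == pytest.approx(
            lam * value(row_a) + (1 - lam) * value(row_b), abs=1e-12
        )

    def test_strictly_below_one_with_any_off_level_mass(self, uk_tariff):
        probs = DimensionProbabilities.uniform_rows(0.999, 0.001, 0.0)
        assert expected_utility_closed_form(probs, uk_tariff) < 1.0


class TestValidation:
    def test_row_not_summing_is_named(self):
        m = np.tile([0.5, 0.3, 0.1], (5, 1))
        with pytest.raises(ProbabilityError, match="mobility"):
            DimensionProbabilities(m)

    def test_out_of_range_rejected(self):
        m = np.tile([1.2, -0.1, -0.1], (5, 1))
        with pytest.raises(ProbabilityError, match=r"\[0, 1\]"):
            DimensionProbabilities(m)


def _intercept_only_fits(df):
    empty = DesignSpec()
    fits = []
    for dim in DIMENSIONS:
        fit = fit_ppom(
            empty.build(df),
            df[dim].to_numpy(),
            dimension=dim,
            design_spec=empty,
            collapse_absent=True,
        )
        fits.append(fit)
    return fits


class TestMapCohort:
    @pytest.fixture
    def cohort(self):
        rng = np.random.default_rng(12)
        return pd.DataFrame(
            {dim: rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1], size=400) for dim in DIMENSIONS}
        )

    def test_intercept_only_maps_to_frequency_expectation(self, cohort, uk_tariff):
        fits = _intercept_only_fits(cohort)
        result = map_cohort(fits, cohort, uk_tariff)
        freq = np.stack(
            [np.bincount(cohort[d], minlength=4)[1:] / len(cohort) for d in DIMENSIONS]
        )
        expected = expected_utility_enumeration(
            DimensionProbabilities(freq), uk_tariff
        )
        np.testing.assert_allclose(result.utilities, expected, atol=1e-5)

    def test_enumeration_route_agrees(self, cohort, uk_tariff):
        fits = _intercept_only_fits(cohort)
        fast = map_cohort(fits, cohort.head(20), uk_tariff, method="closed_form")
        slow = map_cohort(fits, cohort.head(20), uk_tariff, method="enumeration")
        np.testing.assert_allclose(fast.utilities, slow.utilities, atol=1e-12)

    def test_wrong_dimension_order_is_rejected(self, cohort, uk_tariff):
        fits = _intercept_only_fits(cohort)
        with pytest.raises(PPOMError, match="questionnaire order"):
            map_cohort(fits[::-1], cohort, uk_tariff)

    def test_degenerate_full_health_cohort_maps_near_one(self, uk_tariff):
        df = pd.DataFrame({dim: np.ones(300, dtype=int) for dim in DIMENSIONS})
        fits = _intercept_only_fits(df)  # all collapse to smoothed constants
        result = map_cohort(fits, df, uk_tariff)
        np.testing.assert_allclose(result.utilities, 1.0, atol=0.01)
        assert (result.utilities < 1.0).all()

    def test_predictions_stay_inside_the_index(self, benchmark_results):
        for res in benchmark_results.values():
            assert res.ppom_pred.min() > -0.594
            assert res.ppom_pred.max() < 1.0
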