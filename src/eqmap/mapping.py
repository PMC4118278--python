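"""Expected EQ-5D utilities from predicted dimension-level probabilities.

Given, for one individual, a probability triplet over the three levels
of each of the five dimensions (assumed independent across dimensions),
the expected utility is the tariff score of each of the 243 health
states weighted by the product of its five level probabilities.

Two routes are provided: an explicit enumeration over all 243 states
(the reference path) and an algebraically equivalent closed form that
exploits the additive structure of the tariff:

    E[U] = 1 - c * P(any dimension > 1)
             - sum_d (p_d2 * delta2_d + p_d3 * delta3_d)
             - n3 * P(any dimension = 3)

with P(any > 1) = 1 - prod_d p_d1 and
P(any = 3) = 1 - prod_d (1 - p_d3) under independence. The two agree to
floating-point accuracy; the closed form is the fast path used for
cohorts.

Because the expectation averages over states, it can never return
exactly 1 unless every dimension puts all its mass on level 1 —
predicted utilities have no mass at full health even when the data do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ppom import PPOMError, PPOMFit, predict_probs
from .tariff import DIMENSIONS, TariffCoefficients, enumerate_states, score_state

_ROW_TOL = 1e-10


class ProbabilityError(ValueError):
    """Raised for invalid dimension-probability matrices."""


@dataclass(frozen=True)
class DimensionProbabilities:
    """A 5 (dimension) x 3 (level) row-stochastic probability matrix."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (5, 3):
            raise ProbabilityError(f"expected a 5x3 matrix, got shape {m.shape}")
        if np.any(m < 0.0) or np.any(m > 1.0):
            raise ProbabilityError("probabilities must lie in [0, 1]")
        sums = m.sum(axis=1)
        off = np.abs(sums - 1.0) > _ROW_TOL
        if off.any():
            dim = DIMENSIONS[int(np.flatnonzero(off)[0])]
            raise ProbabilityError(
                f"row for dimension {dim!r} sums to {sums[off][0]!r}, not 1"
            )
        object.__setattr__(self, "matrix", m)

    @classmethod
    def uniform_rows(cls, p1: float, p2: float, p3: float) -> "DimensionProbabilities":
        return cls(np.tile([p1, p2, p3], (5, 1)))


def expected_utility_enumeration(
    probs: DimensionProbabilities, tariff: TariffCoefficients
) -> float:
    """Expectation by explicit sum over all 243 health states."""
    m = probs.matrix
    total = 0.0
    for state in enumerate_states():
        weight = 1.0
        for d, level in enumerate(state.levels()):
            weight *= m[d, level - 1]
        total += weight * score_state(state, tariff)
    return total


def expected_utility_closed_form(
    probs: DimensionProbabilities, tariff: TariffCoefficients
) -> float:
    """Algebraic shortcut; equals the enumeration to ~1e-15."""
    return float(
        _closed_form_array(probs.matrix[np.newaxis, :, :], tariff)[0]
    )


def _closed_form_array(P: np.ndarray, tariff: TariffCoefficients) -> np.ndarray:
    """Vectorised closed form over an (n, 5, 3) probability array."""
    p_any_problem = 1.0 - np.prod(P[:, :, 0], axis=1)
    p_any_level3 = 1.0 - np.prod(1.0 - P[:, :, 2], axis=1)
    expected_decrement = np.zeros(P.shape[0])
    for d, dim in enumerate(DIMENSIONS):
        expected_decrement += P[:, d, 1] * tariff.level2_decrement[dim]
        expected_decrement += P[:, d, 2] * tariff.level3_decrement[dim]
    return (
        tariff.full_health_value
        - tariff.constant_any_problem * p_any_problem
        - expected_decrement
        - tariff.any_level3_decrement * p_any_level3
    )


@dataclass(frozen=True)
class MappingResult:
    """Per-row expected utilities plus clamp diagnostics per dimension."""

    utilities: np.ndarray
    neg_p2_fraction: dict[str, float]


def map_cohort(
    fits: Sequence[PPOMFit],
    df: pd.DataFrame,
    tariff: TariffCoefficients,
    method: str = "closed_form",
) -> MappingResult:
    """Expected utility for every row of ``df`` from five fitted models.

    ``fits`` must carry dimension tags in questionnaire order (mobility,
    self-care, usual activities, pain/discomfort, anxiety/depression) and
    each must hold the design recipe it was fitted with, so the per-
    dimension design can be rebuilt from the raw frame. If any fit uses
    other dimensions' responses as covariates, those observed responses
    must be present in ``df`` at prediction time.
    """
    tags = tuple(f.dimension for f in fits)
    if tags != DIMENSIONS:
        raise PPOMError(
            "expected five fits tagged in questionnaire order "
            f"{DIMENSIONS}, got {tags}"
        )
    n = len(df)
    P = np.empty((n, 5, 3))
    neg_frac: dict[str, float] = {}
    for d, fit in enumerate(fits):
        if fit.design_spec is None:
            raise PPOMError(
                f"fit for {fit.dimension!r} carries no design recipe; "
                "refit with design_spec set"
            )
        design = fit.design_spec.build(df)
        pred = predict_probs(fit, design)
        P[:, d, :] = pred.probs
        neg_frac[fit.dimension] = pred.neg_p2_fraction
    if method == "closed_form":
        utilities = _closed_form_array(P, tariff)
    elif method == "enumeration":
        utilities = np.array(
            [
                expected_utility_enumeration(DimensionProbabilities(P[i]), tariff)
                for i in range(n)
            ]
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return MappingResult(utilities=utilities, neg_p2_fraction=neg_frac)
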