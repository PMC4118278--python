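"""Covariate design construction for the regression models.

A design is an intercept-free matrix of continuous terms and dummy
expansions of declared categoricals. Level orders and reference
categories are always declared explicitly (first declared level is the
reference), never inferred from data order, so coefficient signs are
reproducible across runs and datasets.

EQ-5D dimension responses of *other* dimensions can be included as
covariates ("response indicators"): each named dimension expands to two
indicator columns, level 2 and level 3 versus the no-problem reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class DesignError(ValueError):
    """Raised for invalid design specifications or data/spec mismatches."""


class RankDeficientError(DesignError):
    """Raised when a design matrix is not of full column rank."""


@dataclass(frozen=True)
class DesignSpec:
    """Declarative recipe for building a :class:`CovariateDesign` from a frame.

    Parameters
    ----------
    continuous
        Column names taken as-is (e.g. centred age and its square).
    categorical
        Mapping column -> declared level order; the first level is the
        reference and is omitted from the dummy expansion.
    response_indicators
        Dimension columns (integer levels 1-3) expanded into level-2 and
        level-3 indicators against the no-problem reference.
    """

    continuous: tuple[str, ...] = ()
    categorical: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    response_indicators: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "continuous", tuple(self.continuous))
        object.__setattr__(
            self,
            "categorical",
            {k: tuple(v) for k, v in dict(self.categorical).items()},
        )
        object.__setattr__(self, "response_indicators", tuple(self.response_indicators))
        for col, levels in self.categorical.items():
            if len(levels) < 2:
                raise DesignError(
                    f"categorical {col!r} needs at least two declared levels"
                )
            if len(set(levels)) != len(levels):
                raise DesignError(f"categorical {col!r} has duplicate levels")

    def column_names(self) -> list[str]:
        names = list(self.continuous)
        for col, levels in self.categorical.items():
            names.extend(f"{col}[{lv}]" for lv in levels[1:])
        for dim in self.response_indicators:
            names.extend(f"{dim}[{lv}]" for lv in (2, 3))
        return names

    def build(self, df: pd.DataFrame, drop_constant: bool = True) -> "CovariateDesign":
        """Build the design matrix from ``df``.

        Zero-variance columns (e.g. a categorical level that every row or
        no row takes) are dropped and recorded in ``dropped`` so that the
        resulting matrix can be full rank; set ``drop_constant=False`` to
        keep them and fail rank validation instead.
        """
        missing = [
            c
            for c in (*self.continuous, *self.categorical, *self.response_indicators)
            if c not in df.columns
        ]
        if missing:
            raise DesignError(f"data is missing declared column(s): {', '.join(missing)}")

        pieces: list[np.ndarray] = []
        names: list[str] = []
        for col in self.continuous:
            x = np.asarray(df[col], dtype=float)
            if not np.all(np.isfinite(x)):
                raise DesignError(f"continuous column {col!r} contains non-finite values")
            pieces.append(x)
            names.append(col)
        for col, levels in self.categorical.items():
            observed = set(df[col].astype(str))
            unknown = observed - set(levels)
            if unknown:
                raise DesignError(
                    f"column {col!r} contains undeclared level(s): {sorted(unknown)}"
                )
            values = df[col].astype(str).to_numpy()
            for lv in levels[1:]:
                pieces.append((values == lv).astype(float))
                names.append(f"{col}[{lv}]")
        for dim in self.response_indicators:
            levels = np.asarray(df[dim], dtype=int)
            if not np.isin(levels, (1, 2, 3)).all():
                raise DesignError(f"response column {dim!r} has levels outside 1-3")
            for lv in (2, 3):
                pieces.append((levels == lv).astype(float))
                names.append(f"{dim}[{lv}]")

        matrix = np.column_stack(pieces) if pieces else np.empty((len(df), 0))
        dropped: list[str] = []
        if drop_constant and matrix.shape[1]:
            keep = matrix.std(axis=0) > 0
            dropped = [n for n, k in zip(names, keep) if not k]
            matrix = matrix[:, keep]
            names = [n for n, k in zip(names, keep) if k]
        return CovariateDesign(columns=tuple(names), matrix=matrix, dropped=tuple(dropped))


@dataclass(frozen=True)
class CovariateDesign:
    """An intercept-free design matrix with named columns."""

    columns: tuple[str, ...]
    matrix: np.ndarray
    dropped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.columns):
            raise DesignError("matrix shape does not match the column list")

    @property
    def n_obs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def validate_full_rank(self) -> None:
        """Raise :class:`RankDeficientError` naming collinear columns."""
        if self.n_cols == 0:
            return
        collinear = find_collinear_columns(self.matrix, self.columns)
        if collinear:
            raise RankDeficientError(
                f"design is rank deficient; collinear column(s): {', '.join(collinear)}"
            )

    def subset(self, columns: Sequence[str]) -> "CovariateDesign":
        index = {c: i for i, c in enumerate(self.columns)}
        missing = [c for c in columns if c not in index]
        if missing:
            raise DesignError(f"design has no column(s): {', '.join(missing)}")
        idx = [index[c] for c in columns]
        return CovariateDesign(columns=tuple(columns), matrix=self.matrix[:, idx])


def find_collinear_columns(matrix: np.ndarray, names: Sequence[str]) -> list[str]:
    """Names of columns that are linearly dependent on earlier ones.

    Greedy left-to-right: a column is reported when adding it to the
    columns already accepted does not increase the numerical rank, so
    the *later* member of a dependent pair gets named.
    """
    if matrix.shape[1] == 0:
        return []
    total_rank = np.linalg.matrix_rank(matrix)
    if total_rank == matrix.shape[1]:
        return []
    offenders: list[str] = []
    kept: list[int] = []
    rank = 0
    for j in range(matrix.shape[1]):
        candidate = matrix[:, kept + [j]]
        new_rank = np.linalg.matrix_rank(candidate)
        if new_rank > rank:
            kept.append(j)
            rank = new_rank
        else:
            offenders.append(names[j])
    return offenders
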