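"""Accuracy metrics and distributional summaries for predicted utilities.

Individual-level error is summarised by the mean absolute error (MAE)
and root mean squared error (RMSE), overall and within sub-groups of the
*actual* utility. The default bands are utility < 0, [0, 0.5),
[0.5, 0.75) and >= 0.75 — lower-closed, upper-open, except the top band
which is closed on both sides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: The default sub-grouping of the utility index by actual score.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (-math.inf, 0.0),
    (0.0, 0.5),
    (0.5, 0.75),
    (0.75, math.inf),
)


class EvaluationError(ValueError):
    """Raised for invalid metric inputs (length mismatch, bad bands...)."""


def _check_pair(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.ndim != 1 or p.ndim != 1 or a.shape != p.shape:
        raise EvaluationError(
            f"actual and predicted must be equal-length vectors, got {a.shape} vs {p.shape}"
        )
    if a.size == 0:
        raise EvaluationError("empty input")
    return a, p


def compute_errors(actual, predicted) -> tuple[float, float]:
    """(MAE, RMSE) between actual and predicted utilities."""
    a, p = _check_pair(actual, predicted)
    err = a - p
    return float(np.mean(np.abs(err))), float(np.sqrt(np.mean(err**2)))


def _band_label(lo: float, hi: float, last: bool) -> str:
    if math.isinf(lo):
        return f"EQ-5D < {hi:g}"
    if last or math.isinf(hi):
        return f"EQ-5D >= {lo:g}"
    return f"{lo:g} <= EQ-5D < {hi:g}"


def _validate_bands(bands: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    bands = [(float(lo), float(hi)) for lo, hi in bands]
    for lo, hi in bands:
        if not lo < hi:
            raise EvaluationError(f"empty band ({lo}, {hi})")
    for (lo1, hi1), (lo2, hi2) in zip(bands, bands[1:]):
        if hi1 > lo2:
            raise EvaluationError(f"overlapping bands at {hi1} > {lo2}")
        if hi1 < lo2:
            raise EvaluationError(f"gap between bands at {hi1} < {lo2}")
    return bands


def banded_errors(
    actual,
    predicted,
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Per-band n, mean actual, mean predicted, MAE and RMSE.

    Rows are assigned to a band by their *actual* utility: lower-closed,
    upper-open, except the final band which also includes its upper edge.
    """
    a, p = _check_pair(actual, predicted)
    bands = _validate_bands(bands)
    rows = []
    for i, (lo, hi) in enumerate(bands):
        last = i == len(bands) - 1
        mask = (a >= lo) & ((a <= hi) if last else (a < hi))
        label = _band_label(lo, hi, last)
        if mask.any():
            mae, rmse = compute_errors(a[mask], p[mask])
            rows.append((label, int(mask.sum()), float(a[mask].mean()),
                         float(p[mask].mean()), mae, rmse))
        else:
            rows.append((label, 0, np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["band", "n", "mean_actual", "mean_predicted", "mae", "rmse"]
    )


@dataclass(frozen=True)
class DistributionSummary:
    """Histogram plus the two shape features that matter for EQ-5D data."""

    bin_edges: np.ndarray
    counts: np.ndarray
    share_at_one: float
    skewness: float
    minimum: float
    maximum: float
    mean: float


def distribution_summary(values, bin_width: float = 0.05) -> DistributionSummary:
    """Histogram, share exactly at full health, and skewness.

    The share at 1 is computed by equality on the scored index — only the
    11111 profile scores exactly 1, so expected-value predictions (which
    average over states) always report a share of zero here.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise EvaluationError("empty input")
    lo = math.floor(v.min() / bin_width) * bin_width
    hi = math.ceil(v.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(v, bins=edges)
    return DistributionSummary(
        bin_edges=edges,
        counts=counts,
        share_at_one=float(np.mean(v == 1.0)),
        skewness=0.0 if np.ptp(v) == 0 else float(stats.skew(v)),
        minimum=float(v.min()),
        maximum=float(v.max()),
        mean=float(v.mean()),
    )


@dataclass(frozen=True)
class EvaluationReport:
    """Overall and banded accuracy of one predictor against actual utilities."""

    mae: float
    rmse: float
    bands: pd.DataFrame
    actual_summary: DistributionSummary
    predicted_summary: DistributionSummary
    n_obs: int

    @property
    def mse(self) -> float:
        return self.rmse**2

    def to_dict(self) -> dict:
        def _summ(s: DistributionSummary) -> dict:
            return {
                "min": s.minimum,
                "max": s.maximum,
                "mean": s.mean,
                "share_at_one": s.share_at_one,
                "skewness": s.skewness,
                "bin_edges": [float(x) for x in s.bin_edges],
                "counts": [int(c) for c in s.counts],
            }

        return {
            "n_obs": self.n_obs,
            "mae": self.mae,
            "rmse": self.rmse,
            "mse": self.mse,
            "bands": self.bands.to_dict(orient="records"),
            "actual": _summ(self.actual_summary),
            "predicted": _summ(self.predicted_summary),
        }

    def format_table(self) -> str:
        """Text table rounded to 3 decimal places."""
        lines = [
            f"n = {self.n_obs}",
            f"actual    mean {self.actual_summary.mean:.3f} "
            f"({self.actual_summary.minimum:.3f}, {self.actual_summary.maximum:.3f})",
            f"predicted mean {self.predicted_summary.mean:.3f} "
            f"({self.predicted_summary.minimum:.3f}, {self.predicted_summary.maximum:.3f})",
            f"MAE {self.mae:.3f}   RMSE {self.rmse:.3f}",
            f"{'band':<24}{'n':>7}{'actual':>9}{'pred':>9}{'MAE':>8}{'RMSE':>8}",
        ]
        for _, r in self.bands.iterrows():
            lines.append(
                f"{r['band']:<24}{r['n']:>7d}"
                f"{r['mean_actual']:>9.3f}{r['mean_predicted']:>9.3f}"
                f"{r['mae']:>8.3f}{r['rmse']:>8.3f}"
                if r["n"]
                else f"{r['band']:<24}{r['n']:>7d}{'-':>9}{'-':>9}{'-':>8}{'-':>8}"
            )
        return "\n".join(lines)


def evaluate(
    actual,
    predicted,
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
    bin_width: float = 0.05,
) -> EvaluationReport:
    """Full accuracy report for one predictor."""
    a, p = _check_pair(actual, predicted)
    mae, rmse = compute_errors(a, p)
    return EvaluationReport(
        mae=mae,
        rmse=rmse,
        bands=banded_errors(a, p, bands),
        actual_summary=distribution_summary(a, bin_width),
        predicted_summary=distribution_summary(p, bin_width),
        n_obs=a.size,
    )
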