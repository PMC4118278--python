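"""Ordinary least squares on the utility index: the direct-mapping baseline.

The comparator regresses the EQ-5D index itself on the covariates,
``utility = alpha + x @ beta + eps``. Predictions are deliberately not
truncated to the index range: over-shooting past 1 for high-utility
cohorts is part of what the comparison is meant to expose. An explicit
``clamp`` flag on prediction is available for users who want the
post-hoc repair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import (
    CovariateDesign,
    DesignSpec,
    RankDeficientError,
    find_collinear_columns,
)


@dataclass
class OLSFit:
    columns: tuple[str, ...]
    alpha: float
    beta: np.ndarray
    se: np.ndarray  # for (alpha, beta) stacked
    cov: np.ndarray
    sigma2: float
    r_squared: float
    n_obs: int
    design_spec: DesignSpec | None = None


def fit_ols(design: CovariateDesign, utility: np.ndarray,
            design_spec: DesignSpec | None = None) -> OLSFit:
    """Least-squares fit with an intercept."""
    y = np.asarray(utility, dtype=float)
    if y.shape[0] != design.n_obs:
        raise ValueError("utility length does not match the design")
    if not np.all(np.isfinite(y)):
        raise ValueError("utilities contain non-finite values")
    n = design.n_obs
    X1 = np.column_stack([np.ones(n), design.matrix])
    collinear = find_collinear_columns(X1, ("(intercept)", *design.columns))
    if collinear:
        raise RankDeficientError(
            f"design (with intercept) is rank deficient; collinear column(s): "
            f"{', '.join(collinear)}"
        )
    coef, _, _, _ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ coef
    dof = n - X1.shape[1]
    sigma2 = float(resid @ resid / dof) if dof > 0 else np.nan
    xtx_inv = np.linalg.inv(X1.T @ X1)
    cov = sigma2 * xtx_inv if np.isfinite(sigma2) else np.full_like(xtx_inv, np.nan)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else np.nan
    return OLSFit(
        columns=design.columns,
        alpha=float(coef[0]),
        beta=coef[1:],
        se=np.sqrt(np.clip(np.diag(cov), 0.0, None)),
        cov=cov,
        sigma2=sigma2,
        r_squared=r2,
        n_obs=n,
        design_spec=design_spec,
    )


def predict_ols(
    fit: OLSFit,
    design: CovariateDesign,
    clamp: bool = False,
    bounds: tuple[float, float] = (-0.594, 1.0),
) -> np.ndarray:
    """Linear predictions ``alpha + x @ beta``, unbounded by default."""
    missing = [c for c in fit.columns if c not in design.columns]
    extra = [c for c in design.columns if c not in fit.columns]
    if missing or extra:
        raise ValueError(
            f"design columns do not match the fit (missing: {missing}, extra: {extra})"
        )
    X = design.subset(fit.columns).matrix
    pred = fit.alpha + X @ fit.beta
    if clamp:
        pred = np.clip(pred, bounds[0], bounds[1])
    return pred
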