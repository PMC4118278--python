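"""Partial proportional odds models for three-level ordinal responses.

One model is fitted per EQ-5D dimension. The response d takes values
1 (no problems), 2 (some problems), 3 (extreme problems) and is modelled
through two cumulative splits:

    P(d <= 1) = logistic(k1 - x @ beta_eq1)     (none vs some/extreme)
    P(d <= 2) = logistic(k2 - x @ beta_eq2)     (none/some vs extreme)

with category probabilities p1 = P(d<=1), p2 = P(d<=2) - P(d<=1),
p3 = 1 - P(d<=2). A positive coefficient therefore shifts mass towards
worse levels. Covariates flagged *parallel* share a single coefficient
across both splits (the proportional-odds constraint); the others get a
free coefficient per split. With every covariate parallel the model is
the ordinary ordered logit; with none it is the fully generalized
ordered logit.

Estimation is maximum likelihood with an analytic gradient; the
covariance is the inverse observed information (finite differences of
the gradient at the optimum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .design import CovariateDesign, DesignSpec


class PPOMError(ValueError):
    """Invalid model specification or data for a PPOM fit."""


class AbsentLevelError(PPOMError):
    """A response level required by the three-level model is absent."""


class ConvergenceError(RuntimeError):
    """The optimizer failed to meet the gradient tolerance."""

    def __init__(self, message: str, diagnostics: dict | None = None) -> None:
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class PPOMSpec:
    """Which covariates satisfy the parallel-lines constraint.

    ``parallel[i]`` is True when ``columns[i]`` has one shared coefficient
    across both cumulative splits and False when it gets a free
    coefficient per split.
    """

    columns: tuple[str, ...]
    parallel: tuple[bool, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "columns", tuple(self.columns))
        object.__setattr__(self, "parallel", tuple(bool(b) for b in self.parallel))
        if len(self.columns) != len(self.parallel):
            raise PPOMError("spec needs exactly one parallel flag per covariate")

    @classmethod
    def all_parallel(cls, columns: Sequence[str]) -> "PPOMSpec":
        return cls(tuple(columns), (True,) * len(columns))

    @classmethod
    def unconstrained(cls, columns: Sequence[str]) -> "PPOMSpec":
        return cls(tuple(columns), (False,) * len(columns))

    @classmethod
    def with_free(cls, columns: Sequence[str], free: Sequence[str]) -> "PPOMSpec":
        unknown = set(free) - set(columns)
        if unknown:
            raise PPOMError(f"free covariate(s) not in design: {sorted(unknown)}")
        return cls(tuple(columns), tuple(c not in set(free) for c in columns))

    def constrain(self, column: str) -> "PPOMSpec":
        if column not in self.columns:
            raise PPOMError(f"no covariate named {column!r}")
        return PPOMSpec(
            self.columns,
            tuple(p or (c == column) for c, p in zip(self.columns, self.parallel)),
        )

    @property
    def n_free(self) -> int:
        return sum(not p for p in self.parallel)


@dataclass(frozen=True)
class _IndexMaps:
    """Positions of each covariate's split coefficients in the packed vector."""

    idx1: np.ndarray
    idx2: np.ndarray
    k1: int
    k2: int
    n_params: int
    names: tuple[str, ...]


def _index_maps(spec: PPOMSpec) -> _IndexMaps:
    idx1, idx2, names = [], [], []
    pos = 0
    for col, par in zip(spec.columns, spec.parallel):
        if par:
            idx1.append(pos)
            idx2.append(pos)
            names.append(col)
            pos += 1
        else:
            idx1.append(pos)
            idx2.append(pos + 1)
            names.extend((f"{col}:eq1", f"{col}:eq2"))
            pos += 2
    names.extend(("k1", "k2"))
    return _IndexMaps(
        idx1=np.asarray(idx1, dtype=int),
        idx2=np.asarray(idx2, dtype=int),
        k1=pos,
        k2=pos + 1,
        n_params=pos + 2,
        names=tuple(names),
    )


def _validate_response(response: np.ndarray) -> np.ndarray:
    d = np.asarray(response)
    if not np.isin(d, (1, 2, 3)).all():
        bad = d[~np.isin(d, (1, 2, 3))][0]
        raise PPOMError(f"response levels must be 1, 2 or 3; found {bad!r}")
    return d.astype(int)


def _nll_mean(theta: np.ndarray, X: np.ndarray, masks, maps: _IndexMaps):
    """Mean negative log-likelihood and its gradient.

    Rows with non-positive category probability yield an infinite
    objective (never an exception) so line searches back off.
    """
    m1, m2, m3 = masks
    n = X.shape[0]
    beta1 = theta[maps.idx1]
    beta2 = theta[maps.idx2]
    eta1 = X @ beta1
    eta2 = X @ beta2
    c1 = special.expit(theta[maps.k1] - eta1)
    c2 = special.expit(theta[maps.k2] - eta2)

    p_obs = np.where(m1, c1, np.where(m2, c2 - c1, 1.0 - c2))
    if np.any(p_obs <= 0.0):
        return np.inf, np.zeros(maps.n_params)
    f = -np.log(p_obs).sum() / n

    # dNLL/dz_j where z_j = k_j - eta_j enters c_j = logistic(z_j)
    w1 = c1 * (1.0 - c1)
    w2 = c2 * (1.0 - c2)
    g1 = np.zeros(n)
    g2 = np.zeros(n)
    g1[m1] = -(1.0 - c1[m1])
    g1[m2] = w1[m2] / p_obs[m2]
    g2[m2] = -w2[m2] / p_obs[m2]
    g2[m3] = c2[m3]

    grad = np.zeros(maps.n_params)
    gb1 = -(X.T @ g1)
    gb2 = -(X.T @ g2)
    np.add.at(grad, maps.idx1, gb1)
    np.add.at(grad, maps.idx2, gb2)
    grad[maps.k1] = g1.sum()
    grad[maps.k2] = g2.sum()
    return f, grad / n


def negative_log_likelihood(
    params: np.ndarray,
    design: CovariateDesign,
    response: np.ndarray,
    spec: PPOMSpec,
) -> float:
    """Total negative log-likelihood -sum(log p(d_r)) at ``params``.

    ``params`` is the packed free-parameter vector: one coefficient per
    parallel covariate, an eq1/eq2 pair per free covariate (in design
    order), then the two cut points.
    """
    maps = _index_maps(spec)
    params = np.asarray(params, dtype=float)
    if params.shape != (maps.n_params,):
        raise PPOMError(
            f"expected {maps.n_params} packed parameters for this spec, got {params.shape}"
        )
    if not np.all(np.isfinite(design.matrix)):
        raise PPOMError("design matrix contains non-finite values")
    d = _validate_response(response)
    masks = (d == 1, d == 2, d == 3)
    f, _ = _nll_mean(params, design.matrix, masks, maps)
    return f * design.n_obs


@dataclass
class PPOMFit:
    """A fitted partial proportional odds model for one dimension."""

    spec: PPOMSpec
    theta: np.ndarray
    cov: np.ndarray
    log_likelihood: float
    n_obs: int
    converged: bool
    grad_max: float
    n_iter: int
    dimension: str | None = None
    design_spec: DesignSpec | None = None
    collapsed: bool = False
    degenerate: bool = False
    neg_p2_fraction: float = 0.0
    cov_is_pinv: bool = False

    _maps: _IndexMaps = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._maps = _index_maps(self.spec)
        self.theta = np.asarray(self.theta, dtype=float)

    @property
    def columns(self) -> tuple[str, ...]:
        return self.spec.columns

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.collapsed:
            return tuple(self.spec.columns) + ("k1",)
        return self._maps.names

    @property
    def beta_eq1(self) -> np.ndarray:
        if self.collapsed:
            return self.theta[:-1]
        return self.theta[self._maps.idx1]

    @property
    def beta_eq2(self) -> np.ndarray:
        if self.collapsed:
            return self.theta[:-1]
        return self.theta[self._maps.idx2]

    @property
    def k1(self) -> float:
        if self.collapsed:
            return float(self.theta[-1])
        return float(self.theta[self._maps.k1])

    @property
    def k2(self) -> float:
        if self.collapsed:
            return np.inf
        return float(self.theta[self._maps.k2])

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    @classmethod
    def from_params(
        cls,
        columns: Sequence[str],
        parallel: Sequence[bool],
        beta_eq1: Sequence[float],
        beta_eq2: Sequence[float],
        k1: float,
        k2: float,
        dimension: str | None = None,
        design_spec: DesignSpec | None = None,
    ) -> "PPOMFit":
        """Assemble a fit object from explicit parameters (no estimation)."""
        spec = PPOMSpec(tuple(columns), tuple(parallel))
        maps = _index_maps(spec)
        b1 = np.asarray(beta_eq1, dtype=float)
        b2 = np.asarray(beta_eq2, dtype=float)
        for j, par in enumerate(spec.parallel):
            if par and b1[j] != b2[j]:
                raise PPOMError(
                    f"covariate {spec.columns[j]!r} is parallel but eq1/eq2 values differ"
                )
        theta = np.zeros(maps.n_params)
        theta[maps.idx1] = b1
        theta[maps.idx2] = b2
        theta[maps.k1] = k1
        theta[maps.k2] = k2
        return cls(
            spec=spec,
            theta=theta,
            cov=np.zeros((maps.n_params, maps.n_params)),
            log_likelihood=np.nan,
            n_obs=0,
            converged=True,
            grad_max=np.nan,
            n_iter=0,
            dimension=dimension,
            design_spec=design_spec,
        )

    def summary(self) -> str:
        """Two-rows-per-covariate text table (eq1 then eq2)."""
        lines = [
            f"PPOM fit{f' [{self.dimension}]' if self.dimension else ''}: "
            f"n={self.n_obs}, logL={self.log_likelihood:.3f}, "
            f"free covariates={self.spec.n_free}/{len(self.columns)}",
            f"{'covariate':<28}{'eq1':>10}{'eq2':>10}  constraint",
        ]
        for j, col in enumerate(self.columns):
            b1, b2 = self.beta_eq1[j], self.beta_eq2[j]
            tag = "parallel" if self.spec.parallel[j] else "free"
            lines.append(f"{col:<28}{b1:>10.4f}{b2:>10.4f}  {tag}")
        lines.append(f"{'cut points':<28}{self.k1:>10.4f}{self.k2:>10.4f}")
        if self.neg_p2_fraction:
            lines.append(f"negative-p2 clamp fraction: {self.neg_p2_fraction:.4%}")
        return "\n".join(lines)


def _numeric_hessian(theta, X, masks, maps) -> np.ndarray:
    """Central finite differences of the analytic gradient (mean scale)."""
    q = maps.n_params
    H = np.zeros((q, q))
    for i in range(q):
        h = 1e-5 * (1.0 + abs(theta[i]))
        up = theta.copy()
        up[i] += h
        dn = theta.copy()
        dn[i] -= h
        _, g_up = _nll_mean(up, X, masks, maps)
        _, g_dn = _nll_mean(dn, X, masks, maps)
        H[:, i] = (g_up - g_dn) / (2.0 * h)
    return 0.5 * (H + H.T)


_GTOL = 1e-6  # max-norm of the mean-NLL gradient at the reported optimum


def _fit_collapsed(design, d, *, dimension, design_spec, compute_cov) -> PPOMFit:
    """Binary-logit escape hatch when the extreme level is absent.

    Levels 2 and 3 are merged and the single split P(d<=1) is fitted.
    A response that is constant even after collapsing gets an add-one
    smoothed intercept-only fit, flagged ``degenerate``.
    """
    X = design.matrix
    n, p = X.shape
    y_problem = d >= 2
    spec = PPOMSpec.all_parallel(design.columns)

    if y_problem.all() or (~y_problem).all():
        p1 = (np.sum(~y_problem) + 1.0) / (n + 2.0)
        theta = np.zeros(p + 1)
        theta[-1] = special.logit(p1)
        return PPOMFit(
            spec=spec,
            theta=theta,
            cov=np.zeros((p + 1, p + 1)),
            log_likelihood=float(
                np.sum(~y_problem) * np.log(p1) + np.sum(y_problem) * np.log(1 - p1)
            ),
            n_obs=n,
            converged=True,
            grad_max=np.nan,
            n_iter=0,
            dimension=dimension,
            design_spec=design_spec,
            collapsed=True,
            degenerate=True,
        )

    def fun(theta):
        eta = X @ theta[:-1]
        z = theta[-1] - eta  # P(d<=1) = logistic(z)
        # log-likelihood via numerically stable log-logistic
        ll = np.where(y_problem, -np.logaddexp(0.0, z), -np.logaddexp(0.0, -z))
        c1 = special.expit(z)
        resid = (~y_problem) - c1  # d log L / dz
        grad = np.empty(p + 1)
        grad[:-1] = (X.T @ resid) / n  # dz/dbeta = -x, dNLL/dz = -resid
        grad[-1] = -resid.sum() / n
        return -ll.sum() / n, grad

    share_none = np.mean(~y_problem)
    x0 = np.zeros(p + 1)
    x0[-1] = special.logit(share_none)
    res = optimize.minimize(fun, x0, jac=True, method="BFGS",
                            options={"gtol": _GTOL, "maxiter": 1000})
    gmax = float(np.max(np.abs(res.jac)))
    if gmax > 10 * _GTOL:
        raise ConvergenceError(
            f"collapsed binary fit did not converge (max|grad|={gmax:.2e})",
            {"grad_max": gmax, "n_iter": res.nit},
        )
    cov = np.zeros((p + 1, p + 1))
    if compute_cov:
        # observed information of the binary logit
        eta = X @ res.x[:-1]
        c1 = special.expit(res.x[-1] - eta)
        w = c1 * (1 - c1)
        Z = np.column_stack([-X, np.ones(n)])
        H = (Z.T * w) @ Z / n
        cov = np.linalg.inv(H) / n
    return PPOMFit(
        spec=spec,
        theta=res.x,
        cov=cov,
        log_likelihood=float(-res.fun * n),
        n_obs=n,
        converged=True,
        grad_max=gmax,
        n_iter=int(res.nit),
        dimension=dimension,
        design_spec=design_spec,
        collapsed=True,
    )


def fit_ppom(
    design: CovariateDesign,
    response: np.ndarray,
    spec: PPOMSpec | None = None,
    *,
    dimension: str | None = None,
    design_spec: DesignSpec | None = None,
    start: np.ndarray | None = None,
    compute_cov: bool = True,
    collapse_absent: bool = False,
    gtol: float = _GTOL,
) -> PPOMFit:
    """Maximum-likelihood fit of a partial proportional odds model.

    ``spec`` defaults to the all-parallel (proportional odds) model.
    Starting values come from the nested all-parallel fit (itself started
    at zero coefficients with cut points at the empirical cumulative
    logits). If a response level is absent the fit refuses unless
    ``collapse_absent=True``, which merges levels 2 and 3 into a binary
    logit (see :func:`_fit_collapsed`).
    """
    d = _validate_response(response)
    if d.shape[0] != design.n_obs:
        raise PPOMError("response length does not match the design")
    if not np.all(np.isfinite(design.matrix)):
        raise PPOMError("design matrix contains non-finite values")
    design.validate_full_rank()

    counts = {lv: int(np.sum(d == lv)) for lv in (1, 2, 3)}
    absent = [lv for lv, c in counts.items() if c == 0]
    if absent:
        if collapse_absent and counts[1] > 0:
            return _fit_collapsed(
                design, d, dimension=dimension, design_spec=design_spec,
                compute_cov=compute_cov,
            )
        raise AbsentLevelError(
            f"response level(s) {absent} absent (counts {counts}); "
            "collapse levels 2 and 3 with collapse_absent=True to fit a "
            "binary logit, or recode the response"
        )

    if spec is None:
        spec = PPOMSpec.all_parallel(design.columns)
    if tuple(spec.columns) != tuple(design.columns):
        raise PPOMError(
            "spec covariates do not match the design columns: "
            f"{spec.columns} vs {design.columns}"
        )
    maps = _index_maps(spec)
    X = design.matrix
    n = X.shape[0]
    masks = (d == 1, d == 2, d == 3)

    if start is None:
        cum = np.cumsum([counts[1], counts[2]]) / n
        if spec.n_free == 0 or X.shape[1] == 0:
            start = np.zeros(maps.n_params)
            start[maps.k1] = special.logit(cum[0])
            start[maps.k2] = special.logit(cum[1])
        else:
            base = fit_ppom(
                design, d, PPOMSpec.all_parallel(design.columns),
                dimension=dimension, compute_cov=False,
            )
            start = np.zeros(maps.n_params)
            start[maps.idx1] = base.beta_eq1
            start[maps.idx2] = base.beta_eq2
            start[maps.k1] = base.k1
            start[maps.k2] = base.k2

    res = optimize.minimize(
        _nll_mean, start, args=(X, masks, maps), jac=True, method="BFGS",
        options={"gtol": gtol, "maxiter": 2000},
    )
    theta = res.x
    _, grad = _nll_mean(theta, X, masks, maps)
    gmax = float(np.max(np.abs(grad)))
    n_iter = int(res.nit)

    if gmax > gtol:
        # Newton polish with the exact-information Hessian approximation
        for _ in range(25):
            H = _numeric_hessian(theta, X, masks, maps)
            try:
                step = np.linalg.solve(H, -grad)
            except np.linalg.LinAlgError:
                break
            f0, _ = _nll_mean(theta, X, masks, maps)
            scale = 1.0
            while scale > 1e-6:
                f_new, g_new = _nll_mean(theta + scale * step, X, masks, maps)
                if f_new < f0:
                    break
                scale /= 2.0
            else:
                break
            theta = theta + scale * step
            grad = g_new
            gmax = float(np.max(np.abs(grad)))
            n_iter += 1
            if gmax <= gtol:
                break
    if gmax > gtol:
        raise ConvergenceError(
            f"PPOM fit did not reach gradient tolerance (max|grad|={gmax:.2e})",
            {"grad_max": gmax, "n_iter": n_iter, "theta": theta},
        )

    f_opt, _ = _nll_mean(theta, X, masks, maps)
    cov = np.zeros((maps.n_params, maps.n_params))
    cov_is_pinv = False
    if compute_cov:
        H = _numeric_hessian(theta, X, masks, maps)
        try:
            cov = np.linalg.inv(H) / n
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H) / n
            cov_is_pinv = True
        cov = 0.5 * (cov + cov.T)

    fit = PPOMFit(
        spec=spec,
        theta=theta,
        cov=cov,
        log_likelihood=float(-f_opt * n),
        n_obs=n,
        converged=True,
        grad_max=gmax,
        n_iter=n_iter,
        dimension=dimension,
        design_spec=design_spec,
        cov_is_pinv=cov_is_pinv,
    )
    fit.neg_p2_fraction = float(np.mean(predict_probs(fit, design).negative_p2))
    return fit


@dataclass(frozen=True)
class PredictedProbabilities:
    """Per-row level probabilities with negative-p2 diagnostics.

    For non-parallel specs the two cumulative curves can cross, making
    the raw middle probability negative for some covariate patterns.
    Such rows are flagged, clamped to zero and renormalized; ``probs``
    holds the repaired row-stochastic matrix.
    """

    probs: np.ndarray
    negative_p2: np.ndarray

    @property
    def neg_p2_fraction(self) -> float:
        return float(np.mean(self.negative_p2))


def predict_probs(fit: PPOMFit, design: CovariateDesign) -> PredictedProbabilities:
    """Predicted (p1, p2, p3) for every design row."""
    missing = [c for c in fit.columns if c not in design.columns]
    extra = [c for c in design.columns if c not in fit.columns]
    if missing or extra:
        raise PPOMError(
            f"design columns do not match the fit (missing: {missing}, extra: {extra})"
        )
    X = design.subset(fit.columns).matrix
    c1 = special.expit(fit.k1 - X @ fit.beta_eq1)
    if fit.collapsed:
        probs = np.column_stack([c1, 1.0 - c1, np.zeros_like(c1)])
        return PredictedProbabilities(probs, np.zeros(len(c1), dtype=bool))
    c2 = special.expit(fit.k2 - X @ fit.beta_eq2)
    p2 = c2 - c1
    flags = p2 < 0.0
    p2 = np.where(flags, 0.0, p2)
    probs = np.column_stack([c1, p2, 1.0 - c2])
    probs /= probs.sum(axis=1, keepdims=True)
    return PredictedProbabilities(probs, flags)


def _wald_one(fit: PPOMFit, j: int) -> tuple[float, float]:
    maps = fit._maps
    i1, i2 = int(maps.idx1[j]), int(maps.idx2[j])
    diff = fit.theta[i1] - fit.theta[i2]
    var = fit.cov[i1, i1] + fit.cov[i2, i2] - 2.0 * fit.cov[i1, i2]
    if not np.isfinite(var) or var <= 0.0:
        return np.nan, np.nan
    w = diff * diff / var
    return float(w), float(stats.chi2.sf(w, df=1))


def parallel_lines_wald(fit: PPOMFit) -> pd.DataFrame:
    """Per-covariate Wald test of H0: beta_eq1 = beta_eq2 (1 df).

    Requires a fully unconstrained fit. A singular covariance sub-block
    yields NaN (undefined), never an exception.
    """
    if any(fit.spec.parallel):
        raise PPOMError("parallel_lines_wald needs a fully unconstrained fit")
    rows = [_wald_one(fit, j) for j in range(len(fit.columns))]
    return pd.DataFrame(rows, index=list(fit.columns), columns=["statistic", "pvalue"])


def autofit(
    design: CovariateDesign,
    response: np.ndarray,
    alpha: float = 0.05,
    **fit_kwargs,
) -> tuple[PPOMSpec, PPOMFit]:
    """Backward constraint selection in the style of Stata's gologit2.

    Starts from the fully unconstrained model and repeatedly imposes the
    parallel-lines constraint on the free covariate with the largest Wald
    p-value above ``alpha`` (unadjusted tests), refitting after each
    constraint, until every remaining free covariate is significant at
    ``alpha``. Deterministic given the data and ``alpha``; ties break on
    design-column order.
    """
    if not (0.0 < alpha <= 1.0):
        raise PPOMError("alpha must be in (0, 1]")
    fit_kwargs.setdefault("compute_cov", True)
    spec = PPOMSpec.unconstrained(design.columns)
    fit = fit_ppom(design, response, spec, **fit_kwargs)
    while True:
        free = [j for j, par in enumerate(spec.parallel) if not par]
        if not free:
            break
        pvals = {}
        for j in free:
            _, p = _wald_one(fit, j)
            if np.isfinite(p) and p > alpha:
                pvals[j] = p
        if not pvals:
            break
        j_best = max(sorted(pvals), key=lambda j: pvals[j])
        spec = spec.constrain(spec.columns[j_best])
        maps_new = _index_maps(spec)
        warm = np.zeros(maps_new.n_params)
        warm[maps_new.idx1] = 0.5 * (fit.beta_eq1 + fit.beta_eq2)
        b1, b2 = fit.beta_eq1.copy(), fit.beta_eq2.copy()
        keep = np.asarray(spec.parallel)
        warm[maps_new.idx1[~keep]] = b1[~keep]
        warm[maps_new.idx2[~keep]] = b2[~keep]
        warm[maps_new.k1] = fit.k1
        warm[maps_new.k2] = fit.k2
        fit = fit_ppom(design, response, spec, start=warm, **fit_kwargs)
    return spec, fit
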