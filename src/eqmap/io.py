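"""JSON serialization of fitted models (versioned fit bundles)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .design import DesignSpec
from .ols import OLSFit
from .ppom import PPOMFit, PPOMSpec

SCHEMA_VERSION = 1


class BundleError(ValueError):
    """Raised for unreadable or unsupported fit bundles."""


def _spec_to_dict(spec: DesignSpec | None) -> dict | None:
    if spec is None:
        return None
    return {
        "continuous": list(spec.continuous),
        "categorical": {k: list(v) for k, v in spec.categorical.items()},
        "response_indicators": list(spec.response_indicators),
    }


def _spec_from_dict(d: dict | None) -> DesignSpec | None:
    if d is None:
        return None
    return DesignSpec(
        continuous=tuple(d["continuous"]),
        categorical={k: tuple(v) for k, v in d["categorical"].items()},
        response_indicators=tuple(d["response_indicators"]),
    )


def fit_to_dict(fit: PPOMFit | OLSFit) -> dict:
    if isinstance(fit, PPOMFit):
        return {
            "type": "ppom",
            "columns": list(fit.spec.columns),
            "parallel": list(fit.spec.parallel),
            "theta": fit.theta.tolist(),
            "cov": np.asarray(fit.cov).tolist(),
            "log_likelihood": None if np.isnan(fit.log_likelihood) else fit.log_likelihood,
            "n_obs": fit.n_obs,
            "converged": fit.converged,
            "grad_max": None if np.isnan(fit.grad_max) else fit.grad_max,
            "n_iter": fit.n_iter,
            "dimension": fit.dimension,
            "collapsed": fit.collapsed,
            "degenerate": fit.degenerate,
            "neg_p2_fraction": fit.neg_p2_fraction,
            "design_spec": _spec_to_dict(fit.design_spec),
        }
    if isinstance(fit, OLSFit):
        return {
            "type": "ols",
            "columns": list(fit.columns),
            "alpha": fit.alpha,
            "beta": np.asarray(fit.beta).tolist(),
            "se": np.asarray(fit.se).tolist(),
            "cov": np.asarray(fit.cov).tolist(),
            "sigma2": fit.sigma2,
            "r_squared": fit.r_squared,
            "n_obs": fit.n_obs,
            "design_spec": _spec_to_dict(fit.design_spec),
        }
    raise BundleError(f"cannot serialize object of type {type(fit).__name__}")


def fit_from_dict(d: dict) -> PPOMFit | OLSFit:
    kind = d.get("type")
    if kind == "ppom":
        fit = PPOMFit(
            spec=PPOMSpec(tuple(d["columns"]), tuple(d["parallel"])),
            theta=np.asarray(d["theta"], dtype=float),
            cov=np.asarray(d["cov"], dtype=float),
            log_likelihood=np.nan if d["log_likelihood"] is None else d["log_likelihood"],
            n_obs=int(d["n_obs"]),
            converged=bool(d["converged"]),
            grad_max=np.nan if d["grad_max"] is None else d["grad_max"],
            n_iter=int(d["n_iter"]),
            dimension=d.get("dimension"),
            design_spec=_spec_from_dict(d.get("design_spec")),
            collapsed=bool(d.get("collapsed", False)),
            degenerate=bool(d.get("degenerate", False)),
            neg_p2_fraction=float(d.get("neg_p2_fraction", 0.0)),
        )
        return fit
    if kind == "ols":
        return OLSFit(
            columns=tuple(d["columns"]),
            alpha=float(d["alpha"]),
            beta=np.asarray(d["beta"], dtype=float),
            se=np.asarray(d["se"], dtype=float),
            cov=np.asarray(d["cov"], dtype=float),
            sigma2=float(d["sigma2"]),
            r_squared=float(d["r_squared"]),
            n_obs=int(d["n_obs"]),
            design_spec=_spec_from_dict(d.get("design_spec")),
        )
    raise BundleError(f"unknown fit type {kind!r}")


def save_fit_bundle(path: str | Path, fits: Sequence[PPOMFit | OLSFit]) -> None:
    """Write an ordered list of fits (order is preserved on load)."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "fits": [fit_to_dict(f) for f in fits],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_fit_bundle(path: str | Path) -> list[PPOMFit | OLSFit]:
    try:
        with open(path, "r") as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise BundleError(f"not a valid fit bundle ({exc})") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise BundleError("not a fit bundle: missing schema_version")
    version = payload["schema_version"]
    if version != SCHEMA_VERSION:
        raise BundleError(
            f"unsupported bundle schema version {version!r} (supported: {SCHEMA_VERSION})"
        )
    return [fit_from_dict(d) for d in payload["fits"]]
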