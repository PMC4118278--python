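"""Synthetic survey-like cohorts with known ground truth.

Real individual-level EQ-5D survey data of the kind the models target is
restricted, so every stage of the pipeline is exercised on generated
cohorts instead. The generator draws covariates (age, sex, education,
acute sickness, self-rated general health, deprivation quartile, survey
year), then samples each dimension's three-level response from a true
partial-proportional-odds model given those covariates, and finally
scores the realized profile with the tariff to obtain the true utility.

Six named presets emulate the condition sub-groups of a large English
health survey: their per-dimension marginal level shares are matched to
published sub-group profiles by calibrating the cut points against the
realized linear predictors at generation time. Dimension responses are
conditionally independent given the covariates by default; the presets
additionally load a shared latent severity factor onto every dimension,
because observed survey responses are strongly correlated across
dimensions (without this the mass at full health would be far too
small). The factor's scale per preset is calibrated once to the
sub-group's published full-health share.

All randomness flows from one explicit seed through independent spawned
streams, so covariate and response draws are separately reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .design import DesignSpec
from .tariff import DIMENSIONS, TariffCoefficients, load_tariff, score_profiles


class ConfigError(ValueError):
    """Raised for invalid generator configurations."""


#: Declared categorical level orders; the first level is the reference
#: (no qualification, 0 sick days, fair general health, least deprived,
#: year 2003).
BASE_CATEGORICAL: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "education": ("none", "gcse", "alevel", "degree"),
    "acute_sickness": ("none", "sick1", "sick2", "sick3"),
    "general_health": ("fair", "very_good", "good", "bad", "very_bad"),
    "deprivation": ("least", "little", "very", "most"),
    "survey_year": ("2003", "2004", "2005", "2006", "2008"),
}

#: Continuous terms: centred age in decades and its square.
BASE_CONTINUOUS: tuple[str, ...] = ("age_c", "age_c2")


def base_design_spec(cross_dimension_for: str | None = None) -> DesignSpec:
    """The standard covariate design.

    With ``cross_dimension_for`` set to a dimension name, the other four
    dimensions' observed responses are added as level-2/level-3
    indicator covariates — the design used when each dimension's model
    conditions on the remaining responses.
    """
    indicators: tuple[str, ...] = ()
    if cross_dimension_for is not None:
        if cross_dimension_for not in DIMENSIONS:
            raise ConfigError(f"unknown dimension {cross_dimension_for!r}")
        indicators = tuple(d for d in DIMENSIONS if d != cross_dimension_for)
    return DesignSpec(
        continuous=BASE_CONTINUOUS,
        categorical=BASE_CATEGORICAL,
        response_indicators=indicators,
    )


def add_age_terms(df: pd.DataFrame) -> pd.DataFrame:
    """Derive centred-age terms; the square is never sampled separately."""
    out = df.copy()
    out["age_c"] = (out["age"] - 50.0) / 10.0
    out["age_c2"] = out["age_c"] ** 2
    return out


def _check_probs(name: str, probs: Mapping[str, float]) -> dict[str, float]:
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-8:
        raise ConfigError(f"category probabilities for {name!r} sum to {total}, not 1")
    if any(p < 0 for p in probs.values()):
        raise ConfigError(f"negative category probability for {name!r}")
    return dict(probs)


@dataclass(frozen=True)
class CovariateConfig:
    """Marginal distributions of the survey covariates."""

    age_mean: float = 58.0
    age_sd: float = 16.0
    age_min: float = 18.0
    age_max: float = 95.0
    female_share: float = 0.55
    education_probs: Mapping[str, float] = field(
        default_factory=lambda: {"none": 0.35, "gcse": 0.30, "alevel": 0.20, "degree": 0.15}
    )
    acute_probs: Mapping[str, float] = field(
        default_factory=lambda: {"none": 0.65, "sick1": 0.12, "sick2": 0.08, "sick3": 0.15}
    )
    general_health_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "very_good": 0.12, "good": 0.30, "fair": 0.33, "bad": 0.18, "very_bad": 0.07
        }
    )
    deprivation_probs: Mapping[str, float] = field(
        default_factory=lambda: {"least": 0.25, "little": 0.25, "very": 0.25, "most": 0.25}
    )
    year_probs: Mapping[str, float] = field(
        default_factory=lambda: {"2003": 0.2, "2004": 0.2, "2005": 0.2, "2006": 0.2, "2008": 0.2}
    )

    def validate(self) -> None:
        if not 0.0 <= self.female_share <= 1.0:
            raise ConfigError("female_share must lie in [0, 1]")
        if not self.age_min < self.age_max:
            raise ConfigError("age_min must be below age_max")
        for name, probs, levels in (
            ("education", self.education_probs, BASE_CATEGORICAL["education"]),
            ("acute_sickness", self.acute_probs, BASE_CATEGORICAL["acute_sickness"]),
            ("general_health", self.general_health_probs, BASE_CATEGORICAL["general_health"]),
            ("deprivation", self.deprivation_probs, BASE_CATEGORICAL["deprivation"]),
            ("survey_year", self.year_probs, BASE_CATEGORICAL["survey_year"]),
        ):
            _check_probs(name, probs)
            unknown = set(probs) - set(levels)
            if unknown:
                raise ConfigError(f"unknown level(s) for {name!r}: {sorted(unknown)}")


@dataclass(frozen=True)
class TrueDimensionModel:
    """Ground-truth coefficients for one dimension's ordinal model.

    Exactly one of ``cutpoints`` and ``target_cum`` must be set:
    explicit cut points, or cumulative marginal targets (P(d<=1),
    P(d<=2)) against which the cut points are calibrated on the realized
    linear predictors. ``beta_eq2=None`` means fully parallel truth.
    ``latent_loading`` scales a shared standard-normal severity factor
    added to both splits' linear predictors (0 = conditional
    independence across dimensions).
    """

    beta_eq1: Mapping[str, float]
    beta_eq2: Mapping[str, float] | None = None
    cutpoints: tuple[float, float] | None = None
    target_cum: tuple[float, float] | None = None
    latent_loading: float = 0.0

    def __post_init__(self) -> None:
        if (self.cutpoints is None) == (self.target_cum is None):
            raise ConfigError("set exactly one of cutpoints and target_cum")
        if self.target_cum is not None:
            c1, c2 = self.target_cum
            if not 0.0 < c1 < c2 < 1.0:
                raise ConfigError(f"target_cum must satisfy 0 < c1 < c2 < 1, got {self.target_cum}")
        if self.cutpoints is not None and not self.cutpoints[0] < self.cutpoints[1]:
            raise ConfigError("cutpoints must be increasing")


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to generate one cohort."""

    n: int
    models: Mapping[str, TrueDimensionModel]
    covariates: CovariateConfig = field(default_factory=CovariateConfig)
    label: str = "cohort"

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be positive")
        missing = [d for d in DIMENSIONS if d not in self.models]
        if missing:
            raise ConfigError(f"missing true model for dimension(s): {', '.join(missing)}")
        self.covariates.validate()


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_covariates(config: GeneratorConfig, seed_or_rng) -> pd.DataFrame:
    """Draw the covariate frame (with derived age terms)."""
    config.validate()
    rng = _rng(seed_or_rng)
    cov = config.covariates
    n = config.n
    a = (cov.age_min - cov.age_mean) / cov.age_sd
    b = (cov.age_max - cov.age_mean) / cov.age_sd
    age = stats.truncnorm.rvs(a, b, loc=cov.age_mean, scale=cov.age_sd,
                              size=n, random_state=rng)
    df = pd.DataFrame({"age": np.round(age, 1)})
    df["sex"] = np.where(rng.random(n) < cov.female_share, "female", "male")
    for col, probs in (
        ("education", cov.education_probs),
        ("acute_sickness", cov.acute_probs),
        ("general_health", cov.general_health_probs),
        ("deprivation", cov.deprivation_probs),
        ("survey_year", cov.year_probs),
    ):
        levels = [lv for lv in BASE_CATEGORICAL[col] if lv in probs]
        p = np.array([probs[lv] for lv in levels])
        df[col] = rng.choice(levels, size=n, p=p / p.sum())
    return add_age_terms(df)


def _beta_vector(beta: Mapping[str, float], columns: tuple[str, ...]) -> np.ndarray:
    unknown = set(beta) - set(columns)
    if unknown:
        raise ConfigError(f"true coefficients name unknown column(s): {sorted(unknown)}")
    return np.array([beta.get(c, 0.0) for c in columns])


def _calibrate_cutpoint(eta: np.ndarray, target: float) -> float:
    """Solve mean(logistic(k - eta)) = target for k."""
    span = float(np.max(np.abs(eta))) + 40.0

    def f(k):
        return np.mean(special.expit(k - eta)) - target

    return float(optimize.brentq(f, -span, span, xtol=1e-10))


def generate_responses(
    df: pd.DataFrame,
    config: GeneratorConfig,
    seed_or_rng,
    tariff: TariffCoefficients | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Sample the five ordinal responses and score the realized profiles.

    Returns the augmented frame (five level columns, ``profile`` string
    and true ``eq5d`` utility) plus an info dict recording the cut
    points used per dimension. Truth configurations that imply a
    negative middle-category probability for any row are rejected — the
    generator must be a clean oracle, so nothing is clamped silently.
    """
    config.validate()
    rng = _rng(seed_or_rng)
    if tariff is None:
        tariff = load_tariff()
    spec = base_design_spec()
    design = spec.build(df, drop_constant=False)
    X = design.matrix
    n = len(df)
    z = rng.standard_normal(n)

    out = df.copy()
    info: dict = {"cutpoints": {}, "latent_loadings": {}}
    levels = np.empty((n, 5), dtype=int)
    for j, dim in enumerate(DIMENSIONS):
        model = config.models[dim]
        b1 = _beta_vector(model.beta_eq1, design.columns)
        b2 = b1 if model.beta_eq2 is None else _beta_vector(model.beta_eq2, design.columns)
        eta1 = X @ b1 + model.latent_loading * z
        eta2 = X @ b2 + model.latent_loading * z
        if model.cutpoints is not None:
            k1, k2 = model.cutpoints
        else:
            k1 = _calibrate_cutpoint(eta1, model.target_cum[0])
            k2 = _calibrate_cutpoint(eta2, model.target_cum[1])
        c1 = special.expit(k1 - eta1)
        c2 = special.expit(k2 - eta2)
        bad = c2 < c1
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ConfigError(
                f"true model for {dim!r} implies a negative some-problems "
                f"probability at row {row}; adjust beta_eq2 or the cut points"
            )
        u = rng.random(n)
        levels[:, j] = np.where(u < c1, 1, np.where(u < c2, 2, 3))
        out[dim] = levels[:, j]
        info["cutpoints"][dim] = (float(k1), float(k2))
        info["latent_loadings"][dim] = float(model.latent_loading)

    out["profile"] = ["".join(map(str, row)) for row in levels]
    out["eq5d"] = score_profiles(levels, tariff)
    return out, info


def generate_cohort(
    config: GeneratorConfig, seed: int, tariff: TariffCoefficients | None = None
) -> tuple[pd.DataFrame, dict]:
    """Covariates plus responses from one master seed (spawned streams)."""
    ss_cov, ss_resp = np.random.SeedSequence(seed).spawn(2)
    df = generate_covariates(config, np.random.default_rng(ss_cov))
    out, info = generate_responses(df, config, np.random.default_rng(ss_resp), tariff)
    info["seed"] = int(seed)
    info["n"] = int(config.n)
    info["label"] = config.label
    return out, info


# --------------------------------------------------------------------------
# Condition presets
# --------------------------------------------------------------------------

#: Published per-dimension level shares (%) for the six condition
#: sub-groups; rows are (none, some, extreme) and are renormalized to 1.
PRESET_MARGINALS: dict[str, dict[str, tuple[float, float, float]]] = {
    "cvd": {
        "mobility": (55.4, 44.3, 0.3),
        "self_care": (85.8, 13.3, 0.9),
        "usual_activities": (62.5, 32.0, 5.6),
        "pain_discomfort": (41.8, 49.0, 9.3),
        "anxiety_depression": (73.4, 23.8, 2.8),
    },
    "diabetes": {
        "mobility": (61.6, 38.0, 0.4),
        "self_care": (87.5, 11.5, 1.0),
        "usual_activities": (66.9, 28.1, 5.0),
        "pain_discomfort": (45.2, 45.6, 9.2),
        "anxiety_depression": (73.8, 23.2, 3.0),
    },
    "mental_health": {
        "mobility": (65.2, 34.7, 0.1),
        "self_care": (84.2, 15.3, 0.5),
        "usual_activities": (55.4, 40.0, 4.6),
        "pain_discomfort": (46.9, 42.9, 10.2),
        "anxiety_depression": (21.6, 53.6, 24.8),
    },
    "musculoskeletal": {
        "mobility": (45.4, 54.3, 0.3),
        "self_care": (82.3, 16.8, 0.9),
        "usual_activities": (52.4, 41.8, 5.8),
        "pain_discomfort": (20.0, 64.7, 15.4),
        "anxiety_depression": (71.3, 25.3, 3.4),
    },
    "nervous_system": {
        "mobility": (52.6, 46.8, 0.6),
        "self_care": (80.0, 18.2, 1.8),
        "usual_activities": (52.3, 39.6, 8.1),
        "pain_discomfort": (33.8, 51.7, 14.5),
        "anxiety_depression": (64.8, 29.6, 5.6),
    },
    "respiratory": {
        "mobility": (67.0, 32.9, 0.2),
        "self_care": (88.9, 10.5, 0.6),
        "usual_activities": (70.0, 25.6, 4.4),
        "pain_discomfort": (53.1, 38.5, 8.4),
        "anxiety_depression": (73.0, 23.4, 3.6),
    },
}

#: Published share of each sub-group at full health (profile 11111),
#: the calibration target for the shared-severity scale below.
FULL_HEALTH_TARGETS: dict[str, float] = {
    "cvd": 0.315,
    "diabetes": 0.354,
    "mental_health": 0.131,
    "musculoskeletal": 0.151,
    "nervous_system": 0.229,
    "respiratory": 0.415,
}

#: Scale of the shared latent severity factor per preset, calibrated
#: once (scripts/calibrate_presets.py) so the generated full-health
#: share matches FULL_HEALTH_TARGETS given the preset's marginals and
#: covariate effects.
PRESET_LATENT_SD: dict[str, float] = {
    "cvd": 2.15,
    "diabetes": 2.13,
    "mental_health": 1.02,
    "musculoskeletal": 1.78,
    "nervous_system": 1.68,
    "respiratory": 2.16,
}

#: Shared covariate-effect template on the logit scale (positive =
#: worse health); per-dimension sensitivity multipliers below.
BETA_TEMPLATE: dict[str, float] = {
    "age_c": 0.18,
    "age_c2": 0.06,
    "sex[female]": 0.12,
    "education[gcse]": -0.20,
    "education[alevel]": -0.45,
    "education[degree]": -0.65,
    "acute_sickness[sick1]": 0.50,
    "acute_sickness[sick2]": 0.80,
    "acute_sickness[sick3]": 1.30,
    "general_health[very_good]": -2.9,
    "general_health[good]": -1.3,
    "general_health[bad]": 2.0,
    "general_health[very_bad]": 3.6,
    "deprivation[little]": 0.08,
    "deprivation[very]": 0.25,
    "deprivation[most]": 0.45,
    "survey_year[2004]": 0.01,
    "survey_year[2005]": -0.02,
    "survey_year[2006]": 0.02,
    "survey_year[2008]": 0.05,
}

DIMENSION_WEIGHT: dict[str, float] = {
    "mobility": 1.0,
    "self_care": 0.9,
    "usual_activities": 1.0,
    "pain_discomfort": 0.9,
    "anxiety_depression": 0.6,
}

PRESET_NAMES: tuple[str, ...] = tuple(PRESET_MARGINALS)


def make_preset(name: str, n: int = 10_000) -> GeneratorConfig:
    """Generator configuration for one named condition sub-group."""
    if name not in PRESET_MARGINALS:
        raise ConfigError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    marginals = PRESET_MARGINALS[name]
    latent = PRESET_LATENT_SD[name]
    models = {}
    for dim in DIMENSIONS:
        p1, p2, p3 = marginals[dim]
        total = p1 + p2 + p3
        c1, c2 = p1 / total, (p1 + p2) / total
        weight = DIMENSION_WEIGHT[dim]
        models[dim] = TrueDimensionModel(
            beta_eq1={k: v * weight for k, v in BETA_TEMPLATE.items()},
            target_cum=(c1, c2),
            latent_loading=latent,
        )
    covariates = CovariateConfig(age_mean=48.0 if name == "mental_health" else 58.0)
    return GeneratorConfig(n=n, models=models, covariates=covariates, label=name)


def make_benchmark_cohorts(
    outdir: str | Path,
    n: int = 10_000,
    seed: int = 715,
    presets: tuple[str, ...] = PRESET_NAMES,
) -> dict:
    """Generate one labelled CSV per preset plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(seed).spawn(len(presets))
    manifest: dict = {"seed": int(seed), "n": int(n), "cohorts": {}}
    for name, child in zip(presets, children):
        config = make_preset(name, n=n)
        child_seed = int(child.generate_state(1)[0] % (2**31))
        df, info = generate_cohort(config, child_seed)
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        manifest["cohorts"][name] = {
            "path": path.name,
            "seed": child_seed,
            "cutpoints": info["cutpoints"],
            "latent_sd": PRESET_LATENT_SD[name],
            "full_health_share": float(np.mean(df["eq5d"] == 1.0)),
        }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
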