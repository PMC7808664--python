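"""Synthetic primary-prevention cohorts, incidence tables and population structures.

The generator emulates a middle-aged, CVD-free cohort not on lipid-lowering
treatment: correlated conventional risk factors (blood pressure, lipids,
ln-CRP, smoking, diabetes), two standardized polygenic risk scores (one for
coronary heart disease, one for stroke, correlated 0.32 by default), and
cause-specific event times (CHD, stroke, revascularisation, non-CVD death)
drawn from proportional-hazards models.  Everything downstream of the
UK-cohort / primary-care-registry stages of the analysis can therefore run
at desk scale with no external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "generate_incidence_table",
    "generate_population_structure",
    "null_effect_config",
    "CONTINUOUS_PREDICTORS",
    "BINARY_PREDICTORS",
    "CAUSES",
    "COHORT_COLUMNS",
]

#: continuous predictors drawn jointly Gaussian (ln-CRP is already on log scale)
CONTINUOUS_PREDICTORS = (
    "age", "sbp", "tc", "hdl", "ldl", "ln_crp", "prs_chd", "prs_stroke",
)
#: binary predictors obtained by thresholding latent Gaussians
BINARY_PREDICTORS = ("smoker", "diabetes")
#: cause-specific event types; first event before the censoring horizon wins
CAUSES = ("CHD", "stroke", "revasc", "nonCVD_death")

COHORT_COLUMNS = (
    "id", "centre", "sex", "age", "smoker", "diabetes", "sbp", "tc", "hdl",
    "ldl", "ln_crp", "prs_chd", "prs_stroke", "follow_up", "outcome",
)

# Marginal calibration targets: mean age 56.0 (SD 8.0), 57% female,
# SBP 136.9 (19.1) mm Hg, smoking 10.3%, diabetes 1.2%, and lipid/CRP
# means typical of a statin-free cohort.
_DEFAULT_MEANS_SDS: dict[str, tuple[float, float]] = {
    "age": (56.0, 8.0),
    "sbp": (136.9, 19.1),
    "tc": (5.9, 1.1),
    "hdl": (1.5, 0.4),
    "ldl": (3.7, 0.8),
    "ln_crp": (0.3, 1.1),
    "prs_chd": (0.0, 1.0),
    "prs_stroke": (0.0, 1.0),
}

_DEFAULT_PREVALENCES = {"smoker": 0.103, "diabetes": 0.012}

# Pairwise latent correlations.  The PRS-PRS value of 0.32 is the one
# empirically-anchored entry; the remainder are modest, epidemiologically
# plausible free parameters (lipid fractions co-vary, CRP tracks adiposity /
# inflammation, blood pressure rises with age).  PRSs are independent of the
# conventional factors.
_DEFAULT_CORRELATIONS: dict[tuple[str, str], float] = {
    ("prs_chd", "prs_stroke"): 0.32,
    ("age", "sbp"): 0.35,
    ("age", "tc"): 0.20,
    ("age", "ldl"): 0.18,
    ("tc", "ldl"): 0.85,
    ("tc", "hdl"): 0.20,
    ("ln_crp", "hdl"): -0.25,
    ("ln_crp", "sbp"): 0.15,
    ("ln_crp", "tc"): 0.08,
    ("ln_crp", "ldl"): 0.10,
    ("smoker", "hdl"): -0.10,
    ("smoker", "ln_crp"): 0.20,
    ("diabetes", "ln_crp"): 0.15,
    ("diabetes", "sbp"): 0.10,
    ("diabetes", "hdl"): -0.15,
}

# Per-SD (continuous) or per-category (binaries, male sex) log hazard ratios.
# The per-SD PRS effects are ln(1.57) for the CHD score on CHD and ln(1.19)
# for the stroke score on stroke; the conventional-factor effects are chosen
# to give the familiar ordering (age dominant, then smoking/diabetes/SBP).
_DEFAULT_LOG_HRS: dict[str, dict[str, float]] = {
    "CHD": {
        "age": 0.60, "sex": 0.45, "smoker": 0.55, "diabetes": 0.70,
        "sbp": 0.25, "tc": 0.20, "hdl": -0.30, "prs_chd": math.log(1.57),
    },
    "stroke": {
        "age": 0.65, "sex": 0.20, "smoker": 0.40, "diabetes": 0.50,
        "sbp": 0.35, "hdl": -0.10, "prs_stroke": math.log(1.19),
    },
    "revasc": {
        "age": 0.40, "sex": 0.40, "tc": 0.25, "hdl": -0.25,
        "prs_chd": 0.35,
    },
    "nonCVD_death": {
        "age": 0.80, "sex": 0.30, "smoker": 0.60, "diabetes": 0.40,
    },
}

# Per-cause baseline hazards (events per person-year at the covariate means);
# shape 1.0 means exponential.  Tuned so a default cohort accrues roughly 2%
# first CVD events (CHD + stroke) over a 10-year horizon.
_DEFAULT_BASELINE_HAZARDS: dict[str, dict[str, float]] = {
    "CHD": {"scale": 6.5e-4, "shape": 1.0},
    "stroke": {"scale": 5e-4, "shape": 1.0},
    "revasc": {"scale": 2e-4, "shape": 1.0},
    "nonCVD_death": {"scale": 2.5e-3, "shape": 1.0},
}


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Continuous log hazard ratios are per configured SD of the predictor;
    ``sex`` is male versus female, binaries are category versus not.
    """

    n_individuals: int = 20_000
    seed: int = 0
    age_range: tuple[float, float] = (40.0, 75.0)
    fraction_female: float = 0.57
    risk_factor_means_sds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_MEANS_SDS))
    binary_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCES))
    predictor_correlations: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_CORRELATIONS))
    log_hazard_ratios: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in _DEFAULT_LOG_HRS.items()})
    baseline_hazard_params: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in _DEFAULT_BASELINE_HAZARDS.items()})
    censoring_horizon: float = 10.0
    n_centres: int = 22

    def correlation_matrix(self) -> pd.DataFrame:
        names = list(CONTINUOUS_PREDICTORS) + list(BINARY_PREDICTORS)
        mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for (a, b), r in self.predictor_correlations.items():
            if a not in names or b not in names:
                raise ConfigurationError(f"unknown predictor pair ({a}, {b})")
            mat.loc[a, b] = mat.loc[b, a] = r
        return mat

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ConfigurationError("n_individuals must be positive")
        if not (0.0 <= self.fraction_female <= 1.0):
            raise ConfigurationError("fraction_female must lie in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigurationError("age_range must be increasing")
        if self.censoring_horizon <= 0:
            raise ConfigurationError("censoring_horizon must be positive")
        if self.n_centres <= 0:
            raise ConfigurationError("n_centres must be positive")
        for name, (mu, sd) in self.risk_factor_means_sds.items():
            if sd <= 0:
                raise ConfigurationError(f"SD of {name} must be positive")
        for name, p in self.binary_prevalences.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"prevalence of {name} must lie in [0, 1]")
        for cause, params in self.baseline_hazard_params.items():
            if cause not in CAUSES:
                raise ConfigurationError(f"unknown cause {cause!r}")
            if params["scale"] < 0 or params.get("shape", 1.0) <= 0:
                raise ConfigurationError(f"baseline hazard for {cause} must be positive")
        mat = self.correlation_matrix().to_numpy()
        if not np.allclose(mat, mat.T):
            raise ConfigurationError("correlation matrix must be symmetric")
        if np.linalg.eigvalsh(mat).min() < -1e-10:
            raise ConfigurationError("correlation matrix is not positive semi-definite")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["predictor_correlations"] = {
            f"{a}|{b}": r for (a, b), r in self.predictor_correlations.items()}
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "predictor_correlations" in d:
            d["predictor_correlations"] = {
                tuple(k.split("|")): v for k, v in d["predictor_correlations"].items()}
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        if "risk_factor_means_sds" in d:
            d["risk_factor_means_sds"] = {
                k: tuple(v) for k, v in d["risk_factor_means_sds"].items()}
        return cls(**d)


def null_effect_config(**overrides) -> GeneratorConfig:
    """Config with every log hazard ratio set to zero (null-effect cohort)."""
    cfg = GeneratorConfig(**overrides)
    cfg.log_hazard_ratios = {c: {} for c in CAUSES}
    return cfg


def _draw_event_times(rng: np.random.Generator, rate: np.ndarray, shape: float) -> np.ndarray:
    # Inverse-transform sampling from H(t) = scale*exp(lp) * t^shape.
    e = rng.exponential(1.0, size=rate.shape)
    with np.errstate(divide="ignore"):
        t = e / rate
    if shape != 1.0:
        t = t ** (1.0 / shape)
    return t


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one synthetic cohort as a tidy DataFrame.

    Continuous predictors are drawn jointly Gaussian with the configured
    correlation structure (age through a truncated-normal copula so it stays
    inside ``age_range``); binaries threshold their latent Gaussians at the
    configured prevalences.  Cause-specific event times come from
    proportional-hazards models; the first event before the censoring
    horizon determines the outcome label, otherwise the record is censored
    at the horizon with outcome ``"none"``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals

    names = list(CONTINUOUS_PREDICTORS) + list(BINARY_PREDICTORS)
    corr = config.correlation_matrix().to_numpy()
    # eigen decomposition keeps PSD-but-singular matrices usable
    w, v = np.linalg.eigh(corr)
    chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n, len(names))) @ chol.T
    latent = pd.DataFrame(z, columns=names)

    df = pd.DataFrame({"id": np.arange(n, dtype=np.int64)})
    df["centre"] = rng.integers(0, config.n_centres, size=n).astype(np.int64)
    df["sex"] = np.where(rng.random(n) < config.fraction_female, "F", "M")

    lo, hi = config.age_range
    for name in CONTINUOUS_PREDICTORS:
        mu, sd = config.risk_factor_means_sds[name]
        if name == "age":
            a, b = (lo - mu) / sd, (hi - mu) / sd
            u = stats.norm.cdf(latent[name])
            df[name] = stats.truncnorm.ppf(u, a, b, loc=mu, scale=sd)
        else:
            df[name] = mu + sd * latent[name]
    for name in BINARY_PREDICTORS:
        p = config.binary_prevalences[name]
        df[name] = (latent[name] > stats.norm.ppf(1.0 - p)).astype(np.int64)

    # standardized design for the hazard linear predictors
    std = {}
    for name in CONTINUOUS_PREDICTORS:
        mu, sd = config.risk_factor_means_sds[name]
        std[name] = (df[name].to_numpy() - mu) / sd
    for name in BINARY_PREDICTORS:
        std[name] = df[name].to_numpy().astype(float)
    std["sex"] = (df["sex"] == "M").to_numpy().astype(float)

    horizon = config.censoring_horizon
    event_time = np.full(n, np.inf)
    outcome = np.full(n, "none", dtype=object)
    for cause in CAUSES:
        params = config.baseline_hazard_params.get(cause, {"scale": 0.0, "shape": 1.0})
        scale = params["scale"]
        shape = params.get("shape", 1.0)
        lp = np.zeros(n)
        for pred, beta in config.log_hazard_ratios.get(cause, {}).items():
            if pred not in std:
                raise ConfigurationError(f"unknown predictor {pred!r} in log_hazard_ratios")
            lp += beta * std[pred]
        rate = scale * np.exp(lp)
        t = _draw_event_times(rng, rate, shape) if scale > 0 else np.full(n, np.inf)
        sooner = t < event_time
        event_time[sooner] = t[sooner]
        outcome[sooner] = cause

    censored = event_time >= horizon
    outcome[censored] = "none"
    df["follow_up"] = np.where(censored, horizon, event_time)
    df["outcome"] = outcome
    return df[list(COHORT_COLUMNS)]


_DEFAULT_INCIDENCE = {
    # per person-year at the 40-45 band, and exponential age slope per year
    ("CVD", "F"): (9e-4, 0.075),
    ("CVD", "M"): (1.5e-3, 0.075),
    ("nonCVD_death", "F"): (8e-4, 0.090),
    ("nonCVD_death", "M"): (1.0e-3, 0.090),
}


def generate_incidence_table(
    seed: int = 0,
    age_start: float = 40.0,
    age_stop: float = 90.0,
    band_width: float = 5.0,
    params: Mapping[tuple[str, str], tuple[float, float]] | None = None,
    jitter_sd: float = 0.0,
    rate_scale: float = 1.0,
) -> pd.DataFrame:
    """Age-band x sex event-rate table for CVD and non-CVD death.

    Rates rise exponentially with age (higher in men) and are forced
    non-decreasing within sex even when multiplicative jitter is requested.
    Bands extend past 75 so that 10-year risks of the oldest screening-age
    individuals stay inside the table's support.

    Returns a DataFrame with columns ``age_lo, age_hi, sex, cause, rate``.
    """
    if band_width <= 0 or age_stop <= age_start:
        raise ValueError("invalid band definition")
    params = dict(params or _DEFAULT_INCIDENCE)
    rng = np.random.default_rng(seed)
    edges = np.arange(age_start, age_stop + 1e-9, band_width)
    rows = []
    for (cause, sex), (base, slope) in params.items():
        mids = (edges[:-1] + edges[1:]) / 2.0
        rate = base * np.exp(slope * (mids - (age_start + band_width / 2.0)))
        if jitter_sd > 0:
            rate = rate * np.exp(rng.normal(0.0, jitter_sd, size=rate.shape))
        rate = np.maximum.accumulate(rate) * rate_scale
        for lo, hi, r in zip(edges[:-1], edges[1:], rate):
            rows.append((float(lo), float(hi), sex, cause, float(r)))
    table = pd.DataFrame(rows, columns=["age_lo", "age_hi", "sex", "cause", "rate"])
    return table.sort_values(["cause", "sex", "age_lo"]).reset_index(drop=True)


# Plausible shares of the mid-2010s UK adult population across 5-year bands
# of ages 40-75 (younger bands slightly larger), split near-evenly by sex.
_UK_BAND_SHARES = (0.16, 0.17, 0.16, 0.15, 0.13, 0.12, 0.11)
_FEMALE_SHARE = 0.507


def generate_population_structure(
    total: int = 100_000,
    age_start: float = 40.0,
    age_stop: float = 75.0,
    band_width: float = 5.0,
    mode: str = "uk",
    proportions: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Counts per age-band x sex summing exactly to ``total``.

    ``mode="uk"`` uses a contemporary-UK-like age profile, ``"uniform"``
    spreads counts evenly; explicit per-band ``proportions`` override both.
    Largest-remainder rounding guarantees exact conservation of the total.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    edges = np.arange(age_start, age_stop + 1e-9, band_width)
    n_bands = len(edges) - 1
    female_share = _FEMALE_SHARE
    if proportions is not None:
        shares = np.asarray(proportions, dtype=float)
        if len(shares) != n_bands or (shares < 0).any():
            raise ValueError("proportions must be non-negative, one per band")
    elif mode == "uniform":
        shares = np.ones(n_bands)
        female_share = 0.5
    elif mode == "uk":
        if n_bands != len(_UK_BAND_SHARES):
            raise ValueError("uk mode expects 5-year bands over ages 40-75")
        shares = np.asarray(_UK_BAND_SHARES)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    shares = shares / shares.sum()

    cells = []
    for lo, hi, s in zip(edges[:-1], edges[1:], shares):
        cells.append((float(lo), float(hi), "F", s * female_share))
        cells.append((float(lo), float(hi), "M", s * (1.0 - female_share)))
    target = np.array([c[3] for c in cells]) * total
    counts = np.floor(target).astype(np.int64)
    remainder = total - counts.sum()
    order = np.argsort(-(target - counts), kind="stable")
    counts[order[:remainder]] += 1
    out = pd.DataFrame(
        [(lo, hi, sex) for lo, hi, sex, _ in cells],
        columns=["age_lo", "age_hi", "sex"])
    out["count"] = counts
    return out
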