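"""Stratified proportional-hazards engine.

Fits Cox models stratified by arbitrary categorical columns (study centre
and sex in the standard pipeline), stores a Breslow baseline survival per
stratum anchored at the training-data covariate means, and turns fitted
models into t-year absolute risks.  Also provides cause-specific
competing-risk cumulative incidence and the partial likelihood-ratio test
used to compare nested predictor sets.

Model fitting is delegated to :class:`lifelines.CoxPHFitter` (Efron tie
handling by default); this module owns the risk-prediction conventions and
the competing-risk integration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

__all__ = [
    "RiskModel",
    "FitError",
    "fit_cox",
    "predict_risk",
    "cumulative_incidence_competing",
    "partial_lr_test",
    "LRTestResult",
]

CVD_EVENT_LABELS = ("CHD", "stroke")


class FitError(RuntimeError):
    """Raised when partial-likelihood maximisation fails."""


def _stratum_key(values) -> tuple:
    if not isinstance(values, tuple):
        values = (values,)
    return tuple(str(v) for v in values)


@dataclass
class RiskModel:
    """A fitted cause-specific proportional-hazards model.

    ``baseline_cumhaz`` maps each stratum to a step function (pandas Series
    indexed by time) of the Breslow cumulative hazard evaluated at the
    per-stratum mean linear predictor, so an individual's t-year risk is
    ``1 - exp(-H0(t) * exp(lp - mean lp))``.
    """

    predictors: list[str]
    strata: list[str]
    coefficients: pd.Series
    standard_errors: pd.Series
    predictor_means: pd.Series
    baseline_cumhaz: dict[tuple, pd.Series]
    support: dict[tuple, float]
    log_likelihood: float
    n: int
    n_events: int
    event_labels: tuple[str, ...] = CVD_EVENT_LABELS
    ties: str = "efron"
    _fitter: CoxPHFitter | None = field(default=None, repr=False, compare=False)

    def hazard_ratios(self) -> pd.DataFrame:
        """Point estimates and 95% CIs on the hazard-ratio scale."""
        z = stats.norm.ppf(0.975)
        lo = self.coefficients - z * self.standard_errors
        hi = self.coefficients + z * self.standard_errors
        return pd.DataFrame({
            "hr": np.exp(self.coefficients),
            "ci_low": np.exp(lo),
            "ci_high": np.exp(hi),
            "coef": self.coefficients,
            "se": self.standard_errors,
        })

    def linear_predictor(self, records: pd.DataFrame) -> np.ndarray:
        """Centered linear predictor sum(beta * (x - training mean))."""
        x = records[self.predictors].to_numpy(dtype=float)
        centred = x - self.predictor_means[self.predictors].to_numpy(dtype=float)
        return centred @ self.coefficients[self.predictors].to_numpy(dtype=float)

    def _record_strata(self, records: pd.DataFrame) -> list[tuple]:
        if not self.strata:
            return [()] * len(records)
        vals = records[self.strata].astype(str).to_numpy()
        return [tuple(row) for row in vals]

    def cumhaz_at(self, key: tuple, t: float) -> float:
        series = self.baseline_cumhaz.get(key)
        if series is None:
            raise KeyError(f"stratum {key!r} not in fitted model")
        if t > self.support[key] + 1e-12:
            raise ValueError(
                f"horizon {t} exceeds supported follow-up {self.support[key]} "
                f"in stratum {key!r}")
        idx = np.searchsorted(series.index.to_numpy(), t, side="right") - 1
        return 0.0 if idx < 0 else float(series.iloc[idx])

    def schoenfeld_diagnostic(
        self,
        cohort: pd.DataFrame,
        duration_col: str = "follow_up",
        outcome_col: str = "outcome",
    ) -> pd.DataFrame | None:
        """Schoenfeld-residual proportional-hazards diagnostic (advisory only).

        Returns None when the model was built from an explicit baseline
        rather than fitted to data.
        """
        if self._fitter is None:
            return None
        from lifelines.statistics import proportional_hazard_test
        active = [p for p in self.predictors if np.isfinite(self.standard_errors[p])]
        data = cohort[active + self.strata].copy()
        data["_T"] = cohort[duration_col].to_numpy(dtype=float)
        data["_E"] = cohort[outcome_col].isin(list(self.event_labels)).to_numpy()
        return proportional_hazard_test(self._fitter, data).summary

    @classmethod
    def from_baseline(
        cls,
        times: Sequence[float],
        cumhaz: Sequence[float],
        coefficients: Mapping[str, float] | None = None,
        predictor_means: Mapping[str, float] | None = None,
        strata: Sequence[str] = (),
        stratum_keys: Sequence[tuple] = ((),),
        event_labels: tuple[str, ...] = CVD_EVENT_LABELS,
    ) -> "RiskModel":
        """Build a model from an explicit baseline cumulative hazard.

        Used for parametric and hand-set scenarios where the baseline is
        known in closed form rather than estimated from data.
        """
        coefficients = dict(coefficients or {})
        predictor_means = dict(predictor_means or {c: 0.0 for c in coefficients})
        series = pd.Series(np.asarray(cumhaz, dtype=float),
                           index=np.asarray(times, dtype=float))
        if (series.diff().dropna() < -1e-12).any():
            raise ValueError("cumulative hazard must be non-decreasing")
        keys = [_stratum_key(k) if k else () for k in stratum_keys]
        return cls(
            predictors=list(coefficients),
            strata=list(strata),
            coefficients=pd.Series(coefficients, dtype=float),
            standard_errors=pd.Series({k: np.nan for k in coefficients}, dtype=float),
            predictor_means=pd.Series(predictor_means, dtype=float),
            baseline_cumhaz={k: series.copy() for k in keys},
            support={k: float(series.index.max()) for k in keys},
            log_likelihood=np.nan,
            n=0,
            n_events=0,
            event_labels=event_labels,
        )

    # -- serialization (CLI hand-off between pipeline stages) ---------------
    def to_json_dict(self) -> dict:
        return {
            "predictors": self.predictors,
            "strata": self.strata,
            "coefficients": self.coefficients.to_dict(),
            "standard_errors": {k: (None if not np.isfinite(v) else v)
                                for k, v in self.standard_errors.items()},
            "predictor_means": self.predictor_means.to_dict(),
            "baseline_cumhaz": {
                "|".join(k): {"times": s.index.tolist(), "values": s.tolist()}
                for k, s in self.baseline_cumhaz.items()},
            "support": {"|".join(k): v for k, v in self.support.items()},
            "log_likelihood": self.log_likelihood,
            "n": self.n,
            "n_events": self.n_events,
            "event_labels": list(self.event_labels),
            "ties": self.ties,
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "RiskModel":
        def key(s: str) -> tuple:
            return tuple(s.split("|")) if s else ()
        return cls(
            predictors=list(d["predictors"]),
            strata=list(d["strata"]),
            coefficients=pd.Series(d["coefficients"], dtype=float),
            standard_errors=pd.Series(
                {k: (np.inf if v is None else v)
                 for k, v in d["standard_errors"].items()}, dtype=float),
            predictor_means=pd.Series(d["predictor_means"], dtype=float),
            baseline_cumhaz={key(k): pd.Series(v["values"], index=v["times"])
                             for k, v in d["baseline_cumhaz"].items()},
            support={key(k): v for k, v in d["support"].items()},
            log_likelihood=d["log_likelihood"],
            n=d["n"],
            n_events=d["n_events"],
            event_labels=tuple(d["event_labels"]),
            ties=d["ties"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RiskModel":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def _breslow_cumhaz(time: np.ndarray, event: np.ndarray, weights: np.ndarray) -> pd.Series:
    """Breslow baseline cumulative hazard for fixed risk weights exp(lp)."""
    order = np.argsort(time, kind="stable")
    t, e, w = time[order], event[order], weights[order]
    at_risk = np.cumsum(w[::-1])[::-1]
    jumps: dict[float, float] = {}
    i = 0
    n = len(t)
    while i < n:
        j = i
        d = 0.0
        while j < n and t[j] == t[i]:
            if e[j]:
                d += 1.0
            j += 1
        if d > 0:
            jumps[t[i]] = jumps.get(t[i], 0.0) + d / at_risk[i]
        i = j
    times = np.array(sorted(jumps))
    return pd.Series(np.cumsum([jumps[x] for x in times]), index=times)


def fit_cox(
    cohort: pd.DataFrame,
    predictors: Sequence[str],
    strata: Sequence[str] = ("centre", "sex"),
    event_labels: Sequence[str] = CVD_EVENT_LABELS,
    duration_col: str = "follow_up",
    outcome_col: str = "outcome",
    ties: str = "efron",
) -> RiskModel:
    """Fit a cause-specific Cox model; competing outcomes are censored.

    ``event_labels`` defines the cause of interest (the composite CVD
    outcome, CHD plus stroke, by default).  Predictors must be numeric and
    complete; zero-variance predictors are retained with a zero coefficient
    and infinite standard error.
    """
    predictors = list(predictors)
    strata = [s for s in strata if s]
    missing = [c for c in predictors + strata + [duration_col, outcome_col]
               if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks columns {missing}")
    data = cohort[predictors + strata].copy()
    if data[predictors].isna().any().any():
        raise ValueError("missing predictor values are not supported")
    data["_T"] = cohort[duration_col].to_numpy(dtype=float)
    data["_E"] = cohort[outcome_col].isin(list(event_labels)).to_numpy()
    if (data["_T"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    n_events = int(data["_E"].sum())
    if n_events == 0:
        raise FitError("no events of the requested cause")

    # encode any non-numeric predictors is caller's job; sex as predictor must
    # be pre-encoded.  Check numeric dtype here for a clear message.
    for p in predictors:
        if not np.issubdtype(np.asarray(data[p]).dtype, np.number):
            raise ValueError(f"predictor {p!r} must be numeric")

    constant = [p for p in predictors if np.ptp(data[p].to_numpy(dtype=float)) == 0]
    active = [p for p in predictors if p not in constant]
    if constant:
        warnings.warn(f"predictors {constant} are constant; coefficient fixed at 0")

    means = data[predictors].mean()

    if active:
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(
                    data[active + strata + ["_T", "_E"]],
                    duration_col="_T",
                    event_col="_E",
                    strata=strata or None,
                )
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise FitError(f"Cox partial-likelihood maximisation failed: {exc}") from exc
        if not np.isfinite(cph.params_.to_numpy()).all():
            raise FitError("non-finite coefficients (possible complete separation)")
        coef = pd.Series(0.0, index=predictors)
        se = pd.Series(np.inf, index=predictors)
        coef[active] = cph.params_.to_numpy()
        se[active] = cph.standard_errors_.to_numpy()
        log_lik = float(cph.log_likelihood_)
        base = cph.baseline_cumulative_hazard_
        baseline: dict[tuple, pd.Series] = {}
        if strata:
            for col in base.columns:
                baseline[_stratum_key(col)] = base[col].dropna()
        else:
            baseline[()] = base.iloc[:, 0].dropna()
        fitter = cph
    else:
        # all predictors constant: Breslow / Nelson-Aalen baseline, zero betas
        coef = pd.Series(0.0, index=predictors)
        se = pd.Series(np.inf, index=predictors)
        log_lik = float(_log_partial_likelihood(
            data["_T"].to_numpy(), data["_E"].to_numpy(),
            np.zeros(len(data)),
            strata_values=data[strata].astype(str).to_numpy() if strata else None,
            ties=ties))
        baseline = {}
        if strata:
            for key, grp in data.groupby(strata, observed=True):
                baseline[_stratum_key(key)] = _breslow_cumhaz(
                    grp["_T"].to_numpy(), grp["_E"].to_numpy(), np.ones(len(grp)))
        else:
            baseline[()] = _breslow_cumhaz(
                data["_T"].to_numpy(), data["_E"].to_numpy(), np.ones(len(data)))
        fitter = None

    if strata:
        support = {
            _stratum_key(key): float(grp["_T"].max())
            for key, grp in data.groupby(strata, observed=True)}
        empty = [k for k, grp in data.groupby(strata, observed=True)
                 if not grp["_E"].any()]
        if empty:
            warnings.warn(f"strata without events contribute nothing: {empty}")
    else:
        support = {(): float(data["_T"].max())}

    return RiskModel(
        predictors=predictors,
        strata=strata,
        coefficients=coef.astype(float),
        standard_errors=se.astype(float),
        predictor_means=means.astype(float),
        baseline_cumhaz=baseline,
        support=support,
        log_likelihood=log_lik,
        n=len(data),
        n_events=n_events,
        event_labels=tuple(event_labels),
        ties=ties,
        _fitter=fitter,
    )


def _log_partial_likelihood(time, event, lp, strata_values=None, ties="efron") -> float:
    """Efron (or Breslow) log partial likelihood at a fixed linear predictor."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    lp = np.asarray(lp, float)
    if strata_values is not None:
        keys = [tuple(r) for r in np.asarray(strata_values)]
        total = 0.0
        for key in sorted(set(keys)):
            m = np.array([k == key for k in keys])
            total += _log_partial_likelihood(time[m], event[m], lp[m], None, ties)
        return total
    order = np.argsort(time, kind="stable")
    t, e, x = time[order], event[order], lp[order]
    w = np.exp(x)
    at_risk = np.cumsum(w[::-1])[::-1]
    ll = 0.0
    i, n = 0, len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        tied = [k for k in range(i, j) if e[k]]
        d = len(tied)
        if d:
            ll += x[tied].sum()
            tied_w = w[tied].sum()
            for r in range(d):
                if ties == "efron":
                    ll -= np.log(at_risk[i] - (r / d) * tied_w)
                else:
                    ll -= np.log(at_risk[i])
        i = j
    return float(ll)


def predict_risk(model: RiskModel, records: pd.DataFrame, horizon: float) -> pd.DataFrame:
    """t-year absolute risk ``1 - S0(t)^exp(lp - mean lp)`` per record."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    lp = model.linear_predictor(records)
    keys = model._record_strata(records)
    h0 = np.array([model.cumhaz_at(k, horizon) for k in keys])
    risk = -np.expm1(-h0 * np.exp(lp))
    out = pd.DataFrame({"lp": lp, "risk": risk}, index=records.index)
    if "id" in records.columns:
        out.insert(0, "id", records["id"].to_numpy())
    return out


def _step_increments(series: pd.Series, grid: np.ndarray) -> np.ndarray:
    """Increments of a cumulative step function evaluated on a time grid."""
    vals = np.concatenate([[0.0], series.to_numpy()])
    times = series.index.to_numpy()
    idx = np.searchsorted(times, grid, side="right")
    cum = vals[idx]
    return np.diff(np.concatenate([[0.0], cum]))


def cumulative_incidence_competing(
    model_cvd: RiskModel,
    model_death: RiskModel,
    records: pd.DataFrame,
    horizon: float,
    chunk: int = 2048,
) -> pd.DataFrame:
    """Cause-specific cumulative incidence in the presence of competing death.

    Uses the discrete product-integral form ``S(u) = prod(1 - dA1 - dA2)``
    with per-record hazard increments ``dAk = exp(lp_k) dH0k``, so that
    ``cif_cvd + cif_death + surv == 1`` holds exactly.
    """
    if model_cvd.strata != model_death.strata:
        raise ValueError("models must share the same strata definition")
    lp1 = model_cvd.linear_predictor(records)
    lp2 = model_death.linear_predictor(records)
    keys = model_cvd._record_strata(records)

    cif1 = np.zeros(len(records))
    cif2 = np.zeros(len(records))
    surv = np.ones(len(records))
    keys_arr = np.array(["\x1f".join(k) for k in keys])
    for key in np.unique(keys_arr):
        mask = keys_arr == key
        tup = tuple(key.split("\x1f")) if key else ()
        b1 = model_cvd.baseline_cumhaz[tup]
        b2 = model_death.baseline_cumhaz.get(tup)
        if b2 is None:
            raise ValueError(f"stratum {tup!r} missing from competing model")
        grid = np.unique(np.concatenate([
            b1.index.to_numpy(), b2.index.to_numpy()]))
        grid = grid[grid <= horizon + 1e-12]
        dh1 = _step_increments(b1, grid)
        dh2 = _step_increments(b2, grid)
        idx = np.flatnonzero(mask)
        for start in range(0, len(idx), chunk):
            rows = idx[start:start + chunk]
            a1 = np.exp(lp1[rows])[:, None] * dh1[None, :]
            a2 = np.exp(lp2[rows])[:, None] * dh2[None, :]
            tot = np.clip(a1 + a2, 0.0, 1.0)
            s_prev = np.cumprod(1.0 - tot, axis=1)
            s_prev = np.concatenate([np.ones((len(rows), 1)), s_prev[:, :-1]], axis=1)
            cif1[rows] = (s_prev * a1).sum(axis=1)
            cif2[rows] = (s_prev * a2).sum(axis=1)
            surv[rows] = 1.0 - cif1[rows] - cif2[rows]
    out = pd.DataFrame(
        {"cif_cvd": cif1, "cif_death": cif2, "surv": surv}, index=records.index)
    if "id" in records.columns:
        out.insert(0, "id", records["id"].to_numpy())
    return out


@dataclass
class LRTestResult:
    statistic: float
    df: int
    p_value: float


def partial_lr_test(model_full: RiskModel, model_reduced: RiskModel) -> LRTestResult:
    """Partial likelihood-ratio test of nested predictor sets on the same data."""
    if not set(model_reduced.predictors) <= set(model_full.predictors):
        raise ValueError("reduced model's predictors must be a subset of the full model's")
    if (model_full.n, model_full.n_events) != (model_reduced.n, model_reduced.n_events):
        raise ValueError("models must be fitted on the same data")
    stat = 2.0 * (model_full.log_likelihood - model_reduced.log_likelihood)
    df = len(model_full.predictors) - len(model_reduced.predictors)
    if df == 0:
        return LRTestResult(max(stat, 0.0), 0, 1.0)
    p = float(stats.chi2.sf(max(stat, 0.0), df))
    return LRTestResult(float(stat), df, p)
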