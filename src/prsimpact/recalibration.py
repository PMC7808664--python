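"""Recalibration of predicted risks to a target population's incidence.

A model derived in a volunteer cohort under-states absolute risk in the
general primary-care population.  Recalibration rescales each individual's
cumulative hazard by a per-group factor (5-year age band x sex by default)
chosen so the group's mean recalibrated risk equals the risk expected from
the target population's incidence table, ``risk = 1 - exp(-k_g * Lambda_i)``.
Working on the cumulative-hazard scale keeps risks inside [0, 1] and never
reorders individuals within a group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "RecalibratedRiskModel",
    "expected_risk_from_incidence",
    "expected_risks_from_incidence",
    "recalibrate_risks",
    "recalibrate_model",
    "assign_age_band",
]


def expected_risks_from_incidence(
    table: pd.DataFrame,
    ages,
    sex: str,
    horizon: float,
    cause: str = "CVD",
) -> np.ndarray:
    """Vectorised ``horizon``-year risks from piecewise-constant rates.

    Follows each individual's attained age across the table's bands:
    ``risk = 1 - exp(-sum(rate_band * overlap))``.  Raises if any horizon
    extends past the last band.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    rows = table[(table["sex"] == sex) & (table["cause"] == cause)]
    rows = rows.sort_values("age_lo")
    if rows.empty:
        raise ValueError(f"no rates for sex={sex!r}, cause={cause!r}")
    if (rows["rate"] < 0).any():
        raise ValueError("rates must be non-negative")
    lo = rows["age_lo"].to_numpy(dtype=float)
    hi = rows["age_hi"].to_numpy(dtype=float)
    if not np.allclose(lo[1:], hi[:-1]):
        raise ValueError("age bands must be contiguous and non-overlapping")
    end = ages + horizon
    if (ages < lo[0] - 1e-9).any() or (end > hi[-1] + 1e-9).any():
        raise ValueError(
            f"attained ages [{ages.min()}, {end.max()}] not covered by bands "
            f"[{lo[0]}, {hi[-1]}]")
    overlap = np.clip(np.minimum(hi[None, :], end[:, None])
                      - np.maximum(lo[None, :], ages[:, None]), 0.0, None)
    cumhaz = overlap @ rows["rate"].to_numpy(dtype=float)
    return -np.expm1(-cumhaz)


def expected_risk_from_incidence(
    table: pd.DataFrame,
    age: float,
    sex: str,
    horizon: float,
    cause: str = "CVD",
) -> float:
    """Scalar convenience wrapper around :func:`expected_risks_from_incidence`."""
    return float(expected_risks_from_incidence(table, [age], sex, horizon, cause)[0])


def assign_age_band(age, edges) -> np.ndarray:
    """Index of the 5-year band holding each age (clamped to the outer bands)."""
    age = np.asarray(age, dtype=float)
    edges = np.asarray(edges, dtype=float)
    idx = np.searchsorted(edges, age, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def _solve_factor(lam: np.ndarray, target: float) -> float:
    """k such that mean(1 - exp(-k*lam)) == target (monotone in k)."""
    if target <= 0:
        return 0.0
    if target >= 1.0:
        raise ValueError("target risk must be below 1")
    if np.all(lam <= 0):
        raise ValueError("group has no positive baseline cumulative hazard")

    def f(k):
        return float(np.mean(-np.expm1(-k * lam)) - target)

    hi = 1.0
    while f(hi) < 0:
        hi *= 10.0
        if hi > 1e12:
            raise RuntimeError("recalibration factor search did not bracket")
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-13, rtol=1e-14))


def recalibrate_risks(
    risks,
    age,
    sex,
    table: pd.DataFrame,
    horizon: float,
    band_edges=None,
    cause: str = "CVD",
):
    """Per-group recalibration factors and the recalibrated risks.

    Returns ``(factors, recalibrated)`` where ``factors`` is a DataFrame with
    one row per (age band x sex) group present in the reference data, and the
    group target is the mean table-derived expected risk over its members.
    Groups absent from the reference data get factors interpolated from
    neighbouring bands of the same sex (with a warning) when predictions for
    them are later requested.
    """
    risks = np.asarray(risks, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    if (risks < 0).any() or (risks >= 1).any():
        raise ValueError("risks must lie in [0, 1)")
    if band_edges is None:
        lo = table.loc[table["cause"] == cause, "age_lo"].min()
        band_edges = np.arange(lo, 75.0 + 1e-9, 5.0)
        band_edges = np.append(band_edges, 75.0) if band_edges[-1] < 75.0 else band_edges
    band_edges = np.asarray(band_edges, dtype=float)
    band_idx = assign_age_band(age, band_edges)
    lam = -np.log1p(-risks)

    rows = []
    recal = np.empty_like(risks)
    for s in np.unique(sex):
        sm = sex == s
        expected_s = np.empty(len(age))
        expected_s[sm] = expected_risks_from_incidence(
            table, age[sm], s, horizon, cause)
        for b in np.unique(band_idx[sm]):
            m = sm & (band_idx == b)
            target = float(expected_s[m].mean())
            k = _solve_factor(lam[m], target)
            recal[m] = -np.expm1(-k * lam[m])
            rows.append((float(band_edges[b]), float(band_edges[b + 1]), s,
                         k, target, int(m.sum())))
    factors = pd.DataFrame(
        rows, columns=["age_lo", "age_hi", "sex", "factor", "target_risk", "n"])
    return factors.sort_values(["sex", "age_lo"]).reset_index(drop=True), recal


@dataclass
class RecalibratedRiskModel:
    """A fitted risk model plus multiplicative cumulative-hazard factors."""

    source: object  # RiskModel
    factors: pd.DataFrame
    horizon: float
    band_edges: np.ndarray

    def factor_for(self, age, sex) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        sex = np.asarray(sex)
        out = np.empty(len(age))
        for s in np.unique(sex):
            sub = self.factors[self.factors["sex"] == s]
            if sub.empty:
                raise ValueError(f"no recalibration factors for sex {s!r}")
            mids = ((sub["age_lo"] + sub["age_hi"]) / 2.0).to_numpy()
            facs = sub["factor"].to_numpy()
            m = sex == s
            band = assign_age_band(age[m], self.band_edges)
            band_mid = (self.band_edges[band] + self.band_edges[band + 1]) / 2.0
            known = np.isin(np.round(band_mid, 6), np.round(mids, 6))
            if not known.all():
                warnings.warn(
                    f"{int((~known).sum())} records fall in age bands absent from "
                    "the reference cohort; factors interpolated from neighbours")
            out[m] = np.interp(band_mid, mids, facs)
        return out

    def predict_risk(self, records: pd.DataFrame, horizon: float | None = None) -> pd.DataFrame:
        """Recalibrated absolute risks for new records."""
        from .cox import predict_risk

        horizon = self.horizon if horizon is None else horizon
        base = predict_risk(self.source, records, horizon)
        lam = -np.log1p(-base["risk"].to_numpy())
        k = self.factor_for(records["age"].to_numpy(), records["sex"].to_numpy())
        out = base.copy()
        out["risk"] = -np.expm1(-k * lam)
        return out


def recalibrate_model(
    model,
    reference_cohort: pd.DataFrame,
    table: pd.DataFrame,
    horizon: float,
    band_edges=None,
    cause: str = "CVD",
) -> RecalibratedRiskModel:
    """Recalibrate a fitted model against an incidence table.

    The reference cohort supplies the predicted-risk distribution within each
    age band x sex group; the table supplies each group's expected risk.
    """
    from .cox import predict_risk

    if band_edges is None:
        lo = reference_cohort["age"].min()
        start = 5.0 * np.floor(lo / 5.0)
        band_edges = np.arange(start, 75.0 + 1e-9, 5.0)
    band_edges = np.asarray(band_edges, dtype=float)
    base = predict_risk(model, reference_cohort, horizon)
    factors, _ = recalibrate_risks(
        base["risk"].to_numpy(),
        reference_cohort["age"].to_numpy(),
        reference_cohort["sex"].to_numpy(),
        table, horizon, band_edges=band_edges, cause=cause)
    return RecalibratedRiskModel(source=model, factors=factors,
                                 horizon=horizon, band_edges=band_edges)
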