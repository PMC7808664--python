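"""Discrimination and calibration metrics for survival risk models.

Implements Harrell's C-index pooled over strata (a pair is comparable only
within a stratum, and only when the earlier time ends in an event), jackknife
confidence intervals for C and for the change in C when a marker is added,
event-weighted internal/external validation, and censoring-aware calibration
assessment (decile plot quantities, calibration slope, RMSE and the
Greenwood-Nam-D'Agostino chi-square).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcordanceResult",
    "DeltaCResult",
    "ValidationResult",
    "CalibrationReport",
    "harrells_c",
    "delta_c_jackknife",
    "internal_external_validate",
    "pooled_concordance",
    "calibration_assess",
    "cross_validated_risks",
    "km_risk",
]

_LOO_MAX = 5000  # exact leave-one-out below this size, grouped jackknife above


@dataclass
class ConcordanceResult:
    c_index: float
    se: float
    ci_low: float
    ci_high: float
    n_comparable_pairs: float
    n: int
    strata: tuple[str, ...] = ()


@dataclass
class DeltaCResult:
    delta_c: float
    se: float
    ci_low: float
    ci_high: float
    c_base: ConcordanceResult
    c_augmented: ConcordanceResult


@dataclass
class ValidationResult:
    pooled: ConcordanceResult
    per_subset: pd.DataFrame  # subset, c_index, events, n


@dataclass
class CalibrationReport:
    table: pd.DataFrame  # group, n, mean_predicted, observed, km_variance
    slope: float
    intercept: float
    rmse: float
    gnd_statistic: float
    gnd_df: int
    gnd_p: float
    merged_groups: int = 0


def _stratum_codes(strata_frame: pd.DataFrame | None, n: int) -> np.ndarray:
    if strata_frame is None or strata_frame.shape[1] == 0:
        return np.zeros(n, dtype=np.int64)
    key = strata_frame.astype(str).agg("\x1f".join, axis=1)
    return pd.factorize(key)[0]


def _pair_aggregates(score, time, event, codes, chunk=2048):
    """Concordance numerator/denominator totals and per-individual sums.

    Each comparable pair contributes once to the totals and once to each of
    its two members' per-individual sums, so leave-one-out totals are exact:
    removing individual i removes exactly (num_i, den_i).
    """
    n = len(score)
    num_i = np.zeros(n)
    den_i = np.zeros(n)
    total_num = 0.0
    total_den = 0.0
    for code in np.unique(codes):
        idx = np.flatnonzero(codes == code)
        t, e, s = time[idx], event[idx], score[idx]
        m = len(idx)
        for start in range(0, m, chunk):
            rows = slice(start, min(start + chunk, m))
            # rows index i: pair comparable when t_i < t_j and i had an event
            comp = (t[rows, None] < t[None, :]) & e[rows, None]
            conc = np.where(s[rows, None] > s[None, :], 1.0,
                            np.where(s[rows, None] == s[None, :], 0.5, 0.0))
            conc = conc * comp
            total_num += conc.sum()
            total_den += comp.sum()
            num_i[idx[rows]] += conc.sum(axis=1)
            den_i[idx[rows]] += comp.sum(axis=1)
            num_i[idx] += conc.sum(axis=0)
            den_i[idx] += comp.sum(axis=0)
    return total_num, total_den, num_i, den_i


def _within_group_pairs(score, time, event, codes, members):
    """Pair sums with both ends inside ``members`` (same stratum only)."""
    sub_codes = codes[members]
    num = 0.0
    den = 0.0
    for code in np.unique(sub_codes):
        idx = members[sub_codes == code]
        if len(idx) < 2:
            continue
        t, e, s = time[idx], event[idx], score[idx]
        comp = (t[:, None] < t[None, :]) & e[:, None]
        conc = np.where(s[:, None] > s[None, :], 1.0,
                        np.where(s[:, None] == s[None, :], 0.5, 0.0))
        num += (conc * comp).sum()
        den += comp.sum()
    return num, den


def _jackknife_values(score, time, event, codes, n_groups=100, seed=0):
    """Leave-one-out (or leave-one-group-out) C values and the full C."""
    total_num, total_den, num_i, den_i = _pair_aggregates(score, time, event, codes)
    if total_den == 0:
        raise ValueError("no comparable pairs in any stratum")
    c = total_num / total_den
    n = len(score)
    if n <= _LOO_MAX:
        units = [np.array([i]) for i in range(n)]
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        units = [np.sort(perm[g::n_groups]) for g in range(n_groups)]
    values = np.empty(len(units))
    for k, members in enumerate(units):
        rem_num = num_i[members].sum()
        rem_den = den_i[members].sum()
        if len(members) > 1:
            wnum, wden = _within_group_pairs(score, time, event, codes, members)
            rem_num -= wnum  # pairs internal to the group were counted twice
            rem_den -= wden
        den = total_den - rem_den
        values[k] = (total_num - rem_num) / den if den > 0 else c
    return c, values, total_den


def harrells_c(
    score,
    time,
    event,
    strata: pd.DataFrame | None = None,
    n_groups: int = 100,
    seed: int = 0,
) -> ConcordanceResult:
    """Stratified Harrell's C with a jackknife standard error.

    Comparable pairs are counted within strata and pooled; score ties count
    one half.  The CI uses exact leave-one-out below 5,000 records and a
    grouped jackknife (default 100 random groups) above.
    """
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    codes = _stratum_codes(strata, len(score))
    c, values, pairs = _jackknife_values(score, time, event, codes, n_groups, seed)
    g = len(values)
    var = (g - 1) / g * ((values - values.mean()) ** 2).sum()
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.975)
    return ConcordanceResult(
        c_index=float(c), se=se,
        ci_low=float(c - z * se), ci_high=float(c + z * se),
        n_comparable_pairs=float(pairs), n=len(score),
        strata=tuple(strata.columns) if strata is not None else (),
    )


def delta_c_jackknife(
    score_base,
    score_augmented,
    time,
    event,
    strata: pd.DataFrame | None = None,
    n_groups: int = 100,
    seed: int = 0,
) -> DeltaCResult:
    """Change in C with jackknife CI on the paired difference.

    Both scores must be evaluated on the same records; the jackknife
    replicates remove the same units from both C computations so the
    correlation between the two estimates is respected.
    """
    score_base = np.asarray(score_base, dtype=float)
    score_augmented = np.asarray(score_augmented, dtype=float)
    if score_base.shape != score_augmented.shape:
        raise ValueError("both scores must cover the identical record set")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    codes = _stratum_codes(strata, len(time))
    cb, vb, pairs = _jackknife_values(score_base, time, event, codes, n_groups, seed)
    ca, va, _ = _jackknife_values(score_augmented, time, event, codes, n_groups, seed)
    d = va - vb
    g = len(d)
    var = (g - 1) / g * ((d - d.mean()) ** 2).sum()
    se = float(np.sqrt(var))
    delta = float(ca - cb)
    z = stats.norm.ppf(0.975)

    def _as_result(c, vals):
        v = (g - 1) / g * ((vals - vals.mean()) ** 2).sum()
        s = float(np.sqrt(v))
        return ConcordanceResult(float(c), s, float(c - z * s), float(c + z * s),
                                 float(pairs), len(time),
                                 tuple(strata.columns) if strata is not None else ())

    return DeltaCResult(
        delta_c=delta, se=se,
        ci_low=delta - z * se, ci_high=delta + z * se,
        c_base=_as_result(cb, vb), c_augmented=_as_result(ca, va),
    )


def pooled_concordance(c_values: Sequence[float], event_counts: Sequence[float]) -> float:
    """Meta-analytic pooling of subset C values weighted by event counts."""
    c = np.asarray(c_values, dtype=float)
    w = np.asarray(event_counts, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("event counts must be non-negative with positive total")
    return float((w * c).sum() / w.sum())


def internal_external_validate(
    cohort: pd.DataFrame,
    predictors: Sequence[str],
    event_labels: Sequence[str],
    scheme: str = "centre",
    n_folds: int = 10,
    seed: int = 0,
    fit_strata: Sequence[str] = ("centre", "sex"),
    validate_strata: Sequence[str] = ("sex",),
    duration_col: str = "follow_up",
    outcome_col: str = "outcome",
) -> ValidationResult:
    """Internal/external cross-validated discrimination.

    ``scheme="centre"`` leaves one recruitment centre out per iteration,
    ``scheme="kfold"`` uses random folds.  Each held-out subset's C (computed
    from the model fitted on the remainder) is pooled weighted by the number
    of events in that subset; subsets without events are excluded.
    """
    from .cox import fit_cox

    if scheme == "centre":
        labels = cohort["centre"].to_numpy()
        fit_strata_eff = [s for s in fit_strata if s != "centre"]
    elif scheme == "kfold":
        rng = np.random.default_rng(seed)
        labels = rng.permutation(len(cohort)) % n_folds
        fit_strata_eff = list(fit_strata)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    event_all = cohort[outcome_col].isin(list(event_labels)).to_numpy()
    rows = []
    for lab in np.unique(labels):
        held = labels == lab
        if not event_all[held].any():
            warnings.warn(f"validation subset {lab!r} has no events; excluded")
            continue
        if not event_all[~held].any():
            continue
        model = fit_cox(cohort.loc[~held], predictors, strata=fit_strata_eff,
                        event_labels=event_labels, duration_col=duration_col,
                        outcome_col=outcome_col)
        sub = cohort.loc[held]
        lp = model.linear_predictor(sub)
        vs = [s for s in validate_strata if s in sub.columns]
        res = harrells_c(lp, sub[duration_col], event_all[held],
                         strata=sub[vs] if vs else None)
        rows.append((lab, res.c_index, int(event_all[held].sum()), int(held.sum())))
    if len(rows) < 1:
        raise ValueError("no validation subset with events")
    per = pd.DataFrame(rows, columns=["subset", "c_index", "events", "n"])
    pooled_c = pooled_concordance(per["c_index"], per["events"])
    # SE of the pooled estimate from the weighted spread across subsets
    w = per["events"].to_numpy(dtype=float)
    se = float(np.sqrt(((w / w.sum()) ** 2 * np.var(per["c_index"])).sum()))
    z = stats.norm.ppf(0.975)
    pooled = ConcordanceResult(pooled_c, se, pooled_c - z * se, pooled_c + z * se,
                               np.nan, int(per["n"].sum()))
    return ValidationResult(pooled=pooled, per_subset=per)


def km_risk(time, event, horizon: float) -> tuple[float, float]:
    """Kaplan-Meier event risk at ``horizon`` with its Greenwood variance."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = len(t)
    surv = 1.0
    gw = 0.0
    i = 0
    while i < n and t[i] <= horizon:
        j = i
        d = 0
        while j < n and t[j] == t[i]:
            if e[j]:
                d += 1
            j += 1
        at_risk = n - i
        if d > 0:
            surv *= 1.0 - d / at_risk
            if at_risk > d:
                gw += d / (at_risk * (at_risk - d))
            else:
                gw = np.inf
        i = j
    var = surv ** 2 * gw if np.isfinite(gw) else 0.0
    return 1.0 - surv, var


def calibration_assess(
    predicted,
    time,
    event,
    horizon: float,
    n_groups: int = 10,
) -> CalibrationReport:
    """Observed-versus-predicted calibration over risk groups.

    Predictions should come from cross-validated fits (see
    :func:`cross_validated_risks`) to avoid optimism.  Observed risks are
    Kaplan-Meier estimates at the horizon; groups whose KM variance is zero
    (no events) are merged into the neighbouring group before computing the
    Greenwood-Nam-D'Agostino chi-square with (groups - 1) degrees of freedom.
    """
    if n_groups < 2:
        raise ValueError("need at least two risk groups")
    predicted = np.asarray(predicted, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    groups = pd.qcut(pd.Series(predicted).rank(method="first"), n_groups,
                     labels=False).to_numpy()

    merged = 0
    while True:
        rows = []
        for g in np.unique(groups):
            m = groups == g
            obs, var = km_risk(time[m], event[m], horizon)
            rows.append((g, int(m.sum()), float(predicted[m].mean()), obs, var))
        tab = pd.DataFrame(rows, columns=["group", "n", "mean_predicted",
                                          "observed", "km_variance"])
        bad = tab.loc[tab["km_variance"] <= 0.0, "group"]
        if bad.empty or len(tab) <= 2:
            break
        # merge the first degenerate group into its neighbour
        g = bad.iloc[0]
        uniq = np.sort(np.unique(groups))
        pos = int(np.flatnonzero(uniq == g)[0])
        neighbour = uniq[pos + 1] if pos + 1 < len(uniq) else uniq[pos - 1]
        groups[groups == g] = neighbour
        merged += 1
        warnings.warn(f"calibration group {g} had no events; merged into {neighbour}")

    obs = tab["observed"].to_numpy()
    pred = tab["mean_predicted"].to_numpy()
    slope, intercept = np.polyfit(pred, obs, 1)
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    ok = tab["km_variance"].to_numpy() > 0
    gnd = float((((obs - pred) ** 2)[ok] / tab["km_variance"].to_numpy()[ok]).sum())
    df = int(ok.sum()) - 1
    p = float(stats.chi2.sf(gnd, df)) if df > 0 else float("nan")
    return CalibrationReport(table=tab, slope=float(slope), intercept=float(intercept),
                             rmse=rmse, gnd_statistic=gnd, gnd_df=df, gnd_p=p,
                             merged_groups=merged)


def cross_validated_risks(
    cohort: pd.DataFrame,
    predictors: Sequence[str],
    event_labels: Sequence[str],
    horizon: float,
    strata: Sequence[str] = ("centre", "sex"),
    n_folds: int = 10,
    seed: int = 0,
    duration_col: str = "follow_up",
    outcome_col: str = "outcome",
) -> np.ndarray:
    """Out-of-fold t-year risks from k-fold refits (optimism-free calibration)."""
    from .cox import fit_cox, predict_risk

    rng = np.random.default_rng(seed)
    folds = rng.permutation(len(cohort)) % n_folds
    risks = np.full(len(cohort), np.nan)
    for f in range(n_folds):
        held = folds == f
        model = fit_cox(cohort.loc[~held], predictors, strata=strata,
                        event_labels=event_labels, duration_col=duration_col,
                        outcome_col=outcome_col)
        risks[held] = predict_risk(model, cohort.loc[held], horizon)["risk"].to_numpy()
    return risks
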