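"""Net reclassification index for survival outcomes.

Case and non-case status at the horizon are determined with inverse
probability of censoring weights (Kaplan-Meier estimate of the censoring
distribution), which reduces exactly to direct counting when no record is
censored before the horizon.  Both the continuous NRI (any directional
change in predicted risk) and the categorical NRI under guideline risk-band
schemes are provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RiskCategoryScheme",
    "NICE",
    "ACC_AHA",
    "NriResult",
    "categorize",
    "continuous_nri",
    "categorical_nri",
    "ipcw_case_weights",
]


@dataclass(frozen=True)
class RiskCategoryScheme:
    """Ordered probability cut-points defining low/intermediate/high risk.

    Intervals are left-closed, right-open; the top category is closed at 1.
    """

    name: str
    cuts: tuple[float, ...]
    labels: tuple[str, ...] = ("low", "intermediate", "high")

    def __post_init__(self):
        cuts = tuple(self.cuts)
        if any(not (0.0 < c < 1.0) for c in cuts) or list(cuts) != sorted(set(cuts)):
            raise ValueError("cut-points must be strictly increasing within (0, 1)")
        if len(self.labels) != len(cuts) + 1:
            raise ValueError("need one label per category")


#: UK NICE bands: <5%, 5% to <10%, and >=10% predicted 10-year risk
NICE = RiskCategoryScheme("NICE", (0.05, 0.10))
#: ACC/AHA bands: <5%, 5% to <7.5%, and >=7.5%
ACC_AHA = RiskCategoryScheme("ACC/AHA", (0.05, 0.075))

SCHEMES = {"nice": NICE, "accaha": ACC_AHA}


@dataclass
class NriResult:
    case_nri: float  # percent
    noncase_nri: float  # percent
    case_ci: tuple[float, float]
    noncase_ci: tuple[float, float]
    horizon: float
    scheme: str  # "continuous" or a category scheme name
    n_cases: float  # IPCW-weighted
    n_noncases: float


def categorize(risk, scheme: RiskCategoryScheme) -> np.ndarray:
    """Map risks to integer category indices (0 = lowest band)."""
    risk = np.asarray(risk, dtype=float)
    if (risk < 0).any() or (risk > 1).any():
        raise ValueError("risks must lie in [0, 1]")
    return np.digitize(risk, scheme.cuts, right=False)


def ipcw_case_weights(time, event, horizon: float):
    """Per-record case indicator, non-case indicator and IPCW weight.

    Cases (event by the horizon) are weighted by 1/G(t-), known non-cases
    (followed beyond the horizon without an event) by 1/G(horizon), where G
    is the Kaplan-Meier estimate of the censoring survival function.
    Records censored before the horizon receive weight zero.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    case = event & (time <= horizon)
    noncase = (time >= horizon) & ~case
    if not case.any():
        raise ValueError("no cases by the horizon")
    if not noncase.any():
        raise ValueError("no non-cases by the horizon")

    # KM of the censoring distribution: a "censoring event" is end of
    # follow-up without the outcome of interest.
    order = np.argsort(time, kind="stable")
    t, cens = time[order], (~event[order])
    n = len(t)
    uniq_t = []
    surv_vals = []
    surv = 1.0
    i = 0
    while i < n:
        j = i
        d = 0
        while j < n and t[j] == t[i]:
            if cens[j]:
                d += 1
            j += 1
        if d > 0:
            surv *= 1.0 - d / (n - i)
            uniq_t.append(t[i])
            surv_vals.append(surv)
        i = j

    def g_left(times_eval):
        # left limit G(t-): survival just before t
        if not uniq_t:
            return np.ones_like(times_eval)
        idx = np.searchsorted(uniq_t, times_eval, side="left") - 1
        vals = np.concatenate([[1.0], surv_vals])
        return vals[idx + 1]

    w = np.zeros(len(time))
    g_case = g_left(time[case])
    g_h = g_left(np.array([horizon * (1 + 1e-12)]))[0]
    if (g_case <= 0).any() or g_h <= 0:
        raise ValueError("censoring survival reaches zero before the horizon")
    w[case] = 1.0 / g_case
    w[noncase] = 1.0 / g_h
    return case, noncase, w


def _nri(up, down, time, event, horizon, scheme_name, n_boot, seed):
    case, noncase, w = ipcw_case_weights(time, event, horizon)

    def estimate(idx):
        c = case[idx]
        nc = noncase[idx]
        wi = w[idx]
        u, d = up[idx], down[idx]
        wc = wi[c].sum()
        wn = wi[nc].sum()
        if wc <= 0 or wn <= 0:
            return np.nan, np.nan
        case_nri = 100.0 * (wi[c & u].sum() - wi[c & d].sum()) / wc
        noncase_nri = 100.0 * (wi[nc & d].sum() - wi[nc & u].sum()) / wn
        return case_nri, noncase_nri

    all_idx = np.arange(len(time))
    case_nri, noncase_nri = estimate(all_idx)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 2))
    for b in range(n_boot):
        idx = rng.integers(0, len(time), len(time))
        boots[b] = estimate(idx)
    with np.errstate(all="ignore"):
        lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    return NriResult(
        case_nri=float(case_nri), noncase_nri=float(noncase_nri),
        case_ci=(float(lo[0]), float(hi[0])),
        noncase_ci=(float(lo[1]), float(hi[1])),
        horizon=horizon, scheme=scheme_name,
        n_cases=float(w[case].sum()), n_noncases=float(w[noncase].sum()),
    )


def continuous_nri(risk_old, risk_new, time, event, horizon: float,
                   n_boot: int = 200, seed: int = 0) -> NriResult:
    """Continuous (category-free) NRI: any risk increase counts as 'up'."""
    risk_old = np.asarray(risk_old, dtype=float)
    risk_new = np.asarray(risk_new, dtype=float)
    if risk_old.shape != risk_new.shape:
        raise ValueError("old and new risks must be paired on identical records")
    up = risk_new > risk_old
    down = risk_new < risk_old
    return _nri(up, down, time, event, horizon, "continuous", n_boot, seed)


def categorical_nri(risk_old, risk_new, scheme: RiskCategoryScheme,
                    time, event, horizon: float,
                    n_boot: int = 200, seed: int = 0) -> NriResult:
    """Categorical NRI: 'up'/'down' means crossing a scheme cut-point."""
    cat_old = categorize(risk_old, scheme)
    cat_new = categorize(risk_new, scheme)
    up = cat_new > cat_old
    down = cat_new < cat_old
    return _nri(up, down, time, event, horizon, scheme.name, n_boot, seed)
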