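"""Public-health impact of screening strategies with guideline statin rules.

Projects a reference cohort's risk distribution onto a standardized
population (100,000 adults aged 40-75 by default), applies a screening
strategy — conventional risk factors only, blanket reassessment of everyone
with the marker-augmented model, or targeted reassessment of the
intermediate-risk band only — and tallies reclassification flows, expected
events among movers across the treatment threshold, events prevented under a
relative-risk-reduction assumption, and the number needed to screen.

Reporting conventions: prevented events are rounded up to the next whole
event; the number needed to screen is the screened count divided by the
*unrounded* prevented events, rounded to the nearest integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reclassification import RiskCategoryScheme, NICE, categorize
from .recalibration import assign_age_band

__all__ = [
    "TreatmentRule",
    "ScreeningStrategy",
    "CONVENTIONAL_ONLY",
    "TARGETED_PRS",
    "BLANKET_PRS",
    "ReclassificationFlows",
    "ImpactResult",
    "standardize_population",
    "apply_strategy",
    "events_prevented",
    "number_needed_to_screen",
    "percent_additional_high_risk_events",
    "run_impact",
]


@dataclass(frozen=True)
class TreatmentRule:
    """Guideline statin-allocation rule.

    Statins are initiated at or above ``threshold`` predicted 10-year risk;
    people with diabetes or LDL cholesterol >= ``ldl_threshold`` mmol/l are
    treated irrespective of predicted risk and leave the screening pool.
    """

    threshold: float = 0.10
    ldl_threshold: float = 5.0
    rrr: float = 0.20

    def __post_init__(self):
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("treatment threshold must lie in (0, 1)")
        if not (0.0 <= self.rrr <= 1.0):
            raise ValueError("relative risk reduction must lie in [0, 1]")


@dataclass(frozen=True)
class ScreeningStrategy:
    """Which individuals receive the second-stage marker assessment."""

    name: str  # conventional_only | targeted_prs | blanket_prs
    band: tuple[float, float] = (0.05, 0.10)

    def __post_init__(self):
        if self.name not in ("conventional_only", "targeted_prs", "blanket_prs"):
            raise ValueError(f"unknown strategy {self.name!r}")
        lo, hi = self.band
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("targeting band must satisfy 0 < lower < upper < 1")


CONVENTIONAL_ONLY = ScreeningStrategy("conventional_only")
TARGETED_PRS = ScreeningStrategy("targeted_prs")
BLANKET_PRS = ScreeningStrategy("blanket_prs")


@dataclass
class ReclassificationFlows:
    """Weighted counts and expected events by category move."""

    strategy: str
    table: pd.DataFrame  # category_before, category_after, count, expected_events
    screened: float
    already_treated: float
    up_mover_count: float  # crossing the treatment threshold upward
    down_mover_count: float
    up_mover_events: float
    down_mover_events: float
    baseline_treated_events: float  # events among those treated pre-reassessment
    total: float


@dataclass
class ImpactResult:
    strategy: str
    screened: float
    reclassified_up: float
    reclassified_down: float
    up_mover_events: float
    down_mover_events: float
    events_prevented_unrounded: float
    events_prevented: int
    nns: int | None
    rule: TreatmentRule = field(repr=False, default=TreatmentRule())


def standardize_population(
    structure: pd.DataFrame,
    cohort: pd.DataFrame,
    total: int | None = None,
) -> pd.DataFrame:
    """Attach standardization weights so cell weights match the structure.

    Every cohort member in an (age band x sex) cell receives weight
    ``cell count / cell cohort size``; the weights then sum to the structure's
    total (rescaled to ``total`` if given).  Raises if a structure cell has no
    cohort representatives.
    """
    out = cohort.copy()
    edges = np.unique(np.concatenate([
        structure["age_lo"].to_numpy(dtype=float),
        structure["age_hi"].to_numpy(dtype=float)]))
    band = assign_age_band(out["age"].to_numpy(), edges)
    out["_age_lo"] = edges[band]
    counts = structure.set_index(["age_lo", "sex"])["count"]
    scale = 1.0 if total is None else total / counts.sum()
    weights = np.zeros(len(out))
    for (lo, sex), count in counts.items():
        m = (out["_age_lo"].to_numpy() == lo) & (out["sex"].to_numpy() == sex)
        if count > 0 and not m.any():
            raise ValueError(f"no cohort members in structure cell ({lo}, {sex!r})")
        if m.any():
            weights[m] = count * scale / m.sum()
    out["weight"] = weights
    return out.drop(columns=["_age_lo"])


def apply_strategy(
    population: pd.DataFrame,
    strategy: ScreeningStrategy,
    rule: TreatmentRule = TreatmentRule(),
    scheme: RiskCategoryScheme = NICE,
    risk_old_col: str = "risk_old",
    risk_new_col: str = "risk_new",
    event_prob_col: str | None = None,
) -> ReclassificationFlows:
    """Tally reclassification flows for one screening strategy.

    Individuals meeting the unconditional-treatment criteria (diabetes or
    high LDL) are treated first and never reassessed.  ``conventional_only``
    reassesses nobody; ``targeted_prs`` reassesses the targeting band of the
    old risk; ``blanket_prs`` reassesses the whole remaining pool.  Expected
    events use ``event_prob_col`` (the new-model risk by default, falling
    back to the old risk where no reassessment happened).
    """
    w = population["weight"].to_numpy(dtype=float) if "weight" in population \
        else np.ones(len(population))
    risk_old = population[risk_old_col].to_numpy(dtype=float)
    unconditional = (
        population["diabetes"].to_numpy(dtype=bool)
        | (population["ldl"].to_numpy(dtype=float) >= rule.ldl_threshold))
    pool = ~unconditional

    if strategy.name == "conventional_only":
        reassessed = np.zeros(len(population), dtype=bool)
    elif strategy.name == "blanket_prs":
        reassessed = pool
    else:
        lo, hi = strategy.band
        reassessed = pool & (risk_old >= lo) & (risk_old < hi)

    if reassessed.any():
        if risk_new_col not in population:
            raise ValueError(f"reassessment requires column {risk_new_col!r}")
        risk_new = population[risk_new_col].to_numpy(dtype=float)
        if np.isnan(risk_new[reassessed]).any():
            raise ValueError("missing reassessed risks")
    else:
        risk_new = risk_old
    effective = np.where(reassessed, risk_new, risk_old)

    if event_prob_col is not None:
        event_prob = population[event_prob_col].to_numpy(dtype=float)
    else:
        event_prob = effective

    cat_before = categorize(risk_old, scheme)
    cat_after = categorize(effective, scheme)

    # flows are tallied over the screened set
    if strategy.name == "conventional_only":
        screened_mask = np.zeros(len(population), dtype=bool)
    elif strategy.name == "blanket_prs":
        screened_mask = np.ones(len(population), dtype=bool)
    else:
        screened_mask = reassessed

    labels = scheme.labels
    rows = []
    for cb in range(len(labels)):
        for ca in range(len(labels)):
            m = screened_mask & (cat_before == cb) & (cat_after == ca)
            if not m.any() and cb != ca:
                continue
            rows.append((labels[cb], labels[ca],
                         float(w[m].sum()), float((w * event_prob)[m].sum())))
    table = pd.DataFrame(rows, columns=["category_before", "category_after",
                                        "count", "expected_events"])

    up = reassessed & (risk_old < rule.threshold) & (effective >= rule.threshold)
    down = reassessed & (risk_old >= rule.threshold) & (effective < rule.threshold)
    treated_before = unconditional | (risk_old >= rule.threshold)
    return ReclassificationFlows(
        strategy=strategy.name,
        table=table,
        screened=float(w[screened_mask].sum()),
        already_treated=float(w[unconditional].sum()),
        up_mover_count=float(w[up].sum()),
        down_mover_count=float(w[down].sum()),
        up_mover_events=float((w * event_prob)[up].sum()),
        down_mover_events=float((w * event_prob)[down].sum()),
        baseline_treated_events=float((w * event_prob)[treated_before].sum()),
        total=float(w.sum()),
    )


def events_prevented(up_mover_events: float, down_mover_events: float = 0.0,
                     rrr: float = 0.20) -> tuple[float, int]:
    """Events prevented by treating net up-movers, unrounded and as reported.

    ``unrounded = rrr * (up - down)``; the reported figure rounds up to the
    next whole event.  A negative net (reassessment de-treats more expected
    events than it treats) is allowed and reported as harm.
    """
    unrounded = rrr * (up_mover_events - down_mover_events)
    return unrounded, int(math.ceil(unrounded))


def number_needed_to_screen(screened: float, prevented_unrounded: float) -> int | None:
    """Screened individuals per event prevented (nearest integer).

    Returns None when no events are prevented — the quantity is undefined,
    not infinite.
    """
    if prevented_unrounded <= 0:
        return None
    return int(math.floor(screened / prevented_unrounded + 0.5))


def percent_additional_high_risk_events(up_mover_events: float,
                                        baseline_high_risk_events: float) -> float:
    """Up-mover events as a percent of events already at high risk (1 d.p.)."""
    if baseline_high_risk_events <= 0:
        raise ValueError("baseline high-risk events must be positive")
    return round(100.0 * up_mover_events / baseline_high_risk_events, 1)


def run_impact(
    population: pd.DataFrame,
    strategy: ScreeningStrategy,
    rule: TreatmentRule = TreatmentRule(),
    scheme: RiskCategoryScheme = NICE,
    **kwargs,
) -> tuple[ImpactResult, ReclassificationFlows]:
    """Apply a strategy and summarise prevented events and NNS."""
    flows = apply_strategy(population, strategy, rule, scheme, **kwargs)
    unrounded, reported = events_prevented(
        flows.up_mover_events, flows.down_mover_events, rule.rrr)
    nns = number_needed_to_screen(flows.screened, unrounded) \
        if flows.screened > 0 else None
    result = ImpactResult(
        strategy=strategy.name,
        screened=flows.screened,
        reclassified_up=flows.up_mover_count,
        reclassified_down=flows.down_mover_count,
        up_mover_events=flows.up_mover_events,
        down_mover_events=flows.down_mover_events,
        events_prevented_unrounded=unrounded,
        events_prevented=reported,
        nns=nns,
        rule=rule,
    )
    return result, flows
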