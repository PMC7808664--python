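"""Tests of discrimination and calibration metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from prsimpact.evaluation import (harrells_c, delta_c_jackknife,
                                  internal_external_validate,
                                  pooled_concordance, calibration_assess,
                                  cross_validated_risks, km_risk)
from prsimpact.cox import fit_cox


def brute_force_c(score, time, event, codes=None):
    """Exhaustive pair enumeration: comparable if the earlier time is an event."""
    n = len(score)
    codes = np.zeros(n) if codes is None else np.asarray(codes)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j or codes[i] != codes[j]:
                continue
            if time[i] < time[j] and event[i]:
                den += 1
                if score[i] > score[j]:
                    num += 1
                elif score[i] == score[j]:
                    num += 0.5
    return num / den


def test_perfect_ranking_gives_c_one():
    res = harrells_c([4, 3, 2, 1], [1, 2, 3, 4], [1, 1, 1, 1])
    assert res.c_index == 1.0
    assert res.n_comparable_pairs == 6


def test_c_matches_exhaustive_enumeration_toy():
    res = harrells_c([3, 4, 1, 2], [1, 2, 3, 4], [1, 1, 1, 1])
    assert res.c_index == pytest.approx(4 / 6)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_c_matches_brute_force_random_small(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(8, 30)
    time = rng.exponential(5, n).round(1)  # induce some ties in time
    event = rng.random(n) < 0.7
    score = rng.normal(size=n).round(1)  # and ties in score
    codes = rng.integers(0, 3, n)
    res = harrells_c(score, time, event,
                     strata=pd.DataFrame({"g": codes}))
    assert res.c_index == pytest.approx(
        brute_force_c(score, time, event, codes), abs=1e-12)


def test_c_matches_lifelines_on_tie_free_data(rng):
    from lifelines.utils import concordance_index
    n = 300
    time = rng.exponential(5, n)
    event = rng.random(n) < 0.6
    score = rng.normal(size=n)
    res = harrells_c(score, time, event)
    # lifelines concordance_index expects higher score = longer survival
    assert res.c_index == pytest.approx(
        concordance_index(time, -score, event), abs=1e-12)


@settings(derandomize=True, max_examples=25)
@given(st.integers(0, 10_000))
def test_c_antisymmetry_without_ties(seed):
    rng = np.random.default_rng(seed)
    n = 25
    time = rng.exponential(5, n)
    event = rng.random(n) < 0.7
    if not (event.sum() and n):
        return
    score = rng.normal(size=n)
    try:
        a = harrells_c(score, time, event).c_index
    except ValueError:
        return  # no comparable pairs
    b = harrells_c(-score, time, event).c_index
    assert a + b == pytest.approx(1.0, abs=1e-12)


def test_random_score_is_noninformative(small_cohort, rng):
    event = small_cohort.outcome.isin(("CHD", "stroke"))
    score = rng.normal(size=len(small_cohort))
    res = harrells_c(score, small_cohort.follow_up, event,
                     strata=small_cohort[["centre", "sex"]])
    assert abs(res.c_index - 0.5) < 3 * res.se


def test_delta_c_zero_for_identical_scores(small_cohort, rng):
    event = small_cohort.outcome.isin(("CHD", "stroke"))
    score = rng.normal(size=len(small_cohort))
    res = delta_c_jackknife(score, score, small_cohort.follow_up, event)
    assert res.delta_c == 0.0
    assert res.ci_low <= 0.0 <= res.ci_high


def test_delta_c_null_augmentation_covers_zero(small_cohort):
    """Adding a pure-noise predictor should not move C beyond its CI."""
    event = small_cohort.outcome.isin(("CHD", "stroke"))
    base = fit_cox(small_cohort, ["age", "sbp"])
    rng = np.random.default_rng(1)
    noise = base.linear_predictor(small_cohort) + 1e-3 * rng.normal(
        size=len(small_cohort))
    res = delta_c_jackknife(base.linear_predictor(small_cohort), noise,
                            small_cohort.follow_up, event,
                            strata=small_cohort[["centre", "sex"]])
    assert res.ci_low <= 0.0 <= res.ci_high


def test_jackknife_se_close_to_bootstrap_se(rng):
    n = 200
    time = rng.exponential(6, n)
    event = rng.random(n) < 0.6
    score = -np.log(time) + rng.normal(size=n)
    res = harrells_c(score, time, event)

    boots = []
    for _ in range(2000):
        idx = rng.integers(0, n, n)
        try:
            boots.append(harrells_c(score[idx], time[idx], event[idx]).c_index)
        except ValueError:
            continue
    boot_se = np.std(boots)
    assert abs(res.se - boot_se) / boot_se < 0.25


def test_pooled_concordance_hand_weighted():
    assert pooled_concordance([0.7, 0.8], [20, 80]) == pytest.approx(0.78)
    assert pooled_concordance([0.6, 0.8], [50, 50]) == pytest.approx(0.7)
    assert pooled_concordance([0.66], [10]) == pytest.approx(0.66)


def test_internal_external_validation_pooled_within_range(small_cohort):
    res = internal_external_validate(
        small_cohort, ["age", "sbp", "prs_chd"], ("CHD", "stroke"),
        scheme="centre")
    per = res.per_subset
    assert len(per) == small_cohort.centre.nunique()
    assert per.c_index.min() <= res.pooled.c_index <= per.c_index.max()
    hand = (per.c_index * per.events).sum() / per.events.sum()
    assert res.pooled.c_index == pytest.approx(hand, abs=1e-12)

    res_k = internal_external_validate(
        small_cohort, ["age", "sbp", "prs_chd"], ("CHD", "stroke"),
        scheme="kfold", n_folds=5, seed=2)
    assert 0.5 < res_k.pooled.c_index < 1.0


# ---------------------------------------------------------------------------
# calibration


def _exact_groups(probs, per_group=200, horizon=10.0):
    """Uncensored groups whose event fraction equals the prediction exactly."""
    pred, time, event = [], [], []
    for p in probs:
        d = int(round(p * per_group))
        pred += [p] * per_group
        event += [True] * d + [False] * (per_group - d)
        time += [horizon / 2] * d + [horizon * 2] * (per_group - d)
    return np.array(pred), np.array(time), np.array(event)


def test_perfect_calibration():
    probs = np.linspace(0.05, 0.5, 10)
    pred, time, event = _exact_groups(probs)
    rep = calibration_assess(pred, time, event, horizon=10.0)
    assert rep.slope == pytest.approx(1.0, abs=1e-9)
    assert rep.rmse == pytest.approx(0.0, abs=1e-12)
    assert rep.gnd_statistic == pytest.approx(0.0, abs=1e-12)
    assert rep.gnd_p == pytest.approx(1.0)


def test_doubled_predictions_halve_the_slope():
    probs = np.linspace(0.05, 0.4, 8)  # multiples of 1/200: exact group counts
    pred, time, event = _exact_groups(probs)
    rep = calibration_assess(np.clip(2 * pred, 0, 1), time, event, horizon=10.0,
                             n_groups=len(probs))
    assert rep.slope == pytest.approx(0.5, abs=1e-9)
    assert rep.rmse > 0


def test_gnd_reduces_to_binomial_chi_square_without_censoring(rng):
    n = 2000
    pred = rng.uniform(0.02, 0.5, n)
    event = rng.random(n) < pred
    time = np.where(event, 5.0, 20.0)
    rep = calibration_assess(pred, time, event, horizon=10.0)

    # oracle: group by the same deciles, use binomial proportions directly
    groups = pd.qcut(pd.Series(pred).rank(method="first"), 10, labels=False)
    stat = 0.0
    for g in range(10):
        m = (groups == g).to_numpy()
        phat = event[m].mean()
        stat += (phat - pred[m].mean()) ** 2 / (phat * (1 - phat) / m.sum())
    assert rep.gnd_statistic == pytest.approx(stat, rel=1e-9)
    assert rep.gnd_df == 9


def test_gnd_pvalues_uniform_under_correct_model(rng):
    pvals = []
    for _ in range(60):
        n = 3000  # large groups: the chi-square approximation needs them
        pred = rng.uniform(0.05, 0.6, n)
        event = rng.random(n) < pred
        time = np.where(event, 4.0, 15.0)
        pvals.append(calibration_assess(pred, time, event, 10.0).gnd_p)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_empty_event_group_merged_with_warning(rng):
    pred = np.concatenate([np.full(200, 0.001), rng.uniform(0.2, 0.6, 400)])
    event = rng.random(600) < pred
    event[:200] = False  # lowest group: no events at all
    time = np.where(event, 3.0, 20.0)
    with pytest.warns(UserWarning, match="merged"):
        rep = calibration_assess(pred, time, event, 10.0, n_groups=3)
    assert rep.merged_groups >= 1
    assert np.isfinite(rep.gnd_statistic)


def test_km_risk_matches_plain_fraction_without_censoring(rng):
    event = rng.random(500) < 0.3
    time = np.where(event, 5.0, 20.0)
    risk, var = km_risk(time, event, 10.0)
    p = event.mean()
    assert risk == pytest.approx(p, abs=1e-12)
    assert var == pytest.approx(p * (1 - p) / 500, rel=1e-9)


def test_cross_validated_risks_complete_and_bounded(small_cohort):
    risks = cross_validated_risks(small_cohort, ["age", "sbp", "prs_chd"],
                                  ("CHD", "stroke"), horizon=10.0,
                                  n_folds=4, seed=0)
    assert np.isfinite(risks).all()
    assert ((risks >= 0) & (risks <= 1)).all()
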