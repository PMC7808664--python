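"""Tests of the stratified Cox engine, risk prediction and competing risks."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from prsimpact.cox import (RiskModel, fit_cox, predict_risk,
                           cumulative_incidence_competing, partial_lr_test,
                           FitError)
from prsimpact.synthetic import GeneratorConfig, generate_cohort


def _toy_frame(x, times=None, events=None):
    n = len(x)
    return pd.DataFrame({
        "follow_up": times if times is not None else np.arange(1.0, n + 1.0),
        "outcome": ["CHD" if (events is None or e) else "none"
                    for e in (events if events is not None else [1] * n)],
        "x": np.asarray(x, dtype=float),
    })


def test_partial_likelihood_maximizer_matches_grid_oracle():
    """4-subject fit equals the maximizer of the hand-enumerated likelihood."""
    df = _toy_frame([1.0, 0.0, 0.0, 1.0])

    def neg_log_pl(beta):
        # risk sets enumerated by hand: {1,0,0,1}, {0,0,1}, {0,1}, {1}
        eb = np.exp(beta)
        return -(np.log(eb / (2 * eb + 2)) + np.log(1 / (2 + eb))
                 + np.log(1 / (1 + eb)))

    oracle = optimize.minimize_scalar(neg_log_pl, bounds=(-5, 5),
                                      method="bounded",
                                      options={"xatol": 1e-10}).x
    model = fit_cox(df, ["x"], strata=())
    assert model.coefficients["x"] == pytest.approx(oracle, abs=1e-4)
    assert model.log_likelihood == pytest.approx(-neg_log_pl(oracle), abs=1e-6)


def test_constant_covariate_handled_gracefully():
    df = _toy_frame([2.0, 2.0, 2.0, 2.0])
    with pytest.warns(UserWarning, match="constant"):
        model = fit_cox(df, ["x"], strata=())
    assert model.coefficients["x"] == 0.0
    assert not np.isfinite(model.standard_errors["x"])
    risks = predict_risk(model, df, 3.0)
    assert ((0 <= risks.risk) & (risks.risk <= 1)).all()


def test_hand_set_baseline_risk_arithmetic():
    """S0(10)=0.95, beta=ln 2, x - mean = 1 gives risk 1 - 0.95^2."""
    model = RiskModel.from_baseline(
        times=[10.0], cumhaz=[-np.log(0.95)],
        coefficients={"x": np.log(2.0)}, predictor_means={"x": 0.0})
    rec = pd.DataFrame({"x": [1.0]})
    risk = predict_risk(model, rec, 10.0)["risk"].iloc[0]
    assert risk == pytest.approx(1 - 0.95 ** 2, abs=1e-12)


def test_centering_identity_and_monotonicity(small_cohort):
    model = fit_cox(small_cohort, ["age", "sbp", "prs_chd"])
    stratum = small_cohort.iloc[[0]].copy()
    for p in ["age", "sbp", "prs_chd"]:
        stratum[p] = model.predictor_means[p]
    risk = predict_risk(model, stratum, 10.0)["risk"].iloc[0]
    key = tuple(str(v) for v in stratum[["centre", "sex"]].iloc[0])
    assert risk == pytest.approx(-np.expm1(-model.cumhaz_at(key, 10.0)), abs=1e-12)

    # within one stratum, higher linear predictor means higher risk
    sub = small_cohort[(small_cohort.centre == small_cohort.centre.iloc[0])
                       & (small_cohort.sex == "F")].head(50)
    out = predict_risk(model, sub, 10.0)
    order = np.argsort(out.lp.to_numpy())
    assert (np.diff(out.risk.to_numpy()[order]) >= 0).all()


def test_affine_rescaling_invariance(small_cohort):
    df = small_cohort.head(3000)
    m1 = fit_cox(df, ["sbp"], strata=("sex",))
    df2 = df.copy()
    df2["sbp"] = df2["sbp"] * 0.1 + 50.0
    m2 = fit_cox(df2, ["sbp"], strata=("sex",))
    assert m2.coefficients["sbp"] * 0.1 == pytest.approx(
        m1.coefficients["sbp"], abs=1e-6)


def test_single_stratum_equals_unstratified(small_cohort):
    df = small_cohort.head(2000).copy()
    df["one"] = "all"
    m_strat = fit_cox(df, ["age", "prs_chd"], strata=("one",))
    m_plain = fit_cox(df, ["age", "prs_chd"], strata=())
    assert np.allclose(m_strat.coefficients, m_plain.coefficients, atol=1e-8)
    assert m_strat.log_likelihood == pytest.approx(m_plain.log_likelihood, abs=1e-8)


def test_breslow_baseline_steps_at_event_times(small_cohort):
    df = small_cohort.head(2000)
    model = fit_cox(df, ["age"], strata=("sex",))
    for key, series in model.baseline_cumhaz.items():
        vals = series.to_numpy()
        assert (np.diff(vals) >= -1e-15).all()
        sub = df[df.sex == key[0]]
        event_times = set(sub.loc[sub.outcome.isin(model.event_labels),
                                  "follow_up"].round(9))
        jump_times = series.index.to_numpy()[
            np.diff(np.concatenate([[0.0], vals])) > 0]
        assert set(np.round(jump_times, 9)) <= event_times


def test_horizon_beyond_support_raises(small_cohort):
    model = fit_cox(small_cohort, ["age"])
    with pytest.raises(ValueError, match="exceeds supported"):
        predict_risk(model, small_cohort.head(5), 25.0)


def test_missing_predictor_and_no_events_rejected(small_cohort):
    df = small_cohort.head(100).copy()
    df.loc[df.index[0], "age"] = np.nan
    with pytest.raises(ValueError, match="missing"):
        fit_cox(df, ["age"])
    ok = small_cohort.head(100).copy()
    ok["outcome"] = "none"
    with pytest.raises(FitError):
        fit_cox(ok, ["age"])


# ---------------------------------------------------------------------------
# competing risks


def test_cif_reduces_to_naive_risk_without_competing_hazard():
    grid = np.linspace(0.01, 10.0, 500)
    m_cvd = RiskModel.from_baseline(grid, 0.02 * grid,
                                    coefficients={"x": 0.5},
                                    predictor_means={"x": 0.0})
    m_null = RiskModel.from_baseline(grid, np.zeros_like(grid),
                                     coefficients={"x": 0.0},
                                     predictor_means={"x": 0.0})
    rec = pd.DataFrame({"x": [-1.0, 0.0, 1.0]})
    cif = cumulative_incidence_competing(m_cvd, m_null, rec, 10.0)
    naive = predict_risk(m_cvd, rec, 10.0)["risk"]
    assert np.allclose(cif.cif_cvd, naive, atol=2e-4)
    assert np.allclose(cif.cif_death, 0.0)


def test_cif_constant_hazards_closed_form():
    """lambda1 = lambda2 = 0.01: CIF1(10) = 0.5 * (1 - e^-0.2) ~ 0.0906."""
    grid = np.linspace(0.005, 10.0, 2000)
    m1 = RiskModel.from_baseline(grid, 0.01 * grid)
    m2 = RiskModel.from_baseline(grid, 0.01 * grid)
    rec = pd.DataFrame({"dummy": [0.0]})
    cif = cumulative_incidence_competing(m1, m2, rec, 10.0)
    lam = 0.01
    expected = (lam / (2 * lam)) * (1 - np.exp(-2 * lam * 10.0))
    assert cif.cif_cvd.iloc[0] == pytest.approx(expected, abs=1e-3)
    assert cif.cif_death.iloc[0] == pytest.approx(expected, abs=1e-3)


def test_cif_conservation_on_fitted_cohort(small_cohort):
    df = small_cohort.head(3000)
    m_cvd = fit_cox(df, ["age", "prs_chd"])
    m_death = fit_cox(df, ["age", "smoker"], event_labels=("nonCVD_death",))
    cif = cumulative_incidence_competing(m_cvd, m_death, df.head(500), 10.0)
    total = cif[["cif_cvd", "cif_death", "surv"]].sum(axis=1)
    assert np.allclose(total, 1.0, atol=1e-10)
    assert (cif.cif_cvd >= 0).all() and (cif.cif_cvd <= 1).all()


def test_cif_mismatched_strata_rejected(small_cohort):
    df = small_cohort.head(2000)
    m_cvd = fit_cox(df, ["age"], strata=("sex",))
    m_death = fit_cox(df, ["age"], strata=("centre",),
                      event_labels=("nonCVD_death",))
    with pytest.raises(ValueError, match="strata"):
        cumulative_incidence_competing(m_cvd, m_death, df.head(5), 5.0)


# ---------------------------------------------------------------------------
# partial likelihood-ratio test


def test_lr_test_identical_models_is_null(small_cohort):
    m = fit_cox(small_cohort.head(2000), ["age", "sbp"])
    res = partial_lr_test(m, m)
    assert res.statistic == pytest.approx(0.0, abs=1e-10)
    assert res.df == 0 and res.p_value == 1.0


def test_lr_test_statistic_matches_independent_loglik_recomputation():
    """Recompute both Efron log partial likelihoods from scratch."""
    df = generate_cohort(GeneratorConfig(n_individuals=400, seed=21, n_centres=2))
    full = fit_cox(df, ["age", "prs_chd"], strata=("sex",))
    red = fit_cox(df, ["age"], strata=("sex",))

    def efron_loglik(frame, predictors, coefs, means):
        total = 0.0
        for _, grp in frame.groupby("sex"):
            t = grp.follow_up.to_numpy()
            e = grp.outcome.isin(("CHD", "stroke")).to_numpy()
            lp = sum(c * (grp[p].to_numpy() - means[p])
                     for p, c in zip(predictors, coefs))
            w = np.exp(lp)
            for u in np.unique(t[e]):
                tied = e & (t == u)
                at_risk = t >= u
                d = tied.sum()
                total += lp[tied].sum()
                for r in range(d):
                    total -= np.log(w[at_risk].sum() - (r / d) * w[tied].sum())
        return total

    ll_full = efron_loglik(df, full.predictors, full.coefficients.to_numpy(),
                           full.predictor_means)
    ll_red = efron_loglik(df, red.predictors, red.coefficients.to_numpy(),
                          red.predictor_means)
    res = partial_lr_test(full, red)
    assert res.statistic == pytest.approx(2 * (ll_full - ll_red), abs=1e-5)
    assert res.df == 1

    with pytest.raises(ValueError, match="subset"):
        partial_lr_test(red, full)


def test_lr_test_null_pvalues_roughly_uniform():
    """Adding a pure-noise predictor yields approximately uniform p-values."""
    rng = np.random.default_rng(0)
    pvals = []
    for rep in range(120):
        n = 120
        df = pd.DataFrame({
            "follow_up": rng.exponential(8.0, n).clip(0.01, None),
            "x": rng.normal(size=n),
            "noise": rng.normal(size=n),
        })
        df["outcome"] = np.where(df.follow_up < 10.0, "CHD", "none")
        df["follow_up"] = df.follow_up.clip(upper=10.0)
        full = fit_cox(df, ["x", "noise"], strata=())
        red = fit_cox(df, ["x"], strata=())
        pvals.append(partial_lr_test(full, red).p_value)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01
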