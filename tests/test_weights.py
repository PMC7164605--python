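"""Stabilized treatment and censoring weights, and the balance diagnostics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import loadsnmm as L
from loadsnmm import weights as W
from loadsnmm._fit import FitError

from conftest import make_weekly_panel


# ---------------------------------------------------------------------------
# treatment mean models

def test_numerator_excludes_confounders(confounded_panel):
    models = W.fit_treatment_models(confounded_panel)
    for banned in ("rating", "competed_prev_week", "prior_long_timeloss"):
        assert not any(banned in c for c in models.numerator.columns)
    assert any("cr(rating" in c for c in models.denominator.columns)


def test_ar_coefficient_recovered():
    """Weekly load generated as an AR(1) around a common mean: the fitted
    lag coefficient must recover the truth on average."""
    rho = 0.6
    ests = []
    rng = np.random.default_rng(77)
    for rep in range(60):
        rows, g = [], 50.0
        for pid in range(6):
            g, cum = 50.0, 8000.0
            for w in range(1, 41):
                g = 50.0 + rho * (g - 50.0) + rng.normal(0, 6)
                cum += g
                rows.append(dict(player=f"P{pid}", week=w, date="2012-01-02",
                                 games=g, cum=cum, prev=int(w > 1),
                                 rating=2300 + rng.normal(0, 50)))
        # dates irrelevant for the mean model; make them valid and increasing
        p = make_weekly_panel(rows)
        p["calendar_date"] = pd.date_range("2012-01-02", periods=len(p), freq="D").date
        models = W.fit_treatment_models(p)
        i = models.denominator.columns.index("g_lag")
        ests.append(models.denominator.beta[i])
    se = np.std(ests) / np.sqrt(len(ests))
    assert abs(np.mean(ests) - rho) < 2 * se + 0.02


def test_constant_games_degenerate_scale():
    rng = np.random.default_rng(5)
    rows = [dict(player=p, week=w, date=f"2012-{w:02d}-02", games=50,
                 cum=8000 + 50 * w, rating=2300 + rng.normal(0, 40))
            for p in "AB" for w in range(1, 9)]
    p = make_weekly_panel(rows)
    with pytest.raises(FitError, match="degenerate residual scale"):
        W.fit_treatment_models(p)


# ---------------------------------------------------------------------------
# stabilized weights

def _manual_models(panel, m_num, m_den, s_num, s_den):
    n = len(panel)
    num = W.LinearMeanModel(np.zeros(1), ["const"], s_num, np.full(n, m_num))
    den = W.LinearMeanModel(np.zeros(1), ["const"], s_den, np.full(n, m_den))
    return W.TreatmentModelPair(denominator=den, numerator=num)


def two_week_player(g2):
    rows = [dict(player="A", week=1, date="2012-01-02", games=10, cum=8010),
            dict(player="A", week=2, date="2012-01-09", games=g2, cum=8010 + g2)]
    return make_weekly_panel(rows)


def test_identical_models_give_unit_weights(confounded_panel):
    models = W.fit_treatment_models(confounded_panel)
    same = W.TreatmentModelPair(denominator=models.denominator,
                                numerator=models.denominator)
    sw, _ = W.compute_stabilized_weights(confounded_panel, same)
    assert np.allclose(sw, 1.0, atol=1e-12)


def test_single_week_density_ratio():
    # g=10, m_hat=10, sd=2 vs m0_hat=12, sd0=2 -> phi(-1)/phi(0) = exp(-0.5)
    p = two_week_player(10)
    models = _manual_models(p, m_num=12.0, m_den=10.0, s_num=2.0, s_den=2.0)
    sw, _ = W.compute_stabilized_weights(p, models)
    assert sw.iloc[0] == pytest.approx(1.0)  # first week: empty history
    assert sw.iloc[1] == pytest.approx(np.exp(-0.5), rel=1e-12)


def test_cumulative_product_of_reciprocal_factors_is_one():
    rows = [dict(player="A", week=w, date=f"2012-01-{2 + 7 * (w - 1):02d}",
                 games=g, cum=8000 + 10 * w)
            for w, g in [(1, 10), (2, 10), (3, 14)]]
    p = make_weekly_panel(rows)
    # week-2 factor 0.5, week-3 factor 2.0 -> cumulative product 1
    off = 2.0 * np.sqrt(2.0 * np.log(2.0))
    num = W.LinearMeanModel(np.zeros(1), ["c"], 2.0, np.array([10.0, 10.0 - off, 14.0]))
    den = W.LinearMeanModel(np.zeros(1), ["c"], 2.0, np.array([10.0, 10.0, 14.0 - off]))
    sw, _ = W.compute_stabilized_weights(p, W.TreatmentModelPair(den, num))
    assert sw.iloc[1] == pytest.approx(0.5, rel=1e-12)
    assert sw.iloc[2] == pytest.approx(1.0, rel=1e-12)


def test_brute_force_oracle_three_players(tiny_panel):
    """Cumulative products must match a record-by-record direct computation."""
    models = W.fit_treatment_models(tiny_panel)
    sw, _ = W.compute_stabilized_weights(tiny_panel, models)
    cmods = W.fit_censoring_models(tiny_panel)
    cw = W.compute_censoring_weights(tiny_panel, cmods)

    expected_sw, expected_cw = {}, {}
    for pid, grp in tiny_panel.groupby("player_id"):
        acc_s, acc_c = 1.0, 1.0
        for j, (i, row) in enumerate(grp.iterrows()):
            if j > 0:
                num = stats.norm.pdf(row["games"], models.numerator.fitted[i],
                                     models.numerator.resid_sd)
                den = stats.norm.pdf(row["games"], models.denominator.fitted[i],
                                     models.denominator.resid_sd)
                acc_s *= num / den
                acc_c *= (cmods.numerator.prob_uncensored[i]
                          / cmods.denominator.prob_uncensored[i])
            expected_sw[i] = acc_s
            expected_cw[i] = acc_c
    for i in tiny_panel.index:
        assert sw.loc[i] == pytest.approx(expected_sw[i], abs=1e-12, rel=1e-12)
        assert cw.loc[i] == pytest.approx(expected_cw[i], abs=1e-12, rel=1e-12)


def test_weight_mean_near_one_per_week(confounded_panel):
    """Correctly specified treatment model: per-week mean stabilized weight
    within 1 +/- 0.15 for weeks with n >= 200."""
    models = W.fit_treatment_models(confounded_panel)
    sw, _ = W.compute_stabilized_weights(confounded_panel, models)
    df = pd.DataFrame({"week": confounded_panel["week_index"], "sw": sw})
    per_week = df.groupby("week").agg(m=("sw", "mean"), n=("sw", "size"))
    big = per_week[per_week["n"] >= 200]
    assert len(big) > 50
    assert (np.abs(big["m"] - 1.0) < 0.15).mean() == 1.0


def test_no_confounding_weights_concentrated():
    cfg = dataclasses.replace(L.scenario_preset("confounded"), seed=3,
                              ability_on_load=0.0, ability_on_hazard=0.0)
    p = L.simulate_cohort(cfg)
    models = W.fit_treatment_models(p)
    sw, _ = W.compute_stabilized_weights(p, models)
    q5, q95 = np.quantile(sw, [0.05, 0.95])
    assert 0.5 <= q5 and q95 <= 2.0


# ---------------------------------------------------------------------------
# censoring weights

def test_no_censoring_gives_unit_cw(confounded_panel):
    p = confounded_panel.copy()
    p["censored"] = 0
    cmods = W.fit_censoring_models(p)
    cw = W.compute_censoring_weights(p, cmods)
    assert np.allclose(cw, 1.0)


def test_cw_single_week_factor():
    p = two_week_player(12)
    num = W.LogisticModel(np.zeros(1), ["c"], np.array([1.0, 0.99]))
    den = W.LogisticModel(np.zeros(1), ["c"], np.array([1.0, 0.90]))
    cw = W.compute_censoring_weights(p, W.CensoringModelPair(den, num))
    assert cw.iloc[0] == pytest.approx(1.0)
    assert cw.iloc[1] == pytest.approx(0.99 / 0.90, rel=1e-12)


def test_cw_zero_denominator_probability_errors():
    p = two_week_player(12)
    num = W.LogisticModel(np.zeros(1), ["c"], np.array([1.0, 0.99]))
    den = W.LogisticModel(np.zeros(1), ["c"], np.array([1.0, 0.0]))
    with pytest.raises(FitError, match="positivity"):
        W.compute_censoring_weights(p, W.CensoringModelPair(den, num))


# ---------------------------------------------------------------------------
# combined weights

def test_combine_identity_and_positivity(confounded_panel):
    models = W.fit_treatment_models(confounded_panel)
    sw, nf = W.compute_stabilized_weights(confounded_panel, models)
    cmods = W.fit_censoring_models(confounded_panel)
    cw = W.compute_censoring_weights(confounded_panel, cmods)
    ws = W.combine_weights(sw, cw, confounded_panel, nf)
    assert np.allclose(ws.w, sw * cw)
    assert (ws.w > 0).all()
    assert len(ws.w) == len(confounded_panel)  # weighting never drops records


def test_combine_misaligned_errors(confounded_panel):
    sw = pd.Series(1.0, index=confounded_panel.index)
    cw = pd.Series(1.0, index=confounded_panel.index[::-1][:10])
    with pytest.raises(ValueError, match="misaligned"):
        W.combine_weights(sw, cw, confounded_panel)


def test_mean_log_weight_near_zero_early_weeks(confounded_panel):
    models = W.fit_treatment_models(confounded_panel)
    sw, nf = W.compute_stabilized_weights(confounded_panel, models)
    cmods = W.fit_censoring_models(confounded_panel)
    cw = W.compute_censoring_weights(confounded_panel, cmods)
    ws = W.combine_weights(sw, cw, confounded_panel, nf)
    s = ws.weekly_summary
    early = s[(s["n"] >= 200) & (s["week"] <= 10)]
    assert np.abs(early["mean_log_w"]).max() < 0.25


# ---------------------------------------------------------------------------
# PSB balance

def test_psb_constant_covariate_zero(confounded_panel):
    p = confounded_panel.copy()
    p["rating"] = 2300.0
    rep = W.compute_psb(p, covariates=("rating",))
    assert (rep["psb_unweighted"] == 0).all()
    assert rep["zero_sd"].all()


def test_psb_balanced_covariate_small(small_null_panel):
    rng = np.random.default_rng(0)
    p = small_null_panel.copy()
    p["noise"] = rng.normal(size=len(p))  # independent of load by construction
    rep = W.compute_psb(p, covariates=("noise",), min_records=20)
    assert rep["psb_unweighted"].mean() < 0.25


def test_psb_weighting_restores_rating_balance(confounded_panel):
    models = W.fit_treatment_models(confounded_panel)
    sw, nf = W.compute_stabilized_weights(confounded_panel, models)
    cmods = W.fit_censoring_models(confounded_panel)
    cw = W.compute_censoring_weights(confounded_panel, cmods)
    ws = W.combine_weights(sw, cw, confounded_panel, nf)
    rep = W.compute_psb(confounded_panel, ws, covariates=("rating",))
    big = rep[rep["n"] >= 200]
    early = big[big["week"] <= big["week"].median()]
    assert (early["psb_unweighted"] > 0.25).mean() > 0.5
    assert (big["psb_weighted"] < 0.25).mean() >= 0.8
    assert big["psb_weighted"].mean() < big["psb_unweighted"].mean()
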