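"""Effect and risk summaries from a fitted SNMM.

Hazard ratios are reported two ways: the *direct* contrast
exp((beta1 + beta2*age) * delta_g), the causal effect of extra load at a
fixed age, and the *vs-reference* contrast against the reference player (a
25-year-old with 10,000 games), which additionally carries the nuisance
age-residual term and so mixes causal and non-causal age-load association.
Absolute risks anchor the model's hazard ratios to an empirical baseline
rate at the reference player.  The power calculation reproduces the design
sample-size statement: a survival-analysis comparison of the top load
quartile of players against the rest under the study's size and rate
assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._fit import expit, logit
from .snmm import SNMMFit
from .synthetic import REF_AGE, REF_LOAD


@dataclass
class HRContrast:
    age: float
    g_from: float
    g_to: float
    hr: float
    ci_low: float | None
    ci_high: float | None
    contrast_kind: str


def _draw_ci(values: np.ndarray | None, level: float = 0.95):
    if values is None:
        return None, None
    lo = (1.0 - level) / 2.0
    return float(np.quantile(values, lo)), float(np.quantile(values, 1.0 - lo))


def hazard_ratio_direct(fit: SNMMFit, delta_g: float, age: float,
                        level: float = 0.95) -> HRContrast:
    """Hazard ratio for ``delta_g`` additional games from the causal-effect
    function mu alone: exp((beta1 + beta2*age) * delta_g).

    This is the load 'blip' contrast of the structural model.  For same-age
    comparisons that hold the moderator fixed (and hence shift the age
    residual), see :func:`hazard_ratio_fixed_age`; the two coincide when the
    moderator mean does not depend on load (alpha2 = 0).
    """
    hr = float(np.exp((fit.beta1 + fit.beta2 * age) * delta_g))
    draws = None
    if fit.bootstrap_draws is not None:
        d = fit.bootstrap_draws
        draws = np.exp((d["beta1"] + d["beta2"] * age).to_numpy() * delta_g)
    lo, hi = _draw_ci(draws, level)
    return HRContrast(age=age, g_from=0.0, g_to=delta_g, hr=hr,
                      ci_low=lo, ci_high=hi, contrast_kind="direct_fixed_age")


def hazard_ratio_fixed_age(fit: SNMMFit, delta_g: float, age: float,
                           level: float = 0.95) -> HRContrast:
    """Hazard ratio comparing same-age players whose cumulative loads differ
    by ``delta_g`` games: exp(delta_g * (beta1 + beta2*age - nu1*alpha2)).

    Invariant to the residualized-vs-raw-age parameterization; for naive
    (raw-age) fits it reduces to the direct contrast.
    """
    hr = float(np.exp(delta_g * fit.fixed_age_slope(age)))
    draws = None
    if fit.bootstrap_draws is not None:
        d = fit.bootstrap_draws
        draws = np.exp(delta_g * (d["beta1"] + d["beta2"] * age
                                  - d["nu1"] * d["alpha2"]).to_numpy())
    lo, hi = _draw_ci(draws, level)
    return HRContrast(age=age, g_from=0.0, g_to=delta_g, hr=hr,
                      ci_low=lo, ci_high=hi, contrast_kind="fixed_age")


def _log_hr_vs_reference(beta1, beta2, nu1, alpha1, alpha2, age, g, ref_age, ref_g):
    resid = (age - alpha1 - alpha2 * g) - (ref_age - alpha1 - alpha2 * ref_g)
    return beta1 * (g - ref_g) + beta2 * (age * g - ref_age * ref_g) + nu1 * resid


def hazard_ratio_vs_reference(fit: SNMMFit, age: float, g: float,
                              ref_age: float = REF_AGE, ref_g: float = REF_LOAD,
                              level: float = 0.95) -> HRContrast:
    """Full-model hazard ratio of (age, g) against the reference player,
    including the nuisance age-residual term."""
    if fit.moderator is None:
        raise ValueError("vs-reference contrast needs moderator coefficients "
                         "(naive fits have none)")
    m = fit.moderator
    hr = float(np.exp(_log_hr_vs_reference(
        fit.beta1, fit.beta2, fit.nu1, m.alpha1, m.alpha2, age, g, ref_age, ref_g)))
    draws = None
    if fit.bootstrap_draws is not None:
        d = fit.bootstrap_draws
        draws = np.exp(_log_hr_vs_reference(
            d["beta1"].to_numpy(), d["beta2"].to_numpy(), d["nu1"].to_numpy(),
            d["alpha1"].to_numpy(), d["alpha2"].to_numpy(), age, g, ref_age, ref_g))
    lo, hi = _draw_ci(draws, level)
    return HRContrast(age=age, g_from=ref_g, g_to=g, hr=hr,
                      ci_low=lo, ci_high=hi, contrast_kind="vs_reference")


def anchor_risk_empirical(panel: pd.DataFrame, ref_age: float = REF_AGE,
                          ref_g: float = REF_LOAD, age_tol: float = 0.5,
                          g_tol: float = 500.0) -> float:
    """Empirical weekly event rate near the reference player (age within
    ``age_tol`` years, load within ``g_tol`` games)."""
    m = ((panel["age_years"] - ref_age).abs() <= age_tol) \
        & ((panel["cum_games"] - ref_g).abs() <= g_tol)
    if m.sum() == 0:
        raise ValueError("no records near the reference player; widen the anchor window")
    return float(panel.loc[m, "timeloss_event"].mean())


def absolute_risk(fit: SNMMFit, age: float, g: float, anchor_risk: float,
                  ref_age: float = REF_AGE, ref_g: float = REF_LOAD,
                  level: float = 0.90):
    """Absolute weekly risk at (age, g), anchored at the reference player's
    baseline rate; band from the bootstrap draws of the same functional."""
    if not (0.0 < anchor_risk < 1.0):
        raise ValueError("anchor_risk must be in (0, 1)")
    c = hazard_ratio_vs_reference(fit, age, g, ref_age, ref_g)
    risk = float(expit(logit(anchor_risk) + np.log(c.hr)))
    lo = hi = None
    if fit.bootstrap_draws is not None:
        d = fit.bootstrap_draws
        draws = expit(logit(anchor_risk) + _log_hr_vs_reference(
            d["beta1"].to_numpy(), d["beta2"].to_numpy(), d["nu1"].to_numpy(),
            d["alpha1"].to_numpy(), d["alpha2"].to_numpy(), age, g, ref_age, ref_g))
        lo, hi = _draw_ci(draws, level)
    return risk, lo, hi


def risk_reduction(fit: SNMMFit, age: float, g: float, anchor_risk: float,
                   deltas=(1000.0, 5000.0)) -> pd.DataFrame:
    """Absolute risk differences risk(age, g) - risk(age, g - delta) for
    counterfactual load reductions."""
    deltas = list(deltas)
    if g - max(deltas) <= 0:
        raise ValueError(f"counterfactual load g - {max(deltas)} is not positive")
    base, _, _ = absolute_risk(fit, age, g, anchor_risk)
    rows = []
    for d in deltas:
        cf, _, _ = absolute_risk(fit, age, g - d, anchor_risk)
        rows.append((d, base, cf, base - cf))
    return pd.DataFrame(rows, columns=["delta_games", "risk", "risk_reduced_load",
                                       "risk_reduction"])


def power_simulation(
    n_players: int = 389,
    base_rate: float = 0.03,
    risk_increase: float = 0.20,
    alpha: float = 0.05,
    n_sims: int = 1000,
    seed: int = 0,
    total_weeks: float = 55_773.0,
    seasons_per_player: float = 1901.0 / 389.0,
) -> float:
    """Monte-Carlo power of a log-rank comparison of the top load quartile.

    Careers are simulated as player-seasons (the tennis calendar's natural
    survival unit): each player contributes ``seasons_per_player`` seasons on
    average (fixed allocation, as a design calculation assumes equal
    follow-up) whose competition-week counts are drawn so the cohort totals
    about ``total_weeks``.  The top 25% of players by total game load carry
    a ``risk_increase`` relative increase in the weekly event probability.
    Time to first event within each season is compared between the two
    groups with a log-rank test at level ``alpha``; the rejection proportion
    over ``n_sims`` simulations is returned.
    """
    from lifelines.statistics import logrank_test

    if n_sims < 1:
        raise ValueError("n_sims must be positive")
    rng = np.random.default_rng(seed)
    weeks_per_season = total_weeks / (n_players * seasons_per_player)
    # deterministic season allocation averaging seasons_per_player
    lo = int(np.floor(seasons_per_player))
    n_hi = int(round((seasons_per_player - lo) * n_players))
    base_seasons = np.array([lo + 1] * n_hi + [lo] * (n_players - n_hi))
    rej = 0
    for _ in range(n_sims):
        n_seasons = base_seasons
        # total load driven by each player's per-week game rate
        games_rate = rng.normal(50.0, 8.0, size=n_players)
        season_weeks = [np.maximum(rng.poisson(weeks_per_season, size=k), 4)
                        for k in n_seasons]
        total_load = np.array([sw.sum() for sw in season_weeks]) * games_rate
        top = total_load >= np.quantile(total_load, 0.75)

        durations, observed, groups = [], [], []
        for i in range(n_players):
            rate = base_rate * (1.0 + risk_increase) if top[i] else base_rate
            for wk in season_weeks[i]:
                t = rng.geometric(rate)
                if t <= wk:
                    durations.append(t)
                    observed.append(1)
                else:
                    durations.append(wk)
                    observed.append(0)
                groups.append(top[i])
        groups = np.asarray(groups)
        res = logrank_test(
            np.asarray(durations)[groups], np.asarray(durations)[~groups],
            event_observed_A=np.asarray(observed)[groups],
            event_observed_B=np.asarray(observed)[~groups],
        )
        rej += res.p_value < alpha
    return rej / n_sims


def table3_style(fits: dict, ages=(25, 27, 29), loads=None,
                 ref_age: float = REF_AGE, ref_g: float = REF_LOAD) -> pd.DataFrame:
    """Side-by-side hazard-ratio table across estimators.

    ``fits`` maps column labels (e.g. 'naive_unadjusted', 'snmm_adjusted') to
    SNMMFit objects; ``loads`` maps each age to its (low, high) load contrast
    (default: low quartile approx. and +3,000 games).
    """
    if loads is None:
        loads = {25: (10_000, 13_000), 27: (11_000, 14_000), 29: (14_000, 17_000)}
    rows = []
    for label, fit in fits.items():
        c = hazard_ratio_fixed_age(fit, 1000.0, ref_age)
        rows.append((label, "same_age", 1000.0, ref_age, c.hr, c.ci_low, c.ci_high))
        for age in ages:
            lo_g, hi_g = loads[age]
            if fit.moderator is not None:
                for g in (lo_g, hi_g):
                    c = hazard_ratio_vs_reference(fit, age, g, ref_age, ref_g)
                    rows.append((label, "vs_reference", g, age, c.hr, c.ci_low, c.ci_high))
            c = hazard_ratio_fixed_age(fit, hi_g - lo_g, age)
            rows.append((label, "fixed_age", hi_g - lo_g, age,
                         c.hr, c.ci_low, c.ci_high))
    return pd.DataFrame(rows, columns=["estimator", "contrast", "games", "age",
                                       "hr", "ci_low", "ci_high"])
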