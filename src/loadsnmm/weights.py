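"""Stabilized inverse-probability weights for a continuous weekly load exposure.

The treatment at competition week t is the week's game load g_it.  Its
conditional density given history is modelled as normal around a linear mean:
the denominator model conditions on the lagged load and the time-varying
confounders (back-to-back indicator, prior long time-loss, a natural cubic
spline in rating); the numerator model conditions only on lagged load and
lagged age.  The per-week stabilized factor is the ratio of the two fitted
normal densities at the observed load, and the weight at week t is the
cumulative product of factors from each player's baseline.  Censoring weights
take the same form with logistic models for remaining uncensored.  Mean
models are fitted with an independence working structure clustered on player
(point estimates identical to least squares); all inference downstream is by
cluster bootstrap.

Balance is summarized by the population standard bias (PSB) per
week-from-baseline: records are split at that week's median observed load and
the absolute difference in covariate means between the high- and low-load
halves is scaled by the pooled unweighted SD.  PSB <= 0.25 is taken as
adequate balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
from scipy import stats

from ._fit import FitError, drop_constant_columns, expit, irls_logit, wls

PSB_THRESHOLD = 0.25
DEFAULT_COVARIATES = ("rating", "competed_prev_week", "prior_long_timeloss", "games")
_WEEK_DAYS = 7.0 / 365.25


@dataclass
class LinearMeanModel:
    """A fitted linear mean model with residual scale."""

    beta: np.ndarray
    columns: list
    resid_sd: float
    fitted: np.ndarray
    clusters: str = "player_id"
    working: str = "independence"


@dataclass
class TreatmentModelPair:
    denominator: LinearMeanModel
    numerator: LinearMeanModel


@dataclass
class LogisticModel:
    beta: np.ndarray
    columns: list
    prob_uncensored: np.ndarray


@dataclass
class CensoringModelPair:
    denominator: LogisticModel
    numerator: LogisticModel


@dataclass
class WeightSet:
    sw: pd.Series
    cw: pd.Series
    w: pd.Series
    weekly_summary: pd.DataFrame
    n_floored: int = 0


def add_lags(panel: pd.DataFrame) -> pd.DataFrame:
    """Attach lagged load and lagged age within player.

    At each player's first (baseline) week the lagged load is 0 and the
    lagged age is the current age less one week.
    """
    out = panel.copy()
    g = out.groupby("player_id")
    out["g_lag"] = g["games"].shift(1).fillna(0.0)
    out["age_lag"] = g["age_years"].shift(1)
    out["age_lag"] = out["age_lag"].fillna(out["age_years"] - _WEEK_DAYS)
    return out


def treatment_designs(panel: pd.DataFrame, spline_df: int = 4):
    """Design matrices for the denominator and numerator load mean models.

    The spline basis spans the constant, so spline terms stand in for the
    intercept in the denominator design.
    """
    p = add_lags(panel) if "g_lag" not in panel.columns else panel
    X_den = patsy.dmatrix(
        f"cr(rating, df={spline_df}) + g_lag + competed_prev_week "
        "+ prior_long_timeloss - 1", p, return_type="dataframe")
    X_num = patsy.dmatrix("1 + g_lag + age_lag", p, return_type="dataframe")
    # indicators that never vary in a panel (e.g. no prior long time-loss at
    # desk scale) carry no information and would break the design's rank
    for X in (X_den, X_num):
        const = [c for c in X.columns
                 if not c.startswith(("cr(", "Intercept")) and X[c].nunique() <= 1]
        X.drop(columns=const, inplace=True)
    return np.asarray(X_den), list(X_den.columns), np.asarray(X_num), list(X_num.columns)


def _not_first_week(panel: pd.DataFrame) -> np.ndarray:
    """True for records with an observed within-player predecessor.

    At each player's first baseline week the conditioning history of the
    weight models is empty, so numerator and denominator coincide (the
    marginal density) and the week's stabilization factor is exactly 1;
    those rows are excluded from model fitting.
    """
    return (panel.groupby("player_id").cumcount() > 0).to_numpy()


def fit_treatment_models(panel: pd.DataFrame, spline_df: int = 4) -> TreatmentModelPair:
    """Fit the load mean models (denominator with confounders, stabilizing
    numerator without) and their residual scales.

    Models are fitted on weeks with a lagged observation; fitted values are
    produced for every record.
    """
    Xd, cd, Xn, cn = treatment_designs(panel, spline_df)
    y = np.asarray(panel["games"], dtype=float)
    m = _not_first_week(panel)
    kd, kn = _keep_masks(Xd, cd, Xn, cn, m)
    if np.std(y[m]) < 1e-8:
        raise FitError("degenerate residual scale: weekly load has no residual variation")
    bd, sd_d = wls(Xd[m][:, kd], y[m])
    bn, sd_n = wls(Xn[m][:, kn], y[m])
    if sd_d < 1e-8 or sd_n < 1e-8:
        raise FitError("degenerate residual scale: weekly load has no residual variation")
    return TreatmentModelPair(
        denominator=LinearMeanModel(bd, [c for c, k in zip(cd, kd) if k], sd_d,
                                    Xd[:, kd] @ bd),
        numerator=LinearMeanModel(bn, [c for c, k in zip(cn, kn) if k], sd_n,
                                  Xn[:, kn] @ bn),
    )


def _keep_masks(Xd, cd, Xn, cn, m):
    prot_d = np.array([c.startswith(("cr(", "Intercept")) for c in cd])
    prot_n = np.array([c.startswith(("cr(", "Intercept")) for c in cn])
    return (drop_constant_columns(Xd[m], prot_d),
            drop_constant_columns(Xn[m], prot_n))


def _segmented_cumsum(x: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Cumulative sums restarting at each index in ``starts`` (sorted, includes 0)."""
    cs = np.cumsum(x)
    seg_lengths = np.diff(np.r_[starts, len(x)])
    base = np.r_[0.0, cs[starts[1:] - 1]]
    return cs - np.repeat(base, seg_lengths)


def _player_starts(panel: pd.DataFrame) -> np.ndarray:
    pid = panel["player_id"].to_numpy()
    starts = np.flatnonzero(np.r_[True, pid[1:] != pid[:-1]])
    return starts


def compute_stabilized_weights(
    panel: pd.DataFrame,
    models: TreatmentModelPair,
    floor_eps: float = 1e-12,
) -> tuple[pd.Series, int]:
    """Per-record stabilized treatment weight: cumulative product within
    player (from baseline) of normal density ratios evaluated at the
    observed load.

    Returns the weight series and the count of records floored at
    ``floor_eps`` to guard against density underflow.
    """
    g = np.asarray(panel["games"], dtype=float)
    log_num = stats.norm.logpdf(g, loc=models.numerator.fitted,
                                scale=models.numerator.resid_sd)
    log_den = stats.norm.logpdf(g, loc=models.denominator.fitted,
                                scale=models.denominator.resid_sd)
    lf = log_num - log_den
    lf[~_not_first_week(panel)] = 0.0  # empty history: factor 1
    lsw = _segmented_cumsum(lf, _player_starts(panel))
    floored = int(np.sum(lsw < np.log(floor_eps)))
    sw = np.exp(np.maximum(lsw, np.log(floor_eps)))
    return pd.Series(sw, index=panel.index, name="sw"), floored


#: below this many censoring events the covariate-conditional censoring
#: models are unidentifiable (quasi-separation); both sides then collapse to
#: the marginal rate and the censoring weights are exactly 1
MIN_CENSOR_EVENTS = 20


def fit_censoring_models(panel: pd.DataFrame, spline_df: int = 4) -> CensoringModelPair:
    """Logistic models of the end-of-week uncensored indicator, with the same
    right-hand sides as the load mean models.

    With fewer than :data:`MIN_CENSOR_EVENTS` censoring events in the panel
    (or on quasi-separation) both models collapse to the marginal censoring
    rate, giving unit censoring weights.
    """
    Xd, cd, Xn, cn = treatment_designs(panel, spline_df)
    y = 1.0 - np.asarray(panel["censored"], dtype=float)
    m = _not_first_week(panel)
    n_cens = int(np.sum(y[m] == 0))
    if n_cens >= MIN_CENSOR_EVENTS:
        try:
            kd, kn = _keep_masks(Xd, cd, Xn, cn, m)
            bd = irls_logit(Xd[m][:, kd], y[m])
            bn = irls_logit(Xn[m][:, kn], y[m])
            return CensoringModelPair(
                denominator=LogisticModel(bd, [c for c, k in zip(cd, kd) if k],
                                          expit(Xd[:, kd] @ bd)),
                numerator=LogisticModel(bn, [c for c, k in zip(cn, kn) if k],
                                        expit(Xn[:, kn] @ bn)),
            )
        except FitError:
            pass
    p_marg = np.full(len(y), y.mean() if len(y) else 1.0)
    return CensoringModelPair(LogisticModel(np.zeros(Xd.shape[1]), cd, p_marg.copy()),
                              LogisticModel(np.zeros(Xn.shape[1]), cn, p_marg.copy()))


def compute_censoring_weights(panel: pd.DataFrame, models: CensoringModelPair) -> pd.Series:
    """Cumulative product within player of numerator/denominator predicted
    uncensored probabilities."""
    p_den = models.denominator.prob_uncensored
    p_num = models.numerator.prob_uncensored
    if np.any(p_den <= 0):
        raise FitError("positivity violation: predicted probability of remaining "
                       "uncensored is 0 in the denominator model")
    lf = np.log(p_num) - np.log(p_den)
    lf[~_not_first_week(panel)] = 0.0  # empty history: factor 1
    lcw = _segmented_cumsum(lf, _player_starts(panel))
    return pd.Series(np.exp(lcw), index=panel.index, name="cw")


def combine_weights(sw: pd.Series, cw: pd.Series, panel: pd.DataFrame,
                    n_floored: int = 0) -> WeightSet:
    """Elementwise product with per-week-from-baseline summaries."""
    if not (sw.index.equals(cw.index) and sw.index.equals(panel.index)):
        raise ValueError("misaligned records between weights and panel")
    w = (sw * cw).rename("w")
    logw = np.log(w)
    df = pd.DataFrame({"week": panel["week_index"], "logw": logw, "w": w})
    summary = df.groupby("week").agg(
        mean_log_w=("logw", "mean"),
        q1_w=("w", lambda s: s.quantile(0.25)),
        median_w=("w", "median"),
        q3_w=("w", lambda s: s.quantile(0.75)),
        n=("w", "size"),
    ).reset_index()
    return WeightSet(sw=sw, cw=cw, w=w, weekly_summary=summary, n_floored=n_floored)


def _weighted_median(x: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(x, kind="mergesort")
    cw = np.cumsum(w[order])
    cut = 0.5 * cw[-1]
    return float(x[order][np.searchsorted(cw, cut)])


def _psb_one(cov: np.ndarray, split: np.ndarray, pooled_sd: float,
             w: np.ndarray | None = None) -> float:
    hi, lo = split, ~split
    if pooled_sd == 0 or hi.sum() == 0 or lo.sum() == 0:
        return 0.0
    if w is None:
        diff = cov[hi].mean() - cov[lo].mean()
    else:
        diff = (np.average(cov[hi], weights=w[hi])
                - np.average(cov[lo], weights=w[lo]))
    return abs(diff) / pooled_sd


def compute_psb(
    panel: pd.DataFrame,
    weights: WeightSet | pd.Series | None = None,
    covariates=DEFAULT_COVARIATES,
    min_records: int = 20,
    threshold: float = PSB_THRESHOLD,
) -> pd.DataFrame:
    """Population standard bias of each covariate per week-from-baseline.

    At each week, records are split at the (weighted, for the weighted
    version) median of that week's observed load; PSB is the absolute
    high-minus-low mean difference over the pooled unweighted SD.  Weeks with
    fewer than ``min_records`` records are skipped; a zero covariate SD gives
    PSB 0 with a flag.
    """
    w = weights.w if isinstance(weights, WeightSet) else weights
    w = pd.Series(1.0, index=panel.index) if w is None else w
    rows = []
    for week, grp in panel.groupby("week_index"):
        if len(grp) < min_records:
            continue
        g = grp["games"].to_numpy(dtype=float)
        ww = w.loc[grp.index].to_numpy(dtype=float)
        med_u = np.median(g)
        med_w = _weighted_median(g, ww)
        split_u = g > med_u
        split_w = g > med_w
        for cov in covariates:
            x = grp[cov].to_numpy(dtype=float)
            sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
            psb_u = _psb_one(x, split_u, sd)
            psb_w = _psb_one(x, split_w, sd, ww)
            rows.append((cov, week, psb_u, psb_w, len(grp),
                         psb_w > threshold, sd == 0.0))
    return pd.DataFrame(rows, columns=[
        "covariate", "week", "psb_unweighted", "psb_weighted", "n",
        "exceeds_threshold", "zero_sd"])
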