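"""Individualized competition time-loss outcome.

A time-loss event is an unexpectedly long break from competition, judged
against what is *normal for that player in that calendar month*.  The
expected maximum between-competition gap per player-month comes from a linear
mixed model (month fixed effects, player random intercept, REML) trained on
established players; a break at least two weeks longer than expected (four
weeks for January, which follows the off-season) flags a time-loss, anchored
to the last competition week before the gap.

Gap lengths are counted as days strictly between competition spells: a player
competing on consecutive days has a gap of zero.  Each gap belongs wholly to
the calendar month in which it commenced (the day after the last competition
spell), no matter how many months it spans.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

POOLED_ID = "__pooled__"


@dataclass(frozen=True)
class TimeLossRule:
    """Excess-gap thresholds that qualify a break as a time-loss."""

    excess_days_general: float = 14.0
    excess_days_january: float = 28.0
    january_month: int = 1

    def __post_init__(self):
        if self.excess_days_general <= 0 or self.excess_days_january <= 0:
            raise ValueError("time-loss excess thresholds must be positive")

    def excess(self, month: int) -> float:
        return self.excess_days_january if month == self.january_month else self.excess_days_general


def _per_gap_table(panel: pd.DataFrame, competition_days: int) -> pd.DataFrame:
    """One row per between-competition gap.

    ``competition_days`` is the number of days a panel record's competition
    spell occupies (1 for point-event dates, 7 for weekly panels).  The gap
    commences the day after the spell ends.
    """
    d = pd.to_datetime(panel["calendar_date"])
    out = []
    for pid, grp in panel.assign(_d=d).groupby("player_id", sort=False):
        dd = grp["_d"]
        if dd.duplicated().any():
            raise ValueError(f"duplicate competition dates for player {pid}")
        if not dd.is_monotonic_increasing:
            raise ValueError(f"competition dates not sorted for player {pid}")
        if len(grp) < 2:
            continue
        d1 = dd.iloc[:-1].reset_index(drop=True)
        d2 = dd.iloc[1:].reset_index(drop=True)
        gap = (d2 - d1).dt.days - competition_days
        if (gap < 0).any():
            raise ValueError(
                f"overlapping competition spells for player {pid}: "
                f"dates closer than competition_days={competition_days}")
        commence = d1 + pd.Timedelta(days=competition_days)
        out.append(pd.DataFrame({
            "player_id": pid,
            "season_year": commence.dt.year,
            "calendar_month": commence.dt.month,
            "gap_days": gap.astype(int),
            "anchor_index": grp.index[:-1],
        }))
    if not out:
        return pd.DataFrame(columns=["player_id", "season_year", "calendar_month",
                                     "gap_days", "anchor_index"])
    return pd.concat(out, ignore_index=True)


def compute_monthly_gaps(panel: pd.DataFrame, competition_days: int = 1) -> pd.DataFrame:
    """Per player-month maximum between-competition gap.

    Returns a frame with columns player_id, season_year, calendar_month,
    max_gap_days — one row per (player, year, month) in which at least one
    gap commenced.
    """
    gaps = _per_gap_table(panel, competition_days)
    if gaps.empty:
        return pd.DataFrame(columns=["player_id", "season_year", "calendar_month",
                                     "max_gap_days"])
    agg = (gaps.groupby(["player_id", "season_year", "calendar_month"], sort=True)
           ["gap_days"].max().rename("max_gap_days").reset_index())
    return agg


def seasons_at_threshold(panel: pd.DataFrame, rating_threshold: float = 2300.0) -> pd.Series:
    """Calendar years per player with at least one competition week at
    rating >= threshold (the 'season' count for training eligibility)."""
    d = pd.to_datetime(panel["calendar_date"])
    ok = panel["rating"] >= rating_threshold
    sub = pd.DataFrame({"player_id": panel["player_id"], "year": d.dt.year})[ok.values]
    if sub.empty:
        return pd.Series(dtype=int, name="n_seasons")
    return (sub.drop_duplicates().groupby("player_id")["year"].size()
            .rename("n_seasons"))


def fit_expected_gap_model(
    gaps: pd.DataFrame,
    eligibility: pd.Series,
    min_seasons: int = 3,
    per_month_random: bool = False,
) -> pd.DataFrame:
    """Expected maximum gap days per player-month from a linear mixed model.

    Trained only on players with >= ``min_seasons`` qualifying seasons.
    Returns a GapExpectation frame (player_id, calendar_month,
    expected_max_gap_days, is_pooled_fallback) containing the conditional
    (random-effect adjusted) expectation for every trained player-month and a
    pooled pseudo-player row (:data:`POOLED_ID`) per month carrying the
    population-average expectation used for everyone else.  Expectations are
    clamped at zero.

    ``per_month_random`` switches on correlated per-month random effects (an
    unstructured between-month covariance); it needs many seasons per player
    to be stable and is off by default.
    """
    import statsmodels.formula.api as smf

    trained_ids = set(eligibility[eligibility >= min_seasons].index)
    train = gaps[gaps["player_id"].isin(trained_ids)].copy()
    n_players = train["player_id"].nunique()
    n_months = train["calendar_month"].nunique()
    if n_players < 2 or n_months < 2:
        raise ValueError(
            f"degenerate design for the expected-gap model: {n_players} trained "
            f"player(s), {n_months} month(s); need at least 2 of each")

    train["calendar_month"] = train["calendar_month"].astype(int)
    re_formula = "~0 + C(calendar_month)" if per_month_random else "~1"
    model = smf.mixedlm("max_gap_days ~ C(calendar_month)", data=train,
                        groups=train["player_id"], re_formula=re_formula)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # derivative-free Powell is robust when the between-player variance
        # is near zero, where the default gradient optimizers can stall at a
        # spurious optimum
        try:
            fit = model.fit(reml=True, method="powell")
        except (ValueError, np.linalg.LinAlgError):
            fit = model.fit(reml=True)

    months = sorted(train["calendar_month"].unique())
    pooled_grid = pd.DataFrame({"calendar_month": months})
    from patsy import build_design_matrices
    X_grid = np.asarray(build_design_matrices(
        [model.data.design_info], pooled_grid)[0])
    pooled_mean = X_grid @ np.asarray(fit.fe_params)

    try:
        re = fit.random_effects
    except ValueError:
        # between-player variance estimated at 0: BLUPs are all zero and
        # every player's expectation is the month mean
        re = {pid: pd.Series([0.0]) for pid in train["player_id"].unique()}
    rows = []
    for pid in sorted(trained_ids & set(train["player_id"])):
        re_p = re[pid]
        for m, base in zip(months, pooled_mean):
            if per_month_random:
                adj = float(re_p.get(f"C(calendar_month)[{m}]", 0.0))
            else:
                adj = float(re_p.iloc[0])
            rows.append((pid, m, max(base + adj, 0.0), False))
    for m, base in zip(months, pooled_mean):
        rows.append((POOLED_ID, m, max(float(base), 0.0), True))
    out = pd.DataFrame(rows, columns=["player_id", "calendar_month",
                                      "expected_max_gap_days", "is_pooled_fallback"])
    return out


def expected_gap_lookup(expectations: pd.DataFrame, allow_fallback: bool = True):
    """Build a resolver (player_id, month) -> expected_max_gap_days."""
    table = {(r.player_id, r.calendar_month): r.expected_max_gap_days
             for r in expectations.itertuples()}

    def resolve(player_id, month):
        key = (player_id, month)
        if key in table:
            return table[key]
        if allow_fallback and (POOLED_ID, month) in table:
            return table[(POOLED_ID, month)]
        raise KeyError(
            f"no expected gap for player {player_id!r} month {month} "
            f"(fallback {'exhausted' if allow_fallback else 'disabled'})")

    return resolve


def flag_timeloss_events(
    panel: pd.DataFrame,
    expectations: pd.DataFrame,
    rule: TimeLossRule = TimeLossRule(),
    competition_days: int = 7,
    allow_fallback: bool = True,
) -> pd.DataFrame:
    """Set ``timeloss_event`` from the excess-gap rule.

    For each player-month, the largest gap commencing that month is compared
    with the player's expected maximum gap; if actual >= expected + excess
    (two weeks, four for January) the event is flagged on the last
    competition week preceding that gap.  Returns a copy of the panel with
    the flag column replaced.
    """
    out = panel.copy()
    out["timeloss_event"] = 0
    gaps = _per_gap_table(panel, competition_days)
    if gaps.empty:
        return out
    resolve = expected_gap_lookup(expectations, allow_fallback=allow_fallback)
    idx = gaps.groupby(["player_id", "season_year", "calendar_month"])["gap_days"].idxmax()
    top = gaps.loc[idx]
    flagged = []
    for r in top.itertuples():
        expected = resolve(r.player_id, r.calendar_month)
        if r.gap_days >= expected + rule.excess(r.calendar_month):
            flagged.append(r.anchor_index)
    out.loc[flagged, "timeloss_event"] = 1
    return out


def _with_peak_rating(panel: pd.DataFrame) -> pd.DataFrame:
    """Attach the career peak rating as a player-level column.

    Eligibility is a property of the whole observation period ('attained a
    rating of 2300 or higher'), so the peak must survive row filters such as
    the baseline truncation; once attached it is never recomputed.
    """
    if "peak_rating" in panel.columns:
        return panel
    out = panel.copy()
    out["peak_rating"] = out.groupby("player_id")["rating"].transform("max")
    return out


def select_eligible_players(panel: pd.DataFrame, rating_threshold: float = 2300.0) -> pd.DataFrame:
    """Retain all weeks of every player whose career peak rating reaches the
    threshold (including weeks before the peak)."""
    out = _with_peak_rating(panel)
    return out[out["peak_rating"] >= rating_threshold].reset_index(drop=True)


def apply_baseline(panel: pd.DataFrame, baseline_games: float = 8000.0) -> pd.DataFrame:
    """Drop weeks before the career-load baseline and re-index time.

    Players enter the risk pool once cumulative games reach
    ``baseline_games``; ``week_index`` becomes weeks-from-baseline starting
    at 1.
    """
    out = _with_peak_rating(panel)
    out = out[out["cum_games"] >= baseline_games].reset_index(drop=True).copy()
    out["week_index"] = out.groupby("player_id").cumcount() + 1
    return out


def classify_terminal(
    panel: pd.DataFrame,
    window_end: date,
    active_registry: dict | None = None,
    absence_threshold_days: int = 365,
) -> tuple[pd.DataFrame, dict]:
    """Classify each player's final record as censoring or terminal time-loss.

    Players whose last competition is at least ``absence_threshold_days``
    before ``window_end`` are terminal-absence candidates: officially retired
    or banned players are censored (retirement is a competing risk), players
    still registered active are treated as an unintended absence (time-loss
    event on the final record).  Everyone else is censored administratively
    at the window end.  Unknown statuses default to censored and are listed
    in the returned report.
    """
    registry = active_registry or {}
    out = panel.copy()
    d = pd.to_datetime(out["calendar_date"])
    last_idx = out.groupby("player_id")["week_index"].idxmax()
    report = {"unknown_status": [], "terminal_event": [], "terminal_censored": [],
              "administrative": []}
    end = pd.Timestamp(window_end)
    for pid, i in last_idx.items():
        days_out = (end - d.loc[i]).days
        if days_out >= absence_threshold_days:
            status = registry.get(pid)
            if status in ("retired", "banned"):
                out.loc[i, "censored"] = 1
                report["terminal_censored"].append(pid)
            elif status == "active":
                out.loc[i, "timeloss_event"] = 1
                out.loc[i, "censored"] = 0
                report["terminal_event"].append(pid)
            else:
                out.loc[i, "censored"] = 1
                report["unknown_status"].append(pid)
        else:
            if out.loc[i, "timeloss_event"] == 0:
                out.loc[i, "censored"] = 1
            report["administrative"].append(pid)
    return out, report
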