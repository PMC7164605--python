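import dataclasses

import pandas as pd
import pytest

import loadsnmm as L


@pytest.fixture(scope="session")
def confounded_panel():
    """One panel from the confounded scenario (389 players entering at the
    8,000-game baseline)."""
    return L.simulate_cohort(dataclasses.replace(L.scenario_preset("confounded"), seed=11))


@pytest.fixture(scope="session")
def small_null_panel():
    cfg = dataclasses.replace(L.scenario_preset("null"), seed=5, n_players=40,
                              study_years=1.0)
    return L.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def paper_panel():
    """Full-scale calibrated cohort, after eligibility and baseline filters."""
    from loadsnmm.timeloss import apply_baseline, select_eligible_players

    panel = L.simulate_cohort(L.scenario_preset("paper_calibrated"))
    eligible = select_eligible_players(panel, 2300.0)
    return apply_baseline(eligible, 8000.0).reset_index(drop=True)


def make_weekly_panel(rows):
    """Hand-built panel from (player, week_index, date, games, cum, age,
    rating, prev, prior_tl, event, censored, gap) tuples."""
    cols = ["player_id", "week_index", "calendar_date", "calendar_month", "games",
            "cum_games", "age_years", "rating", "competed_prev_week",
            "prior_long_timeloss", "timeloss_event", "censored", "gap_days_after"]
    recs = []
    for r in rows:
        date = pd.Timestamp(r["date"])
        recs.append([
            r["player"], r["week"], date.date(), date.month, r["games"], r["cum"],
            r.get("age", 25.0), r.get("rating", 2300.0), r.get("prev", 0),
            r.get("prior_tl", 0), r.get("event", 0), r.get("censored", 0),
            r.get("gap", 0),
        ])
    return pd.DataFrame(recs, columns=cols)


@pytest.fixture()
def tiny_panel():
    """3 players x 4 weeks, deterministic values, for brute-force oracles."""
    rows = []
    g0 = {"A": 40, "B": 55, "C": 62}
    for i, p in enumerate(["A", "B", "C"]):
        cum = 8000.0
        for w in range(1, 5):
            games = g0[p] + 3 * w * (1 if i != 1 else -1)
            cum += games
            rows.append(dict(player=p, week=w, date=f"2010-0{w}-04", games=games,
                             cum=cum, age=24.0 + i + 0.1 * w,
                             rating=2250.0 + 40 * i + 5 * w,
                             prev=int(w > 1), censored=int(p == "C" and w == 4)))
    return make_weekly_panel(rows)
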