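"""End-to-end orchestration: simulate -> outcome -> weights -> fit -> report.

The canonical interchange format is a single long-format CSV of competition
weeks (ISO-8601 dates, 0/1 flags).  Every stage writes its outputs under the
run directory together with a manifest (config hash, seed, record counts in
and out of each filter) so a rerun with the same config and seed reproduces
every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import effects, snmm, synthetic, timeloss, weights

log = logging.getLogger("loadsnmm")


@dataclass
class PipelineConfig:
    out_dir: str = "results/run"
    panel_path: str | None = None  # read an existing panel instead of simulating
    preset: str | None = "confounded"
    dgp: synthetic.DGPConfig | None = None
    seed: int = 0
    # outcome rule
    excess_days_general: float = 14.0
    excess_days_january: float = 28.0
    min_seasons: int = 3
    use_simulated_events: bool = True  # keep the generator's truth flags
    # filters
    rating_threshold: float = 2300.0
    baseline_games: float = 8000.0
    # estimation
    spline_df: int = 4
    bootstrap_B: int = 1000
    psb_threshold: float = 0.25
    # reporting
    anchor_age_tol: float = 0.5
    anchor_g_tol: float = 500.0
    deltas: tuple = (1000.0, 5000.0)

    def resolve_dgp(self) -> synthetic.DGPConfig:
        cfg = self.dgp if self.dgp is not None else synthetic.scenario_preset(self.preset)
        return dataclasses.replace(cfg, seed=self.seed)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        if d.get("dgp") is not None:
            d["dgp"]["offseason_weeks"] = sorted(d["dgp"]["offseason_weeks"])
            d["dgp"]["start_date"] = str(d["dgp"]["start_date"])
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "dgp" in d and d["dgp"] is not None:
            dd = d["dgp"]
            if "offseason_weeks" in dd:
                dd["offseason_weeks"] = frozenset(dd["offseason_weeks"])
            from datetime import date
            if "start_date" in dd:
                dd["start_date"] = date.fromisoformat(dd["start_date"])
            d["dgp"] = synthetic.DGPConfig(**dd)
        if "deltas" in d:
            d["deltas"] = tuple(d["deltas"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        return cls(**d)


def validate_panel(path) -> list[dict]:
    """Schema and monotonicity checks on a panel CSV.

    Returns a machine-readable list of violations (empty when well formed).
    """
    violations = []
    raw = pd.read_csv(path, dtype={"player_id": str})
    for col in synthetic.PANEL_COLUMNS:
        if col not in raw.columns:
            violations.append({"check": "column_present", "column": col,
                               "detail": "missing"})
    if violations:
        return violations
    try:
        pd.to_datetime(raw["calendar_date"], format="%Y-%m-%d")
    except (ValueError, TypeError):
        violations.append({"check": "iso_date", "column": "calendar_date",
                           "detail": "dates must be ISO-8601 (YYYY-MM-DD)"})
    for col in ("competed_prev_week", "prior_long_timeloss", "timeloss_event", "censored"):
        bad = ~raw[col].isin([0, 1])
        if bad.any():
            violations.append({"check": "flag_domain", "column": col,
                               "rows": raw.index[bad].tolist()[:20]})
    for pid, grp in raw.groupby("player_id"):
        if not grp["cum_games"].is_monotonic_increasing:
            rows = grp.index[grp["cum_games"].diff() < 0].tolist()
            violations.append({"check": "cum_games_monotone", "player_id": pid,
                               "rows": rows[:20]})
        if not grp["age_years"].is_monotonic_increasing:
            violations.append({"check": "age_monotone", "player_id": pid})
        if grp["week_index"].duplicated().any():
            violations.append({"check": "week_index_unique", "player_id": pid})
    if (raw["games"] <= 0).any():
        violations.append({"check": "games_positive",
                           "rows": raw.index[raw["games"] <= 0].tolist()[:20]})
    return violations


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write artifacts; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "stages": {}, "counts": {}}

    # --- simulate / load -------------------------------------------------
    if config.panel_path is not None:
        panel = synthetic.read_panel(config.panel_path)
        manifest["stages"]["simulate"] = f"loaded {config.panel_path}"
    else:
        dgp = config.resolve_dgp()
        panel = synthetic.simulate_cohort(dgp)
        synthetic.write_panel(panel, out / "panel.csv")
        dgp.to_yaml(out / "dgp_config.yaml")
        manifest["stages"]["simulate"] = "ok"
    manifest["counts"]["raw_weeks"] = int(len(panel))
    manifest["counts"]["raw_players"] = int(panel["player_id"].nunique())
    log.info("panel: %d weeks, %d players", len(panel), panel["player_id"].nunique())

    # --- outcome ----------------------------------------------------------
    rule = timeloss.TimeLossRule(config.excess_days_general, config.excess_days_january)
    gaps = timeloss.compute_monthly_gaps(panel, competition_days=7)
    n_seasons = timeloss.seasons_at_threshold(panel, config.rating_threshold)
    try:
        expectations = timeloss.fit_expected_gap_model(
            gaps, n_seasons, min_seasons=config.min_seasons)
        expectations.to_csv(out / "gap_expectations.csv", index=False)
        flagged = timeloss.flag_timeloss_events(panel, expectations, rule,
                                               competition_days=7)
        manifest["counts"]["rule_flagged_events"] = int(flagged["timeloss_event"].sum())
        manifest["stages"]["outcome"] = "ok"
    except ValueError as e:
        flagged = None
        manifest["stages"]["outcome"] = f"skipped: {e}"
    if not config.use_simulated_events and flagged is not None:
        panel = flagged
    manifest["counts"]["events"] = int(panel["timeloss_event"].sum())

    # --- filters ----------------------------------------------------------
    eligible = timeloss.select_eligible_players(panel, config.rating_threshold)
    manifest["counts"]["eligible_players"] = int(eligible["player_id"].nunique())
    based = timeloss.apply_baseline(eligible, config.baseline_games)
    manifest["counts"]["baseline_weeks"] = int(len(based))
    manifest["counts"]["baseline_players"] = int(based["player_id"].nunique())
    if based.empty:
        raise RuntimeError("no records remain after eligibility and baseline filters")
    based = based.reset_index(drop=True)
    synthetic.write_panel(based, out / "panel_analysis.csv")

    # --- weights ----------------------------------------------------------
    tmods = weights.fit_treatment_models(based, config.spline_df)
    sw, n_floored = weights.compute_stabilized_weights(based, tmods)
    cmods = weights.fit_censoring_models(based, config.spline_df)
    cw = weights.compute_censoring_weights(based, cmods)
    ws = weights.combine_weights(sw, cw, based, n_floored)
    pd.DataFrame({"player_id": based["player_id"], "week_index": based["week_index"],
                  "sw": sw, "cw": cw, "w": ws.w}).to_csv(out / "weights.csv", index=False)
    balance = weights.compute_psb(based, ws, threshold=config.psb_threshold)
    balance.to_csv(out / "balance.csv", index=False)
    _diagnostic_plots(ws, balance, out)
    manifest["stages"]["weights"] = "ok"

    # --- fit --------------------------------------------------------------
    fits = {
        "naive_unadjusted": snmm.fit_naive(based, adjusted=False,
                                           spline_df=config.spline_df),
        "naive_adjusted": snmm.fit_naive(based, adjusted=True,
                                         spline_df=config.spline_df),
    }
    snmm_fit = snmm.bootstrap_fit(based, B=config.bootstrap_B, seed=config.seed,
                                  adjusted=True, spline_df=config.spline_df)
    unadj_fit, _ = snmm.fit_snmm(based, adjusted=False, spline_df=config.spline_df)
    fits["snmm_unadjusted"] = unadj_fit
    fits["snmm_adjusted"] = snmm_fit
    _serialize_fits(fits, out / "fits.yaml", config)
    if snmm_fit.bootstrap_draws is not None:
        snmm_fit.bootstrap_draws.to_csv(out / "bootstrap_draws.csv", index=False)
    manifest["stages"]["fit"] = "ok"

    # --- report -----------------------------------------------------------
    table = effects.table3_style(fits)
    table.to_csv(out / "hazard_ratios.csv", index=False)
    try:
        anchor = effects.anchor_risk_empirical(based, age_tol=config.anchor_age_tol,
                                               g_tol=config.anchor_g_tol)
    except ValueError:
        anchor = float(based["timeloss_event"].mean())
    surface = _risk_surface(snmm_fit, based, anchor)
    surface.to_csv(out / "risk_surface.csv", index=False)
    manifest["anchor_risk"] = anchor
    manifest["hr_per_1000_ref"] = snmm_fit.hr_per_1000()
    if snmm_fit.ci is not None:
        manifest["hr_per_1000_ref_ci"] = list(snmm_fit.ci["hr_per_1000_ref"])
    manifest["stages"]["report"] = "ok"

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _risk_surface(fit, panel, anchor, n_grid: int = 12):
    ages = np.linspace(panel["age_years"].quantile(0.05),
                       panel["age_years"].quantile(0.95), n_grid)
    gs = np.linspace(panel["cum_games"].quantile(0.05),
                     panel["cum_games"].quantile(0.95), n_grid)
    rows = []
    for a in ages:
        for g in gs:
            r, lo, hi = effects.absolute_risk(fit, a, g, anchor)
            rows.append((a, g, r, lo, hi))
    return pd.DataFrame(rows, columns=["age_years", "cum_games", "risk",
                                       "band_low", "band_high"])


def _serialize_fits(fits: dict, path, config) -> None:
    blob = {}
    for label, f in fits.items():
        blob[label] = {
            "beta1_per_game": f.beta1,
            "beta2_per_game_year": f.beta2,
            "nu1": f.nu1,
            "hr_per_1000_at_ref_age": f.hr_per_1000(),
            "adjusted": f.adjusted,
            "weighted": f.weighted,
            "naive": f.naive,
            "model_columns": list(f.columns or []),
        }
        if f.moderator is not None:
            blob[label]["alpha1"] = f.moderator.alpha1
            blob[label]["alpha2"] = f.moderator.alpha2
        if f.ci is not None:
            blob[label]["ci_95"] = {k: list(v) for k, v in f.ci.items()}
            blob[label]["bootstrap_B"] = int(len(f.bootstrap_draws))
            blob[label]["seed"] = f.seed
    with open(path, "w") as fh:
        yaml.safe_dump(blob, fh, sort_keys=False)


def _diagnostic_plots(ws, balance, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    s = ws.weekly_summary
    ax.plot(s["week"], np.log(s["median_w"]), lw=1, label="median")
    ax.fill_between(s["week"], np.log(s["q1_w"]), np.log(s["q3_w"]), alpha=0.3,
                    label="IQR")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("weeks from baseline")
    ax.set_ylabel("log combined weight")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "weight_stability.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 4))
    for cov, grp in balance.groupby("covariate"):
        ax.scatter(grp["week"], grp["psb_weighted"], s=4 + grp["n"] / grp["n"].max() * 20,
                   alpha=0.5, label=f"{cov} (weighted)")
    ax.axhline(0.25, color="r", lw=0.8, ls="--")
    ax.set_xlabel("weeks from baseline")
    ax.set_ylabel("PSB")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "psb_by_week.png", dpi=120)
    plt.close(fig)
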