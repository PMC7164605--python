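"""Stabilized treatment and censoring weights with balance diagnostics.

Fits the load mean models, computes the per-week stabilized weights and
censoring weights, and evaluates covariate balance (population standard
bias) before and after weighting.
"""

import pathlib

import pandas as pd

import loadsnmm as L
from loadsnmm import weights as W

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    panel = L.read_panel(OUT / "panel_analysis.csv")
    models = W.fit_treatment_models(panel)
    sw, n_floored = W.compute_stabilized_weights(panel, models)
    cmods = W.fit_censoring_models(panel)
    cw = W.compute_censoring_weights(panel, cmods)
    ws = W.combine_weights(sw, cw, panel, n_floored)
    pd.DataFrame({"player_id": panel["player_id"], "week_index": panel["week_index"],
                  "sw": sw, "cw": cw, "w": ws.w}).to_csv(OUT / "weights.csv",
                                                         index=False)
    ws.weekly_summary.to_csv(OUT / "weight_stability_by_week.csv", index=False)

    balance = W.compute_psb(panel, ws)
    balance.to_csv(OUT / "balance_psb.csv", index=False)

    rating = balance[balance["covariate"] == "rating"]
    big = rating[rating["n"] >= 200]
    print(f"treatment residual SDs: denominator {models.denominator.resid_sd:.2f}, "
          f"numerator {models.numerator.resid_sd:.2f} games")
    print(f"weights floored at epsilon: {n_floored}")
    print(f"rating PSB, weeks with n>=200: unweighted mean "
          f"{big['psb_unweighted'].mean():.2f} (>{0.25} in "
          f"{100 * (big['psb_unweighted'] > 0.25).mean():.0f}% of weeks), "
          f"weighted mean {big['psb_weighted'].mean():.2f} (<0.25 in "
          f"{100 * (big['psb_weighted'] < 0.25).mean():.0f}%)")
    print("(per-week confounding in this calibrated cohort is mild; the strongly")
    print(" confounded scenario used for the balance acceptance checks shows the")
    print(" large unweighted imbalance and its removal by weighting)")
    mean_sw = pd.DataFrame({"week": panel["week_index"], "sw": sw}) \
        .groupby("week")["sw"].mean()
    print(f"per-week mean stabilized weight (weeks with n>=200): "
          f"{mean_sw[big['week']].min():.3f} to {mean_sw[big['week']].max():.3f}")


if __name__ == "__main__":
    main()
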