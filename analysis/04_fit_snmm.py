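"""Fit the SNMM and naive comparators with cluster-bootstrap inference.

Produces the four-estimator hazard-ratio table (naive unadjusted/adjusted,
SNMM unadjusted/adjusted) for the same-age per-1,000-game contrast and the
age-specific +3,000-game contrasts.
"""

import pathlib

import loadsnmm as L
from loadsnmm import effects
from loadsnmm.snmm import bootstrap_fit, fit_naive, fit_snmm

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "analysis"
BOOTSTRAP_B = 200  # cluster-bootstrap replicates for the adjusted SNMM


def main(seed: int = 0) -> None:
    panel = L.read_panel(OUT / "panel_analysis.csv")
    fits = {
        "naive_unadjusted": fit_naive(panel, adjusted=False),
        "naive_adjusted": fit_naive(panel, adjusted=True),
    }
    fits["snmm_unadjusted"], _ = fit_snmm(panel, adjusted=False)
    snmm_adj = bootstrap_fit(panel, B=BOOTSTRAP_B, seed=seed, adjusted=True)
    fits["snmm_adjusted"] = snmm_adj
    snmm_adj.bootstrap_draws.to_csv(OUT / "bootstrap_draws.csv", index=False)

    table = effects.table3_style(fits)
    table.to_csv(OUT / "hazard_ratio_table.csv", index=False)

    lo, hi = snmm_adj.ci["hr_per_1000_ref"]
    truth = L.synthetic.true_hr_per_1000(L.scenario_preset("paper_calibrated"))
    print("per-1,000-game hazard ratio at the same age:")
    for label, f in fits.items():
        print(f"  {label:18s} {f.hr_per_1000():.3f}")
    print(f"SNMM adjusted 95% bootstrap CI: ({lo:.3f}, {hi:.3f})  [B={BOOTSTRAP_B}]")
    print(f"generator truth at the reference age: {truth:.3f}")
    print("(the naive-vs-causal sign reversal is demonstrated on the strongly")
    print(" confounded scenario; see the sign-reversal acceptance check)")


if __name__ == "__main__":
    main()
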