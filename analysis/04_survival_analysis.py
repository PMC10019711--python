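#!/usr/bin/env python
"""Detection dynamics: gamma-frailty Cox models, effect tests, marginal
means with compact letters, diagnostics and predicted curves.

For each experiment: fit the frailty proportional-hazards model for the
experiment's factorial terms, run the sequential likelihood-ratio ANOVA
(including the frailty term), compute estimated marginal means over the
full interaction cells with Tukey-adjusted pairwise comparisons and a
compact letter display, check Cox-Snell residuals, and write predicted
hazard/CDF curves and the segregation time constants per condition.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from tonemask import quantify, survival, synth

MODEL_TERMS = {
    "I": ["uncertainty", "similarity", ("uncertainty", "similarity")],
    "II": ["uncertainty", "similarity", "rate",
           ("uncertainty", "similarity"), ("uncertainty", "rate"),
           ("similarity", "rate"), ("uncertainty", "similarity", "rate")],
    "III": ["uncertainty", "rate", ("uncertainty", "rate")],
}
EMM_FACTORS = {
    "I": ["uncertainty", "similarity"],
    "II": ["similarity", "rate", "uncertainty"],
    "III": ["rate", "uncertainty"],
}


def load_records(out: Path, exp: str, seed: int, i: int) -> pd.DataFrame:
    path = out / f"records_{exp}.csv"
    if path.exists():
        return pd.read_csv(path)
    cfg = synth.default_config(exp, seed=seed + 100 * i)
    return synth.generate_dataset(cfg)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for i, exp in enumerate(["I", "II", "III"]):
        records = load_records(args.out, exp, args.seed, i)
        cat = survival.categorize(survival.drop_first_block(records), exp)
        sd = survival.survival_data(cat)
        terms = MODEL_TERMS[exp]

        fit = survival.cox_frailty_fit(sd, terms, group_col="subject_id")
        anova = survival.anova_effects(sd, terms, group_col="subject_id")
        anova.to_csv(args.out / f"anova_{exp}.csv", index=False)

        emm = survival.emmeans_log_hazard(fit, EMM_FACTORS[exp])
        cld, pairs = survival.tukey_cld(emm, alpha=args.alpha)
        cld = cld.sort_values("emmean")
        cld.to_csv(args.out / f"emmeans_cld_{exp}.csv", index=False)
        pairs.to_csv(args.out / f"pairwise_{exp}.csv", index=False)

        slope = survival.cox_snell_slope(survival.cox_snell(fit, sd))

        # predicted population-averaged curves and segregation tau per cell
        curves, taus = [], []
        for _, row in cld.iterrows():
            pattern = {f: row[f] for f in EMM_FACTORS[exp]}
            cur = survival.predict_curves(fit, pattern)
            for f in EMM_FACTORS[exp]:
                cur[f] = row[f]
            cur[".group"] = row[".group"]
            curves.append(cur)
            tau = quantify.segregation_tau(cur.time_s.to_numpy(),
                                           cur.cdf.to_numpy())
            taus.append({**pattern,
                         "tau_s": np.nan if tau.censored else tau.tau_s,
                         "censored": tau.censored})
        pd.concat(curves).to_csv(args.out / f"curves_{exp}.csv", index=False)
        pd.DataFrame(taus).to_csv(args.out / f"segregation_tau_{exp}.csv",
                                  index=False)

        n_groups = len(set(cld[".group"]))
        frailty_row = anova.set_index("term").loc["frailty"]
        print(f"Experiment {exp}: {fit.n} trials, {fit.n_events} detections; "
              f"frailty variance {fit.theta:.3f} "
              f"(chi2 = {frailty_row.chi2:.1f}, df = {frailty_row.df:.1f}, "
              f"p = {frailty_row.p:.3g}); "
              f"{len(cld)} cells in {n_groups} CLD groups; "
              f"Cox-Snell slope {slope:.2f}")
        for _, r in anova.iterrows():
            print(f"  {r.term}: chi2 = {r.chi2:.1f}, df = {r.df:.1f}, "
                  f"p = {r.p:.3g}")


if __name__ == "__main__":
    main()
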