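#!/usr/bin/env python
"""Analytic fluctuation propagation versus Monte-Carlo simulation.

Over a grid of mean threshold ratios, compares the leading-order
predictions <T> = -tau*ln(1-x_bar) and sigma_T = tau*sigma_x/(1-x_bar)
with empirical statistics of 1e5 threshold draws pushed through the
firing-time law, and reports the waiting probability (gaussian mass at
x >= 1).  The sd amplification by 1/(1-x_bar) is the model's explanation
of the metronomic-to-random continuum.  Writes
``results/theory_check.csv``.
"""

import argparse

import pandas as pd

from utrap.fluctuation_theory import interval_sd, mc_check, mean_interval, predict

GRID = [0.3, 0.5, 0.8, 0.95, 0.99]
X_SD = 0.01
TAU = 1.0


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n", type=int, default=100_000)
    args = ap.parse_args()

    rows = []
    for x_mean in GRID:
        T_mean, valid = mean_interval(x_mean, X_SD, TAU)
        sd = interval_sd(x_mean, X_SD, TAU)
        mc = mc_check(x_mean, X_SD, TAU, n=args.n, seed=args.seed)
        pred = predict(x_mean, X_SD, TAU)
        rows.append({
            "x_mean": x_mean,
            "T_mean_pred_h": T_mean,
            "T_mean_mc_h": mc.mean,
            "T_sd_pred_h": sd,
            "T_sd_mc_h": mc.sd,
            "sd_rel_err": mc.sd / sd - 1.0,
            "valid": valid,
            "waiting_mass": pred.trunc_mass,
        })
    table = pd.DataFrame(rows)
    table.to_csv("results/theory_check.csv", index=False)
    print(table.round(5).to_string(index=False))
    ok = table[table.valid]
    print(f"\nwhere the expansion is valid, |sd relative error| <= "
          f"{ok.sd_rel_err.abs().max():.3%} at n = {args.n}")
    print("near threshold (x_mean -> 1) the prediction degrades and part of "
          "the gaussian mass sits above 1: the trap mixes waiting and random.")


if __name__ == "__main__":
    main()
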