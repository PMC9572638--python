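#!/usr/bin/env python
"""AMMI stability analysis of the simulated trial.

Fits AMMI-2 to the genotype x harvest cell means within the moderate
stress regime, partitions the interaction sum of squares, and ranks
genotypes by ASV and YSI. Requires 02_simulate_met.py.
"""

from pathlib import Path

from metstab.ammi import ammi_anova, cell_means, fit_ammi, stability_ranking
from metstab.trial_io import read_trial_table, records_to_frame

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    frame = records_to_frame(read_trial_table(RESULTS / "simulated_trial.csv"))
    cells = cell_means(frame, "TDW", "MWS")
    fit = fit_ammi(cells, n_axes=2)
    table = ammi_anova(cells, fit)
    table.to_csv(RESULTS / "ammi_anova_MWS.csv")

    gei = table.loc["G x E", "sum_sq"]
    for k in (1, 2):
        ss = table.loc[f"IPC{k}", "sum_sq"]
        print(f"IPC{k}: {100 * ss / gei:.1f}% of interaction SS")

    stab = stability_ranking(fit, cells)
    stab.to_csv(RESULTS / "stability_MWS.csv")
    best = stab.sort_values(["YSI", "RY"]).head(5)
    print("five best genotypes by YSI (yield + stability):")
    for geno, row in best.iterrows():
        print(f"  {geno}: mean yield {row['mean_yield']:.2f}, "
              f"ASV {row['ASV']:.3f}, YSI {row['YSI']:.1f}")


if __name__ == "__main__":
    main()
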