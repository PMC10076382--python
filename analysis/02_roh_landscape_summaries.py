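#!/usr/bin/env python
"""Summarise the simulated ROH landscapes (tables, optional figure).

Reads results/simulations/iterations.csv (written by
01_simulate_scenarios.py) and produces:

  results/tables/scenario_means.csv   scenario x model means, scaled to
                                      the 100 Mb chromosome
  results/tables/iteration_hotspots.csv
                                      per-iteration hotspot threshold and
                                      maximum ROH density
  results/figures/hotspot_violins.png (with --plot) violin plots of the
                                      per-iteration threshold / max density

The headline contrast: mean ROH per individual rises steeply with
bottleneck severity, while strong selection (model 4 vs 1) mainly
raises the maximum ROH density — and does so most where Ne stays large.
"""

import argparse
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--simdir", type=Path,
                        default=ROOT / "results" / "simulations")
    parser.add_argument("--length", type=int, default=25_000_000,
                        help="chromosome length used in step 01")
    parser.add_argument("--plot", action="store_true")
    args = parser.parse_args()

    table = pd.read_csv(args.simdir / "iterations.csv")
    scale = 100_000_000 / args.length
    table["roh_per_individual_100mb"] = scale * table["mean_roh_per_individual"]
    table["kb_per_individual_100mb"] = scale * table["mean_kb_per_individual"]

    tables_dir = ROOT / "results" / "tables"
    tables_dir.mkdir(parents=True, exist_ok=True)
    means = (table.groupby(["scenario", "model"])
             [["roh_per_individual_100mb", "kb_per_individual_100mb",
               "hotspot_threshold", "max_roh_density", "low_D_fraction"]]
             .agg(["mean", "std"]).round(3))
    means.to_csv(tables_dir / "scenario_means.csv")
    hot = table[["scenario", "model", "iteration", "hotspot_threshold",
                 "max_roh_density"]]
    hot.to_csv(tables_dir / "iteration_hotspots.csv", index=False)

    print(means.to_string())
    print("\nWrote", tables_dir / "scenario_means.csv")

    if args.plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=False)
        for ax, column, label in zip(
                axes, ("hotspot_threshold", "max_roh_density"),
                ("ROH hotspot threshold (%)", "Maximum ROH density (%)")):
            order = ["no_bottleneck", "rum", "severe_bottleneck"]
            data, ticks = [], []
            for scenario in order:
                for model in sorted(table["model"].unique()):
                    sub = table.query("scenario == @scenario and model == @model")
                    data.append(sub[column].dropna())
                    ticks.append(f"{scenario[:6]}\nM{model}")
            ax.violinplot(data, showmeans=True)
            ax.set_xticks(range(1, len(ticks) + 1), ticks, fontsize=7)
            ax.set_ylabel(label)
        fig_dir = ROOT / "results" / "figures"
        fig_dir.mkdir(parents=True, exist_ok=True)
        fig.tight_layout()
        fig.savefig(fig_dir / "hotspot_violins.png", dpi=150)
        print("Wrote", fig_dir / "hotspot_violins.png")


if __name__ == "__main__":
    main()
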