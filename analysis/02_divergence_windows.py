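#!/usr/bin/env python
"""Windowed pairwise divergence: the diversity presets at 50 Mb.

Regenerates the polar and brown within-species pairs on 50 Mb genomes,
tiles them into 50 kb windows, and writes the window tables, rate
histograms and a summary.  The polar pair should average ~4 differences
per 10 kb and the brown pair ~17 -- the four-fold diversity gap that makes
brown-into-polar introgression so conspicuous downstream.

Outputs under results/windows/:
    {polar,brown}_windows.tsv, rate_histograms.tsv, summary.tsv,
    rate_histograms.png
"""

import sys
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from islandmix import replication as rep
from islandmix.callmatrix import pair_50mb_layout
from islandmix.seeds import derive_int_seed
from islandmix.synthetic import bear_species_tree, simulate_sites
from islandmix.windows import mean_rate, rate_histogram, window_divergence

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/windows")
OUT.mkdir(parents=True, exist_ok=True)

layout = pair_50mb_layout()
tree = bear_species_tree()
summary, hists = [], []
fig, ax = plt.subplots(figsize=(7, 4))
for taxon, color in (("polar", "tab:blue"), ("brown", "tab:brown")):
    calls = simulate_sites(
        tree, layout, {taxon: 2},
        seed=derive_int_seed(SEED, "pair", taxon),
        recombination_rate=rep._PAIR_RECOMBINATION[taxon])
    table = window_divergence(calls)
    table.to_csv(OUT / f"{taxon}_windows.tsv", sep="\t", index=False,
                 float_format="%.4f")
    hist = rate_histogram(table, bin_width=1.0)
    mids = (hist.edges[:-1] + hist.edges[1:]) / 2
    hists.append(pd.DataFrame({"taxon": taxon, "rate_mid": mids,
                               "density": hist.density}))
    ax.bar(mids, hist.density, width=0.9, alpha=0.6, color=color,
           label=f"{taxon} pair")
    summary.append((taxon, mean_rate(table), hist.n_high, hist.n_windows))

ax.axvline(10, ls="--", c="k", lw=0.8)
ax.set_xlabel("differences per 10 kb (50 kb windows)")
ax.set_ylabel("density")
ax.legend()
fig.tight_layout()
fig.savefig(OUT / "rate_histograms.png", dpi=120)

pd.concat(hists).to_csv(OUT / "rate_histograms.tsv", sep="\t", index=False,
                        float_format="%.5f")
df = pd.DataFrame(summary, columns=["taxon", "mean_rate_per_10kb",
                                    "windows_over_10", "n_windows"])
df.to_csv(OUT / "summary.tsv", sep="\t", index=False, float_format="%.4f")
print(df.to_string(index=False))
print("The polar histogram sits almost entirely below the 10/10 kb "
      "high-diversity threshold; most brown windows exceed it.")
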