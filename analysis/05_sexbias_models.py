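#!/usr/bin/env python
"""Pulse vs continuous male-biased migration: what explains an X:autosome
ratio of ~14?

Three computations:
1. The deterministic recursion for continuous male-biased immigration
   (m = 0.0083, R = 0): autosomal donor ancestry decays as (1-m/2)^t, the
   X lags, mtDNA never moves -- the ratio grows without bound.
2. A sweep of single-pulse models (sizes x {0.25..2}, pulse times across
   (0, t_p2)): the attainable X:autosome D ratio tops out well below 3.
3. A forward two-sex Wright-Fisher check that the recursion describes the
   individual-based process, plus a painted-island D as seen by the
   D-statistic machinery.

Outputs under results/models/: recursion.tsv, pulse_grid.tsv,
ratio_report.json, trajectories.png
"""

import json
import sys
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from islandmix.sexbias import (MigrationModelParams, ancestry_recursion,
                               forward_ancestry, pulse_grid, ratio_comparison)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/models")
OUT.mkdir(parents=True, exist_ok=True)

params = MigrationModelParams(m=0.0083, R=0.0)
traj = ancestry_recursion(params, 3000)
traj.reset_index().to_csv(OUT / "recursion.tsv", sep="\t", index=False,
                          float_format="%.6g")

grid = pulse_grid(n_reps=400_000, seed=SEED)
grid.to_csv(OUT / "pulse_grid.tsv", sep="\t", index=False,
            float_format="%.5f")

report = ratio_comparison(grid, params, observed_ratio=13.75)
(OUT / "ratio_report.json").write_text(json.dumps(report, indent=2,
                                                  sort_keys=True))

fw = forward_ancestry(params, 2000, 400, seed=SEED)
fig, axes = plt.subplots(1, 2, figsize=(10, 4))
axes[0].plot(traj.index[:1500], traj["p_auto"][:1500], label="autosome")
axes[0].plot(traj.index[:1500], traj["p_x_pop"][:1500], label="X")
axes[0].plot(traj.index[:1500], traj["p_mt"][:1500], label="mtDNA")
axes[0].plot(fw.index, fw["p_auto"], "k:", lw=1, label="forward WF (auto)")
axes[0].set_xlabel("generations of male immigration")
axes[0].set_ylabel("donor (polar) ancestry")
axes[0].legend()
axes[1].semilogy(traj.index[:2500], traj["ratio_x_auto"][:2500])
axes[1].axhline(13.75, ls="--", c="r", lw=0.8)
axes[1].axhline(report["pulse_max_ratio"], ls="--", c="g", lw=0.8)
axes[1].set_xlabel("generations")
axes[1].set_ylabel("X : autosome ancestry ratio")
fig.tight_layout()
fig.savefig(OUT / "trajectories.png", dpi=120)

print(json.dumps(report, indent=2, sort_keys=True))
print(f"Single-pulse ratios top out at {report['pulse_max_ratio']:.2f} (red "
      "line far above); continuous male-only immigration crosses the "
      "observed ~13.75 and keeps climbing while mtDNA stays fixed at the "
      "donor haplotype -- the island-conversion signature.")
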