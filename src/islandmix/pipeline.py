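"""End-to-end pipeline: simulate -> windows -> D -> f-hat -> direction ->
models -> calibration, with a reproducible manifest.

The run configuration carries every threshold and seed; re-running with the
same config produces byte-identical outputs (floats serialized at fixed
precision, JSON keys sorted, no timestamps in the manifest).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .callmatrix import AUTOSOME, X, test_scale_layout
from .calibration import BEAR_SCALED_TABLE, bear_anchor, calibrate
from .direction import run_direction
from .dstat import dstat, f_hat
from .sexbias import MigrationModelParams, ancestry_recursion
from .synthetic import PulseSpec, apply_pulse, bear_species_tree, simulate_sites
from .windows import mean_rate, window_divergence

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "results/run"
    # synthetic panel
    samples_per_taxon: dict = field(default_factory=lambda: {
        "polar": 3, "brown": 2, "black": 1})
    n_auto: int = 4
    auto_len: int = 5_000_000
    n_x: int = 3
    x_len: int = 2_000_000
    # admixture pulse injected into the second brown individual ("island")
    pulse_fraction_x: float = 0.065
    pulse_fraction_auto: float = 0.0075
    tract_length: int = 20_000
    # analysis thresholds
    window_span: int = 50_000
    min_callable: int = 10_000
    block_span: int = 5_000_000
    high_threshold: float = 10.0
    direction_replicates: int = 50
    # models
    migration_m: float = 0.0083
    migration_R: float = 0.0
    migration_generations: int = 2000
    # stage toggles
    stages: list = field(default_factory=lambda: [
        "simulate", "windows", "dstat", "fhat", "direction", "models",
        "calibrate"])

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; return (and write) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": asdict(config), "stages": {}}
    stages = list(config.stages)

    if "direction" in stages and config.n_x == 0:
        raise RuntimeError("direction stage requires X scaffolds in the layout")
    need_calls = {"windows", "dstat", "fhat", "direction"} & set(stages)
    if need_calls and "simulate" not in stages:
        raise RuntimeError(
            f"stages {sorted(need_calls)} need the simulate stage")

    calls = admixed = None
    if "simulate" in stages:
        layout = test_scale_layout(config.n_auto, config.auto_len,
                                   config.n_x, config.x_len)
        tree = bear_species_tree()
        calls = simulate_sites(tree, layout, config.samples_per_taxon,
                               seed=config.seed)
        # inject the island signal: polar -> brown2 pulse, X-enriched
        admixed = calls
        for cls, frac in ((X, config.pulse_fraction_x),
                          (AUTOSOME, config.pulse_fraction_auto)):
            if frac > 0 and layout.names(cls):
                res = apply_pulse(admixed, PulseSpec(
                    donor="polar3", recipient="brown2", fraction=frac,
                    tract_length=config.tract_length, restrict_to=cls),
                    seed=config.seed)
                admixed = res.calls
        manifest["stages"]["simulate"] = {
            "n_sites": calls.n_sites(),
            "samples": calls.samples,
        }

    if "windows" in stages:
        table = window_divergence(admixed, span=config.window_span,
                                  min_callable=config.min_callable)
        p = out / "windows.tsv"
        _write_tsv(table, p)
        manifest["stages"]["windows"] = {
            "path": p.name, "sha256": _sha256(p),
            "mean_rate_per_10kb": round(mean_rate(table), 6)}

    if "dstat" in stages:
        rows = []
        for cls in (AUTOSOME, X):
            if not admixed.layout.names(cls):
                continue
            r = dstat(admixed, ("brown1", "brown2", "polar1", "black"),
                      chrom_class=cls, block_span=config.block_span)
            rows.append({"class": cls, "nABBA": r.n_abba, "nBABA": r.n_baba,
                         "D": r.D, "SE": r.SE, "Z": r.Z,
                         "sites_used": r.sites_used})
        df = pd.DataFrame(rows)
        p = out / "dstat.tsv"
        _write_tsv(df, p)
        manifest["stages"]["dstat"] = {"path": p.name, "sha256": _sha256(p)}

    if "fhat" in stages:
        rows = []
        for cls in (AUTOSOME, X):
            if not admixed.layout.names(cls):
                continue
            r = f_hat(admixed, "brown1", "brown2", "polar1", "polar2",
                      "black", chrom_class=cls, block_span=config.block_span)
            rows.append({"class": cls, "f_hat": r.value, "SE": r.SE})
        p = out / "fhat.tsv"
        _write_tsv(pd.DataFrame(rows), p)
        manifest["stages"]["fhat"] = {"path": p.name, "sha256": _sha256(p)}

    if "direction" in stages:
        summaries = []
        for donor, recipient, compare in (("brown1", "polar1", "polar2"),
                                          ("polar1", "brown1", "brown2")):
            s = run_direction(admixed, donor, recipient, compare,
                              fraction=config.pulse_fraction_x,
                              tract_length=config.tract_length,
                              replicates=config.direction_replicates,
                              seed=config.seed,
                              span=config.window_span,
                              min_callable=config.min_callable,
                              high_threshold=config.high_threshold)
            summaries.append(s.to_dict())
        p = out / "direction.json"
        p.write_text(json.dumps(summaries, indent=2, sort_keys=True))
        manifest["stages"]["direction"] = {"path": p.name, "sha256": _sha256(p)}

    if "models" in stages:
        traj = ancestry_recursion(MigrationModelParams(
            m=config.migration_m, R=config.migration_R),
            config.migration_generations)
        p = out / "recursion.tsv"
        _write_tsv(traj.reset_index(), p)
        manifest["stages"]["models"] = {"path": p.name, "sha256": _sha256(p)}

    if "calibrate" in stages:
        frames = [calibrate(BEAR_SCALED_TABLE, bear_anchor(m))
                  for m in ("A", "B", "C")]
        p = out / "calibration.tsv"
        _write_tsv(pd.concat(frames, ignore_index=True), p)
        manifest["stages"]["calibrate"] = {"path": p.name, "sha256": _sha256(p)}

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
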