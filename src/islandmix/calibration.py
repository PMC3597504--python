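"""Scaled pairwise-distance tables and TMRCA calibration.

Genome-wide average pairwise distances between lineages are scale-free once
divided by a reference comparison; absolute divergence times then follow
from an external anchor, either a calibrated date (range) for one
comparison or a mutation rate applied to an absolute per-site distance.
Range anchors propagate linearly by endpoint scaling:

    estimate(c) = scaled(c) / scaled(anchor) * anchor

and a mutation-rate anchor converts one absolute distance d to a reference
time T = d / (2 mu) before the same propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["ScaledDistanceTable", "CalibrationAnchor", "scale_distances",
           "calibrate", "BEAR_SCALED_TABLE", "bear_anchor"]


@dataclass(frozen=True)
class ScaledDistanceTable:
    """Labeled comparisons scaled so the reference comparison equals 1."""

    values: dict[str, float]
    reference: str

    def __post_init__(self):
        if self.reference not in self.values:
            raise KeyError(f"reference {self.reference!r} not in table")
        ref = self.values[self.reference]
        if abs(ref - 1.0) > 1e-9:
            raise ValueError("reference comparison must scale to 1")
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("scaled values must be positive")


@dataclass(frozen=True)
class CalibrationAnchor:
    """One external calibration.

    Either ``comparison`` with an anchor time in Mya (``lo`` == ``hi`` for a
    point anchor), or a mutation rate ``mu`` (per site per year) together
    with the absolute per-site distance of the table's reference comparison.
    """

    method: str
    comparison: str | None = None
    lo: float | None = None
    hi: float | None = None
    mu: float | None = None
    reference_distance: float | None = None

    def __post_init__(self):
        if self.mu is not None:
            if self.mu <= 0:
                raise ValueError("mu must be positive")
            if not self.reference_distance or self.reference_distance <= 0:
                raise ValueError("mu anchor needs a positive reference distance")
        else:
            if self.comparison is None or self.lo is None or self.hi is None:
                raise ValueError("range anchor needs comparison, lo, hi")
            if self.lo > self.hi:
                raise ValueError("anchor range reversed")


def scale_distances(distances: dict[str, float],
                    reference: str) -> ScaledDistanceTable:
    """Divide each comparison's mean pairwise distance by the reference's."""
    if reference not in distances:
        raise KeyError(f"reference {reference!r} missing")
    ref = distances[reference]
    if ref <= 0:
        raise ValueError("reference distance must be positive")
    return ScaledDistanceTable(
        values={k: v / ref for k, v in distances.items()}, reference=reference)


def calibrate(table: ScaledDistanceTable,
              anchor: CalibrationAnchor) -> pd.DataFrame:
    """Mya estimates (point or range) per comparison under one anchor."""
    if anchor.mu is not None:
        t_ref = anchor.reference_distance / (2.0 * anchor.mu) / 1e6  # Mya
        lo_ref = hi_ref = t_ref
        base = 1.0  # scaled value of the reference is 1
    else:
        if anchor.comparison not in table.values:
            raise KeyError(f"anchor comparison {anchor.comparison!r} not in table")
        base = table.values[anchor.comparison]
        lo_ref, hi_ref = anchor.lo, anchor.hi
    rows = []
    for comp, scaled in table.values.items():
        lo = scaled / base * lo_ref
        hi = scaled / base * hi_ref
        rows.append((comp, scaled, lo, hi))
    df = pd.DataFrame(rows, columns=["comparison", "scaled", "lo_mya", "hi_mya"])
    df["method"] = anchor.method
    return df


# The bear panel's printed scaled column (black/brown = 1).
BEAR_SCALED_TABLE = ScaledDistanceTable(
    values={
        "giant panda/black bear": 5.99,
        "black bear/brown bear": 1.0,
        "brown bear/polar bear": 0.6,
        "brown bears (population)": 0.43,
        "polar bears (population)": 0.1,
    },
    reference="black bear/brown bear",
)


def bear_anchor(method: str) -> CalibrationAnchor:
    """Published anchors: A = panda split 12+/-4 Mya; B = black/brown TMRCA
    3.90-6.48 Mya; C = mammalian mutation rate 1e-9 /site/year with the
    reference comparison at 0.004 differences per site."""
    if method == "A":
        return CalibrationAnchor("A", comparison="giant panda/black bear",
                                 lo=8.0, hi=16.0)
    if method == "B":
        return CalibrationAnchor("B", comparison="black bear/brown bear",
                                 lo=3.90, hi=6.48)
    if method == "C":
        return CalibrationAnchor("C", mu=1e-9, reference_distance=0.004)
    raise KeyError(f"unknown method {method!r}")
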