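"""Windowed pairwise divergence and high-diversity summaries.

Scaffolds are tiled from 0 in fixed, non-overlapping, half-open windows
(default 50 kb).  For each window and unordered individual pair the table
reports raw differences, callable sites and the rate in differences per
10 kb; windows with fewer callable sites than ``min_callable`` are flagged
and get a NaN rate.  Trailing partial windows are kept but flagged via the
same mechanism when short of callable sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .callmatrix import CallMatrix

__all__ = ["window_divergence", "rate_histogram", "RateHistogram",
           "mean_rate", "PER_10KB"]

PER_10KB = 10_000.0


def _interval_window_overlap(intervals: np.ndarray, span: int,
                             n_windows: int, length: int) -> np.ndarray:
    """Callable bp per window from half-open callable intervals."""
    out = np.zeros(n_windows, dtype=np.int64)
    for s, e in intervals:
        s, e = int(s), int(min(e, length))
        w0, w1 = s // span, (e - 1) // span
        if w0 == w1:
            out[w0] += e - s
            continue
        out[w0] += (w0 + 1) * span - s
        out[w1] += e - w1 * span
        if w1 > w0 + 1:
            out[w0 + 1:w1] += span
    return out


def window_divergence(calls: CallMatrix, span: int = 50_000,
                      min_callable: int = 10_000,
                      pairs: list[tuple[str, str]] | None = None,
                      chrom_class: str | None = None) -> pd.DataFrame:
    """Per 50-kb-window pairwise difference table.

    Returns a DataFrame with columns scaffold, start, end, ind1, ind2,
    differences, callable, rate (per 10 kb; NaN when insufficient) and
    insufficient flag.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    if len(calls.samples) < 2:
        raise ValueError("need at least two individuals")
    if pairs is None:
        pairs = list(combinations(calls.samples, 2))
    idx = {s: calls.sample_index(s) for s in calls.samples}

    records = []
    for name in calls.scaffold_names(chrom_class):
        length = calls.layout[name].length
        n_win = (length + span - 1) // span
        starts = np.arange(n_win, dtype=np.int64) * span
        ends = np.minimum(starts + span, length)
        base_callable = _interval_window_overlap(
            calls.callable_intervals[name], span, n_win, length)
        pos = calls.positions[name]
        win_of_site = pos // span
        al = calls.alleles[name]
        for a, b in pairs:
            ca, cb = al[:, idx[a]], al[:, idx[b]]
            called = (ca >= 0) & (cb >= 0)
            diff = called & (ca != cb)
            n_diff = np.bincount(win_of_site[diff], minlength=n_win)
            n_uncalled = np.bincount(win_of_site[~called], minlength=n_win)
            callable_ = base_callable - n_uncalled
            rate = np.where(callable_ >= min_callable,
                            n_diff / np.maximum(callable_, 1) * PER_10KB,
                            np.nan)
            records.append(pd.DataFrame({
                "scaffold": name, "start": starts, "end": ends,
                "ind1": a, "ind2": b,
                "differences": n_diff, "callable": callable_,
                "rate": rate, "insufficient": callable_ < min_callable,
            }))
    return pd.concat(records, ignore_index=True)


def mean_rate(table: pd.DataFrame) -> float:
    """Genome-wide mean rate: pooled differences over pooled callable sites,
    expressed per 10 kb (windows with data only)."""
    ok = ~table["insufficient"]
    return float(table.loc[ok, "differences"].sum()
                 / table.loc[ok, "callable"].sum() * PER_10KB)


@dataclass
class RateHistogram:
    edges: np.ndarray
    density: np.ndarray
    n_high: int
    frac_high: float
    n_windows: int


def rate_histogram(table: pd.DataFrame, bin_width: float = 1.0,
                   high_threshold: float = 10.0) -> RateHistogram:
    """Density histogram of window rates plus the count of high-diversity
    windows (rate strictly above ``high_threshold``)."""
    rates = table["rate"].to_numpy()
    rates = rates[~np.isnan(rates)]
    if len(rates) == 0:
        raise ValueError("no windows with sufficient data")
    top = max(rates.max(), high_threshold) + bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    density, _ = np.histogram(rates, bins=edges, density=True)
    n_high = int((rates > high_threshold).sum())
    return RateHistogram(edges=edges, density=density, n_high=n_high,
                         frac_high=n_high / len(rates), n_windows=len(rates))
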