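"""ABBA-BABA D-statistics with weighted block jackknife, f-hat and D decay.

For an ordered quartet (I1, I2, I3, O) a site is informative when all four
individuals are called, at most two alleles segregate, and the pattern is
ABBA (I2 and I3 carry the derived allele, I1 the ancestral) or BABA (I1 and
I3 derived, I2 ancestral), with "ancestral" defined by the outgroup O's
call.  Then

    D = (nABBA - nBABA) / (nABBA + nBABA)

is zero in expectation under incomplete lineage sorting alone and positive
when I2 shares excess derived alleles with I3.  Standard errors come from a
weighted block jackknife over genome-coordinate blocks (default 5 Mb),
weights being per-block informative-site counts; Z = D / SE.

The ancestry-proportion estimator f-hat rescales the ABBA-BABA excess by the
excess observed when the test individual is replaced by a second individual
from the donor population:

    f_hat = S(I1, I2, donor_a, O) / S(I1, donor_b, donor_a, O),
    S = nABBA - nBABA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .callmatrix import CallMatrix

__all__ = ["DStatResult", "count_patterns", "site_patterns", "block_counts",
           "d_statistic", "dstat", "FHatResult", "f_hat", "d_decay",
           "weighted_jackknife", "x_autosome_ratio"]

DEFAULT_BLOCK_SPAN = 5_000_000


# ---------------------------------------------------------------- patterns

def site_patterns(calls: CallMatrix, taxa: tuple[str, str, str, str],
                  scaffold: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-scaffold (positions, labels, usable) for one quartet.

    labels: +1 for ABBA, -1 for BABA, 0 for other usable (all-called,
    biallelic) sites.
    """
    if len(set(taxa)) != 4:
        raise ValueError("quartet individuals must be distinct")
    cols = [calls.sample_index(t) for t in taxa]
    al = calls.alleles[scaffold]
    a1, a2, a3, o = (al[:, c] for c in cols)
    called = (a1 >= 0) & (a2 >= 0) & (a3 >= 0) & (o >= 0)
    # biallelic among the quartet: every allele equals one of two observed
    # values; with the outgroup defining ancestral, "derived" = differs
    # from O and all derived alleles must agree.
    d1, d2, d3 = a1 != o, a2 != o, a3 != o
    same_derived_23 = a2 == a3
    same_derived_13 = a1 == a3
    abba = called & ~d1 & d2 & d3 & same_derived_23
    baba = called & d1 & ~d2 & d3 & same_derived_13
    # a site with three distinct alleles among {a1,a2,a3} is not biallelic
    three_way = called & d1 & d2 & d3 & ~(same_derived_23 & same_derived_13)
    usable = called & ~three_way
    labels = np.zeros(al.shape[0], dtype=np.int8)
    labels[abba] = 1
    labels[baba] = -1
    return calls.positions[scaffold], labels, usable


def count_patterns(calls: CallMatrix, taxa: tuple[str, str, str, str],
                   chrom_class: str | None = None) -> tuple[int, int, int]:
    """(nABBA, nBABA, sites_used) over a scaffold class (or everything)."""
    nA = nB = used = 0
    for name in calls.scaffold_names(chrom_class):
        _, labels, usable = site_patterns(calls, taxa, name)
        nA += int((labels == 1).sum())
        nB += int((labels == -1).sum())
        used += int(usable.sum())
    return nA, nB, used


def block_counts(calls: CallMatrix, taxa: tuple[str, str, str, str],
                 chrom_class: str | None = None,
                 block_span: int = DEFAULT_BLOCK_SPAN) -> pd.DataFrame:
    """Per-block ABBA/BABA counts; blocks are genome-coordinate tiles."""
    rows = []
    for name in calls.scaffold_names(chrom_class):
        pos, labels, usable = site_patterns(calls, taxa, name)
        length = calls.layout[name].length
        n_blocks = max(1, (length + block_span - 1) // block_span)
        blk = np.minimum(pos // block_span, n_blocks - 1)
        for b in range(n_blocks):
            m = blk == b
            rows.append((name, b * block_span, min((b + 1) * block_span, length),
                         int((labels[m] == 1).sum()),
                         int((labels[m] == -1).sum()),
                         int(usable[m].sum())))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end",
                                       "nABBA", "nBABA", "used"])


# --------------------------------------------------------------- jackknife

def weighted_jackknife(theta_full: float, theta_del: np.ndarray,
                       weights: np.ndarray) -> float:
    """Weighted delete-m_j jackknife SE (Busing-style).

    ``theta_del[j]`` is the estimate with block j removed; ``weights[j]`` the
    block's share (informative sites).  With equal weights this reduces to
    the classic delete-one formula sqrt((B-1)/B * sum (theta_del - mean)^2).
    """
    weights = np.asarray(weights, dtype=float)
    n = weights.sum()
    B = len(weights)
    h = n / weights
    theta_J = B * theta_full - float(np.sum((1.0 - 1.0 / h) * theta_del))
    tau = h * theta_full - (h - 1.0) * theta_del
    var = float(np.sum((tau - theta_J) ** 2 / (h - 1.0)) / B)
    return np.sqrt(var)


@dataclass
class DStatResult:
    taxa: tuple[str, str, str, str]
    n_abba: int
    n_baba: int
    D: float
    SE: float | None
    Z: float | None
    sites_used: int
    blocks: pd.DataFrame = field(repr=False, default=None)
    f_hat: float | None = None


def d_statistic(blocks: pd.DataFrame,
                taxa: tuple[str, str, str, str] = ("I1", "I2", "I3", "O"),
                sites_used: int | None = None) -> DStatResult:
    """Pooled D with weighted block-jackknife SE and Z from per-block counts."""
    nA = int(blocks["nABBA"].sum())
    nB = int(blocks["nBABA"].sum())
    used = int(blocks["used"].sum()) if sites_used is None else sites_used
    if nA + nB == 0:
        return DStatResult(taxa, 0, 0, np.nan, None, None, used, blocks)
    D = (nA - nB) / (nA + nB)
    info = (blocks["nABBA"] + blocks["nBABA"]).to_numpy(dtype=float)
    keep = info > 0
    if keep.sum() < 2:
        return DStatResult(taxa, nA, nB, D, None, None, used, blocks)
    bA = blocks["nABBA"].to_numpy(dtype=float)[keep]
    bB = blocks["nBABA"].to_numpy(dtype=float)[keep]
    w = info[keep]
    theta_del = ((nA - bA) - (nB - bB)) / ((nA - bA) + (nB - bB))
    se = weighted_jackknife(D, theta_del, w)
    Z = D / se if se > 0 else (0.0 if D == 0 else np.inf)
    return DStatResult(taxa, nA, nB, D, se, Z, used, blocks)


def dstat(calls: CallMatrix, taxa: tuple[str, str, str, str],
          chrom_class: str | None = None,
          block_span: int = DEFAULT_BLOCK_SPAN) -> DStatResult:
    """Count patterns, block them, and return D with jackknife SE and Z.

    X and autosomes are never pooled into one jackknife: pass
    ``chrom_class`` explicitly to select the region class.
    """
    blocks = block_counts(calls, taxa, chrom_class, block_span)
    return d_statistic(blocks, taxa)


def x_autosome_ratio(d_x: float, d_auto: float) -> float:
    """The X : autosome D ratio summarizing sex-biased admixture."""
    if d_auto == 0:
        raise ZeroDivisionError("autosomal D is zero")
    return d_x / d_auto


# ------------------------------------------------------------------ f-hat

@dataclass
class FHatResult:
    value: float
    SE: float | None
    numerator: float
    denominator: float


def f_hat(calls: CallMatrix, i1: str, i2: str, donor_a: str, donor_b: str,
          outgroup: str, chrom_class: str | None = None,
          block_span: int = DEFAULT_BLOCK_SPAN) -> FHatResult:
    """Admixture proportion of I2 from the donor population.

    Numerator quartet (I1, I2, donor_a, O); denominator quartet
    (I1, donor_b, donor_a, O), i.e. the test individual replaced by a second
    donor-population individual.  SE by delete-one block jackknife of the
    ratio (blocks weighted by denominator informative counts).
    """
    num_blocks = block_counts(calls, (i1, i2, donor_a, outgroup),
                              chrom_class, block_span)
    den_blocks = block_counts(calls, (i1, donor_b, donor_a, outgroup),
                              chrom_class, block_span)
    S_num = float((num_blocks["nABBA"] - num_blocks["nBABA"]).sum())
    S_den = float((den_blocks["nABBA"] - den_blocks["nBABA"]).sum())
    if S_den <= 0:
        return FHatResult(np.nan, None, S_num, S_den)
    value = S_num / S_den
    bn = (num_blocks["nABBA"] - num_blocks["nBABA"]).to_numpy(dtype=float)
    bd = (den_blocks["nABBA"] - den_blocks["nBABA"]).to_numpy(dtype=float)
    w = (den_blocks["nABBA"] + den_blocks["nBABA"]).to_numpy(dtype=float)
    keep = (w > 0) & (S_den - bd > 0)
    if keep.sum() < 2:
        return FHatResult(value, None, S_num, S_den)
    theta_del = (S_num - bn[keep]) / (S_den - bd[keep])
    se = weighted_jackknife(value, theta_del, w[keep])
    return FHatResult(value, se, S_num, S_den)


# ---------------------------------------------------------------- D decay

def d_decay(calls: CallMatrix, taxa: tuple[str, str, str, str],
            max_offset: int, bin_width: int,
            chrom_class: str | None = None) -> pd.DataFrame:
    """Conditional D at offsets downstream of focal ABBA / BABA sites.

    For every focal informative site, informative sites at downstream offsets
    (0, max_offset] are binned by distance; per focal class and bin the
    conditional D is reported.  Linked tracts make the profile cling to the
    focal class at offsets well below the tract length; unlinked data give a
    flat profile at the genome-wide D.
    """
    if max_offset < bin_width:
        raise ValueError("max_offset must be at least bin_width")
    n_bins = int(np.ceil(max_offset / bin_width))
    counts = np.zeros((2, n_bins, 2), dtype=np.int64)  # focal x bin x pattern
    any_focal = False
    for name in calls.scaffold_names(chrom_class):
        pos, labels, _ = site_patterns(calls, taxa, name)
        inf = labels != 0
        p = pos[inf]
        lab = labels[inf]
        if len(p) == 0:
            continue
        any_focal = True
        hi = np.searchsorted(p, p + max_offset, side="right")
        for i in range(len(p)):
            j0, j1 = i + 1, hi[i]
            if j1 <= j0:
                continue
            offs = p[j0:j1] - p[i]
            bins = np.minimum((offs - 1) // bin_width, n_bins - 1)
            f = 0 if lab[i] == 1 else 1
            np.add.at(counts[f], (bins, (lab[j0:j1] == -1).astype(int)), 1)
    if not any_focal:
        raise ValueError("no focal ABBA/BABA sites")
    rows = []
    for f, focal in enumerate(("ABBA", "BABA")):
        for b in range(n_bins):
            nA, nB = counts[f, b, 0], counts[f, b, 1]
            D = (nA - nB) / (nA + nB) if nA + nB else np.nan
            rows.append((focal, b * bin_width, min((b + 1) * bin_width, max_offset),
                         int(nA), int(nB), D))
    return pd.DataFrame(rows, columns=["focal", "offset_lo", "offset_hi",
                                       "nABBA", "nBABA", "D"])
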