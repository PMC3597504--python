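"""Synthetic multi-species genome generator.

Generates pseudo-haploid call matrices for a panel of bear-like taxa under a
multispecies coalescent, calibrated so that expected pairwise distances match
a user-supplied distance table.  The default preset reproduces the bear
panel's scaled distance structure (panda/black 5.99 : black/brown 1 :
brown/polar 0.6 : brown-within 0.43 : polar-within 0.1, anchored at a polar
pair difference of 4 per 10 kb).

Calibration model
-----------------
All ancestral (internal-branch) populations share one size ``NA`` (haploid
scale: the pairwise coalescence rate in a population of size N is 1/N), so
that for two lineages sampled in different species the expected coalescence
time is exactly ``t_split + NA`` and the expected per-site distance is
``2 mu (t_split + NA)``.  Split times follow directly from the between-taxon
distance targets.  Terminal population sizes are then solved numerically from
the within-taxon diversity targets using

    E[T_within] = N (1 - exp(-t/N)) + NA exp(-t/N)

where ``t`` is the taxon's split time: lineages that fail to coalesce before
the split escape into the ancestral size ``NA``.  The escape term is what
creates incomplete lineage sorting, and with it ABBA/BABA-informative sites.

Admixture is injected after the fact by :func:`apply_pulse`, which replaces
uniformly placed tracts of a recipient's haplotype with the donor's calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .callmatrix import CallMatrix, GenomeLayout, MISSING
from .seeds import derive_int_seed, derive_rng

__all__ = [
    "SpeciesTreeSpec", "PulseSpec", "PulseResult", "bear_species_tree",
    "build_demography", "simulate_sites", "apply_pulse",
    "tract_length_from_time", "DEFAULT_RECOMBINATION", "OUTGROUP_RECOMBINATION",
]

#: Within-scaffold recombination rate used by the simulator (per bp per
#: generation).  Chosen so 50-kb windows average over tens of marginal
#: genealogies; lower it for panels including the deep outgroup (panda),
#: whose long root branch makes high recombination rates expensive.
DEFAULT_RECOMBINATION = 5e-9
OUTGROUP_RECOMBINATION = 2e-9


def _canon(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class SpeciesTreeSpec:
    """Taxon panel with target pairwise distances and diversities.

    ``split_depths`` maps unordered taxon pairs to the expected per-site
    distance between one haplotype of each; ``within_diversity`` maps a taxon
    to the expected per-site distance between two of its haplotypes.  The
    between-taxon matrix must be ultrametric-consistent (it is interpreted as
    distances on a clock-like species tree).
    """

    taxa: tuple[str, ...]
    split_depths: dict[tuple[str, str], float]
    within_diversity: dict[str, float]
    ancestral_ne: float = 80_000.0
    mutation_rate: float = 1e-8

    def distance(self, a: str, b: str) -> float:
        if a == b:
            return self.within_diversity.get(a, 0.0)
        return self.split_depths[_canon(a, b)]

    def __post_init__(self):
        for (a, b), d in self.split_depths.items():
            if d < 0:
                raise ValueError(f"negative distance for {(a, b)}")
            if (b, a) in self.split_depths and self.split_depths[(b, a)] != d:
                raise ValueError("asymmetric split_depths")
        for t, w in self.within_diversity.items():
            others = [self.distance(t, u) for u in self.taxa if u != t]
            if others and w > min(others):
                raise ValueError(
                    f"within-diversity of {t} exceeds its nearest between-taxon distance")


# Table-1 scaled ratios anchored at a polar pair distance of 4 per 10 kb,
# i.e. one scaled unit = 40 differences per 10 kb = 4e-3 per site.
_SCALED_UNIT = 4e-4 / 0.1
BEAR_SCALED = {
    ("panda", "black"): 5.99,
    ("black", "brown"): 1.0,
    ("black", "polar"): 1.0,
    ("brown", "polar"): 0.6,
    ("brown", "panda"): 5.99,
    ("panda", "polar"): 5.99,
}
BEAR_WITHIN_SCALED = {"polar": 0.1, "brown": 0.43, "black": 0.43}


def bear_species_tree(mutation_rate: float = 1e-8,
                      ancestral_ne: float = 80_000.0) -> SpeciesTreeSpec:
    """The bear panel preset: ((polar, brown), black) + panda outgroup."""
    return SpeciesTreeSpec(
        taxa=("polar", "brown", "black", "panda"),
        split_depths={_canon(a, b): s * _SCALED_UNIT
                      for (a, b), s in BEAR_SCALED.items()},
        within_diversity={t: s * _SCALED_UNIT
                          for t, s in BEAR_WITHIN_SCALED.items()},
        mutation_rate=mutation_rate,
        ancestral_ne=ancestral_ne,
    )


def _expected_within(N: float, t: float, NA: float) -> float:
    x = t / N
    return N * (1.0 - np.exp(-x)) + NA * np.exp(-x)


def build_demography(tree: SpeciesTreeSpec) -> msprime.Demography:
    """Agglomerate the ultrametric distance table into an msprime demography.

    Repeatedly merges the closest pair of clades; each merge node gets split
    time ``t = d/(2 mu) - NA``.  Raises if the distances are not
    clock-consistent (merge times must be non-decreasing and positive).
    """
    mu, NA = tree.mutation_rate, tree.ancestral_ne
    dem = msprime.Demography()

    clades: dict[str, set[str]] = {t: {t} for t in tree.taxa}
    # terminal sizes: solved from within-diversity given the taxon's own
    # split time, which we only know after clustering -- collect first.
    order: list[tuple[str, str, str, float]] = []  # (new, left, right, time)
    active = dict(clades)
    counter = 0

    def clade_dist(ca: set[str], cb: set[str]) -> float:
        vals = [tree.distance(a, b) for a in ca for b in cb]
        if max(vals) - min(vals) > 0.05 * max(vals) + 1e-12:
            raise ValueError("split_depths are not ultrametric-consistent")
        return float(np.mean(vals))

    times: dict[str, float] = {}
    while len(active) > 1:
        names = list(active)
        best = None
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                d = clade_dist(active[names[i]], active[names[j]])
                if best is None or d < best[0]:
                    best = (d, names[i], names[j])
        d, a, b = best
        t_split = d / (2.0 * mu) - NA
        if t_split <= 0:
            raise ValueError(
                f"distance {d} too small for ancestral_ne={NA}: "
                "reduce ancestral_ne")
        counter += 1
        anc = f"anc{counter}"
        order.append((anc, a, b, t_split))
        times[a] = times.get(a, t_split)
        times[b] = times.get(b, t_split)
        active[anc] = active.pop(a) | active.pop(b)

    if order and any(np.diff([o[3] for o in order]) < 0):
        raise ValueError("split_depths are not ultrametric-consistent")

    for taxon in tree.taxa:
        t_split = times.get(taxon, np.inf)
        w = tree.within_diversity.get(taxon)
        if w is None or not np.isfinite(t_split):
            size = NA
        elif w <= 0:
            size = 1e-6  # identical-twin preset: immediate coalescence
        else:
            target = w / (2.0 * mu)
            hi = max(NA, target) * 50 + 1
            size = brentq(
                lambda N: _expected_within(N, t_split, NA) - target, 1e-3, hi)
        dem.add_population(name=taxon, initial_size=size)
    for anc, a, b, t_split in order:
        dem.add_population(name=anc, initial_size=NA)
        dem.add_population_split(time=t_split, derived=[a, b], ancestral=anc)
    dem.sort_events()
    return dem


def sample_names(samples_per_taxon: dict[str, int]) -> list[str]:
    names = []
    for taxon, n in samples_per_taxon.items():
        if n <= 0:
            continue
        if n == 1:
            names.append(taxon)
        else:
            names.extend(f"{taxon}{i + 1}" for i in range(n))
    return names


def simulate_sites(tree: SpeciesTreeSpec, layout: GenomeLayout,
                   samples_per_taxon: dict[str, int], *, seed: int,
                   recombination_rate: float | None = None) -> CallMatrix:
    """Simulate positioned biallelic pseudo-haploid calls for a taxon panel.

    Each scaffold is one coalescent simulation with within-scaffold
    recombination; scaffolds are independent (free recombination between
    them).  Alleles are coded 0 (ancestral) / 1 (derived) under a binary
    mutation model; the true ancestral state is recorded per site.
    """
    for taxon in samples_per_taxon:
        if taxon not in tree.taxa:
            raise KeyError(f"samples requested for unknown taxon {taxon!r}")
    if not any(n > 0 for n in samples_per_taxon.values()):
        raise ValueError("no samples requested")
    if recombination_rate is None:
        recombination_rate = (OUTGROUP_RECOMBINATION
                              if samples_per_taxon.get("panda", 0) > 0
                              else DEFAULT_RECOMBINATION)

    dem = build_demography(tree)
    names = sample_names(samples_per_taxon)
    positions, alleles, ancestral = {}, {}, {}
    for scaf in layout.scaffolds:
        a_seed = derive_int_seed(seed, "simulate_sites", "ancestry", scaf.name)
        m_seed = derive_int_seed(seed, "simulate_sites", "mutation", scaf.name)
        ts = msprime.sim_ancestry(
            samples={t: n for t, n in samples_per_taxon.items() if n > 0},
            demography=dem, sequence_length=scaf.length,
            recombination_rate=recombination_rate, ploidy=1,
            random_seed=a_seed)
        mts = msprime.sim_mutations(
            ts, rate=tree.mutation_rate,
            model=msprime.BinaryMutationModel(), random_seed=m_seed)
        G = mts.genotype_matrix().astype(np.int8)
        pos = np.array([int(s.position) for s in mts.sites()], dtype=np.int64)
        # discrete-genome positions are unique and sorted by construction
        positions[scaf.name] = pos
        alleles[scaf.name] = G
        ancestral[scaf.name] = np.zeros(len(pos), dtype=np.int8)
    return CallMatrix(samples=names, layout=layout, positions=positions,
                      alleles=alleles, ancestral=ancestral)


@dataclass(frozen=True)
class PulseSpec:
    """A single pulse of introgression realized as haplotype tracts.

    ``fraction`` is the proportion of the (class-restricted) recipient genome
    to replace; ``tract_length`` the tract size in bp, convertible from a
    gene-flow time via :func:`tract_length_from_time`.
    """

    donor: str
    recipient: str
    fraction: float
    tract_length: int
    restrict_to: str | None = None  # scaffold class, or None = all

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        if self.tract_length <= 0:
            raise ValueError("tract_length must be positive")


@dataclass
class PulseResult:
    calls: CallMatrix
    tracts: pd.DataFrame  # scaffold, start, end (0-based half-open)
    realized_fraction: float

    def __iter__(self):
        return iter((self.calls, self.tracts))


def place_tracts(layout: GenomeLayout, fraction: float, tract_length: int,
                 rng: np.random.Generator,
                 chrom_class: str | None = None) -> pd.DataFrame:
    """Uniformly place n = round(f L / l) tracts; overlaps permitted,
    tracts truncated at scaffold ends."""
    scafs = [s for s in layout.scaffolds
             if chrom_class is None or s.chrom_class == chrom_class]
    if not scafs:
        raise ValueError(f"layout has no scaffolds of class {chrom_class!r}")
    if fraction >= 1.0:
        # saturating pulse: one tract per scaffold covers everything
        return pd.DataFrame([(s.name, 0, s.length) for s in scafs],
                            columns=["scaffold", "start", "end"])
    L = sum(s.length for s in scafs)
    n = int(np.floor(fraction * L / tract_length + 0.5))  # round half up
    if fraction > 0 and n == 0:
        raise ValueError(
            f"fraction {fraction} over {L} bp cannot place a {tract_length} bp tract")
    offsets = np.sort(rng.integers(0, L, size=n))
    bounds = np.cumsum([0] + [s.length for s in scafs])
    rows = []
    for off in offsets:
        k = int(np.searchsorted(bounds, off, side="right") - 1)
        start = int(off - bounds[k])
        end = min(start + tract_length, scafs[k].length)
        rows.append((scafs[k].name, start, end))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end"])


def realized_tract_fraction(tracts: pd.DataFrame, layout: GenomeLayout,
                            chrom_class: str | None = None) -> float:
    from .callmatrix import interval_union_length
    L = layout.total_length(chrom_class)
    covered = 0
    for scaf, grp in tracts.groupby("scaffold"):
        covered += interval_union_length(grp["start"].to_numpy(),
                                         grp["end"].to_numpy())
    return covered / L


def apply_pulse(calls: CallMatrix, pulse: PulseSpec, *, seed: int) -> PulseResult:
    """Replace the recipient's calls with the donor's inside random tracts.

    Only the recipient row changes; positions and callability are conserved.
    The donor's calls are copied verbatim (including missingness).
    """
    di = calls.sample_index(pulse.donor)
    ri = calls.sample_index(pulse.recipient)
    rng = derive_rng(seed, "apply_pulse", pulse.donor, pulse.recipient)
    out = calls.copy()
    if pulse.fraction == 0.0:
        empty = pd.DataFrame(columns=["scaffold", "start", "end"])
        return PulseResult(out, empty, 0.0)
    tracts = place_tracts(calls.layout, pulse.fraction, pulse.tract_length,
                          rng, pulse.restrict_to)
    for scaf, grp in tracts.groupby("scaffold"):
        pos = out.positions[scaf]
        al = out.alleles[scaf]
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        s_sorted = np.sort(starts)
        e_sorted = np.sort(ends)
        cov = (np.searchsorted(s_sorted, pos, side="right")
               - np.searchsorted(e_sorted, pos, side="right"))
        inside = cov > 0
        al[inside, ri] = al[inside, di]
    frac = realized_tract_fraction(tracts, calls.layout, pulse.restrict_to)
    return PulseResult(out, tracts, frac)


def tract_length_from_time(t_years: float, r: float, gen_time: float) -> float:
    """Expected introgressed tract length after t years of recombination.

    One crossover per ``r`` per site per generation breaks tracts down to an
    expected length of ``1 / (r * generations)``; 50 kya at r = 1e-8 and a
    10-year generation time gives 20 kb.
    """
    if t_years <= 0 or r <= 0 or gen_time <= 0:
        raise ValueError("all arguments must be positive")
    return 1.0 / (r * (t_years / gen_time))
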