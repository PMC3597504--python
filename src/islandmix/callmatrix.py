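"""Genome layout and pseudo-haploid call matrix containers.

A :class:`CallMatrix` holds one allele per individual per variant site
("composite haplotypes" built by sampling a single high-quality base per
position), over positioned scaffolds classified as autosomal or X-linked.
Sites absent from the matrix but inside the callability mask are implicitly
invariant; this keeps 50-Mb genomes small in memory while letting windowed
statistics report true per-window callable-site counts.

Coordinates are 0-based half-open everywhere except VCF serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

AUTOSOME = "autosome"
X = "X"

MISSING = np.int8(-1)


@dataclass(frozen=True)
class Scaffold:
    name: str
    length: int
    chrom_class: str = AUTOSOME

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"scaffold {self.name!r} has non-positive length")
        if self.chrom_class not in (AUTOSOME, X):
            raise ValueError(f"unknown scaffold class {self.chrom_class!r}")


@dataclass(frozen=True)
class GenomeLayout:
    """Named scaffolds with lengths and autosome/X classification."""

    scaffolds: tuple[Scaffold, ...]

    def __post_init__(self):
        if not self.scaffolds:
            raise ValueError("layout has no scaffolds")
        names = [s.name for s in self.scaffolds]
        if len(set(names)) != len(names):
            raise ValueError("duplicate scaffold names")

    def names(self, chrom_class: str | None = None) -> list[str]:
        return [s.name for s in self.scaffolds
                if chrom_class is None or s.chrom_class == chrom_class]

    def __getitem__(self, name: str) -> Scaffold:
        for s in self.scaffolds:
            if s.name == name:
                return s
        raise KeyError(name)

    def total_length(self, chrom_class: str | None = None) -> int:
        return sum(s.length for s in self.scaffolds
                   if chrom_class is None or s.chrom_class == chrom_class)


def test_scale_layout(n_auto: int = 20, auto_len: int = 5_000_000,
                      n_x: int = 3, x_len: int = 2_000_000) -> GenomeLayout:
    """Default scaled genome: 20 x 5 Mb autosomes + 3 x 2 Mb X scaffolds."""
    scafs = [Scaffold(f"scaffold{i + 1}", auto_len, AUTOSOME) for i in range(n_auto)]
    scafs += [Scaffold(f"scaffoldX{i + 1}", x_len, X) for i in range(n_x)]
    return GenomeLayout(tuple(scafs))


def pair_50mb_layout() -> GenomeLayout:
    """50 Mb of autosome (10 x 5 Mb), for within-species diversity runs."""
    return test_scale_layout(n_auto=10, n_x=0)


def x_layout(n_x: int = 3, x_len: int = 2_000_000) -> GenomeLayout:
    return test_scale_layout(n_auto=0, n_x=n_x, x_len=x_len)


def full_scale_layout() -> GenomeLayout:
    """The real data's X complement: 12 scaffolds totalling ~74 Mb, plus
    42,000 x 50 kb of autosome.  Heavy; intended for full-scale reruns only."""
    x_lens = [74_000_000 // 12] * 12
    scafs = [Scaffold(f"scaffold{i + 1}", 105_000_000, AUTOSOME) for i in range(20)]
    scafs += [Scaffold(f"scaffoldX{i + 1}", ln, X) for i, ln in enumerate(x_lens)]
    return GenomeLayout(tuple(scafs))


@dataclass
class CallMatrix:
    """Per-site single-allele calls for N individuals on positioned scaffolds.

    Attributes
    ----------
    samples
        Ordered individual ids; columns of each allele matrix.
    layout
        Scaffold names, lengths and autosome/X classes.
    positions
        Per scaffold, strictly increasing 0-based variant positions.
    alleles
        Per scaffold, ``(n_sites, n_samples)`` int8; ``-1`` is missing,
        other values are allele codes (0 = ancestral under the generator).
    ancestral
        Per scaffold, per-site ancestral allele code; ``-1`` = unpolarized.
    callable_intervals
        Per scaffold, ``(k, 2)`` half-open intervals of callable sequence.
    """

    samples: list[str]
    layout: GenomeLayout
    positions: dict[str, np.ndarray]
    alleles: dict[str, np.ndarray]
    ancestral: dict[str, np.ndarray] = field(default_factory=dict)
    callable_intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for name in self.layout.names():
            pos = self.positions.setdefault(name, np.empty(0, dtype=np.int64))
            al = self.alleles.setdefault(
                name, np.empty((0, len(self.samples)), dtype=np.int8))
            if len(pos) != al.shape[0]:
                raise ValueError(f"{name}: positions/alleles length mismatch")
            if al.shape[1] != len(self.samples):
                raise ValueError(f"{name}: wrong number of sample columns")
            if len(pos) and (np.diff(pos) <= 0).any():
                raise ValueError(f"{name}: positions not strictly increasing")
            if len(pos) and (pos[-1] >= self.layout[name].length or pos[0] < 0):
                raise ValueError(f"{name}: positions outside scaffold")
            self.ancestral.setdefault(name, np.zeros(len(pos), dtype=np.int8))
            self.callable_intervals.setdefault(
                name,
                np.array([[0, self.layout[name].length]], dtype=np.int64))

    # -- basic queries -------------------------------------------------
    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def n_sites(self, chrom_class: str | None = None) -> int:
        return sum(len(self.positions[n]) for n in self.layout.names(chrom_class))

    def scaffold_names(self, chrom_class: str | None = None) -> list[str]:
        return self.layout.names(chrom_class)

    def copy(self) -> "CallMatrix":
        return CallMatrix(
            samples=list(self.samples),
            layout=self.layout,
            positions={k: v.copy() for k, v in self.positions.items()},
            alleles={k: v.copy() for k, v in self.alleles.items()},
            ancestral={k: v.copy() for k, v in self.ancestral.items()},
            callable_intervals={k: v.copy()
                                for k, v in self.callable_intervals.items()},
        )

    def callable_length(self, scaffold: str) -> int:
        iv = self.callable_intervals[scaffold]
        return int((iv[:, 1] - iv[:, 0]).sum()) if len(iv) else 0


def interval_union_length(starts: np.ndarray, ends: np.ndarray) -> int:
    """Total length covered by the union of half-open intervals."""
    if len(starts) == 0:
        return 0
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    total = 0
    cur_s, cur_e = int(s[0]), int(e[0])
    for i in range(1, len(s)):
        if s[i] > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = int(s[i]), int(e[i])
        else:
            cur_e = max(cur_e, int(e[i]))
    total += cur_e - cur_s
    return total
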