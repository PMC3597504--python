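"""Composite pseudo-haploid calls from diploid genotypes.

Low, uneven sequence coverage makes diploid genotype calls unreliable, so
each individual is down-sampled to a single allele per site: homozygotes
keep their allele, heterozygotes contribute one of their two alleles chosen
uniformly at random, and sites failing the quality threshold become missing.
The result is a composite haplotype per individual, directly comparable
across individuals of different coverage.

Input is genotype-level (VCF); read mapping and genotype calling are
upstream concerns.  A pileup-based adapter would slot in at
:func:`pseudo_haploidize_genotypes`, which is the in-memory core.
"""

from __future__ import annotations

import logging

import numpy as np

from .callmatrix import AUTOSOME, X, CallMatrix, GenomeLayout, Scaffold
from .seeds import derive_rng

logger = logging.getLogger(__name__)

__all__ = ["pseudo_haploidize_genotypes", "pseudo_haploidize_vcf", "polarize",
           "DEFAULT_MIN_QUAL"]

#: Default genotype-quality floor; sites below it become missing.
DEFAULT_MIN_QUAL = 30


def pseudo_haploidize_genotypes(genotypes: np.ndarray, *, seed: int,
                                quals: np.ndarray | None = None,
                                min_qual: float = DEFAULT_MIN_QUAL) -> np.ndarray:
    """One allele per sample per site from diploid genotypes.

    Parameters
    ----------
    genotypes
        ``(n_sites, n_samples, 2)`` int8 allele codes, ``-1`` for missing.
    quals
        Optional ``(n_sites, n_samples)`` per-genotype qualities; entries
        below ``min_qual`` become missing.  When absent the threshold is
        ignored.

    Deterministic given ``seed``; idempotent on already-haploid input (both
    genotype columns equal).
    """
    genotypes = np.asarray(genotypes, dtype=np.int8)
    if genotypes.ndim != 3 or genotypes.shape[2] != 2:
        raise ValueError("genotypes must have shape (n_sites, n_samples, 2)")
    rng = derive_rng(seed, "pseudo_haploidize")
    pick = rng.integers(0, 2, size=genotypes.shape[:2])
    out = np.take_along_axis(genotypes, pick[:, :, None], axis=2)[:, :, 0]
    out = np.where((genotypes == -1).any(axis=2), np.int8(-1), out)
    if quals is not None:
        out = np.where(np.asarray(quals) < min_qual, np.int8(-1), out)
    return out.astype(np.int8)


def _layout_from_header(vcf, x_scaffolds: set[str]) -> GenomeLayout:
    scafs = []
    for name, length in zip(vcf.seqnames, vcf.seqlens):
        cls = X if name in x_scaffolds else AUTOSOME
        scafs.append(Scaffold(name, int(length), cls))
    return GenomeLayout(tuple(scafs))


def pseudo_haploidize_vcf(path: str, *, seed: int,
                          min_qual: float = DEFAULT_MIN_QUAL,
                          x_scaffolds: set[str] | frozenset[str] = frozenset(),
                          layout: GenomeLayout | None = None) -> CallMatrix:
    """Read a diploid (or haploid) VCF and emit a pseudo-haploid CallMatrix.

    Biallelic SNVs only; multi-allelic sites are skipped with a logged
    count.  Scaffold lengths come from the VCF header unless ``layout`` is
    given; membership in ``x_scaffolds`` sets the X class.  Callability is
    taken as the full scaffold (a callability BED can be attached afterwards
    by replacing ``callable_intervals``).
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    if layout is None:
        layout = _layout_from_header(vcf, set(x_scaffolds))
    by_scaf: dict[str, list] = {n: [] for n in layout.names()}
    n_multi = 0
    for var in vcf:
        if not var.is_snp:
            continue
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gt = np.array(var.genotype.array(), dtype=np.int64)
        gq = var.gt_quals if var.format("GQ") is not None else None
        by_scaf[var.CHROM].append((var.POS - 1, gt[:, :2].astype(np.int8), gq))
    vcf.close()
    if n_multi:
        logger.info("skipped %d multi-allelic sites", n_multi)

    positions, alleles = {}, {}
    for name, rows in by_scaf.items():
        if not rows:
            continue
        pos = np.array([r[0] for r in rows], dtype=np.int64)
        gts = np.stack([r[1] for r in rows])  # (n_sites, n_samples, 2)
        quals = (np.stack([r[2] for r in rows])
                 if rows[0][2] is not None else None)
        order = np.argsort(pos, kind="stable")
        hap = pseudo_haploidize_genotypes(
            gts[order], seed=seed, quals=None if quals is None else quals[order],
            min_qual=min_qual)
        positions[name] = pos[order]
        alleles[name] = hap
    return CallMatrix(samples=samples, layout=layout,
                      positions=positions, alleles=alleles,
                      ancestral={n: np.full(len(p), -1, dtype=np.int8)
                                 for n, p in positions.items()})


def polarize(calls: CallMatrix, outgroup: str) -> CallMatrix:
    """Set the ancestral allele from a designated outgroup individual.

    Sites where the outgroup is missing are left unpolarized (ancestral
    ``-1``) and are excluded from D-statistic pattern counts.
    """
    oi = calls.sample_index(outgroup)
    out = calls.copy()
    for name in out.scaffold_names():
        out.ancestral[name] = out.alleles[name][:, oi].copy()
    return out
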