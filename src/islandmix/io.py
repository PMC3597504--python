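"""Serialization: haploid VCF 4.2, FASTA haplotypes, BED intervals, TSV.

VCF is the interchange format for call matrices (one haploid GT column per
sample, ``AA`` INFO for the ancestral allele); FASTA renders one full-length
haplotype per sample (binary allele codes mapped to A/C, missing to N); BED
is 0-based half-open and carries scaffold classes and introgressed tracts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .callmatrix import AUTOSOME, X, CallMatrix, GenomeLayout, Scaffold

__all__ = ["write_vcf", "read_vcf", "write_fasta", "write_bed", "read_bed",
           "write_layout_bed"]

_ALLELE_BASE = np.array(list("ACGT"))


def write_vcf(calls: CallMatrix, path: str) -> None:
    """Write haploid calls as an uncompressed VCF 4.2."""
    header = pysam.VariantHeader()
    for scaf in calls.layout.scaffolds:
        header.contigs.add(scaf.name, length=scaf.length)
    header.info.add("AA", 1, "String", "Ancestral allele")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in calls.samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for name in calls.scaffold_names():
            pos = calls.positions[name]
            al = calls.alleles[name]
            anc = calls.ancestral[name]
            for i in range(len(pos)):
                rec = out.new_record(contig=name, start=int(pos[i]),
                                     stop=int(pos[i]) + 1,
                                     alleles=("A", "C"))
                if anc[i] >= 0:
                    rec.info["AA"] = str(_ALLELE_BASE[anc[i]])
                for j, s in enumerate(calls.samples):
                    a = int(al[i, j])
                    rec.samples[s]["GT"] = (a,) if a >= 0 else (None,)
                out.write(rec)


def read_vcf(path: str, x_scaffolds: set[str] | frozenset[str] = frozenset(),
             layout: GenomeLayout | None = None) -> CallMatrix:
    """Read a haploid VCF back into a CallMatrix."""
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        if layout is None:
            scafs = tuple(
                Scaffold(c.name, c.length, X if c.name in x_scaffolds else AUTOSOME)
                for c in vcf.header.contigs.values())
            layout = GenomeLayout(scafs)
        pos_d: dict[str, list] = {n: [] for n in layout.names()}
        al_d: dict[str, list] = {n: [] for n in layout.names()}
        anc_d: dict[str, list] = {n: [] for n in layout.names()}
        base_code = {"A": 0, "C": 1, "G": 2, "T": 3}
        for rec in vcf:
            alleles = rec.alleles
            row = np.full(len(samples), -1, dtype=np.int8)
            for j, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                if gt and gt[0] is not None:
                    row[j] = gt[0]
            aa = rec.info.get("AA")
            anc = base_code.get(aa, -1) if aa else -1
            # map AA base back through the record's allele list
            if aa in alleles:
                anc = alleles.index(aa)
            pos_d[rec.contig].append(rec.start)
            al_d[rec.contig].append(row)
            anc_d[rec.contig].append(anc)
    positions = {n: np.array(v, dtype=np.int64) for n, v in pos_d.items()}
    alleles = {n: (np.array(v, dtype=np.int8).reshape(len(v), len(samples))
                   if v else np.empty((0, len(samples)), dtype=np.int8))
               for n, v in al_d.items()}
    ancestral = {n: np.array(v, dtype=np.int8) for n, v in anc_d.items()}
    return CallMatrix(samples=samples, layout=layout, positions=positions,
                      alleles=alleles, ancestral=ancestral)


def write_fasta(calls: CallMatrix, path: str) -> None:
    """One full-length haplotype per sample per scaffold (A/C/N coding)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for name in calls.scaffold_names():
        length = calls.layout[name].length
        pos = calls.positions[name]
        al = calls.alleles[name]
        for j, s in enumerate(calls.samples):
            seq = np.full(length, "A", dtype="U1")
            col = al[:, j]
            seq[pos[col >= 0]] = _ALLELE_BASE[col[col >= 0]]
            seq[pos[col < 0]] = "N"
            records.append(SeqRecord(Seq("".join(seq)), id=f"{s}|{name}",
                                     description=""))
    SeqIO.write(records, path, "fasta")


def write_bed(intervals: pd.DataFrame, path: str) -> None:
    """BED3 (0-based half-open) from a scaffold/start/end frame."""
    intervals[["scaffold", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["scaffold", "start", "end"])
    return df


def write_layout_bed(layout: GenomeLayout, path: str,
                     chrom_class: str = X) -> None:
    rows = [(s.name, 0, s.length) for s in layout.scaffolds
            if s.chrom_class == chrom_class]
    write_bed(pd.DataFrame(rows, columns=["scaffold", "start", "end"]), path)
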