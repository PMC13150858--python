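"""File input/output: VCF, FASTA, BED and TSV tables.

VCF is the interchange format for genotype panels (VCFv4.2, GT and DP
FORMAT fields, 1-based positions). Reading goes through cyvcf2; writing
emits the fixed GT/DP schema directly. Multiallelic or non-SNP records are
skipped on read with a warning, as the panel is defined over biallelic
SNPs.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import MISSING, GenotypeMatrix

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a panel as an uncompressed VCFv4.2 file with GT and DP."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=coresnp\n")
        for c in sorted(set(matrix.chrom), key=str):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.accessions) + "\n"
        )
        has_depth = matrix.depth is not None
        fmt = "GT:DP" if has_depth else "GT"
        for j in range(matrix.n_loci):
            cells = []
            for i in range(matrix.n_accessions):
                gt = _GT_STRINGS[int(matrix.genotypes[i, j])]
                if has_depth:
                    cells.append(f"{gt}:{int(matrix.depth[i, j])}")
                else:
                    cells.append(gt)
            fh.write(
                f"{matrix.chrom[j]}\t{matrix.pos[j]}\t"
                f"{matrix.chrom[j]}_{matrix.pos[j]}\t{matrix.ref[j]}\t"
                f"{matrix.alt[j]}\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a :class:`GenotypeMatrix`.

    Multiallelic records and indels are skipped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    chrom, pos, ref, alt, rows, depths = [], [], [], [], [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(var.gt_types)
        rows.append(
            np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        )
        dp = var.format("DP")
        depths.append(
            np.zeros(len(accessions), dtype=np.int32)
            if dp is None else np.where(dp < 0, 0, dp).ravel().astype(np.int32)
        )
    if skipped:
        warnings.warn(f"skipped {skipped} non-biallelic/non-SNP records")
    genotypes = (
        np.array(rows, dtype=np.int8).T
        if rows else np.empty((len(accessions), 0), dtype=np.int8)
    )
    depth = (
        np.array(depths, dtype=np.int32).T
        if depths else np.empty((len(accessions), 0), dtype=np.int32)
    )
    return GenotypeMatrix(
        genotypes=genotypes,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        accessions=accessions,
        depth=depth,
    )


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a BED file (0-based half-open) of region intervals.

    The optional 4th column names the region class (e.g. ``exonic``,
    ``intronic``); it defaults to ``other``.
    """
    intervals = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else "other"
            intervals.append((parts[0], int(parts[1]), int(parts[2]), name))
    return intervals
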