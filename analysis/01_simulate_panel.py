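"""Simulate the study panel: 460 accessions from 3 admixed subpopulations.

Writes the genotype panel (VCF), a matching reference (FASTA), the
simulation ground truth (TSV) and a synthetic gene-model annotation (BED)
under results/data/. Coordinates use desk-scale 1-Mb chromosomes.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from coresnp import io as cio
from coresnp.synthetic_data import PanelConfig, simulate_panel, simulate_reference

OUT = Path("results/data")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20260926

CONFIG = PanelConfig(
    n_accessions=460,
    n_loci=6000,
    n_subpops=3,
    fst=0.15,
    maf_range=(0.05, 0.5),
    mean_depth=17.22,
    seed=SEED,
)


def synthetic_gene_models(config, rng):
    """Random non-overlapping gene models: exon/intron interval pairs."""
    rows = []
    for c in range(config.n_chromosomes):
        start = 0
        while start < config.chrom_length - 10_000:
            start += int(rng.integers(2_000, 20_000))
            gene_len = int(rng.integers(2_000, 8_000))
            cursor, exonic = start, True
            while cursor < start + gene_len:
                piece = int(rng.integers(300, 1_500))
                rows.append((f"Chr{c + 1:02d}", cursor,
                             min(cursor + piece, start + gene_len),
                             "exonic" if exonic else "intronic"))
                cursor += piece
                exonic = not exonic
            start += gene_len
    return rows


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_panel(CONFIG)
    print(f"simulated {matrix.n_accessions} accessions x {matrix.n_loci} loci "
          f"(mean depth {matrix.depth.mean():.2f}x, "
          f"missing {(matrix.genotypes == -1).mean():.3%})")

    cio.write_vcf(matrix, OUT / "panel.vcf")
    reference = simulate_reference(
        [CONFIG.chrom_length] * CONFIG.n_chromosomes, seed=SEED + 1)
    cio.write_fasta(reference, OUT / "reference.fa")

    pd.DataFrame({
        "accession": matrix.accessions,
        "subpop": truth.subpop_label,
        **{f"q{k + 1}": truth.admixture[:, k]
           for k in range(CONFIG.n_subpops)},
    }).to_csv(OUT / "truth_accessions.tsv", sep="\t", index=False)

    rng = np.random.default_rng(SEED + 2)
    with open(OUT / "gene_models.bed", "w") as fh:
        for chrom, s, e, cls in synthetic_gene_models(CONFIG, rng):
            fh.write(f"{chrom}\t{s}\t{e}\t{cls}\n")
    print(f"wrote panel.vcf, reference.fa, truth_accessions.tsv, "
          f"gene_models.bed under {OUT}")


if __name__ == "__main__":
    main()
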