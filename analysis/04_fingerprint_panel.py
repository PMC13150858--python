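"""Screen fingerprint markers, thin to 100, build fingerprints + payloads.

Applies the five screening criteria (clean calls, MAF floor, the 0.4
polymorphism gate, Hardy-Weinberg p > 1e-6, 200-bp flank exclusion),
thins survivors to 100 markers evenly spread over the 12 chromosomes,
computes the minimal discriminating subset and writes the fingerprint
matrix, QR payload texts and a uniqueness report for the core accessions.
"""

import json
import warnings
from pathlib import Path

import pandas as pd

from coresnp import fingerprint as fp
from coresnp import io as cio
from coresnp.marker_panel import (
    ScreenCriteria, discrimination_power, min_discriminating_set,
    screen_candidates, thin_uniform,
)
from coresnp.popgen_stats import panel_diversity, pca_concordance

OUT = Path("results")
CHROM_LENGTH = 1_000_000


def main():
    matrix = cio.read_vcf(OUT / "filtered.vcf")
    stats = panel_diversity(matrix, hwe=True)
    criteria = ScreenCriteria(n_candidates=500, n_core=100)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        candidates = screen_candidates(matrix, stats, criteria)
    for w in caught:
        print(f"note: {w.message}")
    print(f"screen: {len(candidates)} candidate loci")

    lengths = {c: CHROM_LENGTH for c in set(matrix.chrom.astype(str))}
    panel = thin_uniform(candidates, lengths, criteria.n_core)
    per_chrom = pd.Series([l.chrom for l in panel.loci]).value_counts()
    print(f"panel: {len(panel)} markers over {per_chrom.size} chromosomes "
          f"({per_chrom.min()}-{per_chrom.max()} per chromosome); "
          f"mean MAF {panel.mean_maf:.3f}, mean Ho {panel.mean_ho:.3f}")

    pd.DataFrame([
        {"chrom": l.chrom, "pos": l.pos, "ref": l.ref, "alt": l.alt,
         "maf": l.stats.maf, "pic": l.stats.pic, "ho": l.stats.ho,
         "he": l.stats.he, "hwe_p": l.stats.hwe_p}
        for l in panel.loci
    ]).to_csv(OUT / "marker_panel.tsv", sep="\t", index=False)

    panel_matrix = matrix.take_loci(panel.indices)
    min_set, unresolved = min_discriminating_set(
        panel_matrix, [l.stats.pic for l in panel.loci])
    power = discrimination_power(panel_matrix)
    concordance = pca_concordance(matrix, panel.indices, k=2)
    print(f"minimal discriminating set: {len(min_set)} loci; "
          f"{len(unresolved)} unresolved pairs; "
          f"discrimination power {power:.4f}; "
          f"PCA concordance (k=2) {concordance:.3f}")

    core_ids = (OUT / "core_accessions.txt").read_text().split()
    core_matrix = panel_matrix.take_accessions(core_ids)
    profiles = fp.profiles_from_matrix(core_matrix)
    fp.fingerprint_matrix(profiles).to_csv(
        OUT / "fingerprint_matrix.tsv", sep="\t")
    (OUT / "qr_payloads.txt").write_text(
        "\n".join(fp.qr_payload(p) for p in profiles) + "\n")
    uniq = fp.verify_uniqueness(profiles)
    (OUT / "uniqueness.json").write_text(json.dumps(uniq, indent=2) + "\n")
    print(f"fingerprints for {len(profiles)} core accessions: "
          f"{len(uniq['duplicates'])} duplicate groups, "
          f"{len(uniq['ambiguous'])} ambiguous pairs")
    (OUT / "panel_summary.json").write_text(json.dumps({
        "n_candidates": len(candidates), "n_panel": len(panel),
        "min_discriminating_set_size": len(min_set),
        "discrimination_power": power,
        "pca_concordance": concordance,
    }, indent=2) + "\n")


if __name__ == "__main__":
    main()
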