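"""End-to-end pipeline: QC -> stats -> core -> panel -> fingerprints -> KASP.

``run_pipeline`` executes the stages in order on either an input VCF or a
synthetic panel, writes every artifact under an output directory, and
returns a manifest mapping artifact names to file paths and content
hashes. Reruns with the same configuration reproduce identical hashes for
all deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fingerprint as fp
from . import io as cio
from . import kasp as kaspmod
from .containers import GenotypeMatrix
from .core_collection import CoreConfig, compare_core_full, select_core, sweep_fractions
from .marker_panel import (
    ScreenCriteria, discrimination_power, min_discriminating_set,
    screen_candidates, thin_uniform,
)
from .popgen_stats import panel_diversity, pca_concordance
from .synthetic_data import PanelConfig, simulate_panel, simulate_reference
from .variant_qc import filter_variants, matrix_from_records, records_from_matrix

log = logging.getLogger("coresnp")


@dataclass
class PipelineConfig:
    """Declarative configuration for a full run.

    Exactly one of ``vcf`` (with ``reference_fasta``) or ``synthetic``
    must be provided; the seed propagates to every stochastic stage.
    """

    outdir: str = "results"
    seed: int = 0
    vcf: str | None = None
    reference_fasta: str | None = None
    synthetic: PanelConfig | None = None
    qc_min_depth: float = 4.0
    qc_max_missing: float = 0.10
    qc_min_maf: float = 0.005
    core: CoreConfig = field(default_factory=CoreConfig)
    screen: ScreenCriteria = field(default_factory=ScreenCriteria)
    design: kaspmod.DesignConstraints = field(default_factory=kaspmod.DesignConstraints)
    sweep: list[float] = field(default_factory=lambda: [round(f, 1) for f in np.arange(0.1, 1.0, 0.1)])
    n_kasp: int = 40

    def validate(self) -> None:
        if (self.vcf is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of an input VCF or a synthetic config")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; return the artifact manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # --- input panel -----------------------------------------------------
    if config.synthetic is not None:
        cfg = config.synthetic
        matrix, _truth = simulate_panel(cfg)
        reference = simulate_reference(
            [cfg.chrom_length] * cfg.n_chromosomes, seed=cfg.seed + 1)
        vcf_path = outdir / "panel.vcf"
        cio.write_vcf(matrix, vcf_path)
        artifacts["panel_vcf"] = vcf_path
        fasta_path = outdir / "reference.fa"
        cio.write_fasta(reference, fasta_path)
        artifacts["reference_fasta"] = fasta_path
    else:
        matrix = cio.read_vcf(config.vcf)
        reference = cio.read_fasta(config.reference_fasta) if config.reference_fasta else {}
    log.info("input panel: %d accessions x %d loci", matrix.n_accessions, matrix.n_loci)

    # --- QC --------------------------------------------------------------
    records = records_from_matrix(matrix)
    retained, report = filter_variants(
        records, config.qc_min_depth, config.qc_max_missing, config.qc_min_maf)
    filtered = matrix_from_records(retained, matrix.accessions)
    log.info("QC: %d -> %d loci (Ts/Tv %.3f)", report.n_input, report.n_retained, report.tstv)
    qc_path = outdir / "qc_report.json"
    qc_path.write_text(json.dumps(asdict(report), indent=2, default=str))
    artifacts["qc_report"] = qc_path

    # --- diversity stats -------------------------------------------------
    stats = panel_diversity(filtered, hwe=True)
    stats_df = pd.DataFrame([asdict(s) for s in stats])
    stats_df.insert(0, "chrom", filtered.chrom)
    stats_df.insert(1, "pos", filtered.pos)
    stats_path = outdir / "locus_stats.tsv"
    stats_df.to_csv(stats_path, sep="\t", index=False)
    artifacts["locus_stats"] = stats_path

    # --- core collection -------------------------------------------------
    core_cfg = CoreConfig(**{**asdict(config.core), "seed": config.seed})
    sweep = sweep_fractions(filtered, config.sweep, core_cfg)
    sweep_path = outdir / "core_sweep.tsv"
    sweep.to_csv(sweep_path, sep="\t", index=False)
    artifacts["core_sweep"] = sweep_path
    core = select_core(filtered, core_cfg)
    (outdir / "core_accessions.txt").write_text("\n".join(core.accessions) + "\n")
    artifacts["core_accessions"] = outdir / "core_accessions.txt"
    comparison = compare_core_full(filtered, core)
    comp_path = outdir / "core_vs_full.json"
    comp_path.write_text(json.dumps(comparison, indent=2))
    artifacts["core_comparison"] = comp_path
    log.info("core: %d accessions at fraction %.2f", core.size, core_cfg.fraction)

    # --- fingerprint marker panel ---------------------------------------
    candidates = screen_candidates(filtered, stats, config.screen)
    panel = thin_uniform(
        candidates,
        {c: (config.synthetic.chrom_length if config.synthetic else int(filtered.pos.max()))
         for c in set(filtered.chrom.astype(str))},
        config.screen.n_core,
    )
    panel_df = pd.DataFrame([
        {"chrom": l.chrom, "pos": l.pos, "ref": l.ref, "alt": l.alt,
         "maf": l.stats.maf, "pic": l.stats.pic, "ho": l.stats.ho,
         "hwe_p": l.stats.hwe_p}
        for l in panel.loci
    ])
    panel_path = outdir / "marker_panel.tsv"
    panel_df.to_csv(panel_path, sep="\t", index=False)
    artifacts["marker_panel"] = panel_path
    log.info("panel: %d candidates -> %d core markers", len(candidates), len(panel))

    panel_matrix = filtered.take_loci(panel.indices)
    min_set, unresolved = min_discriminating_set(
        panel_matrix, [l.stats.pic for l in panel.loci])
    power = discrimination_power(panel_matrix)
    concordance = pca_concordance(filtered, panel.indices, k=2)
    summary = {
        "n_candidates": len(candidates), "n_panel": len(panel),
        "min_discriminating_set_size": len(min_set),
        "unresolved_pairs": unresolved,
        "discrimination_power": power,
        "pca_concordance": concordance,
    }
    summary_path = outdir / "panel_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    artifacts["panel_summary"] = summary_path

    # --- fingerprints ----------------------------------------------------
    profiles = fp.profiles_from_matrix(panel_matrix)
    fp.fingerprint_matrix(profiles).to_csv(outdir / "fingerprint_matrix.tsv", sep="\t")
    artifacts["fingerprint_matrix"] = outdir / "fingerprint_matrix.tsv"
    payloads = "\n".join(fp.qr_payload(p) for p in profiles) + "\n"
    (outdir / "qr_payloads.txt").write_text(payloads)
    artifacts["qr_payloads"] = outdir / "qr_payloads.txt"
    uniq = fp.verify_uniqueness(profiles)
    (outdir / "uniqueness.json").write_text(json.dumps(uniq, indent=2))
    artifacts["uniqueness"] = outdir / "uniqueness.json"

    # --- KASP design -----------------------------------------------------
    rows = []
    n_ok = 0
    for l in panel.loci[: config.n_kasp]:
        if l.chrom not in reference:
            continue
        result = kaspmod.design_assay(
            reference, l.chrom, l.pos, l.ref, l.alt, config.design,
            check_flanks=False,
        )
        if isinstance(result, kaspmod.KaspAssay):
            n_ok += 1
            rows.append({
                "marker": result.marker, "chrom": result.chrom, "pos": result.pos,
                "allele_x": result.allele_x, "allele_y": result.allele_y,
                "fam_primer": result.fam_primer, "vic_primer": result.vic_primer,
                "common_primer": result.common_primer,
                "product_length": result.product_length, "status": "ok",
            })
        else:
            rows.append({
                "marker": result.marker, "chrom": result.chrom, "pos": result.pos,
                "allele_x": l.ref, "allele_y": l.alt,
                "fam_primer": "", "vic_primer": "", "common_primer": "",
                "product_length": -1, "status": f"fail:{result.constraint}",
            })
    kasp_path = outdir / "kasp_assays.tsv"
    pd.DataFrame(rows).to_csv(kasp_path, sep="\t", index=False)
    artifacts["kasp_assays"] = kasp_path
    if rows:
        log.info("KASP: %d/%d assays designed (%.1f%%)", n_ok, len(rows),
                 100.0 * n_ok / len(rows))

    manifest = {
        name: {"path": str(p), "sha256": _sha256(p)}
        for name, p in artifacts.items()
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
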