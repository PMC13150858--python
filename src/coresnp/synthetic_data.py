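"""Synthetic genotype panels, reference sequences and KASP fluorescence.

Emulates a resequencing panel of several hundred germplasm accessions drawn
from a handful of admixed subpopulations. Subpopulation allele frequencies
drift from a shared ancestral frequency under the Balding-Nichols model:
given ancestral frequency ``p`` and divergence ``F`` (an FST-like
parameter), each subpopulation's frequency is drawn from
``Beta(p(1-F)/F, (1-p)(1-F)/F)``. Each accession receives admixture
fractions from a symmetric Dirichlet(0.2), so most accessions are
near-pure; genotypes are binomial draws from the accession's admixed
frequency. Loci are independent (no linkage disequilibrium) and reads are
not simulated — per-cell depth is Poisson.

All randomness flows from a single integer seed through a named
``numpy.random.Generator``; identical configuration gives bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import MISSING, GenotypeMatrix

ADMIXTURE_ALPHA = 0.2

#: Fluorescence-space class centers, indexed by dosage; missing at origin.
KASP_CENTERS = {0: (1.0, 0.0), 1: (0.5, 0.5), 2: (0.0, 1.0), MISSING: (0.0, 0.0)}


class ConfigError(ValueError):
    """A panel configuration field is out of its valid range."""


@dataclass
class PanelConfig:
    """Study-condition parameters for a simulated germplasm panel.

    Defaults mirror the target study design: 460 accessions at ~17x mean
    depth drawn from a few admixed subpopulations across 12 chromosomes.
    """

    n_accessions: int = 460
    n_loci: int = 2000
    n_subpops: int = 3
    fst: float = 0.15
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.005
    mean_depth: float = 17.22
    seed: int = 0
    n_chromosomes: int = 12
    # desk-scale chromosome coordinate span; real chromosomes are tens of
    # Mb, but flank extraction and spacing logic only need relative scale
    chrom_length: int = 1_000_000

    def validate(self) -> None:
        if self.n_accessions < 1:
            raise ConfigError("n_accessions must be >= 1")
        if self.n_loci < 1:
            raise ConfigError("n_loci must be >= 1")
        if self.n_subpops < 1:
            raise ConfigError("n_subpops must be >= 1")
        if not 0.0 <= self.fst < 1.0:
            raise ConfigError("fst must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range bounds must be ordered within (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")


@dataclass
class TruthRecord:
    """Simulation ground truth retained for downstream checks."""

    ancestral_freq: np.ndarray          # (L,) alt-allele frequency
    subpop_freq: np.ndarray             # (K, L) drifted frequencies
    admixture: np.ndarray               # (N, K) fractions summing to 1
    subpop_label: np.ndarray            # (N,) dominant-component label
    accession_freq: np.ndarray = field(repr=False, default=None)  # (N, L)


_BASES = np.array(list("ACGT"))
# transition partner of each base, used to bias ref/alt pairs realistically
_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _draw_alleles(rng: np.random.Generator, n_loci: int, ts_fraction: float = 0.66):
    """Ref/alt base pairs with roughly the transition excess seen in real data."""
    ref = _BASES[rng.integers(0, 4, size=n_loci)]
    alt = np.empty(n_loci, dtype=object)
    is_ts = rng.random(n_loci) < ts_fraction
    for i, (r, t) in enumerate(zip(ref, is_ts)):
        if t:
            alt[i] = _TS_PARTNER[r]
        else:
            choices = [b for b in "ACGT" if b != r and b != _TS_PARTNER[r]]
            alt[i] = choices[rng.integers(0, len(choices))]
    return ref.astype(object), alt


def simulate_panel(config: PanelConfig) -> tuple[GenotypeMatrix, TruthRecord]:
    """Simulate a genotype panel under the admixed Balding-Nichols model.

    Returns the panel and the ground-truth record (ancestral and drifted
    frequencies, admixture fractions, dominant subpopulation labels).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    N, L, K = config.n_accessions, config.n_loci, config.n_subpops

    lo, hi = config.maf_range
    p_anc = rng.uniform(lo, hi, size=L)
    # the bounded draw is a MAF; flip half the loci so the alt allele is
    # sometimes the major one
    flip = rng.random(L) < 0.5
    p_anc = np.where(flip, 1.0 - p_anc, p_anc)

    if config.fst > 0 and K > 1:
        F = config.fst
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        subpop_freq = rng.beta(a[None, :], b[None, :], size=(K, L))
    else:
        subpop_freq = np.tile(p_anc, (K, 1))

    admixture = rng.dirichlet(np.full(K, ADMIXTURE_ALPHA), size=N)
    labels = admixture.argmax(axis=1)
    acc_freq = admixture @ subpop_freq                      # (N, L)

    genotypes = rng.binomial(2, acc_freq).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random((N, L)) < config.missing_rate
        genotypes[mask] = MISSING
    depth = rng.poisson(config.mean_depth, size=(N, L)).astype(np.int32)

    chrom_ids = np.sort(rng.integers(0, config.n_chromosomes, size=L))
    pos = np.empty(L, dtype=np.int64)
    chrom = np.empty(L, dtype=object)
    for c in range(config.n_chromosomes):
        idx = np.flatnonzero(chrom_ids == c)
        pos[idx] = np.sort(
            rng.choice(
                np.arange(601, config.chrom_length - 600, dtype=np.int64),
                size=idx.size, replace=False,
            )
        )
        chrom[idx] = f"Chr{c + 1:02d}"

    ref, alt = _draw_alleles(rng, L)
    matrix = GenotypeMatrix(
        genotypes=genotypes, chrom=chrom, pos=pos, ref=ref, alt=alt,
        depth=depth,
        accessions=[f"S{i + 1}" for i in range(N)],
    )
    truth = TruthRecord(
        ancestral_freq=p_anc, subpop_freq=subpop_freq,
        admixture=admixture, subpop_label=labels, accession_freq=acc_freq,
    )
    return matrix, truth


def simulate_reference(chrom_lengths: list[int], seed: int) -> dict[str, str]:
    """Random uppercase A/C/G/T chromosome sequences, keyed ``Chr01``…

    Lengths of at least 1200 bp leave room for 500-bp flanks around
    interior loci; shorter sequences are allowed but flank extraction will
    truncate near their edges.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for i, length in enumerate(chrom_lengths):
        if length < 1:
            raise ValueError(f"chromosome length must be >= 1, got {length}")
        seq = rng.integers(0, 4, size=length)
        out[f"Chr{i + 1:02d}"] = "".join(_BASES[seq])
    return out


def simulate_kasp_intensities(
    genotypes, noise_sd: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two-channel endpoint fluorescence for one locus.

    Dosage 0 (X-allele hom) clusters near (1, 0) in (FAM, VIC) space,
    dosage 2 near (0, 1), heterozygotes near (0.5, 0.5) and missing/failed
    wells near the origin, with isotropic Gaussian jitter of ``noise_sd``.

    Returns ``(points, truth)`` where ``points`` is (n, 2) and ``truth``
    the input dosage vector as an int array.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    g = np.asarray(genotypes, dtype=int)
    rng = np.random.default_rng(seed)
    centers = np.array([KASP_CENTERS.get(int(d), KASP_CENTERS[MISSING]) for d in g])
    points = centers + rng.normal(0.0, noise_sd, size=centers.shape)
    return points, g
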