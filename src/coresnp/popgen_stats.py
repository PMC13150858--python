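"""Per-locus diversity statistics, HWE testing, distances and PCA checks.

Conventions for a biallelic locus with alt-allele frequency ``p`` and
``q = 1 - p`` estimated on non-missing diploid calls:

* observed heterozygosity  Ho = het calls / called
* expected heterozygosity  He = 1 - p^2 - q^2
* Nei's gene diversity     (2n / (2n - 1)) * He, clipped to <= 1
* Shannon-Weiner index     -(p log2 p + q log2 q), so the biallelic
  maximum is 1.0 at p = 0.5 (base-2 logs; a natural-log convention caps
  at ln 2 ~= 0.693, below per-locus values this statistic must reach)
* PIC                      1 - (p^2 + q^2) - 2 p^2 q^2

Hardy-Weinberg departure is tested with the exact conditional test
(enumeration of heterozygote counts given the allele counts), which stays
accurate at the extreme p ~ 1e-6 significance gate where the chi-square
approximation fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .containers import MISSING, GenotypeMatrix

LOG2 = np.log(2.0)


@dataclass
class LocusStats:
    """Diversity summary of one biallelic locus."""

    maf: float
    ho: float
    he: float
    nei: float
    shannon: float
    pic: float
    hwe_p: float = float("nan")
    n_called: int = 0
    n_missing: int = 0


def _freq_stats(p: float, n: int) -> tuple[float, float, float, float]:
    q = 1.0 - p
    he = 1.0 - p * p - q * q
    nei = min(1.0, (2.0 * n / (2.0 * n - 1.0)) * he) if n > 1 else he
    shannon = 0.0
    for f in (p, q):
        if f > 0.0:
            shannon -= f * np.log(f) / LOG2
    pic = 1.0 - (p * p + q * q) - 2.0 * p * p * q * q
    return he, nei, float(shannon), pic


def locus_diversity(genotypes) -> LocusStats:
    """Compute MAF, Ho, He, Nei, Shannon and PIC for one locus.

    ``genotypes`` is a dosage vector (0/1/2, -1 missing); frequencies use
    non-missing calls only. Raises on an all-missing locus.
    """
    g = np.asarray(genotypes)
    called = g[g != MISSING]
    n = called.size
    if n == 0:
        raise ValueError("no data: all genotypes missing at locus")
    p = float(called.sum()) / (2.0 * n)
    ho = float((called == 1).sum()) / n
    he, nei, shannon, pic = _freq_stats(p, n)
    return LocusStats(
        maf=float(min(p, 1.0 - p)), ho=ho, he=he, nei=nei,
        shannon=shannon, pic=pic,
        n_called=n, n_missing=int(g.size - n),
    )


def panel_diversity(matrix: GenotypeMatrix, hwe: bool = False) -> list[LocusStats]:
    """Per-locus diversity stats for every locus of a panel."""
    out = []
    for j in range(matrix.n_loci):
        g = matrix.genotypes[:, j]
        stats = locus_diversity(g)
        if hwe:
            called = g[g != MISSING]
            stats.hwe_p = hwe_exact_test(
                int((called == 0).sum()), int((called == 1).sum()),
                int((called == 2).sum()),
            )
        out.append(stats)
    return out


def hwe_exact_test(n_refhom: int, n_het: int, n_althom: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed configuration.
    """
    if min(n_refhom, n_het, n_althom) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_refhom + n_het + n_althom
    if n == 0:
        raise ValueError("no data: empty genotype counts")
    n_ref = 2 * n_refhom + n_het        # ref allele count
    n_alt = 2 * n_althom + n_het
    rare = min(n_ref, n_alt)
    if rare == 0:
        return 1.0

    hets = np.arange(rare % 2, rare + 1, 2)
    n_aa = (n_ref - hets) // 2 if n_ref <= n_alt else (n_alt - hets) // 2
    n_bb = (n - hets - n_aa)
    # log P(h) ∝ log n! - log nAA! - log h! - log nBB! + h log 2
    logp = (
        gammaln(n + 1) - gammaln(n_aa + 1) - gammaln(hets + 1)
        - gammaln(n_bb + 1) + hets * np.log(2.0)
        + gammaln(n_ref + 1) + gammaln(n_alt + 1) - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[hets == n_het][0]
    # tolerance guards against float round-off excluding ties
    return float(min(1.0, prob[prob <= p_obs * (1.0 + 1e-12)].sum()))


def modified_rogers(matrix: GenotypeMatrix) -> np.ndarray:
    """Pairwise modified Rogers' distance matrix over accessions.

    Encodes each call as its within-accession alt-allele frequency
    (0, 0.5, 1); for accessions a, b sharing L non-missing loci,
    ``d = sqrt(sum_l sum_alleles (x_al - x_bl)^2 / (2L))``, which is 0 for
    identical accessions and 1 for opposite homozygotes at every locus.
    Missing calls are excluded pairwise; a pair with no shared loci raises.
    """
    n = matrix.n_accessions
    if n < 2:
        raise ValueError("need at least 2 accessions for a distance matrix")
    x = matrix.genotypes.astype(float) / 2.0
    called = matrix.called()
    x_filled = np.where(called, x, 0.0)
    c = called.astype(float)

    # expand sum over pairwise-complete loci of (x_a - x_b)^2
    sq = x_filled ** 2
    cross = x_filled @ x_filled.T
    a2 = sq @ c.T                        # sum of x_a^2 over loci called in both
    shared = c @ c.T
    ssd = a2 + a2.T - 2.0 * cross
    zero_pairs = np.argwhere((shared == 0) & ~np.eye(n, dtype=bool))
    if zero_pairs.size:
        i, j = zero_pairs[0]
        raise ValueError(
            f"accessions {matrix.accessions[i]!r} and {matrix.accessions[j]!r} "
            "share no called loci"
        )
    # per-allele squared diffs double the dosage-frequency term: 2*ssd/(2L)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(np.maximum(ssd, 0.0) / shared)
    np.fill_diagonal(d, 0.0)
    return np.minimum(d, 1.0)


_GENOTYPE_CLASSES = (
    "AA", "AC", "AG", "AT", "CC", "CG", "CT", "GG", "GT", "TT"
)


def genotype_class_freqs(matrix: GenotypeMatrix) -> dict[str, float]:
    """Frequencies of the 10 unordered base-pair genotype classes.

    Every non-missing call maps to the unordered pair of its two alleles
    (e.g. a C/T heterozygote to ``CT``, a T/T homozygote to ``TT``);
    frequencies are over all non-missing calls and sum to 1.
    """
    counts = dict.fromkeys(_GENOTYPE_CLASSES, 0)
    total = 0
    for j in range(matrix.n_loci):
        ref, alt = str(matrix.ref[j]), str(matrix.alt[j])
        pairs = {
            0: "".join(sorted(ref + ref)),
            1: "".join(sorted(ref + alt)),
            2: "".join(sorted(alt + alt)),
        }
        g = matrix.genotypes[:, j]
        for dosage, cls in pairs.items():
            k = int((g == dosage).sum())
            counts[cls] += k
            total += k
    if total == 0:
        return dict.fromkeys(_GENOTYPE_CLASSES, 0.0)
    return {cls: n / total for cls, n in counts.items()}


def allele_coverage(full: GenotypeMatrix, subset_ids: list[str]) -> float:
    """Fraction of alleles observed in the full panel also seen in a subset."""
    if not subset_ids:
        raise ValueError("subset must be non-empty")
    sub = full.take_accessions(subset_ids)

    def observed(m: GenotypeMatrix) -> np.ndarray:
        g, called = m.genotypes, m.called()
        has_ref = np.any(called & (g <= 1), axis=0)
        has_alt = np.any(called & (g >= 1), axis=0)
        return np.stack([has_ref, has_alt])

    full_obs = observed(full)
    sub_obs = observed(sub)
    denom = int(full_obs.sum())
    if denom == 0:
        return 1.0
    return float((full_obs & sub_obs).sum() / denom)


def _standardized(matrix: GenotypeMatrix) -> np.ndarray:
    """Center and frequency-standardize genotypes; mean-impute missing."""
    g = matrix.genotypes.astype(float)
    called = matrix.called()
    p = matrix.alt_freq()
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    g = np.where(called, g, 2.0 * p[None, :])[:, keep]
    p = p[keep]
    return (g - 2.0 * p[None, :]) / np.sqrt(p * (1.0 - p))[None, :]


def pca_scores(matrix: GenotypeMatrix, k: int) -> np.ndarray:
    """Top-k principal component scores of the standardized panel.

    Constant (monomorphic) loci are dropped before the decomposition.
    """
    import warnings

    x = _standardized(matrix)
    if x.shape[1] < matrix.n_loci:
        warnings.warn(
            f"dropped {matrix.n_loci - x.shape[1]} constant loci before PCA"
        )
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    return u[:, :k] * s[:k]


def pca_concordance(
    full: GenotypeMatrix, marker_subset, k: int = 3
) -> float:
    """Concordance of PCA structure between all loci and a marker subset.

    Computes top-k PCs from the full panel and from the subset loci alone,
    matches components one-to-one, and returns the mean absolute Pearson
    correlation between matched PC score vectors (sign-invariant, in
    [0, 1]).
    """
    from scipy.optimize import linear_sum_assignment

    sub = full.take_loci(np.asarray(marker_subset))
    if sub.n_loci == 0:
        raise ValueError("marker subset is empty")
    k = min(k, full.n_accessions - 1, full.n_loci, sub.n_loci)
    a = pca_scores(full, k)
    b = pca_scores(sub, k)
    # near-degenerate eigenvalues let components rotate between the two
    # decompositions; pair them by maximal |r| rather than by index
    absr = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if np.std(a[:, i]) == 0 or np.std(b[:, j]) == 0:
                continue
            absr[i, j] = abs(float(np.corrcoef(a[:, i], b[:, j])[0, 1]))
    rows, cols = linear_sum_assignment(-absr)
    return float(absr[rows, cols].mean())
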