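"""KASP assay design and fluorescence genotype calling.

A KASP (Kompetitive Allele-Specific PCR) assay for a biallelic SNP is two
allele-specific forward primers — each carrying a universal fluorescent
tail (FAM or VIC) and ending exactly on the SNP base at its 3' terminus —
plus one common primer on the opposite strand. Design grows each
allele-specific primer leftward from the anchored 3' end (18-30 nt core)
until its melting temperature enters the target window with acceptable GC
content, then places the common primer downstream so the product stays
within the size cap. Flank uniqueness is screened by exact k-mer matching
against the reference on both strands before design.

Melting temperatures use nearest-neighbor thermodynamics (unified
SantaLucia parameter set, 50 mM monovalent salt, 200 nM oligo); tail
bases are never counted in the Tm/GC of allele-specific primers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp, gc_fraction as _bio_gc

from .containers import MISSING, VALID_BASES

#: Universal fluorescent tail prefixes of the two allele-specific primers.
FAM_TAIL = "GAAGGTGACCAAGTTCATGCT"
VIC_TAIL = "GAAGGTCGGAGTCAACGGATT"

PRIMER_MIN_LEN = 18
PRIMER_MAX_LEN = 30

NO_CALL_RADIUS = 0.15


@dataclass
class DesignConstraints:
    """Primer acceptance thresholds."""

    max_gc: float = 0.60
    tm_min: float = 55.0
    tm_max: float = 62.0
    max_product: int = 120
    flank_halfwidth: int = 500

    def validate(self) -> None:
        if not (0 < self.max_gc <= 1 and self.tm_min < self.tm_max
                and self.max_product > 2 * PRIMER_MIN_LEN):
            raise ValueError("design constraint bounds are not ordered")


@dataclass
class KaspAssay:
    """A designed assay with per-primer diagnostics."""

    marker: str
    chrom: str
    pos: int
    allele_x: str
    allele_y: str
    fam_primer: str
    vic_primer: str
    common_primer: str
    product_length: int
    diagnostics: dict = field(default_factory=dict)


@dataclass
class DesignFailure:
    """Structured record of why no compliant primer set exists."""

    marker: str
    chrom: str
    pos: int
    constraint: str         # specificity | tm | gc | product_size | flank
    detail: str = ""


def extract_flanks(
    reference: dict[str, str], chrom: str, pos: int, halfwidth: int = 500
) -> tuple[str, str]:
    """Upstream/downstream flanks around a 1-based SNP position.

    The SNP base itself is excluded. Flanks truncated by a sequence edge
    are returned shorter, with a warning.
    """
    if chrom not in reference:
        raise KeyError(f"unknown chromosome {chrom!r}")
    seq = reference[chrom]
    if not 1 <= pos <= len(seq):
        raise ValueError(f"position {pos} outside {chrom} (length {len(seq)})")
    up = seq[max(0, pos - 1 - halfwidth): pos - 1]
    down = seq[pos: pos + halfwidth]
    if len(up) < halfwidth or len(down) < halfwidth:
        warnings.warn(
            f"flanks at {chrom}:{pos} truncated to {len(up)}/{len(down)} bp"
        )
    return up, down


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def check_specificity(
    flank: str, reference: dict[str, str], k: int = 21
) -> str:
    """``unique`` or ``repetitive`` by exact k-mer matching, both strands.

    The flank is repetitive iff any of its length-k windows occurs more
    than once in the reference (counting both orientations) — a stand-in
    for a BLASTN uniqueness screen.
    """
    if len(flank) < k:
        raise ValueError(f"flank shorter than k={k}")
    counts: dict[str, int] = {}
    for seq in reference.values():
        for strand in (seq, _revcomp(seq)):
            for i in range(len(strand) - k + 1):
                kmer = strand[i: i + k]
                counts[kmer] = counts.get(kmer, 0) + 1
    for i in range(len(flank) - k + 1):
        if counts.get(flank[i: i + k], 0) > 1:
            return "repetitive"
    return "unique"


def gc_fraction(seq: str) -> float:
    """G+C fraction of a primer core."""
    _validate_seq(seq)
    return float(_bio_gc(seq))


def melting_temp(seq: str) -> float:
    """Nearest-neighbor melting temperature in deg C."""
    _validate_seq(seq)
    return float(MeltingTemp.Tm_NN(
        Seq(seq), nn_table=MeltingTemp.DNA_NN3, Na=50, dnac1=200, dnac2=0,
    ))


def _validate_seq(seq: str) -> None:
    if not seq or any(b not in VALID_BASES for b in seq):
        raise ValueError(f"sequence must be non-empty A/C/G/T, got {seq!r}")


def _grow_primer(
    context: str, terminal: str, constraints: DesignConstraints
) -> tuple[str | None, str, dict]:
    """Extend a 3'-anchored primer leftward until Tm/GC comply.

    ``context`` is the sequence immediately 5' of the fixed terminal base.
    Returns (core sequence or None, failing constraint, diagnostics).
    """
    reasons = set()
    for length in range(PRIMER_MIN_LEN, PRIMER_MAX_LEN + 1):
        if length - 1 > len(context):
            reasons.add("flank")
            break
        core = context[len(context) - (length - 1):] + terminal
        tm = melting_temp(core)
        gc = gc_fraction(core)
        if gc >= constraints.max_gc:
            reasons.add("gc")
            continue
        if not constraints.tm_min <= tm <= constraints.tm_max:
            reasons.add("tm")
            continue
        return core, "", {"tm": tm, "gc": gc, "length": length}
    failing = "tm" if "tm" in reasons else ("gc" if "gc" in reasons else "flank")
    return None, failing, {}


def design_assay(
    reference: dict[str, str],
    chrom: str,
    pos: int,
    allele_x: str,
    allele_y: str,
    constraints: DesignConstraints = DesignConstraints(),
    marker: str | None = None,
    check_flanks: bool = True,
) -> KaspAssay | DesignFailure:
    """Design a two-tailed-primer KASP assay for one SNP.

    Pure function of (reference, locus, constraints). Returns a
    :class:`DesignFailure` naming the first unsatisfiable constraint when
    no compliant primer set exists.
    """
    constraints.validate()
    marker = marker or f"{chrom}_{pos}"
    up, down = extract_flanks(reference, chrom, pos, constraints.flank_halfwidth)

    if check_flanks:
        for flank in (up, down):
            if len(flank) >= 21 and check_specificity(flank, reference) == "repetitive":
                return DesignFailure(marker, chrom, pos, "specificity",
                                     "flank k-mers occur repeatedly in reference")

    diagnostics: dict = {}
    cores = {}
    for allele, tail_name in ((allele_x, "fam"), (allele_y, "vic")):
        core, failing, diag = _grow_primer(up, allele, constraints)
        if core is None:
            return DesignFailure(marker, chrom, pos, failing,
                                 f"no compliant {tail_name} allele-specific primer")
        cores[tail_name] = core
        diagnostics[tail_name] = diag

    as_span = max(len(cores["fam"]), len(cores["vic"]))
    common, product_length = None, -1
    reasons = set()
    max_gap = constraints.max_product - as_span - PRIMER_MIN_LEN
    for gap in range(1, max(1, max_gap) + 1):
        for length in range(PRIMER_MIN_LEN, PRIMER_MAX_LEN + 1):
            if gap + length > len(down):
                reasons.add("flank")
                break
            product = as_span + gap + length
            if product > constraints.max_product:
                reasons.add("product_size")
                break
            cand = _revcomp(down[gap - 1: gap - 1 + length])
            tm = melting_temp(cand)
            gc = gc_fraction(cand)
            if gc >= constraints.max_gc:
                reasons.add("gc")
                continue
            if not constraints.tm_min <= tm <= constraints.tm_max:
                reasons.add("tm")
                continue
            common, product_length = cand, product
            diagnostics["common"] = {"tm": tm, "gc": gc, "length": length}
            break
        if common is not None:
            break
    if common is None:
        for key in ("tm", "gc", "product_size", "flank"):
            if key in reasons:
                return DesignFailure(marker, chrom, pos, key,
                                     "no compliant common primer")
        return DesignFailure(marker, chrom, pos, "product_size",
                             "no room for a common primer")

    return KaspAssay(
        marker=marker, chrom=chrom, pos=pos,
        allele_x=allele_x, allele_y=allele_y,
        fam_primer=FAM_TAIL + cores["fam"],
        vic_primer=VIC_TAIL + cores["vic"],
        common_primer=common,
        product_length=product_length,
        diagnostics=diagnostics,
    )


def conversion_rate(n_converted: int, n_tested: int) -> float:
    """Percentage of tested SNPs successfully converted into assays."""
    if n_tested <= 0 or not 0 <= n_converted <= n_tested:
        raise ValueError("invalid conversion counts")
    return round(100.0 * n_converted / n_tested, 1)


def strip_tail(primer: str) -> str:
    """Remove the universal tail prefix from an allele-specific primer."""
    for tail in (FAM_TAIL, VIC_TAIL):
        if primer.startswith(tail):
            return primer[len(tail):]
    raise ValueError("primer carries neither universal tail")


def call_genotypes(points, seed: int = 0) -> tuple[np.ndarray, float]:
    """Call genotypes from (FAM, VIC) endpoint fluorescence.

    Points within 0.15 of the origin are no-calls; the rest are clustered
    by seeded k-means (k=3) and clusters are labeled by centroid position:
    FAM-dominant = X-allele homozygote (dosage 0), VIC-dominant = Y-allele
    homozygote (dosage 2), balanced = heterozygote (dosage 1).

    Returns (dosage labels with -1 for no-call, mean silhouette of the
    clustered points or NaN when undefined).
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError("need at least 4 (fam, vic) points")
    labels = np.full(pts.shape[0], MISSING, dtype=int)
    active = np.linalg.norm(pts, axis=1) >= NO_CALL_RADIUS
    act_pts = pts[active]
    if act_pts.shape[0] == 0:
        return labels, float("nan")

    n_unique = np.unique(act_pts, axis=0).shape[0]
    if n_unique < 3:
        warnings.warn("degenerate fluorescence cloud; nearest-center calls")
        centers = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])
        nearest = np.argmin(
            np.linalg.norm(act_pts[:, None, :] - centers[None], axis=2), axis=1)
        labels[active] = nearest       # center order matches dosage 0/1/2
        return labels, float("nan")

    km = KMeans(n_clusters=3, n_init=10, random_state=seed)
    assign = km.fit_predict(act_pts)
    order = {}
    fam_minus_vic = km.cluster_centers_[:, 0] - km.cluster_centers_[:, 1]
    order[int(np.argmax(fam_minus_vic))] = 0
    order[int(np.argmin(fam_minus_vic))] = 2
    order[({0, 1, 2} - set(order)).pop()] = 1
    labels[active] = [order[a] for a in assign]
    quality = float("nan")
    if len(set(assign)) > 1:
        quality = float(silhouette_score(act_pts, assign))
    return labels, quality
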