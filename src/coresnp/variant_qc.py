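"""SNP retention filters and substitution/region-class summaries.

The retention rule keeps a biallelic SNP iff mean coverage depth is
strictly above ``min_depth``, the missing-call fraction strictly below
``max_missing`` and the minor allele frequency (computed on non-missing
calls) strictly above ``min_maf``. Filters are applied in the order depth
-> missingness -> MAF for per-filter attribution; the retained set itself
is order-independent.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .containers import MISSING, VALID_BASES, GenotypeMatrix

PURINES = frozenset("AG")

REGION_CLASSES = ("exonic", "intronic", "intergenic", "other")
# when BED intervals overlap, the more specific annotation wins
_REGION_PRIORITY = {"exonic": 0, "intronic": 1, "other": 2, "intergenic": 3}


@dataclass
class VariantRecord:
    """One biallelic SNP with its genotype vector and annotations."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotypes: np.ndarray          # dosage vector over accessions, -1 missing
    mean_depth: float = 0.0
    region_class: str = "intergenic"

    def __post_init__(self) -> None:
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise ValueError(
                f"alleles must be A/C/G/T, got {self.ref_allele}/{self.alt_allele}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def n_called(self) -> int:
        return int((self.genotypes != MISSING).sum())

    @property
    def missing_fraction(self) -> float:
        # direct ratio keeps boundary cases (e.g. exactly 10%) exact
        return int((self.genotypes == MISSING).sum()) / self.genotypes.size

    @property
    def maf(self) -> float:
        """Minor allele frequency on non-missing calls; NaN if no data."""
        if self.n_called == 0:
            return float("nan")
        called = self.genotypes[self.genotypes != MISSING]
        p = called.sum() / (2.0 * called.size)
        return float(min(p, 1.0 - p))


@dataclass
class QcReport:
    """Funnel counts and substitution/region summaries for one filter run."""

    n_input: int = 0
    n_retained: int = 0
    rejected_depth: int = 0
    rejected_missing: int = 0
    rejected_maf: int = 0
    rejected_no_data: int = 0
    transitions: int = 0
    transversions: int = 0
    tstv: float = float("nan")
    region_counts: dict[str, int] = field(default_factory=dict)
    region_percent: dict[str, float] = field(default_factory=dict)


def classify_substitution(ref_allele: str, alt_allele: str) -> str:
    """Classify a base substitution as ``transition`` or ``transversion``.

    A<->G and C<->T exchanges (purine<->purine, pyrimidine<->pyrimidine)
    are transitions; every other pair is a transversion.
    """
    for b in (ref_allele, alt_allele):
        if b not in VALID_BASES:
            raise ValueError(f"invalid base {b!r}")
    if ref_allele == alt_allele:
        raise ValueError("ref and alt alleles are identical")
    same_class = (ref_allele in PURINES) == (alt_allele in PURINES)
    return "transition" if same_class else "transversion"


def tstv_ratio(transitions: int, transversions: int) -> float:
    """Transition/transversion ratio, rounded to 3 decimals."""
    if transversions <= 0:
        raise ZeroDivisionError("Ts/Tv undefined with zero transversions")
    return round(transitions / transversions, 3)


def filter_variants(
    records: list[VariantRecord],
    min_depth: float = 4.0,
    max_missing: float = 0.10,
    min_maf: float = 0.005,
) -> tuple[list[VariantRecord], QcReport]:
    """Apply the depth / missingness / MAF retention filters.

    All three thresholds are strict: a record survives iff
    ``mean_depth > min_depth``, ``missing_fraction < max_missing`` and
    ``maf > min_maf``. A locus with no called genotypes is rejected with
    the ``no data`` reason rather than raising.
    """
    if not (min_depth >= 0 and 0 <= max_missing <= 1 and 0 <= min_maf <= 0.5):
        raise ValueError("filter thresholds out of valid ranges")
    report = QcReport(n_input=len(records))
    retained: list[VariantRecord] = []
    for rec in records:
        if not rec.mean_depth > min_depth:
            report.rejected_depth += 1
            continue
        if rec.n_called == 0:
            report.rejected_no_data += 1
            continue
        if not rec.missing_fraction < max_missing:
            report.rejected_missing += 1
            continue
        if not rec.maf > min_maf:
            report.rejected_maf += 1
            continue
        retained.append(rec)
    report.n_retained = len(retained)

    for rec in retained:
        if classify_substitution(rec.ref_allele, rec.alt_allele) == "transition":
            report.transitions += 1
        else:
            report.transversions += 1
    if report.transversions > 0:
        report.tstv = tstv_ratio(report.transitions, report.transversions)
    report.region_counts, report.region_percent = region_summary(retained)
    return retained, report


def region_summary(
    records: list[VariantRecord],
) -> tuple[dict[str, int], dict[str, float]]:
    """Counts and one-decimal percentages of SNPs per region class."""
    counts = Counter(rec.region_class for rec in records)
    total = sum(counts.values())
    percent = {
        cls: round(100.0 * n / total, 1) for cls, n in counts.items()
    } if total else {}
    return dict(counts), percent


def assign_regions(
    records: list[VariantRecord],
    intervals: list[tuple[str, int, int, str]],
) -> None:
    """Annotate records in place from BED intervals (0-based half-open).

    Overlapping intervals resolve by priority exonic > intronic > other;
    positions covered by no interval are ``intergenic``.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, name in intervals:
        cls = name if name in _REGION_PRIORITY else "other"
        by_chrom.setdefault(chrom, []).append((start, end, cls))
    for rec in records:
        zero_based = rec.pos - 1
        best = "intergenic"
        for start, end, cls in by_chrom.get(rec.chrom, ()):
            if start <= zero_based < end and _REGION_PRIORITY[cls] < _REGION_PRIORITY[best]:
                best = cls
        rec.region_class = best


def records_from_matrix(matrix: GenotypeMatrix) -> list[VariantRecord]:
    """View a panel as a list of per-locus variant records."""
    depth = matrix.mean_depth() if matrix.depth is not None else np.zeros(matrix.n_loci)
    return [
        VariantRecord(
            chrom=str(matrix.chrom[j]),
            pos=int(matrix.pos[j]),
            ref_allele=str(matrix.ref[j]),
            alt_allele=str(matrix.alt[j]),
            genotypes=matrix.genotypes[:, j],
            mean_depth=float(depth[j]),
        )
        for j in range(matrix.n_loci)
    ]


def matrix_from_records(
    records: list[VariantRecord], accessions: list[str]
) -> GenotypeMatrix:
    """Assemble retained records back into a panel (depth dropped)."""
    return GenotypeMatrix(
        genotypes=np.array([r.genotypes for r in records], dtype=np.int8).T
        if records else np.empty((len(accessions), 0), dtype=np.int8),
        chrom=np.array([r.chrom for r in records], dtype=object),
        pos=np.array([r.pos for r in records], dtype=np.int64),
        ref=np.array([r.ref_allele for r in records], dtype=object),
        alt=np.array([r.alt_allele for r in records], dtype=object),
        accessions=list(accessions),
    )
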