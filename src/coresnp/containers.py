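"""In-memory containers shared across the pipeline.

The central object is :class:`GenotypeMatrix`: accessions x biallelic loci,
with alt-allele dosage coding (0 = ref-hom, 1 = het, 2 = alt-hom, -1 =
missing), per-cell read depth, and per-locus chromosome/position/allele
metadata. Missing calls are a distinct state and are excluded from every
frequency denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -1

VALID_BASES = frozenset("ACGT")


@dataclass
class GenotypeMatrix:
    """Accessions x loci biallelic genotype panel.

    Parameters
    ----------
    genotypes
        ``(n_accessions, n_loci)`` int8 array of alt-allele dosages;
        ``-1`` marks a missing call.
    chrom, pos, ref, alt
        Per-locus metadata; ``pos`` is 1-based.
    depth
        Optional ``(n_accessions, n_loci)`` read-depth array.
    accessions
        Sample identifiers, one per row.
    """

    genotypes: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    accessions: list[str] = field(default_factory=list)
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        n, m = self.genotypes.shape
        if not self.accessions:
            self.accessions = [f"S{i + 1}" for i in range(n)]
        if len(self.accessions) != n:
            raise ValueError(
                f"{len(self.accessions)} accession ids for {n} genotype rows"
            )
        for name, arr in (("chrom", self.chrom), ("pos", self.pos),
                          ("ref", self.ref), ("alt", self.alt)):
            if arr.shape != (m,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({m},)")
        if self.depth is not None and self.depth.shape != (n, m):
            raise ValueError("depth shape does not match genotypes")

    @property
    def n_accessions(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing cells."""
        return self.genotypes != MISSING

    def missing_fraction(self) -> np.ndarray:
        """Per-locus fraction of missing calls."""
        return (self.genotypes == MISSING).mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Per-locus alt-allele frequency on non-missing calls (NaN if none)."""
        called = self.called()
        n_called = called.sum(axis=0)
        alt_count = np.where(called, self.genotypes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt_count / (2.0 * n_called), np.nan)

    def maf(self) -> np.ndarray:
        """Per-locus minor allele frequency (NaN where no calls)."""
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def mean_depth(self) -> np.ndarray:
        """Per-locus mean read depth over all cells."""
        if self.depth is None:
            raise ValueError("panel carries no depth information")
        return self.depth.mean(axis=0, dtype=float)

    def accession_index(self, ids: list[str]) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accessions)}
        try:
            return np.array([lookup[a] for a in ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown accession id: {exc.args[0]!r}") from None

    def take_accessions(self, ids: list[str]) -> "GenotypeMatrix":
        idx = self.accession_index(ids)
        return replace(
            self,
            genotypes=self.genotypes[idx],
            accessions=[self.accessions[i] for i in idx],
            depth=None if self.depth is None else self.depth[idx],
        )

    def take_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            genotypes=self.genotypes[:, idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            depth=None if self.depth is None else self.depth[:, idx],
        )
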