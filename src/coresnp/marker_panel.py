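"""Fingerprint-marker screening, uniform thinning, minimal marker sets.

The screen keeps loci with no missing calls, MAF at or above the 0.5%
floor, PIC strictly above 0.4, exact-test Hardy-Weinberg p strictly above
1e-6, and no neighboring variant within 200 bp on either side; survivors
are ranked by PIC and capped at 500 candidates. Thinning to the final
panel (default 100) assigns per-chromosome quotas proportional to
chromosome length (largest remainder, candidate-bearing chromosomes get at
least one) and maximizes the minimum pairwise spacing within each
chromosome, breaking ties toward higher PIC. Minimal discriminating sets
are built by greedy set cover over unordered accession pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import MISSING, GenotypeMatrix
from .popgen_stats import LocusStats


@dataclass
class ScreenCriteria:
    """Fingerprint candidate screening thresholds."""

    min_maf: float = 0.005
    min_pic: float = 0.4
    min_hwe_p: float = 1e-6
    flank_exclusion_bp: int = 200
    require_no_missing: bool = True
    n_candidates: int = 500
    n_core: int = 100

    def validate(self) -> None:
        if min(self.min_maf, self.min_pic, self.min_hwe_p) <= 0:
            raise ValueError("screen thresholds must be positive")
        if self.flank_exclusion_bp <= 0 or self.n_candidates <= 0:
            raise ValueError("screen thresholds must be positive")
        if self.n_core > self.n_candidates:
            raise ValueError("n_core must not exceed n_candidates")


@dataclass
class PanelLocus:
    """One marker of a fingerprint panel."""

    index: int                      # column index into the source matrix
    chrom: str
    pos: int
    ref: str
    alt: str
    stats: LocusStats


@dataclass
class MarkerPanel:
    """Ordered marker set with panel-level summaries."""

    loci: list[PanelLocus]
    mean_maf: float = field(init=False)
    mean_ho: float = field(init=False)
    pic_range: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.loci = sorted(self.loci, key=lambda l: (l.chrom, l.pos))
        if self.loci:
            mafs = [l.stats.maf for l in self.loci]
            hos = [l.stats.ho for l in self.loci]
            pics = [l.stats.pic for l in self.loci]
            self.mean_maf = float(np.mean(mafs))
            self.mean_ho = float(np.mean(hos))
            self.pic_range = (float(min(pics)), float(max(pics)))
        else:
            self.mean_maf = self.mean_ho = float("nan")
            self.pic_range = (float("nan"), float("nan"))

    @property
    def indices(self) -> np.ndarray:
        return np.array([l.index for l in self.loci], dtype=np.intp)

    def __len__(self) -> int:
        return len(self.loci)


def screen_candidates(
    matrix: GenotypeMatrix,
    stats: list[LocusStats],
    criteria: ScreenCriteria = ScreenCriteria(),
) -> list[PanelLocus]:
    """Apply the fingerprint screening criteria to a filtered panel.

    ``stats`` must carry ``hwe_p`` (see ``panel_diversity(hwe=True)``).
    Survivors are ranked by PIC descending and capped at
    ``criteria.n_candidates``; if fewer survive, all are returned with a
    warning, never padded.
    """
    criteria.validate()
    if len(stats) != matrix.n_loci:
        raise ValueError("one LocusStats per locus required")

    order = np.lexsort((matrix.pos, matrix.chrom.astype(str)))
    pos_by_chrom: dict[str, np.ndarray] = {}
    for c in set(matrix.chrom.astype(str)):
        mask = matrix.chrom.astype(str) == c
        pos_by_chrom[c] = np.sort(matrix.pos[mask])

    survivors: list[PanelLocus] = []
    for j in range(matrix.n_loci):
        s = stats[j]
        g = matrix.genotypes[:, j]
        if criteria.require_no_missing and np.any(g == MISSING):
            continue
        if not s.maf >= criteria.min_maf:
            continue
        # the 0.4 polymorphism gate operates on the gene-diversity scale
        # (max 0.5), on which fingerprinting protocols print their "PIC"
        # column; the strict biallelic PIC formula caps at 0.375 and would
        # retain nothing at 0.4
        if not s.nei > criteria.min_pic:
            continue
        if np.isnan(s.hwe_p) or not s.hwe_p > criteria.min_hwe_p:
            continue
        chrom, pos = str(matrix.chrom[j]), int(matrix.pos[j])
        neighbors = pos_by_chrom[chrom]
        near = neighbors[np.abs(neighbors - pos) <= criteria.flank_exclusion_bp]
        if near.size > 1:       # itself plus any neighbor within the window
            continue
        survivors.append(PanelLocus(
            index=j, chrom=chrom, pos=pos,
            ref=str(matrix.ref[j]), alt=str(matrix.alt[j]), stats=s,
        ))

    survivors.sort(key=lambda l: (-l.stats.pic, l.chrom, l.pos))
    if len(survivors) < criteria.n_candidates:
        warnings.warn(
            f"only {len(survivors)} loci survive the screen "
            f"(requested {criteria.n_candidates})"
        )
    return survivors[: criteria.n_candidates]


def _largest_remainder_quotas(
    weights: dict[str, float], available: dict[str, int], total: int
) -> dict[str, int]:
    """Length-proportional integer quotas, each key >= 1, capped by supply."""
    keys = [k for k in weights if available.get(k, 0) > 0]
    if not keys:
        return {}
    w = np.array([weights[k] for k in keys], dtype=float)
    w = w / w.sum()
    raw = w * total
    quota = {k: max(1, int(np.floor(r))) for k, r in zip(keys, raw)}
    quota = {k: min(q, available[k]) for k, q in quota.items()}
    # distribute the remainder by largest fractional part, then round-robin
    # over chromosomes with spare candidates
    rema = sorted(keys, key=lambda k: -(raw[keys.index(k)] % 1.0))
    while sum(quota.values()) < min(total, sum(available[k] for k in keys)):
        progressed = False
        for k in rema:
            if sum(quota.values()) >= total:
                break
            if quota[k] < available[k]:
                quota[k] += 1
                progressed = True
        if not progressed:
            break
    # trim any overshoot from the smallest fractional parts
    while sum(quota.values()) > total:
        for k in reversed(rema):
            if quota[k] > 1:
                quota[k] -= 1
                break
        else:
            break
    return quota


def _maxmin_spacing_select(loci: list[PanelLocus], quota: int) -> list[PanelLocus]:
    """Choose ``quota`` loci maximizing minimum pairwise spacing.

    Binary search on the achievable spacing (greedy left-to-right
    feasibility is exact on a line), then a deterministic construction
    that prefers higher PIC among choices preserving that spacing.
    """
    loci = sorted(loci, key=lambda l: l.pos)
    if quota >= len(loci):
        return loci
    if quota == 1:
        return [max(loci, key=lambda l: l.stats.pic)]
    pos = np.array([l.pos for l in loci])

    def feasible(d: int) -> bool:
        count, last = 1, pos[0]
        for p in pos[1:]:
            if p - last >= d:
                count += 1
                last = p
        return count >= quota

    lo, hi = 0, int(pos[-1] - pos[0])
    while lo < hi:                      # max d with greedy count >= quota
        mid = (lo + hi + 1) // 2
        if feasible(mid):
            lo = mid
        else:
            hi = mid - 1
    d_star = lo

    def suffix_capacity(start_idx: int) -> int:
        count, last = 1, pos[start_idx]
        for p in pos[start_idx + 1:]:
            if p - last >= d_star:
                count += 1
                last = p
        return count

    chosen: list[PanelLocus] = []
    i = 0
    remaining = quota
    last_pos = None
    while remaining > 0:
        window = [
            j for j in range(i, len(loci))
            if (last_pos is None or pos[j] - last_pos >= d_star)
            and suffix_capacity(j) >= remaining
        ]
        j = max(window, key=lambda j: (loci[j].stats.pic, -pos[j]))
        chosen.append(loci[j])
        last_pos = pos[j]
        i = j + 1
        remaining -= 1
    return chosen


def thin_uniform(
    candidates: list[PanelLocus],
    chrom_lengths: dict[str, int],
    n_core: int = 100,
) -> MarkerPanel:
    """Thin screened candidates to an evenly distributed core panel."""
    if not candidates:
        raise ValueError("no candidate loci to thin")
    n_core = min(n_core, len(candidates))
    by_chrom: dict[str, list[PanelLocus]] = {}
    for l in candidates:
        by_chrom.setdefault(l.chrom, []).append(l)
    lengths = {
        c: float(chrom_lengths.get(c, max(l.pos for l in loci)))
        for c, loci in by_chrom.items()
    }
    quotas = _largest_remainder_quotas(
        lengths, {c: len(v) for c, v in by_chrom.items()}, n_core
    )
    chosen: list[PanelLocus] = []
    for c, q in quotas.items():
        chosen.extend(_maxmin_spacing_select(by_chrom[c], q))
    return MarkerPanel(loci=chosen)


def _separation_matrix(matrix: GenotypeMatrix) -> np.ndarray:
    """(L, n_pairs) booleans: locus separates the unordered accession pair.

    A pair is separated only where both calls are non-missing and differ.
    """
    g = matrix.genotypes
    n = matrix.n_accessions
    iu, ju = np.triu_indices(n, k=1)
    a, b = g[iu, :], g[ju, :]
    sep = (a != b) & (a != MISSING) & (b != MISSING)
    return sep.T, (iu, ju)


def min_discriminating_set(
    matrix: GenotypeMatrix, pic: list[float] | None = None
) -> tuple[list[int], list[tuple[str, str]]]:
    """Greedy minimum set of loci distinguishing all separable pairs.

    Repeatedly picks the locus separating the most still-unseparated
    pairs (ties to higher PIC, then lower locus index) until every
    separable pair is covered. Returns the chosen locus column indices in
    pick order and the accession pairs no locus can separate.
    """
    if matrix.n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    sep, (iu, ju) = _separation_matrix(matrix)
    if pic is None:
        pic = [0.0] * matrix.n_loci
    separable = sep.any(axis=0)
    unresolved_idx = np.flatnonzero(~separable)
    uncovered = separable.copy()
    chosen: list[int] = []
    while uncovered.any():
        gains = sep[:, uncovered].sum(axis=1)
        best_gain = gains.max()
        if best_gain == 0:
            break
        tied = np.flatnonzero(gains == best_gain)
        j = int(tied[np.lexsort((tied, [-pic[t] for t in tied]))[0]])
        chosen.append(j)
        uncovered &= ~sep[j]
    unresolved = [
        (matrix.accessions[iu[k]], matrix.accessions[ju[k]])
        for k in unresolved_idx
    ]
    return chosen, unresolved


def discrimination_power(matrix: GenotypeMatrix, panel_indices=None) -> float:
    """Fraction of accession pairs distinguishable by the panel loci."""
    if matrix.n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    m = matrix if panel_indices is None else matrix.take_loci(
        np.asarray(panel_indices))
    sep, _ = _separation_matrix(m)
    if sep.shape[0] == 0:
        return 0.0
    return float(sep.any(axis=0).mean())
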