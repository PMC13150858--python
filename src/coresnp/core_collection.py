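"""Weighted core-collection selection.

A core subset of a germplasm panel is scored by a weighted multicriteria
objective: ``w_d * (mean pairwise modified Rogers' distance within the
subset) + w_s * (mean per-locus Shannon index within the subset)``, with
default weights 0.7 / 0.3. The search is a deterministic greedy
construction (iteratively add the accession that maximizes the objective)
followed by steepest-ascent 1-swap local search; an exhaustive strategy is
available for small panels. The sampling fraction is a configuration
input: the fraction sweep is reported, the final choice is the user's.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .containers import MISSING, GenotypeMatrix
from .popgen_stats import genotype_class_freqs, locus_diversity, modified_rogers

_STAT_NAMES = ("ho", "he", "nei", "shannon", "pic")


@dataclass
class CoreConfig:
    """Search parameters for core selection."""

    fraction: float = 0.2
    weight_distance: float = 0.7
    weight_shannon: float = 0.3
    search: str = "greedy"          # "greedy" (+ local search) or "exhaustive"
    max_steps: int = 500
    n_restarts: int = 6
    seed: int = 0

    def validate(self, n_accessions: int) -> int:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction must lie in (0, 1)")
        if self.weight_distance < 0 or self.weight_shannon < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.weight_distance + self.weight_shannon - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        size = _round_half_even(self.fraction * n_accessions)
        if size < 2:
            raise ValueError(
                f"fraction {self.fraction} yields subset size {size} < 2"
            )
        return min(size, n_accessions)


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


@dataclass
class CoreSubset:
    """A selected core with its objective, coverage and diversity summary."""

    accessions: list[str]
    objective: float
    coverage: float = float("nan")
    diversity: dict[str, float] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.accessions)


class _ObjectiveState:
    """Incremental evaluation of the weighted objective.

    Maintains, for the current subset, per-locus alt-allele and called
    counts (for the Shannon term) and the sum of within-subset pairwise
    distances (for the distance term), so candidate additions and swaps
    are evaluated in O(L) vectorized work.
    """

    def __init__(self, matrix: GenotypeMatrix, w_dist: float, w_shan: float):
        self.w_dist = w_dist
        self.w_shan = w_shan
        self.D = modified_rogers(matrix) if w_dist > 0 else np.zeros(
            (matrix.n_accessions, matrix.n_accessions))
        g = matrix.genotypes
        self.dosage = np.where(g == MISSING, 0, g).astype(np.float32)  # (N, L)
        self.calledm = (g != MISSING).astype(np.float32)
        self.n_loci = matrix.n_loci

    @staticmethod
    def _shannon_mean(alt: np.ndarray, called: np.ndarray) -> np.ndarray:
        """Mean per-locus base-2 Shannon index; loci without data count 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called > 0, alt / (2.0 * called), 0.0)
        q = 1.0 - p
        h = np.zeros_like(p)
        for f in (p, q):
            nz = f > 0
            h -= np.where(nz, f * np.log2(np.where(nz, f, 1.0)), 0.0)
        return h.mean(axis=-1)

    def objective_of(self, idx: np.ndarray) -> float:
        k = idx.size
        dist = self.D[np.ix_(idx, idx)].sum() / (k * (k - 1)) if k > 1 else 0.0
        shan = self._shannon_mean(
            self.dosage[idx].sum(axis=0).astype(float),
            self.calledm[idx].sum(axis=0).astype(float),
        )
        return self.w_dist * dist + self.w_shan * float(shan)

    def addition_gains(self, idx: np.ndarray, candidates: np.ndarray) -> np.ndarray:
        """Objective value of idx + {c} for every candidate c."""
        k = idx.size + 1
        dist_sums = self.D[np.ix_(idx, idx)].sum() + 2.0 * self.D[candidates][:, idx].sum(axis=1)
        dist = dist_sums / (k * (k - 1)) if k > 1 else np.zeros(candidates.size)
        alt = self.dosage[idx].sum(axis=0)[None, :] + self.dosage[candidates]
        called = self.calledm[idx].sum(axis=0)[None, :] + self.calledm[candidates]
        shan = self._shannon_mean(alt.astype(float), called.astype(float))
        return self.w_dist * dist + self.w_shan * shan


def subset_objective(
    matrix: GenotypeMatrix,
    subset_ids: list[str],
    weights: tuple[float, float] = (0.7, 0.3),
) -> float:
    """Weighted distance + Shannon objective of a given accession subset."""
    if len(subset_ids) < 2:
        raise ValueError("subset must contain at least 2 accessions")
    w_dist, w_shan = weights
    state = _ObjectiveState(matrix, w_dist, w_shan)
    idx = matrix.accession_index(subset_ids)
    return float(state.objective_of(idx))


def _diversity_summary(matrix: GenotypeMatrix) -> dict[str, float]:
    stats = []
    for j in range(matrix.n_loci):
        g = matrix.genotypes[:, j]
        if np.all(g == MISSING):
            continue
        stats.append(locus_diversity(g))
    if not stats:
        return {name: float("nan") for name in _STAT_NAMES}
    return {
        name: float(np.mean([getattr(s, name) for s in stats]))
        for name in _STAT_NAMES
    }


def select_core(matrix: GenotypeMatrix, config: CoreConfig) -> CoreSubset:
    """Select a core subset of ``round(fraction * N)`` accessions.

    Greedy construction from the strongest seed pair, then steepest-ascent
    1-swap local search until no improving swap or ``max_steps`` swaps.
    The result never scores below a seeded random subset of the same size.
    With ``search="exhaustive"`` all subsets are enumerated (small panels
    only).
    """
    from .popgen_stats import allele_coverage

    n = matrix.n_accessions
    size = config.validate(n)
    state = _ObjectiveState(matrix, config.weight_distance, config.weight_shannon)

    if size >= n:
        idx = np.arange(n)
    elif config.search == "exhaustive":
        idx = _exhaustive_search(state, n, size)
    elif config.search == "greedy":
        idx = _greedy_search(state, n, size, config.max_steps)
        best_obj = state.objective_of(idx)
        # seeded basin hopping: re-descend from perturbed copies of the
        # incumbent (escapes the occasional 1-swap local optimum of pure
        # greedy while staying close enough to converge quickly)
        rng = np.random.default_rng(config.seed)
        for _ in range(config.n_restarts):
            start = _perturb(idx, n, rng)
            cand = _local_search(state, start, n, config.max_steps)
            obj = state.objective_of(cand)
            if obj > best_obj:
                idx, best_obj = cand, obj
        random_idx = np.sort(rng.choice(n, size=size, replace=False))
        if state.objective_of(random_idx) > best_obj:   # pragma: no cover
            idx = _local_search(state, random_idx, n, config.max_steps)
    else:
        raise ValueError(f"unknown search strategy {config.search!r}")

    ids = [matrix.accessions[i] for i in idx]
    sub = matrix.take_accessions(ids)
    return CoreSubset(
        accessions=ids,
        objective=float(state.objective_of(np.asarray(idx))),
        coverage=allele_coverage(matrix, ids),
        diversity=_diversity_summary(sub),
    )


def _exhaustive_search(state: _ObjectiveState, n: int, size: int) -> np.ndarray:
    best, best_obj = None, -np.inf
    for combo in itertools.combinations(range(n), size):
        obj = state.objective_of(np.asarray(combo))
        if obj > best_obj:
            best, best_obj = combo, obj
    return np.asarray(best)


def _perturb(idx: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Swap ~20% of the subset for random outsiders (at least one)."""
    outside = np.setdiff1d(np.arange(n), idx)
    k = min(max(1, idx.size // 5), outside.size)
    if k == 0:
        return idx
    keep = rng.choice(idx, size=idx.size - k, replace=False)
    add = rng.choice(outside, size=k, replace=False)
    return np.sort(np.concatenate([keep, add]))


def _greedy_search(state, n: int, size: int, max_steps: int) -> np.ndarray:
    # seed pair: the best 2-subset containing the most distant pair's anchor
    if state.w_dist > 0:
        i0 = int(np.unravel_index(np.argmax(state.D), state.D.shape)[0])
    else:
        i0 = int(np.argmax((state.dosage == 1).sum(axis=1)))
    chosen = [i0]
    remaining = np.array([i for i in range(n) if i != i0])
    while len(chosen) < size:
        gains = state.addition_gains(np.asarray(chosen), remaining)
        best = int(np.argmax(gains))
        chosen.append(int(remaining[best]))
        remaining = np.delete(remaining, best)
    return _local_search(state, np.asarray(sorted(chosen)), n, max_steps)


def _local_search(state, idx: np.ndarray, n: int, max_steps: int) -> np.ndarray:
    """Steepest-ascent 1-swap until no improvement or max_steps swaps."""
    current = set(int(i) for i in idx)
    obj = state.objective_of(np.asarray(sorted(current)))
    for _ in range(max_steps):
        best_swap, best_obj = None, obj + 1e-12
        outside = np.array([i for i in range(n) if i not in current])
        if outside.size == 0:
            break
        for r in sorted(current):
            base = np.array(sorted(current - {r}))
            gains = state.addition_gains(base, outside)
            j = int(np.argmax(gains))
            if gains[j] > best_obj:
                best_obj = float(gains[j])
                best_swap = (r, int(outside[j]))
        if best_swap is None:
            break
        r, a = best_swap
        current.remove(r)
        current.add(a)
        obj = best_obj
    return np.array(sorted(current))


def sweep_fractions(
    matrix: GenotypeMatrix, fractions: list[float], config: CoreConfig
):
    """Run the core selector at each sampling fraction.

    Returns a pandas DataFrame with one row per fraction: subset size,
    objective, allele coverage and mean diversity statistics.
    """
    import pandas as pd
    from dataclasses import replace

    rows, subsets = [], []
    for frac in fractions:
        sub = select_core(matrix, replace(config, fraction=frac))
        subsets.append(sub)
        rows.append({
            "fraction": frac, "size": sub.size,
            "objective": sub.objective, "coverage": sub.coverage,
            **{f"mean_{k}": v for k, v in sub.diversity.items()},
        })
    table = pd.DataFrame(rows)
    table.attrs["subsets"] = subsets
    return table


def compare_core_full(matrix: GenotypeMatrix, subset: CoreSubset) -> dict:
    """Diversity comparison of the core subset against the full panel.

    Reports per-statistic mean and range for both sets, MAF histograms in
    0.1-wide bins, the 10-class genotype frequency curves, and the
    least-squares linear fit of core-vs-full genotype frequencies.
    """
    core = matrix.take_accessions(subset.accessions)

    def stat_table(m: GenotypeMatrix) -> dict[str, dict[str, float]]:
        per_locus = {name: [] for name in _STAT_NAMES}
        for j in range(m.n_loci):
            g = m.genotypes[:, j]
            if np.all(g == MISSING):
                continue
            s = locus_diversity(g)
            for name in _STAT_NAMES:
                per_locus[name].append(getattr(s, name))
        return {
            name: {
                "mean": float(np.mean(vals)), "min": float(np.min(vals)),
                "max": float(np.max(vals)),
            }
            for name, vals in per_locus.items() if vals
        }

    def maf_hist(m: GenotypeMatrix) -> list[int]:
        maf = m.maf()
        maf = maf[np.isfinite(maf)]
        counts, _ = np.histogram(maf, bins=np.arange(0.0, 0.6, 0.1))
        return counts.tolist()

    full_freqs = genotype_class_freqs(matrix)
    core_freqs = genotype_class_freqs(core)
    x = np.array([full_freqs[c] for c in full_freqs])
    y = np.array([core_freqs[c] for c in full_freqs])
    slope, intercept = np.polyfit(x, y, 1) if np.ptp(x) > 0 else (1.0, 0.0)

    return {
        "full": stat_table(matrix),
        "core": stat_table(core),
        "maf_hist_full": maf_hist(matrix),
        "maf_hist_core": maf_hist(core),
        "maf_bin_edges": [round(e, 1) for e in np.arange(0.0, 0.6, 0.1)],
        "genotype_freqs_full": full_freqs,
        "genotype_freqs_core": core_freqs,
        "genotype_fit": {"slope": float(slope), "intercept": float(intercept)},
    }
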