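"""Fingerprint screen, uniform thinning and minimal discriminating sets."""

import itertools

import numpy as np
import pytest

from coresnp.marker_panel import (
    PanelLocus, ScreenCriteria, discrimination_power, min_discriminating_set,
    screen_candidates, thin_uniform,
)
from coresnp.popgen_stats import LocusStats, panel_diversity
from conftest import make_matrix


def stats_for(matrix):
    return panel_diversity(matrix, hwe=True)


def locus(pos, pic=0.3, chrom="Chr01"):
    return PanelLocus(
        index=0, chrom=chrom, pos=pos, ref="A", alt="G",
        stats=LocusStats(maf=0.3, ho=0.4, he=0.42, nei=0.42, shannon=0.88,
                         pic=pic, hwe_p=0.5),
    )


def hw_column(rng, p, n):
    """A column in Hardy-Weinberg proportions at frequency p."""
    return rng.binomial(1, p, size=(n, 2)).sum(axis=1)


class TestScreenCandidates:
    @pytest.fixture()
    def good_panel(self):
        rng = np.random.default_rng(0)
        n = 60
        g = np.column_stack([hw_column(rng, 0.45, n) for _ in range(8)])
        return make_matrix(
            g, pos=np.arange(1, 9) * 10_000,
            chrom=["Chr01"] * 8,
        )

    def test_clean_panel_survives(self, good_panel):
        survivors = screen_candidates(good_panel, stats_for(good_panel))
        assert 0 < len(survivors) <= 8

    def test_low_diversity_rejected(self, good_panel):
        """A locus whose gene diversity sits below the 0.4 gate is dropped."""
        g = good_panel.genotypes.copy()
        g[:, 0] = 0
        g[0, 0] = 1                         # MAF ~ 0.008: well below the gate
        m = make_matrix(g, pos=good_panel.pos, chrom=["Chr01"] * 8)
        survivors = screen_candidates(m, stats_for(m))
        assert 0 not in {s.index for s in survivors}

    def test_missing_call_rejected(self, good_panel):
        g = good_panel.genotypes.copy()
        g[3, 1] = -1
        m = make_matrix(g, pos=good_panel.pos, chrom=["Chr01"] * 8)
        survivors = screen_candidates(m, stats_for(m))
        assert 1 not in {s.index for s in survivors}

    def test_hwe_violation_rejected(self, good_panel):
        g = good_panel.genotypes.copy()
        g[:, 2] = [0, 2] * 30               # no hets at p=0.5: extreme excess
        m = make_matrix(g, pos=good_panel.pos, chrom=["Chr01"] * 8)
        survivors = screen_candidates(m, stats_for(m))
        assert 2 not in {s.index for s in survivors}

    def test_mutual_flank_violation(self, good_panel):
        pos = np.array(good_panel.pos)
        pos[1] = pos[0] + 150               # 150 bp apart: both must go
        m = make_matrix(good_panel.genotypes, pos=pos, chrom=["Chr01"] * 8)
        survivors = screen_candidates(m, stats_for(m))
        assert {0, 1}.isdisjoint({s.index for s in survivors})

    def test_pure_filter_and_idempotent(self, structured_panel):
        matrix, _ = structured_panel
        stats = stats_for(matrix)
        survivors = screen_candidates(matrix, stats, ScreenCriteria(
            n_candidates=500, n_core=100))
        assert {s.index for s in survivors} <= set(range(matrix.n_loci))
        again = screen_candidates(matrix, stats, ScreenCriteria(
            n_candidates=500, n_core=100))
        assert [s.index for s in survivors] == [s.index for s in again]

    def test_fewer_survivors_warns_never_pads(self, good_panel):
        with pytest.warns(UserWarning, match="survive"):
            survivors = screen_candidates(
                good_panel, stats_for(good_panel),
                ScreenCriteria(n_candidates=500, n_core=100))
        assert len(survivors) <= 8


class TestThinUniform:
    def test_equal_chromosome_quotas(self):
        rng = np.random.default_rng(1)
        cands = []
        for c in range(12):
            for i in range(42):
                cands.append(locus(
                    pos=int(rng.integers(1000, 999_000)),
                    pic=float(rng.uniform(0.3, 0.375)),
                    chrom=f"Chr{c + 1:02d}"))
        lengths = {f"Chr{c + 1:02d}": 1_000_000 for c in range(12)}
        panel = thin_uniform(cands, lengths, 100)
        assert len(panel) == 100
        per_chrom = {c: sum(1 for l in panel.loci if l.chrom == c)
                     for c in lengths}
        assert all(8 <= q <= 9 for q in per_chrom.values())

    def test_maxmin_spacing_matches_exhaustive(self):
        """Selected spacing equals the exhaustive max-min optimum."""
        rng = np.random.default_rng(4)
        positions = sorted(rng.choice(10_000, size=12, replace=False))
        cands = [locus(int(p), pic=float(rng.uniform(0.3, 0.375)))
                 for p in positions]
        panel = thin_uniform(cands, {"Chr01": 10_000}, 5)
        got = min(np.diff(sorted(l.pos for l in panel.loci)))
        best = max(
            min(np.diff(sorted(c)))
            for c in itertools.combinations(positions, 5)
        )
        assert got == best

    def test_spacing_on_uniform_grid(self):
        cands = [locus(pos=k * 1000) for k in range(1, 1001)]
        panel = thin_uniform(cands, {"Chr01": 1_000_000}, 10)
        gaps = np.diff(sorted(l.pos for l in panel.loci))
        assert gaps.min() >= 0.9 * 100_000

    def test_quota_larger_than_candidates(self):
        cands = [locus(pos=p) for p in (1000, 50_000, 200_000)]
        panel = thin_uniform(cands, {"Chr01": 1_000_000}, 100)
        assert len(panel) == 3

    def test_respects_flank_spacing(self, structured_panel):
        matrix, _ = structured_panel
        stats = panel_diversity(matrix, hwe=True)
        cands = screen_candidates(matrix, stats, ScreenCriteria(
            n_candidates=500, n_core=100))
        panel = thin_uniform(cands, {}, 60)
        by_chrom = {}
        for l in panel.loci:
            by_chrom.setdefault(l.chrom, []).append(l.pos)
        for pos in by_chrom.values():
            if len(pos) > 1:
                assert min(np.diff(sorted(pos))) > 200

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            thin_uniform([], {"Chr01": 1000}, 10)


class TestMinDiscriminatingSet:
    def test_single_locus_hand_case(self):
        """[0,1,2,0]: accessions 1 and 4 stay inseparable."""
        m = make_matrix([[0], [1], [2], [0]])
        chosen, unresolved = min_discriminating_set(m)
        assert chosen == [0]
        assert unresolved == [(m.accessions[0], m.accessions[3])]

    def test_all_identical(self):
        m = make_matrix([[1, 1], [1, 1], [1, 1]])
        chosen, unresolved = min_discriminating_set(m)
        assert chosen == []
        assert len(unresolved) == 3

    def test_greedy_near_optimal_vs_brute_force(self):
        """Greedy separates all separable pairs within +1 of the optimum."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            g = rng.integers(0, 3, size=(8, 6))
            m = make_matrix(g)
            chosen, unresolved = min_discriminating_set(m)
            sep = {
                (i, j)
                for i in range(8) for j in range(i + 1, 8)
                if any(g[i, l] != g[j, l] for l in range(6))
            }
            covered = {
                (i, j)
                for i in range(8) for j in range(i + 1, 8)
                if any(g[i, l] != g[j, l] for l in chosen)
            }
            assert covered == sep
            optimum = next(
                k for k in range(0, 7)
                if any(
                    all(any(g[i, l] != g[j, l] for l in combo)
                        for i, j in sep)
                    for combo in itertools.combinations(range(6), k)
                )
            )
            assert len(chosen) <= optimum + 1

    def test_never_invents_discrimination(self, clean_panel):
        matrix, _ = clean_panel
        sub = matrix.take_loci(np.arange(30))
        chosen, _ = min_discriminating_set(sub)
        assert discrimination_power(sub, chosen) == pytest.approx(
            discrimination_power(sub))


class TestDiscriminationPower:
    def test_all_distinct(self):
        m = make_matrix([[0, 1], [1, 0], [2, 2]])
        assert discrimination_power(m) == 1.0

    def test_two_clones(self):
        g = np.array([[0, 1, 2], [0, 1, 2], [1, 0, 2], [2, 2, 0]])
        m = make_matrix(g)
        n_pairs = 6
        assert discrimination_power(m) == pytest.approx(1 - 1 / n_pairs)

    def test_monomorphic_locus(self):
        m = make_matrix([[1], [1], [1]])
        assert discrimination_power(m) == 0.0

    def test_monotone_in_panel_size(self, clean_panel):
        matrix, _ = clean_panel
        powers = [discrimination_power(matrix, np.arange(k))
                  for k in (1, 3, 10, 50)]
        assert all(a <= b + 1e-12 for a, b in zip(powers, powers[1:]))

    def test_missing_never_separates(self):
        m = make_matrix([[-1, 0], [1, 0]])
        assert discrimination_power(m, [0]) == 0.0
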