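"""Diversity statistics against independent straight-from-formula oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest

from coresnp.popgen_stats import (
    allele_coverage, genotype_class_freqs, hwe_exact_test, locus_diversity,
    modified_rogers, panel_diversity, pca_concordance, pca_scores,
)
from conftest import make_matrix


def hwe_enumeration_oracle(n_refhom: int, n_het: int, n_althom: int) -> Fraction:
    """Exact-rational enumeration of the conditional HWE distribution."""
    n = n_refhom + n_het + n_althom
    n_a = 2 * n_refhom + n_het
    n_b = 2 * n_althom + n_het

    def weight(h: int) -> Fraction:
        aa = (n_a - h) // 2
        bb = (n_b - h) // 2
        return Fraction(
            math.factorial(n) * 2 ** h,
            math.factorial(aa) * math.factorial(h) * math.factorial(bb),
        )

    hets = range(min(n_a, n_b) % 2, min(n_a, n_b) + 1, 2)
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    observed = weights[n_het]
    return sum(w for w in weights.values() if w <= observed) / total


class TestLocusDiversity:
    def test_closed_forms_at_half(self):
        s = locus_diversity([0, 1, 1, 2] * 25)
        assert s.he == pytest.approx(0.5)
        assert s.shannon == pytest.approx(1.0)
        assert s.pic == pytest.approx(0.375)

    def test_monomorphic(self):
        s = locus_diversity([0] * 10)
        assert (s.he, s.shannon, s.pic, s.maf) == (0.0, 0.0, 0.0, 0.0)

    def test_hand_computation_n4(self):
        """[0,1,1,2]: p=0.5, Ho=0.5, He=0.5, Nei=(8/7)*0.5, PIC=0.375."""
        s = locus_diversity([0, 1, 1, 2])
        assert s.ho == pytest.approx(0.5)
        assert s.he == pytest.approx(0.5)
        assert s.nei == pytest.approx(8 / 7 * 0.5)
        assert s.pic == pytest.approx(0.375)

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="no data"):
            locus_diversity([-1, -1])

    def test_matches_formula_oracle(self, clean_panel):
        """Per-locus stats equal an independent per-formula recomputation."""
        matrix, _ = clean_panel
        stats = panel_diversity(matrix)
        for j in range(matrix.n_loci):
            g = matrix.genotypes[:, j]
            n = g.size
            p = g.sum() / (2 * n)
            q = 1 - p
            assert stats[j].ho == pytest.approx((g == 1).mean(), abs=1e-12)
            assert stats[j].he == pytest.approx(1 - p * p - q * q, abs=1e-12)
            assert stats[j].nei == pytest.approx(
                min(1.0, 2 * n / (2 * n - 1) * (1 - p * p - q * q)), abs=1e-12)
            shannon = -sum(f * math.log2(f) for f in (p, q) if f > 0)
            assert stats[j].shannon == pytest.approx(shannon, abs=1e-12)
            assert stats[j].pic == pytest.approx(
                1 - (p * p + q * q) - 2 * p * p * q * q, abs=1e-12)

    def test_pic_bounded_by_he(self, structured_panel):
        """PIC <= He everywhere; equality only at monomorphic loci."""
        matrix, _ = structured_panel
        for s in panel_diversity(matrix):
            assert s.pic <= s.he + 1e-12
            if s.maf > 0:
                assert s.pic < s.he

    def test_shannon_maximal_at_half(self):
        vals = [locus_diversity([0] * a + [1] * 0 + [2] * (50 - a)).shannon
                for a in (25, 30, 35, 40, 45)]
        assert vals[0] == pytest.approx(1.0)
        assert all(x > y for x, y in zip(vals, vals[1:]))


class TestHweExactTest:
    @pytest.mark.parametrize("counts", [
        (25, 50, 25), (50, 0, 50), (5, 10, 5), (30, 10, 2), (1, 1, 1),
        (0, 7, 13), (40, 80, 80), (12, 0, 3),
    ])
    def test_matches_enumeration_oracle(self, counts):
        expected = float(hwe_enumeration_oracle(*counts))
        assert hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-9)

    def test_equilibrium_is_one(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(
            float(hwe_enumeration_oracle(25, 50, 25)), abs=1e-9)

    def test_extreme_disequilibrium_fails_gate(self):
        assert hwe_exact_test(50, 0, 50) < 1e-6

    def test_monomorphic_is_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    def test_oracle_agreement_random_totals(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(2, 200))
            counts = rng.multinomial(n, [0.3, 0.45, 0.25])
            expected = float(hwe_enumeration_oracle(*counts))
            assert hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-9)


class TestModifiedRogers:
    def test_identical_accessions_zero(self):
        m = make_matrix([[0, 1, 2], [0, 1, 2]])
        assert modified_rogers(m)[0, 1] == 0.0

    def test_opposite_homozygotes_one(self):
        m = make_matrix([[0, 0, 0], [2, 2, 2]])
        assert modified_rogers(m)[0, 1] == pytest.approx(1.0)

    def test_hom_vs_het_single_locus(self):
        m = make_matrix([[0], [1]])
        assert modified_rogers(m)[0, 1] == pytest.approx(0.5)

    def test_symmetric_zero_diagonal_bounded(self, clean_panel):
        matrix, _ = clean_panel
        d = modified_rogers(matrix)
        np.testing.assert_allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert d.min() >= 0 and d.max() <= 1

    def test_triangle_inequality(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, size=(12, 30))
        g[rng.random(g.shape) < 0.1] = -1
        d = modified_rogers(make_matrix(g))
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_no_shared_loci_raises(self):
        m = make_matrix([[0, -1], [-1, 2]])
        with pytest.raises(ValueError, match="share no called loci"):
            modified_rogers(m)


class TestGenotypeClassFreqs:
    def test_all_one_class(self):
        m = make_matrix([[0, 0], [0, 0]], ref=["A", "A"], alt=["G", "G"])
        freqs = genotype_class_freqs(m)
        assert freqs["AA"] == 1.0

    def test_het_and_hom_mix(self):
        m = make_matrix([[1], [2]], ref=["C"], alt=["T"])
        freqs = genotype_class_freqs(m)
        assert freqs["CT"] == 0.5 and freqs["TT"] == 0.5

    def test_matches_brute_force(self, clean_panel):
        matrix, _ = clean_panel
        freqs = genotype_class_freqs(matrix)
        counts = {}
        for i in range(matrix.n_accessions):
            for j in range(matrix.n_loci):
                d = matrix.genotypes[i, j]
                if d == -1:
                    continue
                r, a = str(matrix.ref[j]), str(matrix.alt[j])
                alleles = {0: r + r, 1: r + a, 2: a + a}[int(d)]
                key = "".join(sorted(alleles))
                counts[key] = counts.get(key, 0) + 1
        total = sum(counts.values())
        for cls, freq in freqs.items():
            assert freq == pytest.approx(counts.get(cls, 0) / total)
        assert sum(freqs.values()) == pytest.approx(1.0)


class TestAlleleCoverage:
    def test_full_subset_covers_all(self, clean_panel):
        matrix, _ = clean_panel
        assert allele_coverage(matrix, matrix.accessions) == 1.0

    def test_single_refhom_accession(self):
        m = make_matrix([[0, 0], [1, 1], [2, 2]])
        assert allele_coverage(m, [m.accessions[0]]) == 0.5

    def test_monomorphic_panel(self):
        m = make_matrix([[0, 0], [0, 0], [0, 0]])
        assert allele_coverage(m, [m.accessions[1]]) == 1.0

    def test_unknown_id_rejected(self, clean_panel):
        matrix, _ = clean_panel
        with pytest.raises(KeyError):
            allele_coverage(matrix, ["nope"])

    def test_monotone_under_growth(self, clean_panel):
        matrix, _ = clean_panel
        cov = [allele_coverage(matrix, matrix.accessions[:k])
               for k in (1, 5, 20, 80)]
        assert all(a <= b + 1e-12 for a, b in zip(cov, cov[1:]))


class TestPca:
    def test_identity_subset_full_concordance(self, structured_panel):
        matrix, _ = structured_panel
        score = pca_concordance(matrix, np.arange(matrix.n_loci), k=3)
        assert score == pytest.approx(1.0, abs=1e-8)

    def test_pc1_separates_two_clusters(self):
        from coresnp.synthetic_data import PanelConfig, simulate_panel
        from sklearn.metrics import silhouette_score

        m, truth = simulate_panel(PanelConfig(
            n_accessions=150, n_loci=1000, n_subpops=2, fst=0.3,
            missing_rate=0.0, seed=2))
        pc1 = pca_scores(m, 1)
        assert silhouette_score(pc1, truth.subpop_label) > 0.5

    def test_random_subset_concordant_on_structured_panel(self, structured_panel):
        matrix, _ = structured_panel
        rng = np.random.default_rng(13)
        subset = rng.choice(matrix.n_loci, size=matrix.n_loci // 10,
                            replace=False)
        assert pca_concordance(matrix, subset, k=2) > 0.8
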