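"""Pairwise diversity and normalized Tajima's D from masked alignments."""

import numpy as np
import pytest

from bgsmap.annotation import CODING, INTERGENIC, INTRON
from bgsmap.diversity import (
    alignment_to_matrix,
    per_site_pi,
    site_pi_profile,
    tajima_d,
    tajima_d_normalized,
    window_diversity,
)


def mat(rows):
    return alignment_to_matrix(rows)


class TestPerSitePi:
    def test_identical_alleles_zero(self):
        assert per_site_pi("A" * 10) == 0.0

    def test_insufficient_coverage_missing(self):
        assert np.isnan(per_site_pi("ACAAAAAAA" + "N", min_coverage=10))

    def test_two_sequences_single_difference(self):
        # one polymorphic site between 2 sequences: pi = 1 per site there
        assert per_site_pi("AC", min_coverage=2) == pytest.approx(1.0)

    def test_unbiased_correction(self):
        # 5 A, 5 C among 10: 2*(25/100)*(10/9) = 0.5555...
        assert per_site_pi("AAAAACCCCC") == pytest.approx(2 * 0.25 * 10 / 9)

    def test_profile_matches_all_pairs_oracle(self):
        """Vectorized per-site pi equals the brute-force average over all
        pairs of non-N alleles."""
        rng = np.random.default_rng(5)
        m = rng.choice(np.frombuffer(b"ACGTN", np.uint8), size=(12, 300), p=[0.5, 0.3, 0.1, 0.05, 0.05])
        pi = site_pi_profile(m, min_coverage=4)
        for col in range(300):
            alleles = m[:, col]
            good = alleles[alleles != ord("N")]
            n = len(good)
            if n < 4:
                assert np.isnan(pi[col])
                continue
            diffs = sum(
                good[i] != good[j] for i in range(n) for j in range(i + 1, n)
            )
            expected = diffs / (n * (n - 1) / 2)
            assert pi[col] == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_row_order_and_relabeling(self):
        rng = np.random.default_rng(6)
        m = rng.choice(np.frombuffer(b"ACGT", np.uint8), size=(10, 100))
        base = site_pi_profile(m, min_coverage=2)
        shuffled = m[rng.permutation(10)]
        assert np.allclose(site_pi_profile(shuffled, min_coverage=2), base)
        # relabel A<->G everywhere
        relabeled = m.copy()
        relabeled[m == ord("A")] = ord("G")
        relabeled[m == ord("G")] = ord("A")
        assert np.allclose(site_pi_profile(relabeled, min_coverage=2), base)


class TestWindowDiversity:
    def _alignment(self, n=12, length=2000, seed=0, theta=0.02):
        rng = np.random.default_rng(seed)
        m = np.full((n, length), ord("A"), np.uint8)
        seg = rng.random(length) < theta * np.log(n)
        for pos in np.flatnonzero(seg):
            k = rng.integers(1, n)
            m[rng.choice(n, k, replace=False), pos] = ord("C")
        return m

    def test_window_with_too_few_silent_sites_excluded(self):
        m = self._alignment()
        labels = np.full(2000, CODING, np.uint8)
        labels[:400] = INTERGENIC  # 400 silent sites in window 0
        div = window_diversity(m, labels, window_size=1000, min_coverage=2)
        assert not div["included"].iloc[0]

    def test_monomorphic_window_included_with_zero_pi(self):
        m = np.full((12, 1000), ord("A"), np.uint8)
        labels = np.full(1000, INTERGENIC, np.uint8)
        div = window_diversity(m, labels, window_size=1000, min_coverage=2)
        assert div["included"].iloc[0]
        assert div["pi_sil"].iloc[0] == 0.0

    def test_window_mean_equals_mean_of_site_values(self):
        m = self._alignment()
        labels = np.full(2000, INTERGENIC, np.uint8)
        labels[500:700] = INTRON
        div = window_diversity(m, labels, window_size=1000, min_coverage=2)
        pi = site_pi_profile(m, min_coverage=2)
        expected = np.nanmean(pi[:1000])
        assert div["pi_sil"].iloc[0] == pytest.approx(expected, rel=1e-12)
        # class-specific values drawn from the same per-site profile
        assert div["pi_intron"].iloc[0] == pytest.approx(
            np.nanmean(pi[500:700]), rel=1e-12
        )

    def test_mismatched_labels_raise(self):
        with pytest.raises(ValueError):
            window_diversity(
                np.full((4, 100), ord("A"), np.uint8), np.zeros(50, np.uint8)
            )


class TestTajimaD:
    def test_all_singletons_is_minus_one(self):
        n, s = 12, 7
        m = np.full((n, 100), ord("A"), np.uint8)
        for i in range(s):
            m[i % n, i] = ord("C")  # each variant on a different background
        assert tajima_d_normalized(m) == pytest.approx(-1.0)

    def test_no_segregating_sites_missing(self):
        m = np.full((10, 50), ord("A"), np.uint8)
        assert np.isnan(tajima_d_normalized(m))

    def test_worked_example_textbook_formulas(self):
        """n = 10, folded counts [3, 2, 1]: 3 singleton, 2 doubleton and one
        tripleton site; compared against an explicit from-scratch
        computation of Tajima's constants."""
        n = 10
        m = np.full((n, 50), ord("A"), np.uint8)
        cols = [(0, 1), (1, 1), (2, 1), (3, 2), (4, 2), (5, 3)]
        for col, count in cols:
            m[:count, col] = ord("C")
        # from-scratch: harmonic numbers and variance coefficients
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        s = 6
        k = sum(2 * c * (n - c) / (n * (n - 1)) for _, c in cols)
        d = (k - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))
        k_min = 2 * s / n
        d_min = (k_min - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))
        expected = d / abs(d_min)
        assert tajima_d_normalized(m) == pytest.approx(expected, rel=1e-12)

    def test_columns_with_n_excluded(self):
        n = 12
        m = np.full((n, 20), ord("A"), np.uint8)
        m[:6, 0] = ord("C")  # balanced site
        m[0, 1] = ord("C")
        m[1, 1] = ord("N")  # this singleton site is dropped (contains N)
        with_n = tajima_d_normalized(m)
        m2 = m[:, [0] + list(range(2, 20))]
        assert with_n == pytest.approx(tajima_d_normalized(m2))

    def test_needs_four_sequences(self):
        with pytest.raises(ValueError):
            tajima_d(3, 5, 1.0)

    def test_neutral_equilibrium_mean_near_zero(self):
        """Windows drawn from the standard neutral SFS should average
        D/Dmin ~ 0."""
        rng = np.random.default_rng(11)
        n, vals = 15, []
        k_range = np.arange(1, n)
        w = (1 / k_range) / (1 / k_range).sum()
        for _ in range(300):
            m = np.full((n, 400), ord("A"), np.uint8)
            n_seg = rng.poisson(12)
            pos = rng.choice(400, size=n_seg, replace=False)
            for p in pos:
                k = rng.choice(k_range, p=w)
                m[rng.choice(n, k, replace=False), p] = ord("C")
            v = tajima_d_normalized(m)
            if not np.isnan(v):
                vals.append(v)
        assert abs(np.mean(vals)) < 0.1
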