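"""Kernel quadrature, B landscapes, the brute-force oracle, and D_B scales."""

import dataclasses

import numpy as np
import pytest

from bgsmap.annotation import CODING, INTERGENIC, count_selected_sites
from bgsmap.bgs import (
    ExponentKernel,
    build_kernel,
    compute_B,
    db_quantiles,
    kernel_value,
    oracle_B,
    per_bp_selected_weights,
    xa_summary,
)
from bgsmap.ddfe import MutationRates, NeutralThreshold, make_ddfe
from bgsmap.models import parse_model_id
from bgsmap.recmap import RecombinationMap
from bgsmap.simulate import SyntheticSpec, generate_genome

THR = NeutralThreshold.autosomal(1e6)


def flat_map(c, n_windows=10, window=100_000, **kwargs):
    starts = np.arange(n_windows) * window
    return RecombinationMap(
        "chrT", starts, starts + window, np.full(n_windows, float(c)), **kwargs
    )


def track_from_blocks(length, coding_blocks, window_size=1000):
    """Labels intergenic-free: only explicit coding blocks are selected."""
    labels = np.full(length, 255, dtype=np.uint8)  # unknown -> no weight
    for lo, hi in coding_blocks:
        labels[lo:hi] = CODING
    return count_selected_sites(labels, chromosome="chrT", window_size=window_size)


class TestKernel:
    def test_point_mass_closed_form(self):
        pm = make_ddfe("point_mass", mean_s=0.01, dominance_h=0.5)
        t = 0.01 * 0.5
        assert kernel_value(pm, THR, 0.0) == pytest.approx(1.0 / t, rel=1e-12)
        for r in (1e-6, 1e-3, 0.5):
            expected = t / (t + r * (1 - t)) ** 2
            assert kernel_value(pm, THR, r) == pytest.approx(expected, rel=1e-12)

    def test_lognormal_matches_fine_trapezoid(self, default_model):
        """Adaptive quadrature against an independent fixed-grid trapezoid
        integration of the truncated, clamped density."""
        ddfe = default_model.ddfe_aa
        dist = ddfe.distribution
        y = np.linspace(np.log(THR.s_T), 0.0, 200_001)
        s = np.exp(y)
        dens = dist.pdf(s) * s
        surviving = dist.sf(THR.s_T)
        lethal = dist.sf(1.0)
        h = ddfe.dominance_h
        for r in (0.0, 1e-8, 1e-5, 1e-2, 1.0):
            t = s * h
            f = t / (t + r * (1 - t)) ** 2
            expected = (np.trapezoid(dens * f, y) + lethal * (0.5 / (0.5 + r * 0.5) ** 2)) / surviving
            assert kernel_value(ddfe, THR, r) == pytest.approx(expected, rel=1e-4)

    def test_grid_kernel_monotone_positive(self, kernel_cache):
        for k in kernel_cache.values():
            assert np.all(k.values > 0)
            assert np.all(np.diff(k.values) <= 1e-9 * k.values[:-1])
            assert k.value_at_zero >= k.values[0]

    def test_interpolation_matches_direct_quadrature(self, kernel_cache, default_model):
        k = kernel_cache["LN"]
        for r in (3.3e-9, 7.7e-6, 0.013):  # off-grid points
            assert k(r) == pytest.approx(
                kernel_value(default_model.ddfe_aa, THR, r), rel=1e-3
            )

    def test_too_coarse_grid_rejected(self, default_model):
        with pytest.raises(ValueError):
            build_kernel(default_model.ddfe_aa, THR, n_grid=50)


class TestComputeB:
    def test_zero_selected_sites_gives_unity(self):
        m = flat_map(2.0, n_windows=2, window=50_000)
        track = track_from_blocks(100_000, [])
        rates = MutationRates(u_per_bp=1e-8)
        pm = make_ddfe("point_mass", mean_s=0.01)
        kern = build_kernel(pm, THR)
        land = compute_B(track, m, kern, rates)
        assert np.allclose(land.b, 1.0)

    def test_fully_linked_point_mass_closed_form(self):
        """With no recombination at all, B = exp(-sum u_i/(s h)): the
        classical mutational-load limit exp(-U/(2 s h)) for h = 1/2."""
        m = flat_map(0.0, n_windows=1, window=50_000)
        track = track_from_blocks(50_000, [(10_000, 20_000)])
        u = 1e-8
        rates = MutationRates(u_per_bp=u)
        pm = make_ddfe("point_mass", mean_s=0.01, dominance_h=0.5)
        kern = build_kernel(pm, THR)
        land = compute_B(track, m, kern, rates, include_gc=False)
        n_sel = 10_000 * 0.75 * 0.92
        expected = np.exp(-n_sel * u / (0.01 * 0.5))
        assert land.b == pytest.approx(expected, rel=1e-9)

    def test_exponent_linear_in_mutation_rate(self, toy100kb, kernel_cache, default_model):
        rates1 = default_model.rates_by_class()
        rates2 = {
            cls: dataclasses.replace(r, u_per_bp=2 * r.u_per_bp)
            for cls, r in rates1.items()
        }
        l1 = compute_B(toy100kb["track"], toy100kb["recmap"], kernel_cache["LN"], rates1)
        l2 = compute_B(toy100kb["track"], toy100kb["recmap"], kernel_cache["LN"], rates2)
        assert np.allclose(l2.exponent, 2 * l1.exponent, rtol=1e-12)
        assert np.allclose(l2.b, l1.b**2, rtol=1e-9)

    def test_more_recombination_never_decreases_b(self, kernel_cache, default_model):
        track = track_from_blocks(300_000, [(i * 10_000, i * 10_000 + 2000) for i in range(30)])
        rates = default_model.rates_by_class()
        low = compute_B(track, flat_map(0.5, 3), kernel_cache["LN"], rates)
        high = compute_B(track, flat_map(5.0, 3), kernel_cache["LN"], rates)
        assert np.all(high.b >= low.b)

    def test_adding_selected_sites_never_increases_b(self, kernel_cache, default_model):
        rates = default_model.rates_by_class()
        m = flat_map(2.0, 3)
        few = track_from_blocks(300_000, [(50_000, 55_000)])
        more = track_from_blocks(300_000, [(50_000, 55_000), (150_000, 160_000)])
        l_few = compute_B(few, m, kernel_cache["LN"], rates)
        l_more = compute_B(more, m, kernel_cache["LN"], rates)
        assert np.all(l_more.b <= l_few.b + 1e-15)

    def test_disjoint_sets_multiply(self, kernel_cache, default_model):
        """Exponent additivity: B from two disjoint selected-site sets is the
        product of their separate landscapes."""
        rates = default_model.rates_by_class()
        m = flat_map(2.0, 3)
        a = track_from_blocks(300_000, [(50_000, 55_000)])
        b = track_from_blocks(300_000, [(210_000, 214_000)])
        both = track_from_blocks(300_000, [(50_000, 55_000), (210_000, 214_000)])
        la = compute_B(a, m, kernel_cache["LN"], rates)
        lb = compute_B(b, m, kernel_cache["LN"], rates)
        lab = compute_B(both, m, kernel_cache["LN"], rates)
        assert np.allclose(lab.b, la.b * lb.b, rtol=1e-10)

    def test_gene_conversion_weakens_linkage(self, toy100kb, kernel_cache, default_model):
        rates = default_model.rates_by_class()
        gc = compute_B(toy100kb["track"], toy100kb["recmap"], kernel_cache["LN"], rates, include_gc=True)
        co = compute_B(toy100kb["track"], toy100kb["recmap"], kernel_cache["LN"], rates, include_gc=False)
        assert np.all(gc.b >= co.b)

    def test_track_outside_map_raises(self, kernel_cache, default_model):
        track = track_from_blocks(400_000, [(10_000, 12_000)])
        with pytest.raises(ValueError):
            compute_B(track, flat_map(2.0, 3), kernel_cache["LN"], default_model.rates_by_class())


class TestOracle:
    def test_zero_sites_unity(self):
        m = flat_map(2.0, 1, window=30_000)
        w = {c: np.zeros(30_000) for c in ("aa", "utr", "nc")}
        pm = make_ddfe("point_mass", mean_s=0.01)
        b = oracle_B(w, m, pm, THR, MutationRates(u_per_bp=1e-8), np.array([15_000]))
        assert b == pytest.approx(1.0)

    def test_single_site_fully_linked_point_mass(self):
        m = flat_map(0.0, 1, window=30_000)
        w = {c: np.zeros(30_000) for c in ("aa", "utr", "nc")}
        w["aa"][15_000] = 1.0
        u = 1e-4
        pm = make_ddfe("point_mass", mean_s=0.01, dominance_h=0.5)
        b = oracle_B(
            w, m, pm, THR, MutationRates(u_per_bp=u), np.array([15_000]), include_gc=False
        )
        assert b == pytest.approx(np.exp(-u / (0.01 * 0.5)), rel=1e-9)

    def test_size_guard(self):
        m = flat_map(2.0, 3)
        w = {c: np.zeros(300_000) for c in ("aa", "utr", "nc")}
        pm = make_ddfe("point_mass", mean_s=0.01)
        with pytest.raises(ValueError):
            oracle_B(w, m, pm, THR, MutationRates(u_per_bp=1e-8), np.array([0]))

    def test_windowed_computation_matches_oracle_on_small_chromosome(
        self, tmp_path, kernel_cache, default_model
    ):
        """Spot check at 30 kb; the full three-configuration comparison runs
        in the acceptance suite."""
        spec = SyntheticSpec(seed=3, chromosome_length=30_000, n_genes=3, n_tes=2)
        files = generate_genome(spec, tmp_path)
        from bgsmap.annotation import classify_sites
        from bgsmap.recmap import read_recmap

        rm = read_recmap(files.recmap_tsv)
        labels = classify_sites(
            files.gff3, files.te_bed, chromosome=spec.chromosome,
            chromosome_length=spec.chromosome_length,
        )
        track = count_selected_sites(labels, chromosome=spec.chromosome)
        rates = default_model.rates_by_class()
        land = compute_B(track, rm, kernel_cache["LN"], rates)
        w = per_bp_selected_weights(labels)
        b_oracle = oracle_B(
            w, rm, default_model.ddfe_aa, THR, rates, track.window_centers
        )
        assert np.max(np.abs(land.b - b_oracle) / b_oracle) < 0.01


class TestDBQuantiles:
    def test_fraction_one_is_whole_chromosome(self, kernel_cache, default_model):
        track = track_from_blocks(300_000, [(i * 20_000, i * 20_000 + 2000) for i in range(15)])
        prof = db_quantiles(
            track, flat_map(2.0, 3), kernel_cache["LN"],
            default_model.rates_by_class(), focal_index=150, fractions=(1.0,),
        )
        kb, cm = prof[1.0]
        assert kb == 300.0
        assert cm == pytest.approx(0.02 * 300_000 / 1e6 * 100, rel=1e-6)

    def test_single_cluster_interval_covers_cluster(self, kernel_cache, default_model):
        track = track_from_blocks(200_000, [(99_000, 102_000)])
        prof = db_quantiles(
            track, flat_map(2.0, 2), kernel_cache["LN"],
            default_model.rates_by_class(), focal_index=100,
        )
        kb90, _ = prof[0.9]
        assert kb90 <= 7.0  # a few windows around the cluster suffice

    def test_quantiles_nested(self, toy100kb, kernel_cache, default_model):
        prof = db_quantiles(
            toy100kb["track"], toy100kb["recmap"], kernel_cache["LN"],
            default_model.rates_by_class(), focal_index=50,
        )
        (k50, c50), (k75, c75), (k90, c90) = prof[0.5], prof[0.75], prof[0.9]
        assert k50 <= k75 <= k90
        assert c50 <= c75 <= c90

    def test_matches_direct_cumulative_scan(self, toy100kb, kernel_cache, default_model):
        """Independent check: reproduce the symmetric growth with an explicit
        python loop over per-window contributions."""
        from bgsmap.bgs import _class_weights, _near_field_corrections, NEAR_FIELD_WINDOWS
        from bgsmap.recmap import pairwise_r

        track, rm = toy100kb["track"], toy100kb["recmap"]
        rates = default_model.rates_by_class()
        kern = kernel_cache["LN"]
        focal = 50
        centers = track.window_centers
        contrib = np.zeros(len(centers))
        for i, c in enumerate(centers):
            r = pairwise_r(rm, centers[focal], c)
            for cls, wts in _class_weights(track).items():
                contrib[i] += kern(r) * wts[i] * rates[cls].u_effective
        corr = _near_field_corrections(
            track, rm, {c: kern for c in ("aa", "utr", "nc")}, rates, True
        )
        for d in range(-NEAR_FIELD_WINDOWS, NEAR_FIELD_WINDOWS + 1):
            contrib[focal + d] += corr[focal, d + NEAR_FIELD_WINDOWS]
        total = contrib.sum()
        lo = hi = focal
        acc = contrib[focal]
        while acc < 0.75 * total:
            if lo > 0:
                lo -= 1
                acc += contrib[lo]
            if hi < len(centers) - 1:
                hi += 1
                acc += contrib[hi]
        expected_kb = (hi - lo + 1) * 1.0
        prof = db_quantiles(track, rm, kern, rates, focal_index=focal)
        assert prof[0.75][0] == pytest.approx(expected_kb, abs=2.0)

    def test_zero_exponent_is_error(self, kernel_cache, default_model):
        track = track_from_blocks(200_000, [])
        with pytest.raises(ArithmeticError):
            db_quantiles(
                track, flat_map(2.0, 2), kernel_cache["LN"],
                default_model.rates_by_class(), focal_index=10,
            )


class TestXASummary:
    def _land(self, b):
        from bgsmap.bgs import BLandscape

        b = np.asarray(b, dtype=float)
        return BLandscape(
            "m", "c", 1000, np.arange(len(b)) * 1000, b, -np.log(b)
        )

    def test_equal_landscapes_give_0_75(self):
        a = self._land([0.5, 0.6, 0.7])
        x = self._land([0.5, 0.6, 0.7])
        assert xa_summary([a], x)["xa_predicted_ratio"] == pytest.approx(0.75)

    def test_stronger_autosomal_bgs_raises_ratio(self):
        a = self._land([0.75, 0.75])
        x = self._land([1.0, 1.0])
        assert xa_summary([a], x)["xa_predicted_ratio"] == pytest.approx(1.0)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            xa_summary([], self._land([0.5]))
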