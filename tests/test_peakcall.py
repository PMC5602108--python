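"""Peak calling: smoothing, summit detection, exact test, FDR, filters."""

import math

import numpy as np
import pytest

from meripeak.alignment_io import AlignedFragment, CoverageTrack
from meripeak.peakcall import (
    PeakCall,
    PeakCallConfig,
    adjust_fdr,
    apply_filters,
    call_peaks,
    call_peaks_from_fragments,
    define_regions,
    find_local_maxima,
    reproducibility_filter,
    smooth,
)
from meripeak.peakcall import test_enrichment as enrichment_p
from meripeak.simdata import SimConfig, simulate_reference, simulate_library_fragments, \
    fragments_to_genomic


def _track(values, start=0):
    return CoverageTrack("chr1", start, np.array(values, dtype=float))


class TestSmooth:
    def test_window_one_is_identity(self):
        t = _track([1, 5, 2, 8])
        np.testing.assert_array_equal(smooth(t, 1).values, t.values)

    def test_constant_track_fixed_point(self):
        t = _track([4.0] * 50)
        np.testing.assert_allclose(smooth(t, 7).values, t.values)

    def test_impulse_moving_average(self):
        t = _track([0, 0, 6, 0, 0])
        np.testing.assert_allclose(smooth(t, 3).values, [0, 2, 2, 2, 0])

    def test_even_window_incremented(self):
        t = _track([0, 0, 6, 0, 0])
        np.testing.assert_allclose(smooth(t, 2).values, smooth(t, 3).values)

    def test_interior_mass_preserved(self):
        rng = np.random.default_rng(0)
        t = _track(rng.integers(0, 50, size=200))
        s = smooth(t, 9)
        # away from edges a moving average redistributes but preserves mass
        assert abs(s.values.sum() - t.values.sum()) <= 9 * t.values[:9].max() + 9 * t.values[-9:].max()


class TestFindLocalMaxima:
    def test_single_peak(self):
        t = _track([0, 1, 2, 3, 2, 1, 0])
        assert find_local_maxima(t, 4) == [3]

    def test_plateau_reports_center(self):
        t = _track([0, 2, 5, 5, 5, 2, 0])
        assert find_local_maxima(t, 4) == [3]

    def test_two_lobes_with_deep_valley(self):
        v = [0, 2, 8, 2, 0, 0, 2, 9, 2, 0]
        t = _track(v)
        found = find_local_maxima(t, 4)
        # brute-force gradient sign scan
        expected = [i for i in range(1, len(v) - 1)
                    if v[i] > v[i - 1] and v[i] > v[i + 1]]
        assert found == expected

    def test_shallow_valley_merges_to_higher(self):
        v = [0, 2, 8, 7.5, 9, 2, 0]
        assert find_local_maxima(_track(v), 4, min_valley_fraction=0.75) == [4]

    def test_floor_suppresses_low_maxima(self):
        t = _track([0, 1, 2, 1, 0, 0, 5, 9, 5, 0])
        assert find_local_maxima(t, 4, min_height=5) == [7]

    def test_flat_track_empty(self):
        assert find_local_maxima(_track([3.0] * 20), 4) == []

    def test_track_offset_respected(self):
        t = _track([0, 1, 5, 1, 0], start=1000)
        assert find_local_maxima(t, 4) == [1002]


class TestMinSeparation:
    def test_off_by_default(self):
        from meripeak.peakcall import enforce_min_separation
        assert enforce_min_separation([100, 110], [5.0, 3.0], 0) == [100, 110]

    def test_keeps_higher_of_close_pair(self):
        from meripeak.peakcall import enforce_min_separation
        assert enforce_min_separation([100, 110, 400], [3.0, 5.0, 2.0], 50) == [110, 400]


class TestDefineRegions:
    def test_single_summit(self):
        assert define_regions([500], 100) == [(400, 600)]

    def test_overlap_split_at_midpoint(self):
        assert define_regions([500, 560], 100) == [(400, 530), (530, 660)]

    def test_distant_summits_unmodified(self):
        assert define_regions([500, 900], 100) == [(400, 600), (800, 1000)]

    def test_regions_disjoint_and_cover_summits(self):
        rng = np.random.default_rng(4)
        summits = sorted(int(x) for x in rng.choice(5000, size=40, replace=False))
        regions = define_regions(summits, 100)
        for s, (lo, hi) in zip(summits, regions):
            assert lo <= s < hi
        for (a, b), (c, d) in zip(regions, regions[1:]):
            assert b <= c


class TestEnrichmentTest:
    def test_identical_proportions_not_significant(self):
        assert enrichment_p(10, 10, 1000, 1000) >= 0.5

    def test_extreme_table_exact_value(self):
        # all 10 successes in IP out of 10+10 draws: p = 1/C(20,10)
        p = enrichment_p(10, 0, 10, 10)
        assert p == pytest.approx(1.0 / math.comb(20, 10), rel=1e-12)

    def test_zero_ip_count(self):
        assert enrichment_p(0, 5, 100, 100) == 1.0

    def test_empty_library_total(self):
        assert enrichment_p(0, 0, 0, 10) == 1.0

    def test_matches_hypergeometric_enumeration(self):
        # exact integer-arithmetic tail oracle on a small grid
        for n1 in (5, 12):
            for n2 in (7, 12):
                for a in range(n1 + 1):
                    for b in range(n2 + 1):
                        K, N = a + b, n1 + n2
                        num = sum(
                            math.comb(K, k) * math.comb(N - K, n1 - k)
                            for k in range(a, min(K, n1) + 1)
                        )
                        expected = num / math.comb(N, n1)
                        assert enrichment_p(a, b, n1, n2) == pytest.approx(
                            expected, rel=1e-9, abs=1e-300
                        )


def _bh_oracle(p):
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


class TestAdjustFdr:
    def test_single_p_bh(self):
        assert adjust_fdr([0.04], "bh")[0] == pytest.approx(0.04)

    def test_bh_step_up_example(self):
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.03], "bh"),
                                   [0.03, 0.03, 0.03])

    def test_bonferroni_capped(self):
        assert adjust_fdr([0.2] * 10, "bonferroni")[0] == 1.0

    def test_none_identity(self):
        p = [0.5, 0.01, 0.7]
        np.testing.assert_array_equal(adjust_fdr(p, "none"), p)

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="bh"):
            adjust_fdr([0.5], "holmes")

    def test_bh_matches_oracle_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(adjust_fdr(p, "bh"), _bh_oracle(p), atol=1e-12)

    def test_bonferroni_dominates_bh(self):
        rng = np.random.default_rng(9)
        p = rng.random(30)
        assert (adjust_fdr(p, "bonferroni") >= adjust_fdr(p, "bh") - 1e-12).all()

    def test_by_more_conservative_than_bh(self):
        rng = np.random.default_rng(10)
        p = rng.random(25)
        assert (adjust_fdr(p, "by") >= adjust_fdr(p, "bh") - 1e-12).all()


def _peak(summit=500, enrichment=3.0, ip_count=30, q=0.01, chrom="chr1"):
    return PeakCall(chrom=chrom, summit=summit, region_start=summit - 100,
                    region_end=summit + 100, ip_count=ip_count, input_count=5,
                    ip_total=1000, input_total=1000, enrichment=enrichment,
                    p_value=q, q_value=q)


class TestApplyFilters:
    def test_low_enrichment_flagged(self):
        peaks = apply_filters([_peak(enrichment=1.5)], PeakCallConfig())
        assert "low_enrichment" in peaks[0].flags

    def test_low_coverage_flagged(self):
        peaks = apply_filters([_peak(ip_count=19)], PeakCallConfig())
        assert "low_coverage" in peaks[0].flags

    def test_good_peak_retained(self):
        peaks = apply_filters([_peak(enrichment=2.5, ip_count=25, q=0.01)],
                              PeakCallConfig())
        assert peaks[0].retained

    def test_order_preserved(self):
        peaks = [_peak(summit=s) for s in (100, 500, 900)]
        out = apply_filters(peaks, PeakCallConfig())
        assert [p.summit for p in out] == [100, 500, 900]


class TestReproducibility:
    def test_matched_within_window_retained(self):
        a, b = [_peak(1000)], [_peak(1005)]
        reproducibility_filter([a, b], match_window=50)
        assert a[0].retained and b[0].retained

    def test_unmatched_flagged(self):
        a, b = [_peak(1000), _peak(5000)], [_peak(1005)]
        reproducibility_filter([a, b], match_window=50)
        assert "not_reproducible" in a[1].flags
        assert a[0].retained

    def test_three_replicates_against_bruteforce(self):
        sets = [[_peak(s) for s in summits]
                for summits in ([100, 300, 900], [110, 310], [95, 290, 905])]
        reproducibility_filter(sets, match_window=30)
        for i, peaks in enumerate(sets):
            for p in peaks:
                ok = all(
                    any(abs(q.summit - p.summit) <= 30 for q in other)
                    for j, other in enumerate(sets) if j != i
                )
                assert p.retained == ok

    def test_single_replicate_noop(self):
        a = [_peak(1000)]
        reproducibility_filter([a])
        assert a[0].retained


class TestCallPeaks:
    def test_null_same_bam_retains_nothing(self, small_sim):
        peaks = call_peaks(small_sim["input"], small_sim["input"], PeakCallConfig())
        assert sum(p.retained for p in peaks) == 0

    def test_planted_sites_recovered(self, small_sim):
        ref = small_sim["ref"]
        peaks = call_peaks(small_sim["ip"], small_sim["input"], PeakCallConfig())
        retained = [p for p in peaks if p.retained]
        assert retained
        hits = 0
        for s in ref.truth.sites:
            if any(p.chrom == s.chrom and p.region_start <= s.position < p.region_end
                   for p in retained):
                hits += 1
        assert hits / len(ref.truth.sites) >= 0.8

    def test_depth_doubling_keeps_summits(self):
        cfg = SimConfig(n_transcripts=3, depth=20_000, seed=21)
        ref = simulate_reference(cfg)
        rng = np.random.default_rng(2)
        ip = fragments_to_genomic(ref, simulate_library_fragments(ref, cfg, True, rng))
        ctrl = fragments_to_genomic(ref, simulate_library_fragments(ref, cfg, False, rng))
        pcfg = PeakCallConfig()
        for chrom in ip:
            length = len(ref.sequences[chrom])
            p1 = call_peaks_from_fragments(ip[chrom], ctrl.get(chrom, []), chrom,
                                           length, pcfg)
            p2 = call_peaks_from_fragments(ip[chrom] * 2, ctrl.get(chrom, []) * 2,
                                           chrom, length, pcfg)
            assert [p.summit for p in p1 if p.retained] == \
                [p.summit for p in p2 if p.retained]

    def test_mismatched_chromosomes_fatal(self, small_sim, bam_factory):
        other = bam_factory(
            [{"name": "r", "ref": "weird", "start": 10, "cigar": "30M"}],
            references=(("weird", 1000),),
        )
        with pytest.raises(ValueError, match="no shared chromosomes"):
            call_peaks(small_sim["ip"], other, PeakCallConfig())
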