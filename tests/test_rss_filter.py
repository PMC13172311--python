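import numpy as np
import pytest

from rescursor.rss_detect import RssCatalog
from rescursor.rss_filter import (
    FilterConfig,
    apply_filters,
    conservation_filter,
    overhang_filter,
    polyA_site_set,
    polyA_subtraction,
    sawtooth_pass,
    sawtooth_test,
)
from conftest import constant_track, dense_track
from helpers import make_candidate


def step_coverage(intron=(200, 2200), rs=1000, up=10.0, down=4.0, chrom="chr1"):
    vals = np.full(intron[1] - intron[0], down)
    vals[: rs - intron[0]] = up
    return dense_track(chrom, intron[0], vals)


class TestConservationFilter:
    def test_mean_over_five_motif_bases(self):
        c = make_candidate()
        # motif window for + strand is [rs-3, rs+2)
        t = dense_track("chr1", 997, [0.8, 0.7, 0.6, 0.5, 0.4], kind="conservation")
        mean, ok = conservation_filter(c, t, FilterConfig())
        assert mean == pytest.approx(0.6) and ok

    def test_exactly_half_fails_strict_threshold(self):
        c = make_candidate()
        t = constant_track("chr1", 0, 3000, 0.5, kind="conservation")
        mean, ok = conservation_filter(c, t, FilterConfig())
        assert mean == 0.5 and not ok

    def test_empty_track_fails_with_gap_flag(self):
        from rescursor.genome_io import SignalTrack

        c = make_candidate()
        mean, ok = conservation_filter(c, SignalTrack("conservation"), FilterConfig())
        assert mean == 0.0 and not ok
        assert c.filter_flags["conservation_gap"]

    def test_minus_strand_window(self):
        c = make_candidate(strand="-")
        # motif window for - strand is [rs-2, rs+3)
        t = dense_track("chr1", 998, [1.0] * 5, kind="conservation")
        mean, ok = conservation_filter(c, t, FilterConfig())
        assert mean == 1.0 and ok


class TestOverhangFilter:
    @pytest.mark.parametrize("overhang,expected", [(6, True), (5, False), (0, False)])
    def test_strictly_greater_than_five(self, overhang, expected):
        assert overhang_filter(make_candidate(overhang=overhang), FilterConfig()) is expected


class TestSawtooth:
    def test_hand_computed_fold(self):
        """up 10, down 4, eps 0.5 -> 10.5/4.5 ~ 2.333 (passes the 2-fold bar)."""
        c = make_candidate()
        res = sawtooth_test(c, step_coverage(), FilterConfig(), np.random.default_rng(0))
        assert res.fold == pytest.approx(10.5 / 4.5)
        assert res.up_mean == pytest.approx(10.0) and res.down_mean == pytest.approx(4.0)
        assert sawtooth_pass(res, FilterConfig())

    def test_subthreshold_fold_fails(self):
        """up 8, down 4 -> 8.5/4.5 ~ 1.889 < 2 -> fail regardless of P."""
        c = make_candidate()
        cov = step_coverage(up=8.0)
        res = sawtooth_test(c, cov, FilterConfig(), np.random.default_rng(0))
        assert res.fold == pytest.approx(8.5 / 4.5)
        assert not sawtooth_pass(res, FilterConfig())

    def test_exactly_two_fold_fails(self):
        """(6.5+0.5)/(3.0+0.5) is exactly 2.0; the criterion is strict."""
        c = make_candidate()
        cov = step_coverage(up=6.5, down=3.0)
        res = sawtooth_test(c, cov, FilterConfig(), np.random.default_rng(0))
        assert res.fold == 2.0
        assert not sawtooth_pass(res, FilterConfig())

    def test_flat_coverage_fold_is_one(self):
        c = make_candidate()
        cov = constant_track("chr1", 200, 2200, 5.0)
        res = sawtooth_test(c, cov, FilterConfig(), np.random.default_rng(0))
        assert res.fold == pytest.approx(1.0)
        assert not sawtooth_pass(res, FilterConfig())

    def test_p_lower_bound_attained_on_clean_step(self):
        c = make_candidate()
        cfg = FilterConfig(n_perm=500)
        res = sawtooth_test(c, step_coverage(up=40.0, down=1.0), cfg,
                            np.random.default_rng(0))
        # clean planted step: only the true breakpoint reaches the max
        assert res.p_perm == pytest.approx(1 / (cfg.n_perm + 1))

    def test_short_intron_untestable(self):
        c = make_candidate(rs_point=230, intron=(200, 260))
        res = sawtooth_test(c, constant_track("chr1", 200, 260, 5.0),
                            FilterConfig(), np.random.default_rng(0))
        assert not res.testable
        assert not sawtooth_pass(res, FilterConfig())

    def test_minus_strand_swaps_windows(self):
        """The same genomic step is a pass on + and a fail (inverted) on -."""
        cov = step_coverage(up=10.0, down=4.0)
        plus = sawtooth_test(make_candidate(), cov, FilterConfig(), np.random.default_rng(0))
        minus = sawtooth_test(make_candidate(strand="-"), cov, FilterConfig(),
                              np.random.default_rng(0))
        assert minus.fold == pytest.approx(1 / plus.fold, rel=1e-3)

    def test_fold_monotone_in_planted_step(self):
        """Mean observed statistic increases with the planted step fold."""
        rng_data = np.random.default_rng(42)
        mean_s = []
        for fold in (1, 2, 4, 8):
            stats = []
            for rep in range(10):
                lam = np.full(2000, 20.0 / fold)
                lam[:800] = 20.0
                cov = dense_track("chr1", 200, rng_data.poisson(lam).astype(float))
                c = make_candidate(rs_point=1000, intron=(200, 2200))
                res = sawtooth_test(c, cov, FilterConfig(n_perm=10),
                                    np.random.default_rng(rep))
                stats.append(res.fold)
            mean_s.append(np.mean(stats))
        assert all(a < b for a, b in zip(mean_s, mean_s[1:]))


class TestPolyASubtraction:
    def _catalog(self, reads=3):
        cat = RssCatalog("s1", [make_candidate()])
        cat.candidates[0].unique_reads = reads
        return cat

    def test_candidate_in_polyA_removed(self):
        keys = {("g1", 1000)}
        cat = polyA_subtraction(self._catalog(), keys)
        assert cat.candidates[0].in_polyA

    def test_absent_candidate_kept(self):
        cat = polyA_subtraction(self._catalog(), {("g1", 999)})
        assert not cat.candidates[0].in_polyA

    def test_empty_polyA_set_is_identity(self):
        cat = polyA_subtraction(self._catalog(), set())
        assert not cat.candidates[0].in_polyA

    def test_site_set_respects_min_reads(self):
        cat = self._catalog(reads=0)
        assert polyA_site_set([cat], min_reads=1) == set()
        cat2 = self._catalog(reads=3)
        assert polyA_site_set([cat2], min_reads=1) == {("g1", 1000)}


class TestApplyFilters:
    def _inputs(self):
        cov = step_coverage(up=30.0, down=5.0)
        cons = constant_track("chr1", 0, 3000, 0.9, kind="conservation")
        return cov, cons

    def test_all_pass_conjunction(self):
        cov, cons = self._inputs()
        cat = RssCatalog("s1", [make_candidate()])
        apply_filters(cat, cov, cons, FilterConfig(seed=3))
        assert cat.candidates[0].status == "pass"

    def test_single_failure_reason_recorded(self):
        cov, cons = self._inputs()
        cat = RssCatalog("s1", [make_candidate(overhang=5)])
        apply_filters(cat, cov, cons, FilterConfig(seed=3))
        c = cat.candidates[0]
        assert c.status == "fail" and c.fail_reason == "overhang"

    def test_polyA_blocks_pass(self):
        cov, cons = self._inputs()
        cat = RssCatalog("s1", [make_candidate()])
        apply_filters(cat, cov, cons, FilterConfig(seed=3), polyA_keys={("g1", 1000)})
        assert cat.candidates[0].status == "fail"
        assert cat.candidates[0].fail_reason == "polyA"

    def test_rerun_same_seed_identical_p(self):
        cov, cons = self._inputs()
        ps = []
        for _ in range(2):
            cat = RssCatalog("s1", [make_candidate()])
            apply_filters(cat, cov, cons, FilterConfig(seed=3))
            ps.append(cat.candidates[0].sawtooth_p)
        assert ps[0] == ps[1]

    def test_stage_counts_non_increasing(self):
        cov, cons = self._inputs()
        cands = [
            make_candidate(),
            make_candidate(rs_point=1200, overhang=5),
            make_candidate(rs_point=1400),
        ]
        cands[2].filter_flags["motif"] = False
        cat = RssCatalog("s1", cands)
        apply_filters(cat, cov, cons, FilterConfig(seed=3))
        sc = cat.stage_counts
        chain = [sc["hybrid"], sc["motif"], sc["conservation"], sc["overhang"],
                 sc["sawtooth"], sc["final"]]
        assert chain == sorted(chain, reverse=True)


class TestPermutationCalibration:
    def test_null_rate_at_alpha(self):
        """On flat Poisson introns the sawtooth permutation P is calibrated:
        the rate of p < 0.01 stays within binomial tolerance of nominal."""
        rng_data = np.random.default_rng(2024)
        cfg = FilterConfig(n_perm=400, seed=0)
        rng_test = np.random.default_rng(cfg.seed)
        n_sig = 0
        n = 200
        for i in range(n):
            cov = dense_track(
                "chr1", 200, rng_data.poisson(8.0, size=1600).astype(float)
            )
            c = make_candidate(rs_point=1000, intron=(200, 1800))
            res = sawtooth_test(c, cov, cfg, rng_test)
            n_sig += res.p_perm < 0.01
        assert n_sig / n <= 0.03
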