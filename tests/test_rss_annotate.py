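import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rescursor.genome_io import Transcript, derive_introns
from rescursor.rss_annotate import (
    as_overlap_enrichment,
    associate_rs_exon,
    conservation_profile,
    cryptic_exon_flag,
    donor_class_enrichment,
    random_intronic_sites,
    sequence_probability_matrix,
    stratify_conservation,
)
from conftest import constant_track, dense_track, toy_annotation
from helpers import fisher_two_sided_exact, make_candidate


def ann_with_rs_exon(exon=None):
    ann = toy_annotation([(50, 200), (2200, 2300)])
    if exon is not None:
        ann.transcripts["g1.t2"] = Transcript(
            "g1.t2", "g1", "chr1", "+", [(50, 200), exon, (2200, 2300)]
        )
    return derive_introns(ann)


class TestAssociateRsExon:
    def test_exon_starting_at_rs_point(self):
        link = associate_rs_exon(make_candidate(), ann_with_rs_exon((1000, 1087)))
        assert link.associated and link.exon == (1000, 1087)

    def test_zero_length_mode_no_exon(self):
        link = associate_rs_exon(make_candidate(), ann_with_rs_exon(None))
        assert not link.associated and link.exon is None

    def test_offset_start_outside_tolerance(self):
        link = associate_rs_exon(make_candidate(), ann_with_rs_exon((1005, 1090)))
        assert not link.associated
        link = associate_rs_exon(
            make_candidate(), ann_with_rs_exon((1005, 1090)), tolerance_nt=5
        )
        assert link.associated

    def test_minus_strand_uses_exon_end(self):
        ann = toy_annotation([(50, 200), (2200, 2300)], strand="-")
        ann.transcripts["g1.t2"] = Transcript(
            "g1.t2", "g1", "chr1", "-", [(50, 200), (910, 1000), (2200, 2300)]
        )
        derive_introns(ann)
        link = associate_rs_exon(make_candidate(strand="-"), ann)
        assert link.associated and link.exon == (910, 1000)


class TestCrypticExonFlag:
    def test_hand_computed_fold(self):
        """Exon mean 20 vs flank mean 5 -> (20.5)/(5.5) ~ 3.73 -> cryptic."""
        ann = ann_with_rs_exon((1000, 1090))
        link = associate_rs_exon(make_candidate(), ann)
        vals = np.full(2000, 5.0)
        vals[800:890] = 20.0  # exon is [1000,1090), track starts at 200
        cov = dense_track("chr1", 200, vals)
        link = cryptic_exon_flag(link, make_candidate(), cov)
        assert link.coverage_fold == pytest.approx(20.5 / 5.5)
        assert link.cryptic

    def test_equal_coverage_not_cryptic(self):
        ann = ann_with_rs_exon((1000, 1090))
        link = associate_rs_exon(make_candidate(), ann)
        cov = constant_track("chr1", 200, 2200, 7.0)
        link = cryptic_exon_flag(link, make_candidate(), cov)
        assert link.coverage_fold == pytest.approx(1.0) and not link.cryptic

    def test_all_zero_coverage_epsilon_forces_fold_one(self):
        from rescursor.genome_io import SignalTrack

        ann = ann_with_rs_exon((1000, 1090))
        link = associate_rs_exon(make_candidate(), ann)
        link = cryptic_exon_flag(link, make_candidate(), SignalTrack("coverage"))
        assert link.coverage_fold == 1.0 and not link.cryptic

    def test_unassociated_link_raises(self):
        link = associate_rs_exon(make_candidate(), ann_with_rs_exon(None))
        with pytest.raises(ValueError):
            cryptic_exon_flag(link, make_candidate(), constant_track("chr1", 0, 10, 1.0))


class TestStratifyConservation:
    def test_partition_and_boundary(self):
        cands = [
            make_candidate(conservation_mean=0.9),
            make_candidate(rs_point=1100, conservation_mean=0.1),
            make_candidate(rs_point=1200, conservation_mean=0.45),
        ]
        strata = stratify_conservation(cands)
        assert [c.conservation_mean for c in strata["high"]] == [0.9]
        assert sorted(c.conservation_mean for c in strata["low"]) == [0.1, 0.45]


class TestConservationProfile:
    def test_constant_track(self):
        t = constant_track("chr1", 0, 3000, 0.7, kind="conservation")
        prof = conservation_profile([("chr1", 1000, "+")], t, half_window=5)
        assert np.allclose(prof, 0.7)

    def test_single_site_equals_window_slice(self):
        vals = np.arange(100, dtype=float) / 100
        t = dense_track("chr1", 0, vals, kind="conservation")
        prof = conservation_profile([("chr1", 50, "+")], t, half_window=3)
        assert np.allclose(prof, vals[47:54])

    def test_minus_strand_reverses_offsets(self):
        vals = np.arange(100, dtype=float) / 100
        t = dense_track("chr1", 0, vals, kind="conservation")
        plus = conservation_profile([("chr1", 50, "+")], t, half_window=3)
        minus = conservation_profile([("chr1", 50, "-")], t, half_window=3)
        assert np.allclose(minus, plus[::-1])

    def test_mean_of_two_sites(self):
        t = dense_track("chr1", 0, np.r_[np.full(50, 0.2), np.full(50, 0.6)],
                        kind="conservation")
        prof = conservation_profile([("chr1", 25, "+"), ("chr1", 75, "+")], t, 3)
        assert np.allclose(prof, 0.4)

    def test_union_profile_is_weighted_mean(self):
        rng = np.random.default_rng(3)
        vals = rng.random(500)
        t = dense_track("chr1", 0, vals, kind="conservation")
        g1 = [("chr1", int(p), "+") for p in rng.integers(20, 480, 4)]
        g2 = [("chr1", int(p), "+") for p in rng.integers(20, 480, 8)]
        p1 = conservation_profile(g1, t, 5)
        p2 = conservation_profile(g2, t, 5)
        pu = conservation_profile(g1 + g2, t, 5)
        assert np.allclose(pu, (4 * p1 + 8 * p2) / 12)

    def test_empty_sites_raise(self):
        with pytest.raises(ValueError):
            conservation_profile([], constant_track("c", 0, 10, 0.5, "conservation"))

    def test_random_background_sites_stay_in_intron(self):
        sites = random_intronic_sites(
            [make_candidate()], np.random.default_rng(0), margin=20
        )
        ((_, p, _),) = sites
        assert 220 <= p < 2180


class TestSequencePPM:
    def test_single_sequence_one_hot(self):
        fasta = {"chr1": "AAAACGTAAAA"}
        m = sequence_probability_matrix([("chr1", 5, "+")], fasta, half_window=2)
        # window [3,8) = "ACGTA"
        assert m[0, 0] == 1.0 and m[1, 1] == 1.0 and m[2, 2] == 1.0 and m[3, 3] == 1.0

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(4)
        fasta = {"chr1": "".join(rng.choice(list("ACGT"), 400))}
        sites = [("chr1", int(p), "+") for p in rng.integers(30, 370, 25)]
        m = sequence_probability_matrix(sites, fasta, half_window=10)
        assert np.allclose(m.sum(axis=0), 1.0, atol=1e-12)

    def test_aligned_acceptor_ag(self):
        fasta = {"chr1": "T" * 30 + "AG" + "GT" + "T" * 30}
        # rs_point at 32: offsets -2,-1 are A,G
        m = sequence_probability_matrix([("chr1", 32, "+")], fasta, half_window=5)
        assert m[0, 3] == 1.0 and m[2, 4] == 1.0  # A at -2, G at -1

    def test_mixed_donors_half_half(self):
        fasta = {"chr1": "T" * 50 + "GT" + "T" * 50, "chr2": "T" * 50 + "AT" + "T" * 50}
        m = sequence_probability_matrix(
            [("chr1", 50, "+"), ("chr2", 50, "+")], fasta, half_window=3
        )
        assert m[2, 3] == 0.5 and m[0, 3] == 0.5  # G/A split at offset 0


class TestDonorClassEnrichment:
    def test_lost_an_depletion_signal(self):
        """10/12 lost vs 30/100 unchanged AN-donors: Fisher on
        [[10,2],[30,70]] is strongly significant (hypergeometric oracle)."""
        status, donors = {}, {}
        k = 0
        for i in range(12):
            status[f"l{i}"] = "lost"
            donors[f"l{i}"] = "AT" if i < 10 else "GT"
        for i in range(100):
            status[f"u{i}"] = "unchanged"
            donors[f"u{i}"] = "AC" if i < 30 else "GT"
        results = donor_class_enrichment(status, donors, ["AN"], ("lost",))
        (r,) = results
        assert r.table == ((10, 2), (30, 70))
        p_oracle = fisher_two_sided_exact(10, 2, 30, 70)
        assert r.p_value == pytest.approx(p_oracle, abs=1e-10)
        assert r.p_value < 1e-3

    def test_empty_pattern_flagged_p_one(self):
        status = {"a": "lost", "b": "unchanged"}
        donors = {"a": "GT", "b": "GT"}
        (r,) = donor_class_enrichment(status, donors, ["CN"], ("lost",))
        assert r.flagged and r.p_value == 1.0

    def test_balanced_table_or_one(self):
        status = {f"l{i}": "lost" for i in range(10)}
        status.update({f"u{i}": "unchanged" for i in range(10)})
        donors = {k: ("GT" if int(k[1:]) % 2 else "AT") for k in status}
        (r,) = donor_class_enrichment(status, donors, ["GT"], ("lost",))
        assert r.p_value == 1.0 and r.odds_ratio == pytest.approx(1.0)


class TestAsOverlapEnrichment:
    def _events(self, genes, as_type="CE"):
        return pd.DataFrame({"gene_id": list(genes), "as_type": as_type})

    def test_maximal_enrichment_closed_form(self):
        universe = {f"g{i}" for i in range(100)}
        type_genes = {f"g{i}" for i in range(10)}
        rs = set(type_genes)
        (r,) = as_overlap_enrichment(rs, self._events(type_genes), universe, ["CE"])
        from math import comb

        assert r.p_value == pytest.approx(1 / comb(100, 10), rel=1e-9)

    def test_zero_overlap_p_one(self):
        universe = {f"g{i}" for i in range(50)}
        (r,) = as_overlap_enrichment(
            {"g40"}, self._events({"g0", "g1"}), universe, ["CE"]
        )
        assert r.p_value == 1.0

    def test_saturated_universe_p_one(self):
        universe = {f"g{i}" for i in range(30)}
        (r,) = as_overlap_enrichment(
            universe, self._events({"g0", "g1", "g2"}), universe, ["CE"]
        )
        assert r.p_value == pytest.approx(1.0)

    def test_rs_gene_outside_universe_raises(self):
        with pytest.raises(ValueError, match="outside"):
            as_overlap_enrichment({"gX"}, self._events({"g0"}), {"g0"}, ["CE"])
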