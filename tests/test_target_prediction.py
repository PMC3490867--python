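import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dna
from helpers import brute_force_seed_sites, revcomp_dna
from polymirts.core_io import MatureMiRNA
from polymirts.target_prediction import (
    AU_FLANK,
    POSITION_BONUS,
    SITE_TYPE_TERM,
    TargetSite,
    assess_accessibility,
    check_conservation,
    context_score,
    find_compensatory_sites,
    find_seed_sites,
    predict_accessible_sites,
    rank_overrepresentation,
    seed_match_patterns,
)

# miRNA whose seed-complementary site is GGG followed by A's: its pairing
# behaviour under folding is fully controlled by nearby C/T content
OPEN_MIRNA = MatureMiRNA("mir-open", "AUUUUCCCACACACACACACAC")


class TestFindSeedSites:
    def test_let7a_8mer(self, let7a):
        sites = find_seed_sites("GGGGCTACCTCAGGGG", let7a)
        assert [(s.start, s.end, s.site_type) for s in sites] == [(4, 12, "8mer")]

    def test_no_sites_in_poly_g(self, let7a):
        assert find_seed_sites("G" * 50, let7a) == []

    def test_6mer_only(self, let7a):
        sites = find_seed_sites("TACCTCT", let7a)
        assert [(s.start, s.end, s.site_type) for s in sites] == [(0, 6, "6mer")]

    def test_7mer_variants(self, let7a):
        # m8 base present, no A1
        sites = find_seed_sites("GCTACCTCT", let7a)
        assert [(s.start, s.end, s.site_type) for s in sites] == [(1, 8, "7mer-m8")]
        # A1 present, no m8
        sites = find_seed_sites("TTACCTCAT", let7a)
        assert [(s.start, s.end, s.site_type) for s in sites] == [(1, 8, "7mer-A1")]

    def test_n_never_matches(self, let7a):
        assert find_seed_sites("GGGGCTACNTCAGGGG", let7a) == []

    def test_empty_input(self, let7a):
        assert find_seed_sites("", let7a) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random(self, seed, let7a):
        rng = np.random.default_rng(seed)
        utr = random_dna(rng, 400)
        # spike in real patterns so matches actually occur
        patterns = list(seed_match_patterns(let7a).values())
        for k in range(4):
            pos = int(rng.integers(0, 380))
            p = patterns[int(rng.integers(len(patterns)))]
            utr = utr[:pos] + p + utr[pos + len(p):]
        got = {(s.start, s.end, s.site_type) for s in find_seed_sites(utr, let7a)}
        assert got == brute_force_seed_sites(utr, let7a.sequence)

    def test_matches_brute_force_5kb(self, let7a):
        rng = np.random.default_rng(99)
        utr = random_dna(rng, 5000)
        got = {(s.start, s.end, s.site_type) for s in find_seed_sites(utr, let7a)}
        assert got == brute_force_seed_sites(utr, let7a.sequence)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_property_vs_oracle(self, seed):
        let7a = MatureMiRNA("let-7a", "UGAGGUAGUAGGUUGUAUAGUU")
        rng = np.random.default_rng(seed)
        utr = random_dna(rng, 150)
        got = {(s.start, s.end, s.site_type) for s in find_seed_sites(utr, let7a)}
        assert got == brute_force_seed_sites(utr, let7a.sequence)


class TestContextScore:
    def test_type_ordering(self, let7a):
        utr = "T" * 20 + "GCTACCTCAG" + "T" * 20
        s8 = TargetSite("let-7a", "u", 20, 28, "8mer", "seed_context")
        s6 = TargetSite("let-7a", "u", 21, 27, "6mer", "seed_context")
        assert context_score(s8, utr, let7a) > context_score(s6, utr, let7a)

    def test_au_flank_monotonic(self, let7a):
        site = lambda: TargetSite("let-7a", "u", 30, 38, "8mer", "seed_context")
        au_utr = "A" * 30 + "CTACCTCA" + "T" * 30
        gc_utr = "G" * 30 + "CTACCTCA" + "C" * 30
        assert context_score(site(), au_utr, let7a) > context_score(site(), gc_utr, let7a)

    def test_hand_computed_sum(self, let7a):
        # flanks: 10 nt left ("ATATATATAT": 10 AU), 12 nt right (all G)
        utr = "ATATATATAT" + "CTACCTCA" + "G" * 12
        site = TargetSite("let-7a", "u", 10, 18, "8mer", "seed_context")
        au = 10 / 22
        expected = 10.0 * (SITE_TYPE_TERM["8mer"] + au + 0.0)  # dist 10 < 15: no bonus
        assert context_score(site, utr, let7a) == pytest.approx(expected)

    def test_position_bonus_in_band(self, let7a):
        utr = "G" * 20 + "CTACCTCA" + "G" * 20
        site = TargetSite("let-7a", "u", 20, 28, "8mer", "seed_context")
        expected = 10.0 * (SITE_TYPE_TERM["8mer"] + 0.0 + POSITION_BONUS)
        assert context_score(site, utr, let7a) == pytest.approx(expected)

    def test_compensatory_rejected(self, let7a):
        site = TargetSite("let-7a", "u", 0, 7, "compensatory", "compensatory")
        with pytest.raises(ValueError, match="unsupported"):
            context_score(site, "A" * 40, let7a)

    def test_deterministic(self, let7a, rng):
        utr = random_dna(rng, 100)
        utr = utr[:40] + "CTACCTCA" + utr[48:]
        [site] = find_seed_sites(utr, let7a)
        assert context_score(site, utr, let7a) == context_score(site, utr, let7a)


def _open_site(utr):
    [site] = find_seed_sites(utr, OPEN_MIRNA)
    assert site.site_type == "8mer"
    return site


class TestAccessibility:
    # OPEN_MIRNA's 8mer site reads GGGAAAA + A; only its G's can ever pair
    # in a window that contains no T/U

    def test_hairpin_stem_blocks_site(self):
        # full reverse complement upstream: all 7 seed-pairing bases pair
        utr = "A" * 10 + "TTTTCCC" + "AAA" + "GGGAAAAA" + "A" * 10
        site = _open_site(utr)
        assert assess_accessibility(site, utr, folding_window=40) is False

    def test_homopolymer_flanks_open(self):
        utr = "A" * 15 + "GGGAAAAA" + "A" * 15
        site = _open_site(utr)
        assert assess_accessibility(site, utr, folding_window=40) is True

    def test_boundary_exactly_four_unpaired(self):
        # only CCC upstream: the 3 G's pair, the 4 A's cannot (no T around)
        utr = "A" * 10 + "CCC" + "AAA" + "GGGAAAAA" + "A" * 10
        site = _open_site(utr)
        assert assess_accessibility(site, utr, folding_window=40) is True

    def test_deterministic(self):
        utr = "A" * 10 + "CCC" + "AAA" + "GGGAAAAA" + "A" * 10
        site = _open_site(utr)
        results = {assess_accessibility(site, utr, folding_window=40) for _ in range(3)}
        assert len(results) == 1

    def test_predict_accessible_sites_flags(self):
        utr = "A" * 15 + "GGGAAAAA" + "A" * 15
        sites = predict_accessible_sites(utr, OPEN_MIRNA, folding_window=40)
        assert len(sites) == 1
        assert sites[0].accessible is True
        assert 0.0 < sites[0].score <= 1.0


class TestOverrepresentation:
    def test_count_zero_is_one(self, let7a):
        assert rank_overrepresentation(0, "ACGT" * 30, let7a) == 1.0

    def test_uniform_closed_form(self, let7a):
        utr = "ACGT" * 25  # uniform composition, length 100
        expected = 1 - (1 - 0.25 ** 7) ** 94
        assert rank_overrepresentation(1, utr, let7a) == pytest.approx(expected, rel=1e-9)

    def test_monotone_in_count(self, let7a):
        utr = "ACGT" * 25
        scores = [rank_overrepresentation(k, utr, let7a) for k in range(4)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_range(self, let7a, rng):
        utr = random_dna(rng, 200)
        for k in range(5):
            assert 0.0 < rank_overrepresentation(k, utr, let7a) <= 1.0


class TestCompensatory:
    def test_perfect_seed_not_reported(self, let7a):
        utr = "GG" + "TACAA" + "AAA" + "CTACCTCA" + "GG"
        spans = {s.span for s in find_compensatory_sites(utr, let7a)}
        canonical = {s.span for s in find_seed_sites(utr, let7a)}
        assert not spans & canonical

    def test_central_mismatch_with_3p_pairing(self, let7a):
        # seed window CTAGCTC: one defect at offset 3; nt13-17 block TACAA
        # placed 3 nt upstream of the seed region
        utr = "GG" + "TACAA" + "AAA" + "CTAGCTC" + "GG"
        sites = find_compensatory_sites(utr, let7a)
        assert [(s.start, s.end) for s in sites] == [(10, 17)]
        assert sites[0].site_type == "compensatory"

    def test_defect_without_3p_pairing_empty(self, let7a):
        utr = "GG" + "GGGGG" + "AAA" + "CTAGCTC" + "GG"
        assert find_compensatory_sites(utr, let7a) == []

    def test_bulge_rescued(self, let7a):
        # CTA|G|CCTC: removing the bulged G restores CTACCTC
        utr = "GG" + "TACAA" + "AAA" + "CTAGCCTC" + "GG"
        sites = find_compensatory_sites(utr, let7a)
        assert any(s.end - s.start == 8 for s in sites)

    def test_gap_outside_range_rejected(self, let7a):
        utr = "GG" + "TACAA" + "AAAAAAA" + "CTAGCTC" + "GG"  # gap 7 > 6
        assert find_compensatory_sites(utr, let7a) == []

    def test_never_overlaps_canonical_spans(self, let7a, rng):
        for _ in range(10):
            utr = random_dna(rng, 300)
            comp = {s.span for s in find_compensatory_sites(utr, let7a)}
            canon = {s.span for s in find_seed_sites(utr, let7a)}
            assert not comp & canon


class TestConservation:
    def test_same_site_string_conserved(self, let7a):
        site = TargetSite("let-7a", "u", 4, 12, "8mer", "seed_context")
        assert check_conservation(site, "TTCTACCTCATT", let7a) is True

    def test_no_family_site_not_conserved(self, let7a):
        site = TargetSite("let-7a", "u", 4, 12, "8mer", "seed_context")
        assert check_conservation(site, "G" * 40, let7a) is False

    def test_weaker_family_site_suffices(self, let7a):
        # ortholog holds a 7mer-A1 while the query site is an 8mer
        site = TargetSite("let-7a", "u", 4, 12, "8mer", "seed_context")
        assert check_conservation(site, "TTTACCTCATT", let7a) is True

    def test_empty_ortholog_raises(self, let7a):
        site = TargetSite("let-7a", "u", 4, 12, "8mer", "seed_context")
        with pytest.raises(ValueError):
            check_conservation(site, "", let7a)


def test_site_span_invariants(let7a, rng):
    for _ in range(5):
        utr = random_dna(rng, 500)
        for s in find_seed_sites(utr, let7a):
            assert 0 <= s.start < s.end <= len(utr)
            assert s.end - s.start in (6, 7, 8)
            assert "N" not in utr[s.start:s.end]
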