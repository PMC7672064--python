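import numpy as np
import pytest

from orbitag import (
    Peak,
    ProteinRecord,
    Spectrum,
    Tolerance,
    common_peak_fraction,
    common_peak_percent,
    kmer_uniqueness,
    score_proteins,
    search_tags,
    sequence_coverage,
)
from orbitag.identify import TagMatch, make_reversed_decoys
from orbitag.simulate import AA20, make_decoy_db
from oracles import brute_force_kmer_uniqueness, naive_tag_search


class TestSearchTags:
    def test_forward_match_position(self):
        db = [ProteinRecord("p1", "", "MKVFGRCELA"), ProteinRecord("p2", "", "AAAAAAAA")]
        out = search_tags(["KVFGRC"], db)
        assert len(out) == 1
        m = out[0]
        assert (m.protein, m.start, m.orientation, m.length) == ("p1", 2, "forward", 6)

    def test_reverse_match(self):
        db = [ProteinRecord("p1", "", "QQWAGQQ")]
        out = search_tags(["GAW"], db)
        assert len(out) == 1
        assert (out[0].start, out[0].orientation) == (3, "reverse")

    def test_lysozyme_n_terminal_diagnostic(self, lysozyme, decoy_db):
        # the KVFGRC tag characteristic of hen lysozyme must hit the
        # lysozyme record in any database containing it
        out = search_tags(["KVFGRC"], decoy_db)
        assert any(m.protein == "LYSC_CHICK" and m.start == 1 for m in out)

    def test_bracketed_alternatives_expand(self):
        db = [ProteinRecord("p1", "", "GAKW"), ProteinRecord("p2", "", "GAQW")]
        out = search_tags(["GA[KQ]W"], db)
        assert {m.protein for m in out} == {"p1", "p2"}

    def test_il_collapse_in_database(self):
        db = [ProteinRecord("p1", "", "GLIG")]
        out = search_tags(["JJ"], db)
        assert out and out[0].start == 2

    def test_overlapping_occurrences_all_reported(self):
        db = [ProteinRecord("p1", "", "AAAA")]
        out = search_tags(["AA"], db)
        assert [m.start for m in out] == [1, 2, 3]

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            search_tags(["GAW"], [])

    def test_matches_naive_scan_oracle(self):
        rng = np.random.default_rng(11)
        db = make_decoy_db(50, length_range=(40, 2000), seed=3)
        sequences = {r.identifier: r.sequence for r in db}
        tags = []
        # real substrings, reversed substrings, and random strings
        for _ in range(10):
            rec = db[rng.integers(0, len(db))]
            i = int(rng.integers(0, len(rec.sequence) - 8))
            tags.append(rec.sequence[i : i + 6].replace("I", "J").replace("L", "J"))
        tags += ["".join(AA20[j] for j in rng.integers(0, 20, 5)) for _ in range(5)]
        tags += ["GA[KQ]W", "A[ST]C"]
        for tag in tags:
            expected = sorted(naive_tag_search(tag, sequences))
            got = sorted(
                (m.protein, m.start, m.orientation) for m in search_tags([tag], db)
            )
            assert got == expected


class TestScoring:
    def test_single_unique_six_step_tag(self):
        db = [ProteinRecord("p1", "", "MKVFGRCELA"), ProteinRecord("p2", "", "WWWWWWWW")]
        matches = [TagMatch(0, "p1", 2, "forward", 6)]
        results = score_proteins(matches, db)
        assert results[0].protein == "p1"
        assert results[0].score == (6 - 2) * 2

    def test_no_matches_empty_ranking(self):
        db = [ProteinRecord("p1", "", "MKVFGRCELA")]
        assert score_proteins([], db) == []

    def test_short_tags_get_no_uniqueness_bonus(self):
        db = [ProteinRecord("p1", "", "MKVFGRCELA")]
        matches = [TagMatch(0, "p1", 2, "forward", 4)]
        assert score_proteins(matches, db)[0].score == (4 - 2) * 1

    def test_shared_tag_counts_once_per_protein_no_bonus(self):
        db = [ProteinRecord("p1", "", "AKVFGRCA"), ProteinRecord("p2", "", "KVFGRCWW")]
        matches = [
            TagMatch(0, "p1", 2, "forward", 6),
            TagMatch(0, "p2", 1, "forward", 6),
        ]
        results = score_proteins(matches, db)
        assert all(r.score == 4 for r in results)
        assert results[0].ambiguous  # tie within 10%

    def test_score_monotone_in_added_tags(self):
        db = [ProteinRecord("p1", "", "MKVFGRCELAWNQH")]
        base = [TagMatch(0, "p1", 2, "forward", 6)]
        more = base + [TagMatch(1, "p1", 9, "forward", 5)]
        s0 = score_proteins(base, db)[0]
        s1 = score_proteins(more, db)[0]
        assert s1.score >= s0.score
        assert s1.coverage_percent >= s0.coverage_percent

    def test_unambiguous_requires_long_unique_tag(self):
        db = [ProteinRecord("p1", "", "MKVFGRCELAWNQHYSTV")]
        short = score_proteins([TagMatch(0, "p1", 2, "forward", 6)], db)[0]
        assert not short.unambiguous_identification
        long = score_proteins([TagMatch(0, "p1", 2, "forward", 8)], db)[0]
        assert long.unambiguous_identification


class TestCoverage:
    # the published worked examples: 68/129 -> 53%, 33/679 -> 5%
    @pytest.mark.parametrize(
        "n,length,expected", [(68, 129, 53), (33, 679, 5), (0, 100, 0)]
    )
    def test_rounding_contract(self, n, length, expected):
        assert sequence_coverage(n, length) == expected

    def test_positions_deduplicated(self):
        assert sequence_coverage([1, 2, 2, 3], 6) == 50

    def test_positions_validated(self):
        with pytest.raises(ValueError):
            sequence_coverage([0, 5], 10)


class TestCommonPeaks:
    def test_published_counts_round_to_32(self):
        assert common_peak_percent(1178, 3709) == 32

    def test_identical_spectra(self):
        s = Spectrum(peaks=[Peak(400.0, 1), Peak(500.0, 1)])
        assert common_peak_fraction(s, s) == (2, 2, 100)

    def test_disjoint_spectra(self):
        a = Spectrum(peaks=[Peak(400.0, 1)])
        b = Spectrum(peaks=[Peak(900.0, 1)])
        assert common_peak_fraction(a, b) == (0, 1, 0)

    def test_each_b_peak_used_once(self):
        # two A peaks near one B peak: only one can pair
        a = Spectrum(peaks=[Peak(500.0, 1), Peak(500.0005, 1)])
        b = Spectrum(peaks=[Peak(500.0001, 1)])
        n, total, pct = common_peak_fraction(a, b, Tolerance(2.0))
        assert (n, total, pct) == (1, 2, 50)


class TestKmerUniqueness:
    def test_duplicate_sequences_share_every_kmer(self):
        rng = np.random.default_rng(2)
        third = "".join(AA20[j] for j in rng.integers(0, 20, 50))
        db = [
            ProteinRecord("a", "", "KVFGRCELAW" * 3),
            ProteinRecord("b", "", "KVFGRCELAW" * 3),
            ProteinRecord("c", "", third),
        ]
        assert kmer_uniqueness(db, 8) == pytest.approx(1 / 3)

    def test_random_sequences_all_unique(self):
        db = make_decoy_db(20, length_range=(100, 100), seed=9)
        assert kmer_uniqueness(db, 8) == 1.0

    def test_k_longer_than_sequences(self):
        db = [ProteinRecord("a", "", "KVFGR"), ProteinRecord("b", "", "WNQHY")]
        assert kmer_uniqueness(db, 8) == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            db = make_decoy_db(
                int(rng.integers(5, 30)), length_range=(10, 120), seed=trial
            )
            # plant duplicates to exercise the shared-kmer path
            db[1] = ProteinRecord("dup", "", db[0].sequence)
            for k in (3, 8):
                expected = brute_force_kmer_uniqueness(
                    [r.sequence for r in db], k
                )
                assert kmer_uniqueness(db, k) == pytest.approx(expected)

    def test_k_validated(self, lysozyme):
        with pytest.raises(ValueError):
            kmer_uniqueness([lysozyme], 0)


def test_reversed_decoys_preserve_length(lysozyme):
    decoys = make_reversed_decoys([lysozyme])
    assert decoys[0].sequence == lysozyme.sequence[::-1]
    assert decoys[0].identifier.startswith("decoy_")
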