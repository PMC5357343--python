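"""Index extraction, whitelist filtering and index-distribution statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from midedup.mi_extract import (
    ChiSquareResult,
    DelimiterCollisionError,
    Mate,
    MIExtractionError,
    MIWhitelist,
    RawRead,
    chi_square_homogeneity,
    chi_square_uniform,
    extract_mi,
    extract_stream,
    filter_whitelist,
    index_counts,
    match_whitelist,
    pair_passes,
    parse_tagged_name,
    perfect_index_summary,
    read_tagged_fastq,
    tagged_name,
    write_tagged_fastq,
)

BASES = np.array(list("ACGT"))


def random_seq(rng, n):
    return "".join(rng.choice(BASES, size=n))


class TestExtract:
    def test_slicing_definition(self):
        read = RawRead("r1", "ACGTACGTA" + "TTTT", "I" * 13)
        t = extract_mi(read)
        assert t.mi == "ACGTACGT"
        assert t.spacer_ok is True
        assert t.cdna_sequence == "TTTT"
        assert t.cdna_qualities == "IIII"

    def test_100nt_read_gives_91nt_cdna(self, rng):
        read = RawRead("r1", random_seq(rng, 100), "I" * 100)
        t = extract_mi(read)
        assert len(t.mi) == 8
        assert len(t.cdna_sequence) == 91

    def test_bad_spacer_flagged(self):
        read = RawRead("r1", "ACGTACGT" + "G" + "TTTT", "I" * 13)
        assert extract_mi(read).spacer_ok is False

    def test_too_short_read_raises(self):
        with pytest.raises(MIExtractionError):
            extract_mi(RawRead("r1", "ACGTACGTA", "I" * 9))

    def test_stream_collects_errors_and_planted_spacers(self, rng):
        # 1,000 reads, exactly 30 with a planted non-A spacer
        reads = []
        bad_idx = set(rng.choice(1000, size=30, replace=False).tolist())
        for i in range(1000):
            seq = list(random_seq(rng, 50))
            seq[8] = "C" if i in bad_idx else "A"
            reads.append(RawRead(f"r{i}", "".join(seq), "I" * 50))
        reads.append(RawRead("short", "ACGT", "IIII"))
        tagged, errors = extract_stream(reads)
        assert len(tagged) == 1000
        assert len(errors) == 1 and errors[0]["read_id"] == "short"
        assert sum(not t.spacer_ok for t in tagged) == 30

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_reconstruction_invariant(self, seed):
        """mi + spacer + cdna reproduces the raw sequence for spacer-ok reads."""
        r = np.random.default_rng(seed)
        seq = random_seq(r, int(r.integers(11, 120)))
        read = RawRead("x", seq, "".join(chr(33 + int(q)) for q in r.integers(0, 42, len(seq))))
        t = extract_mi(read)
        if t.spacer_ok:
            assert t.mi + "A" + t.cdna_sequence == seq
        assert t.mi + read.sequence[8] + t.cdna_sequence == seq
        assert t.cdna_qualities == read.qualities[9:]


class TestWhitelist:
    @pytest.fixture
    def wl(self):
        return MIWhitelist(
            frozenset({"AAAAAAAA", "CCCCCCCC"}), frozenset({"GGGGGGGG", "TTTTTTTT"})
        )

    def test_exact_membership(self, wl):
        assert match_whitelist("AAAAAAAA", wl.forward_set, 0)
        assert not match_whitelist("AAAAAAAC", wl.forward_set, 0)

    def test_one_mismatch_accepted_when_unique(self, wl):
        assert match_whitelist("AAAAAAAC", wl.forward_set, 1)

    def test_ambiguous_match_rejected(self):
        entries = frozenset({"AAAA", "AACC"})
        # "AACA" is at distance 1 from both entries -> ambiguous
        assert not match_whitelist("AACA", entries, 1)

    def test_pair_requires_both_mates(self, wl):
        from midedup.mi_extract import TaggedRead

        fwd = TaggedRead("r", "ACGT", "IIII", "AAAAAAAA", True, mate=Mate.FORWARD)
        rev_ok = TaggedRead("r", "ACGT", "IIII", "GGGGGGGG", True, mate=Mate.REVERSE)
        rev_bad = TaggedRead("r", "ACGT", "IIII", "AAAAAAAA", True, mate=Mate.REVERSE)
        assert pair_passes(fwd, rev_ok, wl)
        assert not pair_passes(fwd, rev_bad, wl)  # forward 8-mer is not on the reverse side

    def test_acceptance_matches_bruteforce_hamming(self, rng):
        """Planted mismatches: acceptance equals an exhaustive Hamming scan."""
        entries = frozenset("".join(rng.choice(BASES, 8)) for _ in range(40))
        queries = []
        for _ in range(300):
            base = str(rng.choice(sorted(entries)))
            seq = list(base)
            for pos in rng.choice(8, size=int(rng.integers(0, 3)), replace=False):
                seq[pos] = str(rng.choice(BASES))
            queries.append("".join(seq))
        for mm in (0, 1):
            for q in queries:
                dists = sorted(sum(a != b for a, b in zip(q, e)) for e in entries)
                expect = dists[0] == 0 or (
                    dists[0] <= mm and (len(dists) < 2 or dists[1] > dists[0])
                )
                assert match_whitelist(q, entries, mm) == expect, (q, mm)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_acceptance_monotone_in_mismatch_budget(self, seed):
        r = np.random.default_rng(seed)
        entries = frozenset("".join(r.choice(BASES, 6)) for _ in range(10))
        q = "".join(r.choice(BASES, 6))
        accepted = [match_whitelist(q, entries, mm) for mm in range(4)]
        # exact membership can only gain matches as the budget grows, except
        # where ambiguity kicks in; membership at 0 implies acceptance at any mm
        if accepted[0]:
            assert all(accepted)

    def test_filter_whitelist_sets_flag(self, wl):
        from midedup.mi_extract import TaggedRead

        t = TaggedRead("r", "ACGT", "IIII", "AAAAAAAA", True, mate=Mate.FORWARD)
        assert filter_whitelist(t, wl).whitelist_ok is True
        t2 = TaggedRead("r", "ACGT", "IIII", "AAAATTTT", True, mate=Mate.FORWARD)
        assert filter_whitelist(t2, wl).whitelist_ok is False

    def test_perfect_index_summary_per_read_and_pair(self):
        s = perfect_index_summary([True, True, False], [True, False, False])
        assert s.n_reads == 6 and s.n_perfect_reads == 3
        assert s.per_read_fraction == 0.5
        assert s.n_pairs == 3 and s.n_perfect_pairs == 1
        assert s.per_pair_fraction == pytest.approx(1 / 3)


class TestTaggedFastq:
    def test_naming_convention(self):
        assert tagged_name("r1", ["AACCGGTT"]) == "r1_AACCGGTT"
        assert tagged_name("r1", ["AAAA", "TTTT"]) == "r1_AAAA_TTTT"

    def test_delimiter_collision_fails_loudly(self):
        with pytest.raises(DelimiterCollisionError):
            tagged_name("r_1", ["AAAA"])

    def test_delimiter_escape_round_trips(self):
        name = tagged_name("r_1%x", ["AAAA"], on_collision="escape")
        rid, mis = parse_tagged_name(name, 1)
        assert rid == "r_1%x" and mis == ("AAAA",)

    def test_roundtrip_over_random_reads(self, rng, tmp_path):
        """Write -> read preserves (id, mi_fwd, mi_rev) for 10,000 random reads."""
        recs = []
        for i in range(10_000):
            recs.append(
                (
                    f"read{i}.{rng.integers(1e6)}",
                    random_seq(rng, 30),
                    "I" * 30,
                    ("".join(rng.choice(BASES, 8)), "".join(rng.choice(BASES, 8))),
                )
            )
        path = tmp_path / "tagged.fastq"
        assert write_tagged_fastq(path, recs) == 10_000
        back = list(read_tagged_fastq(path, n_mis=2))
        assert [(r[0], r[3]) for r in back] == [(r[0], r[3]) for r in recs]
        assert [r[1] for r in back] == [r[1] for r in recs]


class TestChiSquare:
    def test_perfect_uniformity(self):
        res = chi_square_uniform([50, 50, 50, 50])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form_60_40(self):
        res = chi_square_uniform([60, 40])
        assert res.statistic == pytest.approx(4.0)
        assert res.df == 1
        assert res.p_value == pytest.approx(0.04550026389635857)

    def test_low_expected_flag(self):
        assert chi_square_uniform([3, 2]).low_expected is True
        assert chi_square_uniform([50, 50]).low_expected is False

    def test_statistic_zero_iff_equal_and_permutation_invariant(self, rng):
        counts = rng.integers(1, 100, size=12)
        res = chi_square_uniform(counts)
        perm = rng.permutation(counts)
        assert chi_square_uniform(perm).statistic == pytest.approx(res.statistic)
        assert (res.statistic == 0) == bool(len(set(counts.tolist())) == 1)

    def test_homogeneity_identical_samples(self):
        v = {"a": 10, "b": 20, "c": 30}
        res = chi_square_homogeneity([v, v])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_homogeneity_2x2_textbook_value(self):
        # hand computation: all expected cells 15, X2 = 4 * 25/15 = 20/3
        res = chi_square_homogeneity([{"a": 10, "b": 20}, {"a": 20, "b": 10}])
        assert res.statistic == pytest.approx(20 / 3)
        assert res.df == 1
        assert res.p_value == pytest.approx(0.009823274507519235)

    def test_homogeneity_mismatched_categories_names_offenders(self):
        with pytest.raises(ValueError, match="zzz"):
            chi_square_homogeneity([{"a": 1, "b": 2}, {"a": 1, "zzz": 2}])

    def test_homogeneity_type_one_error_calibrated(self, rng):
        """Samples from one multinomial reject at roughly the nominal 5% rate."""
        k, n, reps = 20, 2000, 400
        p = np.ones(k) / k
        rejections = 0
        for _ in range(reps):
            a = rng.multinomial(n, p)
            b = rng.multinomial(n, p)
            res = chi_square_homogeneity(
                [dict(zip(map(str, range(k)), a)), dict(zip(map(str, range(k)), b))]
            )
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_index_counts_tally(self):
        assert index_counts(["A", "B", "A"]) == {"A": 2, "B": 1}
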