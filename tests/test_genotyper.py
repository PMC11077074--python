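"""Fuzzy matching, re-mapping classification, rule engine and calls."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from polyfusion.experiments import best_infix_distance
from polyfusion.genome import revcomp
from polyfusion.genotyper import (
    BreakpointQuery,
    GenotypeRule,
    SeedExtendMapper,
    call_genotype,
    fuzzy_match,
    quality_filter,
    remap_classify,
)


def mutate(seq, positions, rng):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestFuzzyMatch:
    def test_exact_containment(self):
        q = "ACGTACGTAACC"
        read = "TTTT" + q + "GGGG"
        (m,) = fuzzy_match(q, [("r1", read)], max_edits=0)
        assert (m.strand, m.edit_distance) == ("+", 0)

    def test_two_substitutions_need_k2(self):
        rng = np.random.default_rng(0)
        q = "ACGTACGTAACCGGTTACGT"
        read = "AAAA" + mutate(q, [3, 11], rng) + "CCCC"
        assert fuzzy_match(q, [("r", read)], max_edits=1) == []
        (m,) = fuzzy_match(q, [("r", read)], max_edits=2)
        assert m.edit_distance == 2

    def test_reverse_complement_only_matches_minus_strand(self):
        q = "ACGTACGTAACCGGTT"
        read = "TTTT" + revcomp(q) + "AAAA"
        (m,) = fuzzy_match(q, [("r", read)], max_edits=0)
        assert m.strand == "-"

    def test_non_acgt_query_rejected(self):
        with pytest.raises(ValueError):
            fuzzy_match("ACGTN", [("r", "ACGTACGT")], max_edits=0)

    def test_n_in_read_counts_as_mismatch(self):
        q = "ACGTACGTAACC"
        read = "TT" + q.replace("G", "N", 1) + "TT"
        assert fuzzy_match(q, [("r", read)], max_edits=0) == []
        (m,) = fuzzy_match(q, [("r", read)], max_edits=1)
        assert m.edit_distance == 1

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_monotone_in_max_edits(self, k):
        rng = np.random.default_rng(k)
        bases = np.array(list("ACGT"))
        reads = [(f"r{i}", "".join(rng.choice(bases, 60))) for i in range(30)]
        q = "".join(rng.choice(bases, 15))
        smaller = {m.read_id for m in fuzzy_match(q, reads, max_edits=k)}
        larger = {m.read_id for m in fuzzy_match(q, reads, max_edits=k + 1)}
        assert smaller <= larger

    @given(
        st.data(),
        st.integers(8, 16),
        st.integers(30, 60),
        st.integers(0, 3),
    )
    def test_agrees_with_exhaustive_dp_oracle(self, data, qlen, rlen, k):
        bases = "ACGT"
        q = "".join(data.draw(st.sampled_from(bases)) for _ in range(qlen))
        read = "".join(data.draw(st.sampled_from(bases)) for _ in range(rlen))
        oracle = best_infix_distance(q, read)
        matches = fuzzy_match(q, [("r", read)], max_edits=k)
        if oracle <= k:
            assert len(matches) == 1 and matches[0].edit_distance == oracle
        else:
            assert matches == []

    def test_strand_symmetry_of_match_sets(self):
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        q = "".join(rng.choice(bases, 20))
        reads = [(f"r{i}", "".join(rng.choice(bases, 80))) for i in range(20)]
        reads[5] = ("r5", reads[5][1][:10] + q + reads[5][1][30:])
        flipped = [(rid, revcomp(seq)) for rid, seq in reads]
        ids = {m.read_id for m in fuzzy_match(q, reads, max_edits=1)}
        ids_flipped = {m.read_id for m in fuzzy_match(q, flipped, max_edits=1)}
        assert ids == ids_flipped


@pytest.fixture(scope="module")
def locus():
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    ref = "".join(rng.choice(bases, 12_000))
    # plant a decoy copy of the window's core far outside the window
    window = (2_000, 5_000)
    core = ref[3_000:3_150]
    ref = ref[:9_000] + core + ref[9_150:]
    mapper = SeedExtendMapper({"chrT": ref})
    return ref, mapper, ("chrT", *window)


class TestRemapClassify:
    def test_unique_in_window_read_is_true_positive(self, locus):
        ref, mapper, window = locus
        cls, _ = remap_classify(ref[2_500:2_600], mapper, window)
        assert cls == "TRUE_POSITIVE"

    def test_unique_out_of_window_read_is_false_positive(self, locus):
        ref, mapper, window = locus
        cls, _ = remap_classify(ref[7_000:7_100], mapper, window)
        assert cls == "FALSE_POSITIVE"

    def test_read_matching_window_and_decoy_is_uncertain(self, locus):
        ref, mapper, window = locus
        cls, alignments = remap_classify(ref[3_020:3_120], mapper, window)
        assert cls == "UNCERTAIN"
        assert len(alignments) == 2

    def test_junction_read_rescued_by_target_contig(self, locus):
        ref, mapper, window = locus
        junction = ref[2_500:2_550] + revcomp(ref[4_000:4_050])
        aware = SeedExtendMapper({"chrT": ref, "jx": junction}, target_contigs={"jx"})
        cls, _ = remap_classify(junction, aware, window)
        assert cls == "TRUE_POSITIVE"
        # without the junction contig the read has no >=90-score alignment
        cls_plain, _ = remap_classify(junction, mapper, window)
        assert cls_plain is None

    def test_reverse_complement_read_maps_identically(self, locus):
        ref, mapper, window = locus
        read = ref[2_500:2_600]
        cls_f, a_f = remap_classify(read, mapper, window)
        cls_r, a_r = remap_classify(revcomp(read), mapper, window)
        assert cls_f == cls_r == "TRUE_POSITIVE"
        assert a_f[0].start == a_r[0].start


class TestRuleEngine:
    def test_sc_style_rule_calls(self):
        rule = GenotypeRule("CTRL & JUNCTION & !DEL_INTERNAL")
        assert call_genotype({"CTRL": 3, "JUNCTION": 2, "DEL_INTERNAL": 0}, rule).call == "POSITIVE"
        assert call_genotype({"CTRL": 3, "JUNCTION": 0, "DEL_INTERNAL": 5}, rule).call == "NEGATIVE"
        assert call_genotype({"CTRL": 0, "JUNCTION": 0, "DEL_INTERNAL": 0}, rule).call == "NO_CALL"

    def test_min_reads_present_threshold(self):
        rule = GenotypeRule("JUNCTION", min_reads_present=3)
        assert call_genotype({"JUNCTION": 2}, rule).call == "NEGATIVE"
        assert call_genotype({"JUNCTION": 3}, rule).call == "POSITIVE"

    def test_parentheses_and_or(self):
        rule = GenotypeRule("(A | B) & !C")
        assert rule.evaluate({"A": False, "B": True, "C": False})
        assert not rule.evaluate({"A": True, "B": True, "C": True})

    def test_unknown_query_in_rule_raises(self):
        rule = GenotypeRule("CTRL & MISSING")
        with pytest.raises(KeyError):
            call_genotype({"CTRL": 3}, rule)

    @pytest.mark.parametrize("bad", ["A &", "& A", "(A", "A ! B", ""])
    def test_syntax_errors_rejected(self, bad):
        with pytest.raises(ValueError):
            GenotypeRule(bad)


class TestQualityFilter:
    def test_low_quality_and_n_heavy_reads_dropped(self):
        reads = [
            ("ok", "ACGTACGTAC", "I" * 10),
            ("lowq", "ACGTACGTAC", "#" * 10),
            ("enns", "ANNNNCGTAC", "I" * 10),
        ]
        kept = [rid for rid, _ in quality_filter(reads)]
        assert kept == ["ok"]


class TestQueryValidation:
    def test_window_must_exceed_twice_query_length(self):
        with pytest.raises(ValueError, match="window too narrow"):
            BreakpointQuery("q", "ACGT" * 20, "CTRL", "chrT", 0, 100).validate()

    def test_lowercase_sequence_rejected(self):
        with pytest.raises(ValueError, match="uppercase"):
            BreakpointQuery("q", "acgtacgt", "CTRL", "chrT", 0, 1000).validate()
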