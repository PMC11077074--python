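"""Discordant-pair extraction, SV-type rules and chimera matching."""

import numpy as np
import pandas as pd
import pytest

from polyfusion import experiments
from polyfusion.genome import apply_sv
from polyfusion.reads import ReadSimConfig, simulate_wgs
from polyfusion.sv_evidence import (
    InsertModel,
    PairCluster,
    SVCall,
    classify_sv,
    extract_signatures,
    match_sv_to_chimera,
    pairs_from_readset,
    pairs_from_sam,
)

MODEL = InsertModel(mean=350, sd=50)


def fr_pair(left, insert, read_length=100):
    return {"r1_pos": left, "r1_strand": 1, "r2_pos": left + insert - read_length,
            "r2_strand": -1, "read_length": read_length}


class TestExtractSignatures:
    def test_concordant_fr_pair_excluded(self):
        pairs = pd.DataFrame([fr_pair(1_000, 350)])
        assert extract_signatures(pairs, MODEL) == []

    def test_long_insert_fr_pair_clusters(self):
        pairs = pd.DataFrame([fr_pair(1_000 + i * 10, 350 + 4 * 50) for i in range(4)])
        (cluster,) = extract_signatures(pairs, MODEL)
        assert cluster.orientation == "FR_LONG"
        assert cluster.n == 4

    def test_clusters_split_by_gap(self):
        pairs = pd.DataFrame(
            [fr_pair(1_000, 600)] * 3 + [fr_pair(9_000, 600)] * 3
        )
        clusters = extract_signatures(pairs, MODEL)
        assert sorted(c.n for c in clusters) == [3, 3]

    def test_support_invariant_under_row_shuffling(self, rng):
        pairs = pd.DataFrame(
            [fr_pair(1_000 + i * 20, 700) for i in range(6)]
            + [fr_pair(3_000 + i * 20, 350) for i in range(10)]
        )
        shuffled = pairs.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = sorted((c.orientation, c.n) for c in extract_signatures(pairs, MODEL))
        b = sorted((c.orientation, c.n) for c in extract_signatures(shuffled, MODEL))
        assert a == b

    def test_rr_cluster_near_planted_inversion_breakpoint(self, genome):
        sv = experiments.toy_sv("INV")
        alt = apply_sv(genome.sequence, sv)
        rs = simulate_wgs(genome.sequence, alt, 1, ReadSimConfig(seed=4),
                          with_sequences=False)
        clusters = extract_signatures(pairs_from_readset(rs), MODEL)
        rr = [c for c in clusters if c.orientation == "RR" and c.n >= 3]
        assert rr
        (a, b), = sv.breakpoints
        assert min(abs(rr[0].left_pos.min() - a), abs(rr[0].left_pos.min() - b)) < 1_000


def synthetic_cluster(orientation, left, right, n, read_length=100):
    lefts = np.array([left + 10 * i for i in range(n)])
    rights = np.array([right + 10 * i for i in range(n)])
    return PairCluster(orientation, lefts, lefts + read_length, rights, rights + read_length)


class TestClassifySV:
    def flat_coverage(self, length=50_000, depth=30.0):
        return np.full(length, depth)

    def test_ff_and_rr_with_flat_coverage_is_inversion(self):
        clusters = [
            synthetic_cluster("FF", 20_000, 24_700, 5),
            synthetic_cluster("RR", 20_000, 24_900, 5),
        ]
        call = classify_sv(clusters, self.flat_coverage(), MODEL)
        assert call.sv_type == "INV"

    def test_rf_with_coverage_gain_is_duplication(self):
        coverage = self.flat_coverage()
        coverage[20_000:24_000] *= 2.0
        call = classify_sv([synthetic_cluster("RF", 20_000, 23_900, 5)], coverage, MODEL)
        assert call.sv_type == "DUP"
        assert call.coverage_ratio == pytest.approx(2.0, rel=0.05)

    def test_rf_without_gain_is_none(self):
        call = classify_sv([synthetic_cluster("RF", 20_000, 23_900, 5)],
                           self.flat_coverage(), MODEL)
        assert call.sv_type == "NONE"

    def test_long_fr_with_loss_is_deletion(self):
        coverage = self.flat_coverage()
        coverage[25_000:28_000] *= 0.5
        call = classify_sv([synthetic_cluster("FR_LONG", 24_800, 28_050, 5)], coverage, MODEL)
        assert call.sv_type == "DEL"

    def test_inversion_with_adjacent_depletion_is_complex(self):
        coverage = self.flat_coverage()
        coverage[24_824:28_052] *= 0.4
        clusters = [
            synthetic_cluster("FF", 20_000, 24_700, 5),
            synthetic_cluster("RR", 20_000, 27_952, 5),
        ]
        call = classify_sv(clusters, coverage, MODEL)
        assert call.sv_type == "COMPLEX_INV_DEL"
        assert len(call.breakpoints) == 2

    def test_below_min_support_is_none(self):
        clusters = [
            synthetic_cluster("FF", 20_000, 24_700, 2),
            synthetic_cluster("RR", 20_000, 24_900, 2),
        ]
        assert classify_sv(clusters, self.flat_coverage(), MODEL).sv_type == "NONE"

    def test_breakpoint_localization_within_insert_mean(self, genome):
        for sv_type in ("DEL", "INV"):
            sv = experiments.toy_sv(sv_type)
            alt = apply_sv(genome.sequence, sv)
            rs = simulate_wgs(genome.sequence, alt, 1, ReadSimConfig(seed=13),
                              with_sequences=False)
            call = classify_sv(
                extract_signatures(pairs_from_readset(rs), MODEL),
                rs.coverage_profile(), MODEL,
            )
            assert call.sv_type == sv_type
            (truth_lo, truth_hi) = sv.breakpoints[0]
            (lo, hi) = call.breakpoints[0]
            assert abs(lo - truth_lo) <= MODEL.mean
            assert abs(hi - truth_hi) <= MODEL.mean


class TestMatchSVToChimera:
    GENE5 = ("chrT", 8_000, 18_250, "+")

    def test_deletion_fusing_same_strand_neighbours(self):
        call = SVCall("DEL", ((20_000, 28_000),))
        gene3 = ("chrT", 30_000, 36_220, "+")
        status, _ = match_sv_to_chimera(call, self.GENE5, gene3)
        assert status == "DIRECT_EVIDENCE"

    def test_inversion_reorienting_opposite_strand_pair(self):
        call = SVCall("INV", ((20_000, 24_824),))
        gene3 = ("chrT", 30_000, 36_220, "-")
        status, _ = match_sv_to_chimera(call, self.GENE5, gene3)
        assert status == "DIRECT_EVIDENCE"

    def test_inversion_of_same_strand_pair_is_not_evidence(self):
        call = SVCall("INV", ((20_000, 24_824),))
        gene3 = ("chrT", 30_000, 36_220, "+")
        status, _ = match_sv_to_chimera(call, self.GENE5, gene3)
        assert status == "NO_EVIDENCE"

    def test_interchromosomal_pair_never_matches(self):
        call = SVCall("DEL", ((20_000, 28_000),))
        gene3 = ("chr9", 30_000, 36_220, "+")
        status, reason = match_sv_to_chimera(call, self.GENE5, gene3)
        assert status == "NO_EVIDENCE"
        assert "interchromosomal" in reason

    def test_distant_breakpoints_rejected(self):
        call = SVCall("DEL", ((500_000, 540_000),))
        gene3 = ("chrT", 30_000, 36_220, "+")
        status, _ = match_sv_to_chimera(call, self.GENE5, gene3, max_distance=100_000)
        assert status == "NO_EVIDENCE"


def test_pairs_round_trip_through_sam(tmp_path, genome, complex_hap):
    rs = simulate_wgs(genome.sequence, complex_hap, 1, ReadSimConfig(coverage=3.0, seed=2))
    sam = tmp_path / "t.sam"
    rs.write_sam(sam)
    pairs = pairs_from_sam(sam)
    assert len(pairs) == rs.n_pairs
    direct = pairs_from_readset(rs)
    unordered = lambda df: sorted(
        tuple(sorted((int(a), int(b)))) for a, b in df[["r1_pos", "r2_pos"]].to_numpy()
    )
    assert unordered(pairs) == unordered(direct)
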