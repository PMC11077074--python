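"""Confidence filtering, junction classes, frame prediction, polymorphic filter."""

import numpy as np
import pandas as pd
import pytest

from polyfusion.catalog import (
    FormatError,
    PolymorphicFilterConfig,
    classify_junction,
    confidence_filter,
    polymorphic_filter,
    predict_frame,
)


def occurrence_row(**kwargs):
    row = {
        "chimera_id": "c1", "gene5": "G5", "gene3": "G3",
        "chrom5": "chrT", "pos5": 1_000, "strand5": "+",
        "chrom3": "chrT", "pos3": 5_000, "strand3": "+",
        "score": 0.9, "identity": 0.5,
        "sample_id": "s1", "individual_id": "i1", "tissue": "t1",
    }
    row.update(kwargs)
    return row


class TestConfidenceFilter:
    def test_score_boundary_is_strict_below(self):
        df = pd.DataFrame([occurrence_row(score=0.59), occurrence_row(score=0.60)])
        kept, counts = confidence_filter(df)
        assert kept["score"].tolist() == [0.60]
        assert counts["low_score"] == 1

    def test_identity_above_90_percent_removed(self):
        df = pd.DataFrame([occurrence_row(identity=0.91), occurrence_row(identity=0.90)])
        kept, counts = confidence_filter(df)
        assert kept["identity"].tolist() == [0.90]
        assert counts["high_identity"] == 1

    def test_undefined_junction_removed_and_counts_sum(self):
        df = pd.DataFrame([
            occurrence_row(pos5=np.nan), occurrence_row(score=0.1), occurrence_row(),
        ])
        kept, counts = confidence_filter(df)
        assert len(kept) == 1
        assert sum(counts.values()) == 2

    def test_empty_table(self):
        df = pd.DataFrame(columns=list(occurrence_row()))
        kept, counts = confidence_filter(df)
        assert kept.empty and sum(counts.values()) == 0

    def test_missing_score_column_is_format_error(self):
        with pytest.raises(FormatError):
            confidence_filter(pd.DataFrame({"identity": [0.5]}))

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_thresholds(self, seed):
        """Raising min_score or lowering max_identity never grows the kept set."""
        rng = np.random.default_rng(seed)
        df = pd.DataFrame([
            occurrence_row(score=s, identity=i)
            for s, i in zip(rng.random(50), rng.random(50))
        ])
        base, _ = confidence_filter(df, 0.5, 0.9)
        stricter_score, _ = confidence_filter(df, 0.7, 0.9)
        stricter_ident, _ = confidence_filter(df, 0.5, 0.7)
        assert set(stricter_score.index) <= set(base.index)
        assert set(stricter_ident.index) <= set(base.index)


@pytest.fixture(scope="module")
def annotation():
    # one + strand gene with exon ending at 1000, one - strand gene with an
    # exon whose 5' edge (minus strand) is its end coordinate 5400
    return pd.DataFrame({
        "contig": ["chrT", "chrT", "chrT"],
        "start": [800, 5_000, 9_000],
        "end": [1_000, 5_400, 9_300],
        "gene": ["G5", "G3", "G3"],
        "strand": ["+", "-", "-"],
    })


class TestClassifyJunction:
    def test_exact_exon_edges_give_E_E(self, annotation):
        occ = occurrence_row(pos5=1_000, strand5="+", pos3=5_400, strand3="-")
        assert classify_junction(occ, annotation) == "E_E"

    @pytest.mark.parametrize("offset,expected", [(2, "E"), (3, "M")])
    def test_two_bp_tolerance_boundary(self, annotation, offset, expected):
        occ = occurrence_row(pos5=1_000 + offset, strand5="+", pos3=5_400, strand3="-")
        assert classify_junction(occ, annotation).startswith(expected)

    def test_both_sides_mid_exon(self, annotation):
        occ = occurrence_row(pos5=900, strand5="+", pos3=5_200, strand3="-")
        assert classify_junction(occ, annotation) == "M_M"

    def test_unannotated_contig_warns_and_gives_M(self, annotation):
        occ = occurrence_row(chrom5="chrZ", pos5=1_000, pos3=5_400, strand3="-")
        with pytest.warns(UserWarning):
            assert classify_junction(occ, annotation) == "M_E"

    def test_invariant_under_coordinate_translation(self, annotation):
        shift = 10_000
        shifted = annotation.assign(start=annotation["start"] + shift,
                                    end=annotation["end"] + shift)
        occ = occurrence_row(pos5=1_001, strand5="+", pos3=5_398, strand3="-")
        occ_shifted = dict(occ, pos5=occ["pos5"] + shift, pos3=occ["pos3"] + shift)
        assert classify_junction(occ, annotation) == classify_junction(occ_shifted, shifted)


@pytest.fixture(scope="module")
def cds():
    return pd.DataFrame({
        "gene": ["G5", "G3"],
        "contig": ["chrT", "chrT"],
        "start": [700, 5_000],
        "end": [1_300, 5_600],
        "strand": ["+", "+"],
    })


class TestPredictFrame:

    def test_multiple_of_three_joined_at_phase0_is_in_frame(self, cds):
        occ = occurrence_row(pos5=1_000, strand5="+", pos3=5_000, strand3="+")
        assert predict_frame(occ, cds) == "IN_FRAME"  # 300 nt from 700

    def test_off_by_one_is_frameshift(self, cds):
        occ = occurrence_row(pos5=1_001, strand5="+", pos3=5_000, strand3="+")
        assert predict_frame(occ, cds) == "FRAMESHIFT"  # 301 nt

    def test_phase_matching_restores_frame(self, cds):
        occ = occurrence_row(pos5=1_001, strand5="+", pos3=5_001, strand3="+")
        assert predict_frame(occ, cds) == "IN_FRAME"  # 301 ≡ 1 (mod 3)

    def test_junction_in_utr_is_non_coding(self, cds):
        occ = occurrence_row(pos5=650, strand5="+", pos3=5_000, strand3="+")
        assert predict_frame(occ, cds) == "NON_CODING"

    def test_no_remaining_cds_downstream_is_non_coding(self, cds):
        occ = occurrence_row(pos5=1_000, strand5="+", pos3=5_700, strand3="+")
        assert predict_frame(occ, cds) == "NON_CODING"


def make_cohort_tables(expressing: dict, samples_per_individual=10, n_tissues=10):
    """expressing: individual -> (n_samples_expressing, n_tissues_expressing)"""
    manifest_rows = []
    occ_rows = []
    individuals = set(expressing) | {f"bg{i}" for i in range(3)}
    for ind in sorted(individuals):
        for s in range(samples_per_individual):
            tissue = f"t{s % n_tissues}"
            manifest_rows.append((f"{ind}_s{s}", ind, tissue))
    for ind, (n_samples, n_tiss) in expressing.items():
        for s in range(n_samples):
            tissue = f"t{s % n_tiss}"
            occ_rows.append(occurrence_row(
                sample_id=f"{ind}_s{s}", individual_id=ind, tissue=tissue))
    manifest = pd.DataFrame(manifest_rows, columns=["sample_id", "individual_id", "tissue"])
    return pd.DataFrame(occ_rows), manifest


class TestPolymorphicFilter:
    def test_broadly_expressing_few_individuals_selected(self):
        occ, manifest = make_cohort_tables({f"i{k}": (8, 7) for k in range(10)})
        selected, metrics = polymorphic_filter(occ, manifest)
        assert selected == ["c1"]
        assert metrics.loc[0, "n_individuals"] == 10

    def test_individual_count_boundary_is_strict(self):
        expressing = {f"i{k}": (8, 7) for k in range(250)}
        occ, manifest = make_cohort_tables(expressing)
        selected, _ = polymorphic_filter(occ, manifest)
        assert selected == []
        selected249, _ = polymorphic_filter(
            *make_cohort_tables({f"i{k}": (8, 7) for k in range(249)})
        )
        assert selected249 == ["c1"]

    def test_mean_aggregation_arithmetic(self):
        # fractions (1.0, 1.0, 0.1) mean 0.7 > 2/3 but tissue counts
        # (7, 7, 1) mean exactly 5, and 5 > 5 is false -> excluded
        occ, manifest = make_cohort_tables({"i0": (10, 7), "i1": (10, 7), "i2": (1, 1)})
        selected, metrics = polymorphic_filter(occ, manifest)
        assert metrics.loc[0, "mean_sample_fraction"] == pytest.approx(0.7)
        assert metrics.loc[0, "mean_tissue_count"] == pytest.approx(5.0)
        assert selected == []

    def test_mean_fraction_at_exactly_two_thirds_is_excluded(self):
        # fractions (1.0, 0.5, 0.5): mean exactly 2/3, and the rule is
        # strictly greater-than, so the chimera is excluded at the default
        # threshold but selected at a slightly lower one
        occ, manifest = make_cohort_tables({"i0": (10, 7), "i1": (5, 5), "i2": (5, 5)})
        selected, metrics = polymorphic_filter(occ, manifest)
        assert metrics.loc[0, "mean_sample_fraction"] == pytest.approx(2 / 3)
        assert selected == []
        relaxed = PolymorphicFilterConfig(min_sample_fraction=0.66)
        selected_relaxed, _ = polymorphic_filter(occ, manifest, relaxed)
        assert selected_relaxed == ["c1"]

    def test_per_individual_all_aggregation(self):
        occ, manifest = make_cohort_tables({"i0": (10, 7), "i1": (10, 7), "i2": (1, 1)})
        config = PolymorphicFilterConfig(aggregation="per_individual_all")
        selected, _ = polymorphic_filter(occ, manifest, config)
        assert selected == []  # i2 fails both per-individual criteria

    def test_unknown_sample_raises(self):
        occ, manifest = make_cohort_tables({"i0": (8, 7)})
        occ.loc[0, "sample_id"] = "phantom"
        with pytest.raises(ValueError, match="absent from the manifest"):
            polymorphic_filter(occ, manifest)
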