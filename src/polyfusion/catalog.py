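"""Chimeric-RNA catalog filtering and annotation.

Operates on prediction tables with one row per chimera occurrence per sample
(the output shape of EricScript-style callers).  Three stages:

* a confidence filter removing low-score predictions, predictions without a
  defined junction, and predictions nearly identical to annotated
  transcripts;
* junction classification against exon annotation — each side of a junction
  is End-of-exon (E) if it coincides with an annotated exon boundary within
  a small tolerance, else Middle-of-exon (M);
* a polymorphic filter selecting chimeras seen in few individuals but, in
  each expressing individual, across many tissues and most of that
  individual's samples — the signature of a transcript tracking a
  segregating DNA variant rather than a tissue-specific splicing event;
* reading-frame prediction for exon–exon junctions from CDS annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PolymorphicFilterConfig",
    "confidence_filter",
    "classify_junction",
    "classify_junctions",
    "predict_frame",
    "polymorphic_filter",
]

JUNCTION_CLASSES = ("E_E", "E_M", "M_E", "M_M")
FRAME_CALLS = ("IN_FRAME", "FRAMESHIFT", "NON_CODING")


class FormatError(ValueError):
    """A required column is missing or malformed."""


@dataclass(frozen=True)
class PolymorphicFilterConfig:
    """Thresholds of the polymorphic filter.

    Default thresholds: a chimera qualifies when seen in
    fewer than 250 unique individuals while, among expressing individuals,
    present in more than 5 unique tissues and more than two-thirds of each
    individual's samples.  ``aggregation`` selects whether the per-individual
    criteria are applied to the mean over expressing individuals (``mean``,
    the default) or to every expressing individual (``per_individual_all``).
    """

    max_individuals: int = 250
    min_tissues: float = 5
    min_sample_fraction: float = 2 / 3
    aggregation: str = "mean"

    def validate(self) -> None:
        if self.max_individuals <= 0 or self.min_tissues <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 < self.min_sample_fraction <= 1):
            raise ValueError("min_sample_fraction must be in (0, 1]")
        if self.aggregation not in ("mean", "per_individual_all"):
            raise ValueError("aggregation must be 'mean' or 'per_individual_all'")


def confidence_filter(
    occurrences: pd.DataFrame,
    min_score: float = 0.6,
    max_identity: float = 0.9,
) -> tuple[pd.DataFrame, dict]:
    """Drop low-confidence predictions.

    Retains rows with score ≥ ``min_score`` (i.e. removes scores < 0.6 at
    the default), defined junction positions, and identity to annotated
    transcripts ≤ ``max_identity`` (removes > 90% identity).  Each dropped
    row is attributed to the first rule it fails, so the counts sum to the
    number removed.
    """
    if not (0 <= min_score <= 1 and 0 <= max_identity <= 1):
        raise ValueError("thresholds must be in [0,1]")
    if "score" not in occurrences.columns:
        raise FormatError("prediction table lacks a 'score' column")
    score = pd.to_numeric(occurrences["score"], errors="coerce")
    low_score = score.isna() | (score < min_score)
    pos5 = pd.to_numeric(occurrences.get("pos5"), errors="coerce")
    pos3 = pd.to_numeric(occurrences.get("pos3"), errors="coerce")
    undefined = (pos5.isna() | pos3.isna()) & ~low_score
    identity = pd.to_numeric(occurrences.get("identity"), errors="coerce")
    high_identity = (identity > max_identity) & ~low_score & ~undefined
    removed = low_score | undefined | high_identity
    counts = {
        "low_score": int(low_score.sum()),
        "undefined_junction": int(undefined.sum()),
        "high_identity": int(high_identity.sum()),
    }
    return occurrences.loc[~removed].copy(), counts


def _side_is_exon_edge(
    annotation: pd.DataFrame,
    contig: str,
    pos: int,
    strand: str,
    side: str,
    tolerance_bp: int,
) -> bool:
    """True if *pos* matches the appropriate exon edge within tolerance.

    The donor (5′) side must match an exon's 3′ edge, the acceptor (3′)
    side an exon's 5′ edge, with edges taken strand-aware: on the plus
    strand an exon's 3′ edge is its end coordinate, on the minus strand its
    start, and vice versa for 5′ edges.
    """
    exons = annotation[(annotation["contig"] == contig) & (annotation["strand"] == strand)]
    if exons.empty:
        warnings.warn(f"no exon annotation for contig {contig} strand {strand}; side set to M")
        return False
    want_three_prime = side == "donor"
    use_end = (strand == "+") == want_three_prime
    edges = exons["end"].to_numpy() if use_end else exons["start"].to_numpy()
    return bool(np.any(np.abs(edges - pos) <= tolerance_bp))


def classify_junction(
    occurrence, annotation: pd.DataFrame, tolerance_bp: int = 2
) -> str:
    """Classify one occurrence's junction as E_E / E_M / M_E / M_M."""
    donor = _side_is_exon_edge(
        annotation, occurrence["chrom5"], int(occurrence["pos5"]),
        occurrence["strand5"], "donor", tolerance_bp,
    )
    acceptor = _side_is_exon_edge(
        annotation, occurrence["chrom3"], int(occurrence["pos3"]),
        occurrence["strand3"], "acceptor", tolerance_bp,
    )
    return f"{'E' if donor else 'M'}_{'E' if acceptor else 'M'}"


def classify_junctions(
    occurrences: pd.DataFrame, annotation: pd.DataFrame, tolerance_bp: int = 2
) -> pd.Series:
    """Vectorised over rows; returns a Series aligned with *occurrences*."""
    return occurrences.apply(
        lambda row: classify_junction(row, annotation, tolerance_bp), axis=1
    )


def _cds_prefix_length(cds: pd.DataFrame, strand: str, pos: int) -> tuple[int, int]:
    """CDS nucleotides transcribed before *pos*, and the total CDS length.

    ``cds`` holds this gene's CDS intervals (columns start/end, 0-based
    half-open).  Transcription direction follows *strand*.
    """
    starts = cds["start"].to_numpy()
    ends = cds["end"].to_numpy()
    total = int((ends - starts).sum())
    if strand == "+":
        before = np.clip(np.minimum(ends, pos) - starts, 0, None)
    else:
        before = np.clip(ends - np.maximum(starts, pos), 0, None)
    return int(before.sum()), total


def predict_frame(occurrence, cds_annotation: pd.DataFrame) -> str:
    """Predict the fusion reading frame from CDS annotation.

    IN_FRAME when the 5′ partner's cumulative CDS length up to the junction
    is congruent (mod 3) with the 3′ partner's CDS phase at its junction;
    FRAMESHIFT otherwise; NON_CODING when either side contributes no CDS at
    the junction (5′ junction upstream of the CDS, or 3′ junction with no
    CDS remaining downstream).
    """
    cds5 = cds_annotation[
        (cds_annotation["gene"] == occurrence["gene5"])
        & (cds_annotation["contig"] == occurrence["chrom5"])
    ]
    cds3 = cds_annotation[
        (cds_annotation["gene"] == occurrence["gene3"])
        & (cds_annotation["contig"] == occurrence["chrom3"])
    ]
    if cds5.empty or cds3.empty:
        return "NON_CODING"
    len5, _ = _cds_prefix_length(cds5, occurrence["strand5"], int(occurrence["pos5"]))
    phase3, total3 = _cds_prefix_length(cds3, occurrence["strand3"], int(occurrence["pos3"]))
    if len5 == 0 or phase3 >= total3:
        return "NON_CODING"
    return "IN_FRAME" if len5 % 3 == phase3 % 3 else "FRAMESHIFT"


def polymorphic_filter(
    occurrences: pd.DataFrame,
    manifest: pd.DataFrame,
    config: PolymorphicFilterConfig | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Select chimeras with a polymorphic occurrence pattern.

    ``manifest`` must list every sample of every individual in the cohort
    (columns sample_id, individual_id, tissue); it is the denominator for
    per-individual sample fractions.  Returns the selected chimera ids and a
    per-chimera metrics table (n_individuals, mean_sample_fraction,
    mean_tissue_count, selected) covering all chimeras.
    """
    config = config or PolymorphicFilterConfig()
    config.validate()
    unknown = set(occurrences["sample_id"]) - set(manifest["sample_id"])
    if unknown:
        raise ValueError(
            f"occurrences reference samples absent from the manifest: {sorted(unknown)[:5]}"
        )
    samples_per_ind = manifest.groupby("individual_id")["sample_id"].nunique()

    dedup = occurrences.drop_duplicates(["chimera_id", "sample_id"])
    per_ind = (
        dedup.groupby(["chimera_id", "individual_id"])
        .agg(n_samples=("sample_id", "nunique"), n_tissues=("tissue", "nunique"))
        .reset_index()
    )
    per_ind["fraction"] = (
        per_ind["n_samples"] / samples_per_ind.reindex(per_ind["individual_id"]).to_numpy()
    )

    metrics = (
        per_ind.groupby("chimera_id")
        .agg(
            n_individuals=("individual_id", "nunique"),
            mean_sample_fraction=("fraction", "mean"),
            mean_tissue_count=("n_tissues", "mean"),
            min_sample_fraction=("fraction", "min"),
            min_tissue_count=("n_tissues", "min"),
        )
        .reset_index()
    )
    few = metrics["n_individuals"] < config.max_individuals
    if config.aggregation == "mean":
        broad = (metrics["mean_sample_fraction"] > config.min_sample_fraction) & (
            metrics["mean_tissue_count"] > config.min_tissues
        )
    else:
        broad = (metrics["min_sample_fraction"] > config.min_sample_fraction) & (
            metrics["min_tissue_count"] > config.min_tissues
        )
    metrics["selected"] = few & broad
    selected = metrics.loc[metrics["selected"], "chimera_id"].tolist()
    return selected, metrics
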