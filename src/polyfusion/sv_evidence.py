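"""Discordant read-pair signatures and SV-type classification.

Paired-end fragments sequenced across a structural variant breakpoint land
in reference space with diagnostic mate orientations: an inversion flips one
mate, producing FF ("left–left") and RR ("right–right") pairs at its two
breakpoints; a tandem duplication produces outward-facing RF pairs at the
copy junction together with a coverage gain inside the duplicated interval;
a deletion stretches FR pairs far beyond the insert-size distribution and
depletes coverage inside the removed interval; and an inversion with an
adjacent deletion combines the inversion signature with a depleted interval
abutting it.  This module clusters discordant pairs by orientation and
proximity, quantifies coverage gain/loss against flanking sequence, applies
those rules, and matches resulting calls to candidate chimera gene pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InsertModel",
    "PairCluster",
    "SVCall",
    "pairs_from_readset",
    "pairs_from_sam",
    "extract_signatures",
    "coverage_ratio",
    "classify_sv",
    "match_sv_to_chimera",
]


@dataclass(frozen=True)
class InsertModel:
    mean: float
    sd: float
    discordance_multiplier: float = 3.0

    def validate(self) -> None:
        if self.sd <= 0:
            raise ValueError("insert sd must be positive")


@dataclass
class PairCluster:
    """A proximity cluster of same-orientation discordant pairs."""

    orientation: str  # FR_LONG / FR_SHORT / RF / FF / RR
    left_pos: np.ndarray  # leftmost coordinate of the left mate
    left_end: np.ndarray
    right_pos: np.ndarray
    right_end: np.ndarray

    @property
    def n(self) -> int:
        return len(self.left_pos)

    @property
    def median_insert(self) -> float:
        return float(np.median(self.right_end - self.left_pos))


@dataclass
class SVCall:
    sv_type: str  # DEL / DUP / INV / COMPLEX_INV_DEL / NONE
    breakpoints: tuple[tuple[int, int], ...] = ()
    support: dict = field(default_factory=dict)
    coverage_ratio: float = float("nan")


def pairs_from_readset(readset) -> pd.DataFrame:
    """Pair table from a simulated :class:`~polyfusion.reads.ReadSet`."""
    return pd.DataFrame({
        "r1_pos": readset.r1_pos,
        "r1_strand": readset.r1_strand,
        "r2_pos": readset.r2_pos,
        "r2_strand": readset.r2_strand,
        "read_length": readset.read_length,
    })


def pairs_from_sam(path, contig: str | None = None) -> pd.DataFrame:
    """Pair table from a SAM/BAM file (primary alignments, both mates mapped)."""
    import pysam

    first: dict[str, tuple] = {}
    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or not rec.is_paired:
                continue
            if contig is not None and rec.reference_name != contig:
                continue
            strand = -1 if rec.is_reverse else 1
            if rec.query_name in first:
                pos2, strand2, len2 = first.pop(rec.query_name)
                rows.append((rec.reference_start, strand, pos2, strand2,
                             max(rec.query_length or len2, len2)))
            else:
                first[rec.query_name] = (rec.reference_start, strand, rec.query_length or 0)
    return pd.DataFrame(rows, columns=["r1_pos", "r1_strand", "r2_pos", "r2_strand", "read_length"])


def _orient_pairs(pairs: pd.DataFrame) -> tuple[np.ndarray, ...]:
    """Order mates left/right in reference space and derive the orientation."""
    p1 = pairs["r1_pos"].to_numpy()
    p2 = pairs["r2_pos"].to_numpy()
    s1 = pairs["r1_strand"].to_numpy()
    s2 = pairs["r2_strand"].to_numpy()
    rl = pairs["read_length"].to_numpy()
    swap = p2 < p1
    left = np.where(swap, p2, p1)
    left_strand = np.where(swap, s2, s1)
    right = np.where(swap, p1, p2)
    right_strand = np.where(swap, s1, s2)
    # orientation from (left strand, right strand): +/- FR, -/+ RF, +/+ FF, -/- RR
    orient = np.full(len(pairs), "FR", dtype=object)
    orient[(left_strand == -1) & (right_strand == 1)] = "RF"
    orient[(left_strand == 1) & (right_strand == 1)] = "FF"
    orient[(left_strand == -1) & (right_strand == -1)] = "RR"
    insert = right + rl - left
    return left, left + rl, right, right + rl, orient, insert


def extract_signatures(
    pairs: pd.DataFrame,
    insert_model: InsertModel,
    region: tuple[int, int] | None = None,
    cluster_gap: float | None = None,
    sorted_input: bool = True,
) -> list[PairCluster]:
    """Cluster discordant pairs by orientation and proximity.

    A pair is concordant — and excluded — iff FR-oriented with an implied
    insert within ``discordance_multiplier`` standard deviations of the
    model mean.  Remaining pairs are grouped per orientation class (FR pairs
    split into long- and short-insert classes) into clusters whose adjacent
    left coordinates differ by at most ``cluster_gap`` (default: the insert
    mean).  Cluster membership is invariant to input row order: pairs are
    sorted internally.
    """
    insert_model.validate()
    if cluster_gap is None:
        cluster_gap = insert_model.mean
    left, left_end, right, right_end, orient, insert = _orient_pairs(pairs)
    if region is not None:
        keep = (left >= region[0]) & (right_end <= region[1])
        left, left_end, right, right_end = left[keep], left_end[keep], right[keep], right_end[keep]
        orient, insert = orient[keep], insert[keep]

    dev = insert_model.discordance_multiplier * insert_model.sd
    concordant = (orient == "FR") & (np.abs(insert - insert_model.mean) <= dev)

    classes = np.where(
        orient == "FR",
        np.where(insert > insert_model.mean + dev, "FR_LONG", "FR_SHORT"),
        orient,
    )
    clusters: list[PairCluster] = []
    for cls in ("FR_LONG", "FR_SHORT", "RF", "FF", "RR"):
        sel = (classes == cls) & ~concordant
        if not np.any(sel):
            continue
        order = np.argsort(left[sel], kind="stable")
        L, LE = left[sel][order], left_end[sel][order]
        R, RE = right[sel][order], right_end[sel][order]
        breaks = np.nonzero(np.diff(L) > cluster_gap)[0] + 1
        for idx in np.split(np.arange(len(L)), breaks):
            clusters.append(PairCluster(cls, L[idx], LE[idx], R[idx], RE[idx]))
    return clusters


def coverage_ratio(
    coverage: np.ndarray, interval: tuple[int, int], flank: int | None = None
) -> float:
    """Mean depth inside *interval* over mean depth in equal-length flanks."""
    lo, hi = int(interval[0]), int(interval[1])
    if hi <= lo:
        return float("nan")
    if flank is None:
        flank = hi - lo
    inner = coverage[max(0, lo) : hi].mean() if hi > lo else float("nan")
    left = coverage[max(0, lo - flank) : lo]
    right = coverage[hi : hi + flank]
    flanks = np.concatenate([left, right])
    if flanks.size == 0 or flanks.mean() == 0:
        return float("nan")
    return float(inner / flanks.mean())


def _depleted_run_adjacent(
    coverage: np.ndarray,
    start: int,
    loss: float,
    baseline: float,
    bin_size: int = 200,
    max_scan: int = 20_000,
    min_len: int = 500,
    adjacency: int = 1_000,
) -> tuple[int, int] | None:
    """Maximal depleted interval starting within *adjacency* bp of *start*."""
    end = min(len(coverage), start + max_scan)
    pos = start
    run_start = None
    while pos + bin_size <= end:
        depleted = coverage[pos : pos + bin_size].mean() < loss * baseline
        if depleted and run_start is None:
            run_start = pos
        if not depleted and run_start is not None:
            break
        pos += bin_size
    if (
        run_start is not None
        and run_start - start <= adjacency
        and pos - run_start >= min_len
    ):
        return run_start, pos
    return None


def classify_sv(
    clusters: list[PairCluster],
    coverage: np.ndarray,
    insert_model: InsertModel,
    min_support: int = 3,
    gain_threshold: float = 1.3,
    loss_threshold: float = 0.7,
) -> SVCall:
    """Call the SV type from discordant clusters and the coverage profile.

    Rules, in precedence order: INV iff FF and RR clusters are both present
    (upgraded to COMPLEX_INV_DEL when a depleted interval abuts the
    inversion); DUP iff an RF cluster is present with coverage gain above
    ``gain_threshold`` inside the implied interval; DEL iff a long-insert FR
    cluster is present with coverage loss below ``loss_threshold``; NONE
    otherwise.  Every supporting cluster must contain at least
    ``min_support`` pairs.
    """
    by_class: dict[str, PairCluster] = {}
    for c in clusters:
        if c.n >= min_support and (c.orientation not in by_class or c.n > by_class[c.orientation].n):
            by_class[c.orientation] = c

    ff, rr = by_class.get("FF"), by_class.get("RR")
    if ff is not None and rr is not None:
        # both inversion breakpoints attract left mates ending just before
        # the upstream breakpoint and right mates just inside the downstream one
        b1 = int(np.median(np.concatenate([ff.left_end, rr.left_end])))
        b2 = int(np.median(ff.right_end))
        support = {"FF": ff.n, "RR": rr.n}
        ratio = coverage_ratio(coverage, (b1, b2))
        baseline = float(np.median(coverage[coverage > 0])) if np.any(coverage > 0) else 0.0
        run = _depleted_run_adjacent(coverage, b2, loss_threshold, baseline)
        if run is not None:
            del_ratio = coverage_ratio(coverage, run)
            return SVCall(
                "COMPLEX_INV_DEL", ((b1, b2), run), support, del_ratio
            )
        return SVCall("INV", ((b1, b2),), support, ratio)

    rf = by_class.get("RF")
    if rf is not None:
        lo = int(np.median(rf.left_pos))
        hi = int(np.median(rf.right_end))
        ratio = coverage_ratio(coverage, (lo, hi))
        if ratio > gain_threshold:
            return SVCall("DUP", ((lo, hi),), {"RF": rf.n}, ratio)

    fr_long = by_class.get("FR_LONG")
    if fr_long is not None:
        lo = int(np.median(fr_long.left_end))
        hi = int(np.median(fr_long.right_pos))
        ratio = coverage_ratio(coverage, (lo, hi))
        if ratio < loss_threshold:
            return SVCall("DEL", ((lo, hi),), {"FR_LONG": fr_long.n}, ratio)

    return SVCall("NONE")


def match_sv_to_chimera(
    svcall: SVCall,
    gene5: tuple[str, int, int, str],
    gene3: tuple[str, int, int, str],
    max_distance: int = 100_000,
    contig: str = "chrT",
) -> tuple[str, str]:
    """Decide whether an SV call directly explains a chimera's gene pair.

    Genes are ``(contig, start, end, strand)``.  DIRECT_EVIDENCE requires a
    non-NONE call on the genes' shared contig whose breakpoints each fall
    within ``max_distance`` of a parental gene, with SV geometry able to
    place the two genes in a transcribable 5′→3′ same-strand adjacency:
    deletions/duplications fuse same-strand neighbours, inversions (and
    inversion+deletion complexes) re-orient one partner of an
    opposite-strand pair.  Interchromosomal pairs are never matched by this
    intrachromosomal detector.  Returns ``(status, reason)``.
    """
    c5, s5, e5, strand5 = gene5
    c3, s3, e3, strand3 = gene3
    if c5 != c3:
        return "NO_EVIDENCE", "interchromosomal gene pair"
    if c5 != contig:
        return "NO_EVIDENCE", "call on a different contig"
    if svcall.sv_type == "NONE":
        return "NO_EVIDENCE", "no SV call"

    bps = [b for interval in svcall.breakpoints for b in interval]
    near5 = any(s5 - max_distance <= b <= e5 + max_distance for b in bps)
    near3 = any(s3 - max_distance <= b <= e3 + max_distance for b in bps)
    if not (near5 and near3):
        return "NO_EVIDENCE", "breakpoints not near both parental genes"

    if svcall.sv_type in ("DEL", "DUP"):
        if strand5 == strand3:
            return "DIRECT_EVIDENCE", f"{svcall.sv_type} fusing same-strand neighbours"
        return "NO_EVIDENCE", f"{svcall.sv_type} cannot re-orient an opposite-strand pair"
    # INV / COMPLEX_INV_DEL flip one partner's strand
    if strand5 != strand3:
        return "DIRECT_EVIDENCE", f"{svcall.sv_type} re-orients an opposite-strand pair"
    return "NO_EVIDENCE", "inversion of a same-strand pair breaks colinearity"
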