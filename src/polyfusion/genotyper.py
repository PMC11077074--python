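"""Alignment-free SV genotyping from raw reads.

The pipeline mirrors an agrep-style in silico genotyping protocol: short
(typically 70 bp) query sequences are designed against a locus — a control
region untouched by the variant, the interior of a deleted interval, and
sequence spanning each novel breakpoint junction — and matched approximately
against quality-filtered FASTQ reads on both strands.  Every matching read is
then re-mapped to the reference with a seed-and-extend aligner; reads whose
retained alignments fall exclusively inside a window (default 100 kb) around
the locus count as true-positive evidence, reads mapping exclusively
elsewhere as false positive, and reads hitting both as uncertain.  A boolean
rule over per-query true-positive presence (e.g. ``CTRL & JUNCTION &
!DEL_INTERNAL``) yields the per-sample genotype call.

Because a breakpoint-spanning read has no full-length colinear alignment to
the reference, the re-mapping target also carries the variant junction
context sequences, flagged as part of the target locus; this preserves the
purpose of the re-mapping step (discarding off-target approximate hits from
repeats or paralogs) without discarding true junction evidence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Haplotype, revcomp

__all__ = [
    "BreakpointQuery",
    "ReadMatch",
    "Alignment",
    "GenotypeRule",
    "GenotypeCall",
    "GenotypeConfig",
    "SeedExtendMapper",
    "fuzzy_match",
    "remap_classify",
    "call_genotype",
    "genotype_cohort",
    "design_queries",
    "quality_filter",
    "load_fastq",
]

_DNA = re.compile(r"^[ACGT]+$")

ROLES = ("CTRL", "DEL_INTERNAL", "JUNCTION")


@dataclass(frozen=True)
class BreakpointQuery:
    """A short query sequence targeting one region of an SV locus."""

    query_id: str
    sequence: str
    role: str
    contig: str
    window_start: int
    window_end: int

    def validate(self) -> None:
        if not _DNA.match(self.sequence):
            raise ValueError(f"query {self.query_id}: sequence must be uppercase ACGT")
        if self.role not in ROLES:
            raise ValueError(f"query {self.query_id}: unknown role {self.role!r}")
        if self.window_end - self.window_start <= 2 * len(self.sequence):
            raise ValueError(f"query {self.query_id}: window too narrow")


@dataclass
class ReadMatch:
    read_id: str
    query_id: str
    strand: str
    edit_distance: int
    classification: str | None = None


@dataclass(frozen=True)
class Alignment:
    contig: str
    start: int
    end: int
    strand: str
    score: int
    identity: float


@dataclass(frozen=True)
class GenotypeConfig:
    max_edits: int = 0
    min_reads_present: int = 1
    min_score: int = 90
    min_identity: float = 0.90
    min_mean_quality: float = 20.0
    max_n_fraction: float = 0.10


# --------------------------------------------------------------------------
# fuzzy matching


def fuzzy_match(query: str, reads, max_edits: int = 0) -> list[ReadMatch]:
    """Find reads containing *query* within ``max_edits`` Levenshtein edits.

    Both strands are searched; the reported distance is the minimum over all
    substring placements and strands (plus strand preferred on ties).  Reads
    are ``(read_id, sequence)`` pairs.  N bases in reads count as mismatches;
    a non-ACGT query symbol is a validation error.
    """
    if max_edits < 0:
        raise ValueError("max_edits must be non-negative")
    if not _DNA.match(query):
        raise ValueError("query must be uppercase ACGT")
    rc = revcomp(query)
    matches: list[ReadMatch] = []
    if max_edits == 0:
        for read_id, seq in reads:
            if query in seq:
                matches.append(ReadMatch(read_id, "", "+", 0))
            elif rc in seq:
                matches.append(ReadMatch(read_id, "", "-", 0))
        return matches
    import edlib

    for read_id, seq in reads:
        fwd = edlib.align(query, seq, mode="HW", task="distance", k=max_edits)["editDistance"]
        rev = edlib.align(rc, seq, mode="HW", task="distance", k=max_edits)["editDistance"]
        cands = [(d, s) for d, s in ((fwd, "+"), (rev, "-")) if d != -1]
        if cands:
            d, s = min(cands)
            matches.append(ReadMatch(read_id, "", s, d))
    return matches


# --------------------------------------------------------------------------
# re-mapping validation


_CIG = re.compile(r"(\d+)([=XIDM])")


def _score_cigar(cigar: str) -> tuple[int, float]:
    """Score an extended CIGAR with match +1 / mismatch −1 / gap −2.

    Identity is matches over alignment columns (gaps count against it).
    """
    match = mismatch = gap = 0
    for n, op in _CIG.findall(cigar):
        n = int(n)
        if op == "=":
            match += n
        elif op in "XM":
            mismatch += n
        else:
            gap += n
    columns = match + mismatch + gap
    return match - mismatch - 2 * gap, (match / columns if columns else 0.0)


class SeedExtendMapper:
    """k-mer seeded local re-mapper over one or more target contigs.

    Exact k-mers sampled from the read anchor candidate loci; each candidate
    window is then aligned with an edit-distance optimal path and scored with
    the +1/−1/−2 scheme.  ``target_contigs`` names contigs (e.g. variant
    junction contexts) whose alignments always count as inside the target
    locus.
    """

    def __init__(self, contigs: dict[str, str], k: int = 11, seed_step: int = 5,
                 slack: int = 25, target_contigs: set[str] | None = None):
        self.contigs = contigs
        self.k = k
        self.seed_step = seed_step
        self.slack = slack
        self.target_contigs = target_contigs or set()
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in contigs.items():
            for pos in range(0, len(seq) - k + 1):
                self._index.setdefault(seq[pos : pos + k], []).append((name, pos))

    def _candidates(self, read: str) -> set[tuple[str, int]]:
        k, step = self.k, self.seed_step
        anchors: set[tuple[str, int]] = set()
        for off in range(0, max(1, len(read) - k + 1), step):
            for contig, pos in self._index.get(read[off : off + k], ()):
                anchors.add((contig, max(0, pos - off)))
        # merge anchors within slack of each other on the same contig
        merged: set[tuple[str, int]] = set()
        for contig, start in sorted(anchors):
            if not any(c == contig and abs(s - start) <= self.slack for c, s in merged):
                merged.add((contig, start))
        return merged

    def map_read(self, read: str) -> list[Alignment]:
        import edlib

        alignments: list[Alignment] = []
        for strand, seq in (("+", read), ("-", revcomp(read))):
            for contig, start in self._candidates(seq):
                ref = self.contigs[contig]
                lo = max(0, start - self.slack)
                hi = min(len(ref), start + len(seq) + self.slack)
                res = edlib.align(seq, ref[lo:hi], mode="HW", task="path")
                if res["editDistance"] < 0 or not res["locations"]:
                    continue
                a, b = res["locations"][0]
                score, identity = _score_cigar(res["cigar"])
                alignments.append(Alignment(contig, lo + a, lo + b + 1, strand, score, identity))
        # deduplicate near-identical loci, keeping the best score
        best: dict[tuple[str, int], Alignment] = {}
        for aln in alignments:
            key = (aln.contig, aln.start // (2 * self.slack))
            if key not in best or aln.score > best[key].score:
                best[key] = aln
        return sorted(best.values(), key=lambda a: -a.score)


def remap_classify(
    read: str,
    mapper: SeedExtendMapper,
    window: tuple[str, int, int],
    min_score: int = 90,
    min_identity: float = 0.90,
) -> tuple[str | None, list[Alignment]]:
    """Classify a fuzzy-matched read by where its retained alignments fall.

    Retains alignments with score ≥ ``min_score``, identity ≥
    ``min_identity`` and score within 1% of the best retained score.
    TRUE_POSITIVE if every retained locus lies inside *window* (or on a
    designated target contig), FALSE_POSITIVE if none does, UNCERTAIN if
    mixed, and ``None`` (dropped from evidence) if nothing is retained.
    """
    wcontig, wstart, wend = window
    retained = [
        a for a in mapper.map_read(read)
        if a.score >= min_score and a.identity >= min_identity
    ]
    if not retained:
        return None, []
    best = max(a.score for a in retained)
    retained = [a for a in retained if a.score >= 0.99 * best]
    inside = [
        (a.contig in mapper.target_contigs)
        or (a.contig == wcontig and wstart <= (a.start + a.end) // 2 < wend)
        for a in retained
    ]
    if all(inside):
        return "TRUE_POSITIVE", retained
    if not any(inside):
        return "FALSE_POSITIVE", retained
    return "UNCERTAIN", retained


# --------------------------------------------------------------------------
# rule engine and calls


class GenotypeRule:
    """Boolean presence rule over query ids/roles.

    Grammar: ``expr := term ('|' term)* ; term := factor ('&' factor)* ;
    factor := '!' factor | '(' expr ')' | NAME``.  Example (a typical
    complex-rearrangement rule): ``CTRL & JUNCTION & !DEL_INTERNAL``.
    """

    _TOKEN = re.compile(r"\s*([A-Za-z_][A-Za-z0-9_]*|[&|!()])")

    def __init__(self, expression: str, min_reads_present: int = 1):
        self.expression = expression
        self.min_reads_present = min_reads_present
        self._tokens = self._tokenize(expression)
        self.names = {t for t in self._tokens if t not in "&|!()"}
        self._ast = self._parse(list(self._tokens))

    @classmethod
    def _tokenize(cls, text: str) -> list[str]:
        tokens, pos = [], 0
        while pos < len(text):
            m = cls._TOKEN.match(text, pos)
            if not m:
                raise ValueError(f"bad rule syntax at {text[pos:]!r}")
            tokens.append(m.group(1))
            pos = m.end()
        return tokens

    def _parse(self, tokens: list[str]):
        ast = self._expr(tokens)
        if tokens:
            raise ValueError(f"unexpected trailing tokens {tokens!r}")
        return ast

    def _expr(self, tokens):
        node = self._term(tokens)
        while tokens and tokens[0] == "|":
            tokens.pop(0)
            node = ("or", node, self._term(tokens))
        return node

    def _term(self, tokens):
        node = self._factor(tokens)
        while tokens and tokens[0] == "&":
            tokens.pop(0)
            node = ("and", node, self._factor(tokens))
        return node

    def _factor(self, tokens):
        if not tokens:
            raise ValueError("unexpected end of rule")
        tok = tokens.pop(0)
        if tok == "!":
            return ("not", self._factor(tokens))
        if tok == "(":
            node = self._expr(tokens)
            if not tokens or tokens.pop(0) != ")":
                raise ValueError("unbalanced parentheses in rule")
            return node
        if tok in "&|)":
            raise ValueError(f"unexpected token {tok!r}")
        return ("name", tok)

    def evaluate(self, present: dict[str, bool]) -> bool:
        def ev(node):
            op = node[0]
            if op == "name":
                if node[1] not in present:
                    raise KeyError(f"rule references unknown query {node[1]!r}")
                return present[node[1]]
            if op == "not":
                return not ev(node[1])
            if op == "and":
                return ev(node[1]) and ev(node[2])
            return ev(node[1]) or ev(node[2])

        return ev(self._ast)


@dataclass
class GenotypeCall:
    sample_id: str
    variant_id: str
    call: str  # POSITIVE / NEGATIVE / NO_CALL
    evidence: dict[str, int] = field(default_factory=dict)


def call_genotype(
    counts: dict[str, int],
    rule: GenotypeRule,
    sample_id: str = "",
    variant_id: str = "",
) -> GenotypeCall:
    """Apply a presence rule to per-query true-positive read counts.

    A query is present when its count reaches the rule's
    ``min_reads_present``; the call is NO_CALL when there is no evidence at
    all (every count zero), otherwise POSITIVE/NEGATIVE per the rule.
    """
    missing = rule.names - set(counts)
    if missing:
        raise KeyError(f"rule references unknown queries: {sorted(missing)}")
    if sum(counts.values()) == 0:
        return GenotypeCall(sample_id, variant_id, "NO_CALL", dict(counts))
    present = {q: c >= rule.min_reads_present for q, c in counts.items()}
    call = "POSITIVE" if rule.evaluate(present) else "NEGATIVE"
    return GenotypeCall(sample_id, variant_id, call, dict(counts))


# --------------------------------------------------------------------------
# cohort-level driver


def quality_filter(reads, min_mean_quality: float = 20.0, max_n_fraction: float = 0.10):
    """Drop reads with low mean base quality or too many Ns.

    ``reads`` yields ``(read_id, sequence)`` or ``(read_id, sequence,
    quality_string)``; reads without qualities are filtered on Ns only.
    """
    for rec in reads:
        read_id, seq = rec[0], rec[1]
        qual = rec[2] if len(rec) > 2 else None
        if seq.count("N") > max_n_fraction * len(seq):
            continue
        if qual is not None:
            mean_q = sum(ord(c) - 33 for c in qual) / len(qual)
            if mean_q < min_mean_quality:
                continue
        yield read_id, seq


def load_fastq(*paths):
    """Yield ``(read_id, sequence, quality)`` from FASTQ files (gz ok)."""
    import pysam

    for path in paths:
        with pysam.FastxFile(str(path)) as fh:
            for rec in fh:
                yield rec.name, rec.sequence.upper(), rec.quality


def design_queries(
    reference: str,
    haplotype: Haplotype,
    sv_intervals,
    contig: str = "chrT",
    query_length: int = 70,
    window: tuple[int, int] | None = None,
) -> list[BreakpointQuery]:
    """Design CTRL / DEL_INTERNAL / JUNCTION queries for a planted SV.

    CTRL is reference sequence inside the window but clear of every SV
    interval; DEL_INTERNAL sits inside a deleted interval when one exists;
    one JUNCTION query is centred on each novel adjacency of *haplotype*.
    """
    n = len(reference)
    wstart, wend = window or (0, n)
    queries: list[BreakpointQuery] = []

    occupied = sorted(sv_intervals)
    if not occupied:
        raise ValueError("sv_intervals must list at least one affected interval")
    ctrl_start = None
    margin = 200
    for lo, hi in [(wstart, occupied[0][0])] + [
        (occupied[i][1], occupied[i + 1][0]) for i in range(len(occupied) - 1)
    ] + [(occupied[-1][1], wend)]:
        if hi - lo >= query_length + 2 * margin:
            ctrl_start = lo + margin
            break
    if ctrl_start is None:
        raise ValueError("no room for a control query clear of the SV")
    queries.append(BreakpointQuery(
        "CTRL", reference[ctrl_start : ctrl_start + query_length], "CTRL",
        contig, wstart, wend,
    ))

    # a deleted interval is reference sequence unrepresented on the haplotype
    hap_ref = {
        (s.ref_start, s.ref_start + (s.hap_end - s.hap_start)) for s in haplotype.segments
    }
    for lo, hi in occupied:
        covered = any(rs <= lo and hi <= re_ for rs, re_ in hap_ref)
        if not covered and hi - lo >= query_length + 20:
            mid = (lo + hi - query_length) // 2
            queries.append(BreakpointQuery(
                "DEL_INTERNAL", reference[mid : mid + query_length],
                "DEL_INTERNAL", contig, wstart, wend,
            ))
            break

    for i, junction in enumerate(haplotype.junctions):
        seq = junction.sequence
        mid = len(seq) // 2
        qseq = seq[mid - query_length // 2 : mid + (query_length + 1) // 2]
        queries.append(BreakpointQuery(
            f"JUNCTION_{i + 1}" if len(haplotype.junctions) > 1 else "JUNCTION",
            qseq, "JUNCTION", contig, wstart, wend,
        ))
    for q in queries:
        q.validate()
    return queries


def genotype_sample(
    reads,
    queries: list[BreakpointQuery],
    rule: GenotypeRule,
    mapper: SeedExtendMapper,
    config: GenotypeConfig = GenotypeConfig(),
    sample_id: str = "",
    variant_id: str = "SV",
) -> GenotypeCall:
    """Run the fuzzy-match → re-map → rule pipeline for one sample."""
    reads = list(quality_filter(reads, config.min_mean_quality, config.max_n_fraction))
    counts: dict[str, int] = {}
    seq_by_id = None
    for query in queries:
        matches = fuzzy_match(query.sequence, reads, config.max_edits)
        tp = 0
        if matches and seq_by_id is None:
            seq_by_id = dict(reads)
        for m in matches:
            cls, _ = remap_classify(
                seq_by_id[m.read_id], mapper,
                (query.contig, query.window_start, query.window_end),
                config.min_score, config.min_identity,
            )
            if cls == "TRUE_POSITIVE":
                tp += 1
        counts[query.query_id] = tp
    return call_genotype(counts, rule, sample_id, variant_id)


def genotype_cohort(
    samples,
    queries: list[BreakpointQuery],
    rule: GenotypeRule,
    mapper: SeedExtendMapper,
    config: GenotypeConfig = GenotypeConfig(),
    variant_id: str = "SV",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype every sample and summarise detection per population.

    ``samples`` yields ``(sample_id, population, reads)`` where ``reads`` is
    an iterable of read tuples (or None → NO_CALL with reason).  Returns the
    per-sample call table and a per-population detection summary
    (population, detected, total, percentage).
    """
    from .popgen import detection_summary

    rows = []
    for sample_id, population, reads in samples:
        if reads is None:
            call = GenotypeCall(sample_id, variant_id, "NO_CALL", {q.query_id: 0 for q in queries})
            reason = "missing reads"
        else:
            call = genotype_sample(reads, queries, rule, mapper, config, sample_id, variant_id)
            reason = ""
        rows.append({
            "sample_id": sample_id,
            "population": population,
            "variant_id": variant_id,
            "call": call.call,
            "reason": reason,
            **{f"n_{q}": c for q, c in call.evidence.items()},
        })
    calls = pd.DataFrame(rows)
    flags = calls[["population"]].copy()
    flags["detected"] = calls["call"] == "POSITIVE"
    summary = detection_summary(flags)
    return calls, summary
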