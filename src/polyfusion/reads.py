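"""Paired-end short-read simulation with truth alignments.

Fragments are drawn from each allele in proportion to genotype dosage, pairs
are emitted FR-oriented on their haplotype of origin, and every read carries
its reference-space truth coordinates computed through the haplotype→
reference liftover — so reads crossing a novel adjacency become discordant
or split in reference space exactly as they would in a real aligner's output.

Sequencing error is a uniform substitution process (no indels), which keeps
downstream approximate-matching behaviour interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Haplotype, reference_haplotype, revcomp

__all__ = ["ReadSimConfig", "ReadSet", "simulate_wgs"]


@dataclass(frozen=True)
class ReadSimConfig:
    read_length: int = 100
    insert_mean: int = 350
    insert_sd: int = 50
    coverage: float = 30.0
    base_error_rate: float = 0.001
    seed: int = 0

    def validate(self) -> None:
        if self.insert_mean <= self.read_length:
            raise ValueError("insert_mean must exceed read_length")
        if not (0 <= self.base_error_rate < 0.1):
            raise ValueError("base_error_rate must be in [0, 0.1)")


@dataclass
class ReadSet:
    """Simulated pairs: truth coordinates always, sequences optionally.

    All arrays are parallel over pairs.  Strand arrays are ±1 in reference
    space; ``r*_pos`` is the leftmost reference coordinate of the mate.
    """

    contig: str
    contig_length: int
    read_length: int
    names: list[str]
    r1_pos: np.ndarray
    r1_strand: np.ndarray
    r1_split: np.ndarray
    r2_pos: np.ndarray
    r2_strand: np.ndarray
    r2_split: np.ndarray
    allele: np.ndarray  # 0 = reference allele, 1 = alternate
    seqs1: list[str] | None = None
    seqs2: list[str] | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.names)

    def coverage_profile(self) -> np.ndarray:
        """Per-base reference depth implied by the truth alignments."""
        depth = np.zeros(self.contig_length + 1)
        for pos in (self.r1_pos, self.r2_pos):
            lo = np.clip(pos, 0, self.contig_length)
            hi = np.clip(pos + self.read_length, 0, self.contig_length)
            np.add.at(depth, lo, 1)
            np.add.at(depth, hi, -1)
        return np.cumsum(depth)[:-1]

    # ------------------------------------------------------------------ I/O

    def write_fastq(self, path1, path2) -> None:
        if self.seqs1 is None:
            raise ValueError("read set was simulated without sequences")
        qual = "I" * self.read_length
        with open(path1, "w") as fh1, open(path2, "w") as fh2:
            for name, s1, s2 in zip(self.names, self.seqs1, self.seqs2):
                fh1.write(f"@{name}/1\n{s1}\n+\n{qual}\n")
                fh2.write(f"@{name}/2\n{s2}\n+\n{qual}\n")

    def write_sam(self, path) -> None:
        """Truth alignments as an unsorted SAM with proper pair flags."""
        rl = self.read_length
        qual = "I" * rl
        cigar = f"{rl}M"
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            fh.write(f"@SQ\tSN:{self.contig}\tLN:{self.contig_length}\n")
            fh.write("@PG\tID:polyfusion\tPN:polyfusion-simulate\n")
            for i, name in enumerate(self.names):
                for mate, (pos, strand, mpos, mstrand) in enumerate(
                    (
                        (self.r1_pos[i], self.r1_strand[i], self.r2_pos[i], self.r2_strand[i]),
                        (self.r2_pos[i], self.r2_strand[i], self.r1_pos[i], self.r1_strand[i]),
                    )
                ):
                    flag = 0x1 | (0x40 if mate == 0 else 0x80)
                    if strand == -1:
                        flag |= 0x10
                    if mstrand == -1:
                        flag |= 0x20
                    if self.seqs1 is not None:
                        seq = (self.seqs1 if mate == 0 else self.seqs2)[i]
                        if strand == -1:
                            seq = revcomp(seq)
                    else:
                        seq = "*"
                    left = min(pos, mpos)
                    right = max(pos, mpos) + rl
                    tlen = right - left if pos <= mpos else -(right - left)
                    fh.write(
                        f"{name}\t{flag}\t{self.contig}\t{int(pos) + 1}\t60\t{cigar}\t"
                        f"=\t{int(mpos) + 1}\t{int(tlen)}\t{seq}\t"
                        f"{qual if seq != '*' else '*'}\n"
                    )

    def reads(self):
        """Iterate ``(read_id, sequence)`` over both mates (sequences required)."""
        if self.seqs1 is None:
            raise ValueError("read set was simulated without sequences")
        for name, s1, s2 in zip(self.names, self.seqs1, self.seqs2):
            yield f"{name}/1", s1
            yield f"{name}/2", s2


_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


def _apply_errors(seqs: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    if rate <= 0 or not seqs:
        return seqs
    rl = len(seqs[0])
    n_err = rng.binomial(rl, rate, size=len(seqs))
    for i in np.nonzero(n_err)[0]:
        arr = bytearray(seqs[i], "ascii")
        for pos in rng.integers(0, rl, size=n_err[i]):
            old = arr[pos]
            new = _ALPHABET[rng.integers(0, 4)]
            while new == old:
                new = _ALPHABET[rng.integers(0, 4)]
            arr[pos] = new
        seqs[i] = arr.decode("ascii")
    return seqs


def simulate_wgs(
    reference: str | Haplotype,
    alternate: Haplotype | None,
    genotype: int,
    config: ReadSimConfig,
    *,
    contig: str = "chrT",
    sample_id: str = "S0",
    with_sequences: bool = True,
    rng: np.random.Generator | None = None,
) -> ReadSet:
    """Simulate a diploid sample's paired-end WGS reads.

    ``genotype`` counts alternate alleles (0/1/2); fragments are allocated
    between the reference and alternate haplotypes accordingly.  Mean
    reference coverage tracks ``config.coverage`` (dosage-weighted across
    alleles).  Deterministic given ``config.seed`` (or a supplied ``rng``).
    """
    if genotype not in (0, 1, 2):
        raise ValueError("genotype must be 0, 1 or 2")
    config.validate()
    ref_hap = reference if isinstance(reference, Haplotype) else reference_haplotype(reference)
    if genotype > 0 and alternate is None:
        raise ValueError("alternate haplotype required for genotype > 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    contig_length = max(s.ref_start + (s.hap_end - s.hap_start) for s in ref_hap.segments)
    rl = config.read_length
    total_pairs = int(round(config.coverage * contig_length / (2 * rl)))
    weights = np.array([(2 - genotype) / 2.0, genotype / 2.0])
    alleles = [ref_hap, alternate]
    n_per_allele = rng.multinomial(total_pairs, weights)

    names: list[str] = []
    parts = {k: [] for k in ("r1_pos", "r1_strand", "r1_split", "r2_pos", "r2_strand", "r2_split", "allele")}
    seqs1: list[str] | None = [] if with_sequences else None
    seqs2: list[str] | None = [] if with_sequences else None

    pair_no = 0
    for allele_idx, (hap, n_frags) in enumerate(zip(alleles, n_per_allele)):
        if n_frags == 0:
            continue
        assert hap is not None
        L = hap.length
        if config.insert_mean >= L:
            raise ValueError("insert_mean must be smaller than the haplotype length")
        inserts = rng.normal(config.insert_mean, config.insert_sd, size=n_frags)
        inserts = np.clip(np.round(inserts), rl, L - 1).astype(np.int64)
        starts = (rng.random(n_frags) * (L - inserts)).astype(np.int64)

        # FR on the haplotype: mate 1 forward at the fragment start, mate 2
        # reverse at the fragment end.
        h1_start, h1_end = starts, starts + rl
        h2_start, h2_end = starts + inserts - rl, starts + inserts
        r1_pos, r1_strand, r1_split = hap.lift_reads(h1_start, h1_end, np.ones(n_frags, dtype=np.int64))
        r2_pos, r2_strand, r2_split = hap.lift_reads(h2_start, h2_end, -np.ones(n_frags, dtype=np.int64))

        parts["r1_pos"].append(r1_pos)
        parts["r1_strand"].append(r1_strand)
        parts["r1_split"].append(r1_split)
        parts["r2_pos"].append(r2_pos)
        parts["r2_strand"].append(r2_strand)
        parts["r2_split"].append(r2_split)
        parts["allele"].append(np.full(n_frags, allele_idx))
        names.extend(f"{sample_id}_p{pair_no + i}" for i in range(n_frags))
        pair_no += n_frags

        if with_sequences:
            seq = hap.sequence
            s1 = [seq[a:b] for a, b in zip(h1_start, h1_end)]
            s2 = [revcomp(seq[a:b]) for a, b in zip(h2_start, h2_end)]
            seqs1.extend(_apply_errors(s1, config.base_error_rate, rng))
            seqs2.extend(_apply_errors(s2, config.base_error_rate, rng))

    def cat(key, dtype=np.int64):
        if not parts[key]:
            return np.empty(0, dtype=dtype)
        return np.concatenate(parts[key]).astype(dtype)

    return ReadSet(
        contig=contig,
        contig_length=contig_length,
        read_length=rl,
        names=names,
        r1_pos=cat("r1_pos"),
        r1_strand=cat("r1_strand"),
        r1_split=cat("r1_split", bool),
        r2_pos=cat("r2_pos"),
        r2_strand=cat("r2_strand"),
        r2_split=cat("r2_split", bool),
        allele=cat("allele"),
        seqs1=seqs1,
        seqs2=seqs2,
    )
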