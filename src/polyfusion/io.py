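"""TSV plumbing and light-weight well-formedness checks for pipeline files.

TSV outputs carry a single provenance comment line (`# polyfusion ...`)
echoing the parameters and seed that produced them; readers skip comment
lines transparently.  The validators are deliberately shallow — they check
record structure and required columns, not biological plausibility — and
report one message per offending record.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd

__all__ = ["write_tsv", "read_tsv", "validate_fasta", "validate_fastq",
           "validate_sam", "validate_bed", "validate_tsv", "validate_formats"]


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def write_tsv(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    with open(path, "w") as fh:
        if provenance:
            echo = " ".join(f"{k}={v}" for k, v in provenance.items())
            fh.write(f"# polyfusion {echo}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def validate_fasta(path) -> list[str]:
    issues = []
    with _open_text(path) as fh:
        saw_header = False
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith(">"):
                saw_header = True
            elif not saw_header and line:
                issues.append(f"{path}:{i}: sequence before first header")
            elif line and not set(line.upper()) <= set("ACGTNRYSWKMBDHV-"):
                issues.append(f"{path}:{i}: non-nucleotide characters")
        if not saw_header:
            issues.append(f"{path}: no FASTA records")
    return issues


def validate_fastq(path) -> list[str]:
    issues = []
    with _open_text(path) as fh:
        record = []
        for i, line in enumerate(fh, 1):
            record.append((i, line.rstrip("\n")))
            if len(record) == 4:
                (l1, h), (l2, seq), (l3, plus), (l4, qual) = record
                if not h.startswith("@"):
                    issues.append(f"{path}:{l1}: header must start with @")
                if not plus.startswith("+"):
                    issues.append(f"{path}:{l3}: separator must start with +")
                if len(seq) != len(qual):
                    issues.append(f"{path}:{l4}: sequence/quality length mismatch")
                record = []
        if record:
            issues.append(f"{path}: truncated FASTQ record at line {record[0][0]}")
    return issues


def validate_sam(path) -> list[str]:
    issues = []
    with _open_text(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                issues.append(f"{path}:{i}: fewer than 11 SAM fields")
                continue
            if not fields[1].isdigit() or not fields[3].isdigit():
                issues.append(f"{path}:{i}: FLAG/POS must be integers")
    return issues


def validate_bed(path) -> list[str]:
    issues = []
    with _open_text(path) as fh:
        for i, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                issues.append(f"{path}:{i}: fewer than 3 BED fields")
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                issues.append(f"{path}:{i}: start/end must be integers")
                continue
            if not (0 <= start < end):
                issues.append(f"{path}:{i}: require 0 <= start < end")
    return issues


def validate_tsv(path, required_columns=()) -> list[str]:
    issues = []
    try:
        df = read_tsv(path)
    except Exception as exc:  # malformed table
        return [f"{path}: unreadable TSV ({exc})"]
    missing = [c for c in required_columns if c not in df.columns]
    for col in missing:
        issues.append(f"{path}: missing required column '{col}'")
    return issues


_VALIDATORS = {
    ".fa": validate_fasta, ".fasta": validate_fasta,
    ".fq": validate_fastq, ".fastq": validate_fastq,
    ".sam": validate_sam,
    ".bed": validate_bed,
    ".tsv": validate_tsv,
}


def validate_formats(paths, tsv_columns: dict | None = None) -> list[str]:
    """Validate each path by extension; returns all issues (empty = clean)."""
    issues = []
    for path in paths:
        p = Path(path)
        if not p.exists():
            issues.append(f"{path}: file does not exist")
            continue
        suffix = p.suffix if p.suffix != ".gz" else Path(p.stem).suffix
        validator = _VALIDATORS.get(suffix)
        if validator is None:
            issues.append(f"{path}: unknown format '{suffix}'")
        elif validator is validate_tsv:
            issues.extend(validate_tsv(path, (tsv_columns or {}).get(str(path), ())))
        else:
            issues.extend(validator(path))
    return issues
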