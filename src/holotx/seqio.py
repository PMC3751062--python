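"""FASTA/FASTQ readers and writers plus the small sequence utilities the
pipeline needs: mate interleaving, length filtering and sub-sequence
extraction.

Coordinates in emitted files and public function signatures are 1-based
inclusive; internal arithmetic is 0-based half-open.  FASTQ qualities are
Phred+33 only.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "SeqRecord",
    "FastqRead",
    "FastaParseError",
    "FastqParseError",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "interleave_pairs",
    "deinterleave",
    "filter_by_length",
    "extract_subsequence",
]

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """A named sequence (nucleotide or amino acid)."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class FastqRead:
    """A read with Phred+33 qualities."""

    id: str
    seq: str
    qual: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


class FastaParseError(ValueError):
    pass


class FastqParseError(ValueError):
    pass


def _open_text(path) :
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file into an ordered list of :class:`SeqRecord`.

    Raises :class:`FastaParseError` (naming the offending line) on a file
    whose first non-blank character is not ``>``, on a record with an empty
    id or empty sequence, and on duplicate ids.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_desc = ""
    cur_seq: list[str] = []
    cur_line = 0

    def _flush() -> None:
        if cur_id is None:
            return
        seq = "".join(cur_seq)
        if not seq:
            raise FastaParseError(
                f"record '{cur_id}' (header at line {cur_line}) has no sequence")
        records.append(SeqRecord(cur_id, seq, cur_desc))

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"empty FASTA header at line {lineno}")
                parts = header.split(None, 1)
                cur_id = parts[0]
                cur_desc = parts[1] if len(parts) > 1 else ""
                cur_line = lineno
                if cur_id in seen:
                    raise FastaParseError(
                        f"duplicate FASTA id '{cur_id}' at line {lineno}")
                seen.add(cur_id)
                cur_seq = []
            else:
                if cur_id is None:
                    raise FastaParseError(
                        f"expected '>' header, got sequence data at line {lineno}")
                cur_seq.append(line)
        _flush()
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at *width* columns."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_fastq(path) -> list[FastqRead]:
    """Read a (optionally gzipped) Phred+33 FASTQ file.

    Raises :class:`FastqParseError` on a missing ``+`` separator line, a
    sequence/quality length mismatch, or quality characters outside the
    printable Phred+33 range.
    """
    reads: list[FastqRead] = []
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    # drop trailing blank lines
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) % 4 != 0:
        raise FastqParseError(
            f"FASTQ file does not contain complete 4-line records ({len(lines)} lines)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i:i + 4]
        lineno = i + 1
        if not head.startswith("@"):
            raise FastqParseError(f"expected '@' header at line {lineno}")
        if not plus.startswith("+"):
            raise FastqParseError(f"expected '+' separator at line {lineno + 2}")
        if len(seq) != len(qual):
            raise FastqParseError(
                f"sequence/quality length mismatch for record at line {lineno}")
        if any(ord(c) < 33 or ord(c) > 126 for c in qual):
            raise FastqParseError(
                f"quality characters outside Phred+33 range at line {lineno + 3}")
        parts = head[1:].split(None, 1)
        reads.append(FastqRead(parts[0], seq, qual,
                               parts[1] if len(parts) > 1 else ""))
    return reads


def write_fastq(reads: Iterable[FastqRead], path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in reads:
            header = r.id if not r.description else f"{r.id} {r.description}"
            fh.write(f"@{header}\n{r.seq}\n+\n{r.qual}\n")


def interleave_pairs(mate1_path, mate2_path) -> list[FastqRead]:
    """Interleave two mate FASTQ files as a1,a2,b1,b2,...

    Pairing is inferred by file position; unequal record counts are an error.
    """
    m1 = read_fastq(mate1_path)
    m2 = read_fastq(mate2_path)
    if len(m1) != len(m2):
        raise ValueError(
            f"mate files have unequal read counts ({len(m1)} vs {len(m2)})")
    out: list[FastqRead] = []
    for a, b in zip(m1, m2):
        out.append(a)
        out.append(b)
    return out


def deinterleave(reads: Sequence[FastqRead]) -> tuple[list[FastqRead], list[FastqRead]]:
    """Inverse of :func:`interleave_pairs` on an in-memory read list."""
    if len(reads) % 2 != 0:
        raise ValueError("interleaved read list has odd length")
    return list(reads[0::2]), list(reads[1::2])


def filter_by_length(records: Iterable[SeqRecord], min_len: int) -> list[SeqRecord]:
    """Keep records with length >= *min_len* (strictly shorter ones removed),
    preserving order."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    return [r for r in records if len(r.seq) >= min_len]


def extract_subsequence(record: SeqRecord, start: int, end: int,
                        strand: str = "+") -> SeqRecord:
    """Extract the 1-based inclusive span [start, end] of *record*.

    With strand ``-`` the reverse complement of the span is returned.  The
    output id encodes the parent id and coordinates.
    """
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if not (1 <= start <= end <= len(record.seq)):
        raise ValueError(
            f"coordinates {start}..{end} out of range for sequence of "
            f"length {len(record.seq)}")
    sub = record.seq[start - 1:end]
    if strand == "-":
        sub = reverse_complement(sub)
    return SeqRecord(f"{record.id}:{start}-{end}({strand})", sub)
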