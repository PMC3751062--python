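"""Read mapping to annotated cDNA regions and RPKM quantification.

Mapping is seed-and-verify: exact 31-mer seeds anchor candidate ungapped
full-length placements on either strand; the placement with the fewest
mismatches wins, reads tied between different transcripts are discarded as
ambiguous, and only uniquely mapped reads are counted (the convention the
RPKM definition assumes).  Mates are mapped independently as single-end
reads.

RPKM = 1e9 * C / (N * L) with C mapped reads on the transcript, N total
uniquely mapped reads, L transcript length in bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqio import FastqRead, SeqRecord, reverse_complement

__all__ = [
    "ExpressionRecord",
    "MappingResult",
    "map_reads",
    "rpkm",
    "expression_table",
    "expression_summary",
]


@dataclass
class ExpressionRecord:
    transcript_id: str
    length_bp: int
    mapped_reads: int
    rpkm: float


@dataclass
class MappingResult:
    counts: dict[str, int]           # transcript id -> uniquely mapped reads
    n_mapped: int                    # total uniquely mapped reads
    n_ambiguous: int
    n_unmapped: int
    coverage: dict[str, list[int]] | None = None   # optional per-base depth


def _seed_index(transcripts: Sequence[SeqRecord], seed_len: int):
    index: dict[str, list[tuple[int, int]]] = {}
    for ti, t in enumerate(transcripts):
        s = t.seq.upper()
        for pos in range(len(s) - seed_len + 1):
            index.setdefault(s[pos:pos + seed_len], []).append((ti, pos))
    return index


def _mismatches(read: str, target: str, start: int, limit: int) -> int | None:
    """Mismatch count of an ungapped full-length placement, or None if the
    placement runs off the transcript or exceeds *limit*."""
    if start < 0 or start + len(read) > len(target):
        return None
    mm = 0
    for i, c in enumerate(read):
        if target[start + i] != c:
            mm += 1
            if mm > limit:
                return None
    return mm


def map_reads(reads: Iterable[FastqRead], transcripts: Sequence[SeqRecord],
              seed_len: int = 31, max_mismatch: int = 2,
              track_coverage: bool = False) -> MappingResult:
    """Map reads to transcripts; only unique best placements are counted.

    A read maps where an exact *seed_len*-mer seed (``max_mismatch + 1``
    seed offsets spread evenly across the read, so scattered mismatches
    rarely break every seed) anchors a full-length ungapped alignment with
    at most *max_mismatch* mismatches.  Reads with equally good placements
    on multiple transcripts are discarded as ambiguous.
    """
    if not transcripts:
        raise ValueError("empty transcript set")
    index = _seed_index(transcripts, seed_len)
    seqs = [t.seq.upper() for t in transcripts]
    counts = {t.id: 0 for t in transcripts}
    coverage = {t.id: [0] * len(t.seq) for t in transcripts} if track_coverage else None
    n_mapped = n_ambig = n_unmapped = 0
    for read in reads:
        r = read.seq.upper()
        if len(r) < seed_len:
            n_unmapped += 1
            continue
        span = len(r) - seed_len
        n_seeds = max_mismatch + 1
        if n_seeds == 1:
            offsets = [0]
        else:
            offsets = sorted({round(i * span / (n_seeds - 1))
                              for i in range(n_seeds)})
        best_mm = max_mismatch + 1
        placements: set[tuple[int, int, str]] = set()
        for oriented in (r, reverse_complement(r)):
            strand = "+" if oriented is r else "-"
            tried: set[tuple[int, int]] = set()
            for off in offsets:
                for ti, pos in index.get(oriented[off:off + seed_len], ()):
                    start = pos - off
                    if (ti, start) in tried:
                        continue
                    tried.add((ti, start))
                    mm = _mismatches(oriented, seqs[ti], start, max_mismatch)
                    if mm is None:
                        continue
                    if mm < best_mm:
                        best_mm = mm
                        placements = {(ti, start, strand)}
                    elif mm == best_mm:
                        placements.add((ti, start, strand))
        if not placements:
            n_unmapped += 1
            continue
        tids = {ti for ti, _, _ in placements}
        if len(tids) > 1:
            n_ambig += 1
            continue
        ti = tids.pop()
        tid = transcripts[ti].id
        counts[tid] += 1
        n_mapped += 1
        if coverage is not None:
            _, start, _ = sorted(placements)[0]
            for p in range(start, start + len(r)):
                coverage[tid][p] += 1
    return MappingResult(counts, n_mapped, n_ambig, n_unmapped, coverage)


def rpkm(c: int, n: int, length_bp: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if n <= 0:
        raise ValueError("total mapped reads N must be > 0")
    if length_bp <= 0:
        raise ValueError("transcript length must be > 0")
    return 1e9 * c / (n * length_bp)


def expression_table(mapping: MappingResult,
                     transcripts: Sequence[SeqRecord]) -> list[ExpressionRecord]:
    """Per-transcript expression records from a mapping result."""
    n = mapping.n_mapped
    out = []
    for t in transcripts:
        c = mapping.counts.get(t.id, 0)
        out.append(ExpressionRecord(t.id, len(t.seq), c,
                                    rpkm(c, n, len(t.seq)) if n > 0 else 0.0))
    return out


def expression_summary(records: Sequence[ExpressionRecord],
                       min_reads: int = 1) -> dict:
    """Min / mean / max of mapped reads and RPKM over expressed transcripts.

    Transcripts below *min_reads* mapped reads are excluded from the
    summary denominators (no floor beyond >=1 by default; the floor is a
    report filter, not part of quantification).
    """
    if not records:
        raise ValueError("no expression records")
    expressed = [r for r in records if r.mapped_reads >= max(min_reads, 1)]
    if not expressed:
        return {"n_expressed": 0}
    reads = [r.mapped_reads for r in expressed]
    rp = [r.rpkm for r in expressed]
    return {
        "n_expressed": len(expressed),
        "reads_min": min(reads),
        "reads_mean": sum(reads) / len(reads),
        "reads_max": max(reads),
        "rpkm_min": min(rp),
        "rpkm_mean": sum(rp) / len(rp),
        "rpkm_max": max(rp),
    }


def write_expression(records: Sequence[ExpressionRecord], path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, sep="\t",
                                                       index=False)
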