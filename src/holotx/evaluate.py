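"""Scoring of pipeline stages against simulated ground truth.

These helpers turn SimTruth labels into the recovery/accuracy numbers the
test-suite asserts: assembly recovery (edit-distance based, via edlib),
cluster agreement (adjusted Rand index, via scikit-learn) and
host/symbiont classification accuracy.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import edlib
from sklearn.metrics import adjusted_rand_score

from .seqio import SeqRecord, reverse_complement

__all__ = [
    "transcript_recovery",
    "assembly_recovery_fraction",
    "cluster_ari",
    "partition_accuracy",
]


def _identity_and_coverage(transcript: str, contig: str) -> tuple[float, float]:
    """Best (identity, coverage) of a transcript against one contig: the
    shorter sequence is infix-aligned into the longer."""
    t, c = transcript.upper(), contig.upper()
    if len(c) >= len(t):
        query, target, cov = t, c, 1.0
    else:
        query, target, cov = c, t, len(c) / len(t)
    res = edlib.align(query, target, mode="HW", task="distance")
    ident = 1.0 - res["editDistance"] / len(query)
    return ident, cov


def transcript_recovery(transcript: SeqRecord, contigs: Sequence[SeqRecord],
                        min_coverage: float = 0.95,
                        min_identity: float = 0.99) -> bool:
    """True if some contig covers >= min_coverage of the transcript's
    length at >= min_identity (either orientation)."""
    t = transcript.seq
    for c in contigs:
        for seq in (c.seq, reverse_complement(c.seq)):
            ident, cov = _identity_and_coverage(t, seq)
            if cov >= min_coverage and ident >= min_identity:
                return True
    return False


def assembly_recovery_fraction(transcripts: Sequence[SeqRecord],
                               contigs: Sequence[SeqRecord],
                               min_coverage: float = 0.95,
                               min_identity: float = 0.99) -> float:
    """Fraction of planted transcripts recovered by the contig set."""
    if not transcripts:
        raise ValueError("no transcripts to score")
    hit = sum(transcript_recovery(t, contigs, min_coverage, min_identity)
              for t in transcripts)
    return hit / len(transcripts)


def cluster_ari(assignment: Mapping[str, str], truth: Mapping[str, str]) -> float:
    """Adjusted Rand index between a cluster assignment and planted labels,
    over the ids present in both mappings."""
    ids = sorted(set(assignment) & set(truth))
    if not ids:
        raise ValueError("no overlapping ids between assignment and truth")
    return float(adjusted_rand_score([truth[i] for i in ids],
                                     [assignment[i] for i in ids]))


def partition_accuracy(labels: Mapping[str, str],
                       truth: Mapping[str, str]) -> float:
    """Fraction of regions whose host/symbiont label matches the truth."""
    ids = sorted(set(labels) & set(truth))
    if not ids:
        raise ValueError("no overlapping ids between labels and truth")
    return sum(labels[i] == truth[i] for i in ids) / len(ids)
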