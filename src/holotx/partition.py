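"""Symbiont/host partitioning of annotated cDNA regions.

Holobiont assemblies mix host transcripts with transcripts of the resident
algal endosymbiont.  The cutoff separating "background cross-taxon
similarity" from "genuinely symbiont-derived" is calibrated from a
reciprocal nucleotide search between the host-side reference and the
symbiont transcriptome: the geometric mean (mean in log10 space) of the
pooled cross-hit E-values.  A region whose best hit against the symbiont
database is more significant than that background average is labelled
symbiont; everything else is host.  The default operating cutoff is 1e-80.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .homology import NUCLEOTIDE_SCHEME, PROTEIN_SCHEME, ScoringScheme, best_hits, search
from .seqio import SeqRecord

__all__ = [
    "PartitionResult",
    "DEFAULT_SYMBIONT_CUTOFF",
    "pooled_evalue_cutoff",
    "calibrate_threshold",
    "classify_origin",
    "classify_from_hits",
    "confirm_translated_annotation",
]

DEFAULT_SYMBIONT_CUTOFF = 1e-80
_CALIBRATION_CEILING = 10.0


@dataclass
class PartitionResult:
    """Binary, exhaustive host/symbiont labelling of cDNA regions."""

    labels: dict[str, str]                    # region id -> "host" | "symbiont"
    best_evalue: dict[str, float]             # best symbiont-db E per region (inf if none)
    threshold: float
    fraction_symbiont_of_annotated: float     # percent
    fraction_symbiont_of_total_contigs: float  # percent

    @property
    def n_symbiont(self) -> int:
        return sum(1 for v in self.labels.values() if v == "symbiont")

    @property
    def n_host(self) -> int:
        return sum(1 for v in self.labels.values() if v == "host")


def pooled_evalue_cutoff(evalues: Sequence[float],
                         method: str = "geometric") -> float:
    """Cutoff from pooled cross-search E-values.

    ``geometric`` (default) returns ``10 ** mean(log10 E)``; the arithmetic
    mean is available behind the flag but is dominated by the largest
    value.  Zero E-values are excluded from the geometric mean with a
    warning.
    """
    vals = list(evalues)
    if not vals:
        raise ValueError("no E-values to pool")
    if method == "arithmetic":
        return sum(vals) / len(vals)
    if method != "geometric":
        raise ValueError(f"unknown averaging method {method!r}")
    nonzero = [e for e in vals if e > 0]
    if len(nonzero) < len(vals):
        warnings.warn(f"excluded {len(vals) - len(nonzero)} zero E-values "
                      "from the geometric mean")
    if not nonzero:
        raise ValueError("all pooled E-values are zero")
    return 10 ** (sum(math.log10(e) for e in nonzero) / len(nonzero))


def calibrate_threshold(host_reference_seqs: Sequence[SeqRecord],
                        symbiont_seqs: Sequence[SeqRecord],
                        scheme: ScoringScheme = NUCLEOTIDE_SCHEME,
                        method: str = "geometric",
                        reporting_ceiling: float = _CALIBRATION_CEILING) -> float:
    """Reciprocal cross-taxon calibration of the symbiont E-value cutoff.

    Runs the nucleotide search in both directions, pools the reported hit
    E-values and returns their geometric mean.  Raises if the two sets
    share no similarity at the reporting ceiling (choose a cutoff
    manually in that case, e.g. :data:`DEFAULT_SYMBIONT_CUTOFF`).
    """
    if not host_reference_seqs or not symbiont_seqs:
        raise ValueError("both sequence sets must be non-empty")
    fwd = search(host_reference_seqs, symbiont_seqs, scheme,
                 evalue_max=reporting_ceiling)
    rev = search(symbiont_seqs, host_reference_seqs, scheme,
                 evalue_max=reporting_ceiling)
    pooled = list(fwd["evalue"]) + list(rev["evalue"])
    if not pooled:
        raise ValueError(
            "no cross-hits at the reporting ceiling; set the cutoff "
            "manually (the published operating point is 1e-80)")
    return pooled_evalue_cutoff(pooled, method=method)


def classify_from_hits(region_ids: Sequence[str],
                       symbiont_hits: pd.DataFrame, cutoff: float,
                       total_contigs: int | None = None) -> PartitionResult:
    """Label regions from a precomputed region-vs-symbiont-db hit table.

    A region is symbiont iff its best hit has E <= *cutoff*.  Exposed
    separately so a single search supports several cutoffs (the labelling
    is monotone in the cutoff).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if not region_ids:
        raise ValueError("empty region set")
    best = {}
    if not symbiont_hits.empty:
        for row in best_hits(symbiont_hits).itertuples(index=False):
            best[row.qseqid] = row.evalue
    labels = {}
    best_e = {}
    for rid in region_ids:
        e = best.get(rid, math.inf)
        best_e[rid] = e
        labels[rid] = "symbiont" if e <= cutoff else "host"
    n = len(region_ids)
    n_sym = sum(1 for v in labels.values() if v == "symbiont")
    total = total_contigs if total_contigs is not None else n
    return PartitionResult(labels, best_e, cutoff,
                           100.0 * n_sym / n,
                           100.0 * n_sym / total if total else 0.0)


def classify_origin(cdna_regions: Sequence[SeqRecord],
                    symbiont_db: Sequence[SeqRecord],
                    scheme: ScoringScheme = NUCLEOTIDE_SCHEME,
                    cutoff: float = DEFAULT_SYMBIONT_CUTOFF,
                    total_contigs: int | None = None
                    ) -> tuple[PartitionResult, list[SeqRecord]]:
    """Partition annotated cDNA regions into host and symbiont sets.

    Each region's best nucleotide hit against *symbiont_db* decides its
    label (E <= cutoff => symbiont).  Returns the partition plus the
    non-symbiont (host) records, ready to be written as FASTA.  Symbiont
    percentages are reported against the annotated-region set and, when
    *total_contigs* is given, against the total contig count.
    """
    if not cdna_regions:
        raise ValueError("empty region set")
    hits = search(cdna_regions, symbiont_db, scheme,
                  evalue_max=max(cutoff, _CALIBRATION_CEILING))
    result = classify_from_hits([r.id for r in cdna_regions], hits, cutoff,
                                total_contigs)
    non_symbiont = [r for r in cdna_regions if result.labels[r.id] == "host"]
    return result, non_symbiont


def confirm_translated_annotation(host_regions: Sequence[SeqRecord],
                                  reference_proteome: Sequence[SeqRecord],
                                  expected_subject: Mapping[str, str],
                                  evalue_max: float = 2e-30) -> float:
    """Translated-search confirmation of the peptide annotation.

    Six-frame-translates each host-labelled cDNA region, searches the
    reference proteome in protein mode, and checks that the best subject
    equals the subject found by the original peptide search.  Returns the
    agreement fraction over regions with an expectation.
    """
    regions = [r for r in host_regions if r.id in expected_subject]
    if not regions:
        raise ValueError("no regions with an expected subject")
    hits = search(regions, reference_proteome, PROTEIN_SCHEME,
                  evalue_max=evalue_max, mode="translated")
    top = {row.qseqid: row.sseqid
           for row in best_hits(hits).itertuples(index=False)}
    agree = sum(1 for r in regions if top.get(r.id) == expected_subject[r.id])
    return agree / len(regions)


def write_partition(result: PartitionResult, path) -> None:
    """Labels TSV: region_id, origin, best_E."""
    with open(path, "w") as fh:
        fh.write("region_id\torigin\tbest_E\n")
        for rid in sorted(result.labels):
            e = result.best_evalue.get(rid, math.inf)
            fh.write(f"{rid}\t{result.labels[rid]}\t"
                     f"{'NA' if math.isinf(e) else format(e, '.6g')}\n")
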