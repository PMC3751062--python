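"""Six-frame stop-to-stop ORF extraction.

An ORF is a maximal stop-free codon run between two stop codons (or between
a sequence end and the nearest stop) in one of the six reading frames.  The
interval is stop-exclusive: neither flanking stop codon is part of the ORF.
Partial runs at contig edges are reported, since assembled transcripts are
frequently truncated.  Runs are kept when their nucleotide span is strictly
greater than ``min_nt`` (default 150).

Codons containing ambiguity codes translate to ``X`` and never terminate a
run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id as _tables

from .seqio import SeqRecord, reverse_complement

__all__ = ["Orf", "find_orfs", "orf_cdna_export", "orf_table"]

_CODON_TABLE = dict(_tables[1].forward_table)
_STOPS = set(_tables[1].stop_codons)          # TAA, TAG, TGA


def translate_codon(codon: str) -> str | None:
    """Amino acid for a codon; 'X' for ambiguous codons; None for stops."""
    codon = codon.upper()
    if codon in _STOPS:
        return None
    return _CODON_TABLE.get(codon, "X")


def translate(seq: str) -> str:
    """Translate a stop-free nucleotide sequence (length divisible by 3)."""
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = translate_codon(seq[i:i + 3])
        out.append("*" if aa is None else aa)
    return "".join(out)


@dataclass
class Orf:
    """A stop-to-stop open reading frame on an assembled contig.

    ``nt_start``/``nt_end`` are 1-based inclusive on the forward contig;
    ``cdna`` is the contig span, reverse-complemented for minus-strand
    ORFs, and translates exactly to ``peptide``.
    """

    orf_id: str
    contig_id: str
    strand: str                  # '+' | '-'
    frame: int                   # 1..3 within the strand
    nt_start: int
    nt_end: int
    peptide: str
    cdna: str

    @property
    def aa_len(self) -> int:
        return len(self.peptide)


def find_orfs(contig: SeqRecord, min_nt: int = 150) -> list[Orf]:
    """All six-frame stop-to-stop ORFs of *contig* with nucleotide span
    strictly greater than *min_nt*, in deterministic (strand, frame,
    position) order."""
    if min_nt < 3:
        raise ValueError("min_nt must be >= 3")
    min_nt -= min_nt % 3
    seq = contig.seq.upper()
    L = len(seq)
    orfs: list[Orf] = []
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for off in range(3):
            n_codons = (L - off) // 3
            if n_codons == 0:
                continue
            run_start = None
            for ci in range(n_codons + 1):
                codon = s[off + 3 * ci: off + 3 * ci + 3] if ci < n_codons else None
                is_stop = codon is not None and codon in _STOPS
                if ci < n_codons and not is_stop:
                    if run_start is None:
                        run_start = ci
                    continue
                if run_start is not None:
                    a = off + 3 * run_start          # 0-based on strand s
                    b = off + 3 * ci                 # exclusive
                    if b - a > min_nt:
                        cdna = s[a:b]
                        pep = translate(cdna)
                        if strand == "+":
                            nt_start, nt_end = a + 1, b
                        else:
                            nt_start, nt_end = L - b + 1, L - a
                        orfs.append(Orf("", contig.id, strand, off + 1,
                                        nt_start, nt_end, pep, cdna))
                    run_start = None
    for i, orf in enumerate(orfs, start=1):
        orf.orf_id = f"{contig.id}-{i}"
    return orfs


def orf_cdna_export(orfs: Iterable[Orf]) -> list[SeqRecord]:
    """FASTA records of the cDNA regions backing each ORF."""
    return [SeqRecord(o.orf_id, o.cdna,
                      f"{o.contig_id}:{o.nt_start}-{o.nt_end}({o.strand})")
            for o in orfs]


def orf_peptides(orfs: Iterable[Orf]) -> list[SeqRecord]:
    """FASTA records of ORF peptides."""
    return [SeqRecord(o.orf_id, o.peptide) for o in orfs]


def orf_table(orfs: Sequence[Orf]):
    """Tabular view (orf_id, contig, strand, frame, start, end, aa_len)."""
    import pandas as pd

    return pd.DataFrame(
        [{"orf_id": o.orf_id, "contig": o.contig_id, "strand": o.strand,
          "frame": o.frame, "start": o.nt_start, "end": o.nt_end,
          "aa_len": o.aa_len} for o in orfs])
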