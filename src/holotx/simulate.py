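"""Synthetic holobiont data with known ground truth.

The generator emulates the inputs of a coral-holobiont transcriptome study:
a reference proteome organised into gene families with paralogs (standing in
for the distant cnidarian reference used for annotation), host transcripts
encoding diverged copies of reference proteins (optionally with N-terminal
extensions, emulating long fluorescent-protein isoforms), symbiont
transcripts drawn from a heavily diverged pool (the algal endosymbiont), a
per-transcript expression profile, and 75 bp paired-end reads with
substitution errors.

Every downstream stage can be scored against the returned
:class:`SimTruth`: assembly recovery, ORF correctness, cluster purity,
symbiont classification accuracy and expression recovery.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .seqio import FastqRead, SeqRecord, reverse_complement, write_fasta, write_fastq

__all__ = [
    "SimTruth",
    "simulate_reference_proteome",
    "simulate_annotation",
    "simulate_holobiont_transcripts",
    "simulate_expression",
    "simulate_reads",
    "simulate_holobiont",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")

# standard genetic code (table 1), amino acid -> codons
_CODONS_BY_AA: dict[str, list[str]] = {}
from Bio.Data.CodonTable import unambiguous_dna_by_id as _tables

for _codon, _aa in _tables[1].forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()


@dataclass
class TranscriptInfo:
    """Ground-truth provenance of one simulated transcript."""

    transcript_id: str
    origin: str                  # "host" | "symbiont"
    source_id: str               # reference protein id (host) or pool transcript id
    family: str                  # gene family label ("" for symbiont)
    cds_start: int               # 1-based inclusive, 0 if not applicable
    cds_end: int
    peptide: str                 # encoded peptide (host); "" for symbiont
    has_extension: bool = False


@dataclass
class SimTruth:
    """Everything needed to score the pipeline on synthetic data."""

    reference_proteome: list[SeqRecord]
    family_of: dict[str, str]                    # protein id -> family id
    host_transcripts: list[SeqRecord]
    symbiont_transcripts: list[SeqRecord]
    symbiont_pool: list[SeqRecord]               # the symbiont reference transcriptome
    transcript_info: dict[str, TranscriptInfo]
    expression: dict[str, float] = field(default_factory=dict)
    read_origin: dict[str, tuple[str, int, str]] = field(default_factory=dict)

    @property
    def transcripts(self) -> list[SeqRecord]:
        return self.host_transcripts + self.symbiont_transcripts


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate_peptide(pep: str, rate: float, rng: np.random.Generator) -> str:
    out = list(pep)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _mutate_nt(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [c for c in NUCLEOTIDES if c != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def back_translate(pep: str, rng: np.random.Generator) -> str:
    """Back-translate a peptide choosing synonymous codons uniformly."""
    return "".join(_CODONS_BY_AA[a][rng.integers(len(_CODONS_BY_AA[a]))] for a in pep)


def _random_utr(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(NUCLEOTIDES), size=n))


def simulate_reference_proteome(
    n_families: int,
    paralogs_per_family: int = 2,
    length_range: tuple[int, int] = (100, 200),
    seed=0,
    within_family_divergence: float = 0.10,
) -> tuple[list[SeqRecord], dict[str, str]]:
    """Reference proteome organised into gene families.

    Each family is drawn from a random common ancestor; paralogs carry
    independent substitutions at *within_family_divergence* per site, so
    within-family identity stays well above between-family identity (random
    20-letter background, ~5%).

    Returns (proteins, family_of) where ``family_of`` maps protein id to
    family id.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    lo, hi = length_range
    if lo > hi or lo < 60:
        raise ValueError("degenerate length_range; lengths must be >= 60 aa")
    rng = _rng(seed)
    proteins: list[SeqRecord] = []
    family_of: dict[str, str] = {}
    for f in range(n_families):
        fam = f"fam{f:03d}"
        ancestor = _random_peptide(rng, int(rng.integers(lo, hi + 1)))
        for p in range(paralogs_per_family):
            pep = _mutate_peptide(ancestor, within_family_divergence, rng)
            pid = f"ref{f:03d}_{p}"
            proteins.append(SeqRecord(pid, pep, f"family={fam}"))
            family_of[pid] = fam
    return proteins, family_of


_GO_VOCAB = {
    "molecular_function": [
        "nucleic acid binding", "protein kinase activity", "catalytic activity",
        "calcium ion binding", "ATP binding", "transporter activity",
    ],
    "biological_process": [
        "metabolism", "electron transport", "intracellular signaling cascade",
        "proteolysis and peptidolysis", "protein folding",
    ],
    "cellular_component": [
        "membrane", "nucleus", "cytoplasm", "ubiquitin ligase complex",
    ],
}
_KOG_VOCAB = ["E3 ubiquitin ligase", "Zn-finger protein", "GPCR Rhodopsin family",
              "Ras GTPase superfamily", "EGF-like domain protein"]
_IPR_VOCAB = ["IPR000001", "IPR000719", "IPR001841", "IPR011009", "IPR013087"]


def simulate_annotation(
    proteome: Sequence[SeqRecord],
    family_of: Mapping[str, str],
    seed=0,
    annotated_fraction: float = 0.9,
):
    """Reference functional-annotation table (gene name, GO, KOG, InterPro).

    Labels are family-consistent: paralogs of one family share a gene name.
    Returns a pandas DataFrame with columns protein_id, gene_name, go_terms,
    kog_terms, interpro_terms; GO terms are "category:term" tokens joined by
    ';'.  A configurable fraction of proteins is left unannotated.
    """
    import pandas as pd

    rng = _rng(seed)
    fam_rows: dict[str, tuple[str, str, str, str]] = {}
    rows = []
    for rec in proteome:
        fam = family_of[rec.id]
        if fam not in fam_rows:
            if rng.random() < annotated_fraction:
                cat = list(_GO_VOCAB)[rng.integers(len(_GO_VOCAB))]
                terms = [f"{cat}:{_GO_VOCAB[cat][rng.integers(len(_GO_VOCAB[cat]))]}"]
                if rng.random() < 0.5:
                    cat2 = list(_GO_VOCAB)[rng.integers(len(_GO_VOCAB))]
                    terms.append(f"{cat2}:{_GO_VOCAB[cat2][rng.integers(len(_GO_VOCAB[cat2]))]}")
                go = ";".join(sorted(set(terms)))
                kog = _KOG_VOCAB[rng.integers(len(_KOG_VOCAB))]
                ipr = _IPR_VOCAB[rng.integers(len(_IPR_VOCAB))]
                fam_rows[fam] = (f"gene_{fam}", go, kog, ipr)
            else:
                fam_rows[fam] = ("", "", "", "")
        name, go, kog, ipr = fam_rows[fam]
        rows.append({"protein_id": rec.id, "gene_name": name, "go_terms": go,
                     "kog_terms": kog, "interpro_terms": ipr})
    return pd.DataFrame(rows)


def simulate_holobiont_transcripts(
    proteome: Sequence[SeqRecord],
    family_of: Mapping[str, str],
    n_host: int,
    n_symbiont: int,
    host_divergence: float = 0.05,
    symbiont_pool_divergence: float = 0.50,
    utr_range: tuple[int, int] = (30, 90),
    extension_fraction: float = 0.10,
    extension_aa_range: tuple[int, int] = (20, 60),
    symbiont_copy_divergence: float = 0.01,
    seed=0,
) -> tuple[list[SeqRecord], list[SeqRecord], list[SeqRecord], dict[str, TranscriptInfo]]:
    """Host and symbiont transcripts plus the symbiont reference pool.

    Host transcript = 5'UTR + in-frame stop + CDS + stop + 3'UTR, where the
    CDS back-translates a copy of a reference protein mutated at
    *host_divergence* per residue; a fraction carries an N-terminal
    extension.  The symbiont pool derives from the same ancestral proteins
    but at *symbiont_pool_divergence* (must exceed *host_divergence*), so
    cross-taxon similarity exists but is far weaker — which is what makes
    the E-value cutoff calibration meaningful.  Each expressed symbiont
    transcript is a pool member with light extra substitutions.

    Returns (host_transcripts, symbiont_transcripts, symbiont_pool, info).
    """
    if not (0 <= host_divergence < symbiont_pool_divergence):
        raise ValueError(
            "require 0 <= host_divergence < symbiont_pool_divergence")
    rng = _rng(seed)
    info: dict[str, TranscriptInfo] = {}

    host: list[SeqRecord] = []
    for i in range(n_host):
        src = proteome[i % len(proteome)]
        pep = _mutate_peptide(src.seq, host_divergence, rng)
        extended = rng.random() < extension_fraction
        if extended:
            ext_len = int(rng.integers(extension_aa_range[0], extension_aa_range[1] + 1))
            pep = _random_peptide(rng, ext_len) + pep
        cds = back_translate(pep, rng)
        utr5 = _random_utr(rng, *utr_range)
        utr3 = _random_utr(rng, *utr_range)
        seq = utr5 + "TAA" + cds + "TAA" + utr3
        tid = f"host{i:04d}"
        cds_start = len(utr5) + 4          # 1-based first CDS base
        host.append(SeqRecord(tid, seq, f"source={src.id}"))
        info[tid] = TranscriptInfo(tid, "host", src.id, family_of[src.id],
                                   cds_start, cds_start + len(cds) - 1, pep,
                                   extended)

    pool: list[SeqRecord] = []
    symb: list[SeqRecord] = []
    for j in range(n_symbiont):
        src = proteome[j % len(proteome)]
        pep = _mutate_peptide(src.seq, symbiont_pool_divergence, rng)
        cds = back_translate(pep, rng)
        pseq = _random_utr(rng, *utr_range) + "TAA" + cds + "TAA" + _random_utr(rng, *utr_range)
        pid = f"sympool{j:03d}"
        pool.append(SeqRecord(pid, pseq))
        tid = f"symb{j:04d}"
        symb.append(SeqRecord(tid, _mutate_nt(pseq, symbiont_copy_divergence, rng),
                              f"source={pid}"))
        info[tid] = TranscriptInfo(tid, "symbiont", pid, "", 0, 0, "")
    return host, symb, pool, info


def simulate_expression(transcript_ids: Sequence[str], seed=0,
                        sigma: float = 1.0) -> dict[str, float]:
    """Log-normal relative abundances, normalised to sum to 1."""
    rng = _rng(seed)
    w = rng.lognormal(mean=0.0, sigma=sigma, size=len(transcript_ids))
    w = w / w.sum()
    return {tid: float(x) for tid, x in zip(transcript_ids, w)}


def simulate_reads(
    transcripts: Sequence[SeqRecord],
    expression: Mapping[str, float],
    n_pairs: int,
    read_len: int = 75,
    insert_mean: int = 200,
    insert_sd: int = 30,
    error_rate: float = 0.01,
    seed=0,
) -> tuple[list[FastqRead], list[FastqRead], dict[str, tuple[str, int, str]]]:
    """Paired 75 bp reads from an expression-weighted fragment model.

    Fragment start positions are uniform within the transcript; the expected
    read share of transcript t is proportional to
    ``expression(t) * effective_length(t)`` with effective length
    ``max(L - insert_mean + 1, 1)``.  Mate 2 is the reverse complement of
    the fragment's 3' end.  Substitution errors are applied per base at
    *error_rate*; no indels.

    Returns (mate1 reads, mate2 reads, read_origin) with
    ``read_origin[pair_id] = (transcript_id, fragment_start0, '+')``.
    """
    rng = _rng(seed)
    usable = [t for t in transcripts if len(t.seq) >= read_len]
    dropped = [t.id for t in transcripts if len(t.seq) < read_len]
    if dropped:
        warnings.warn(f"excluded {len(dropped)} transcripts shorter than read_len")
    if not usable:
        raise ValueError("no transcript is long enough to sequence")
    weights = np.array(
        [expression.get(t.id, 0.0) * max(len(t.seq) - insert_mean + 1, 1)
         for t in usable], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("expression weights sum to zero over usable transcripts")
    weights = weights / weights.sum()

    mate1: list[FastqRead] = []
    mate2: list[FastqRead] = []
    origin: dict[str, tuple[str, int, str]] = {}
    qual = "I" * read_len
    choices = rng.choice(len(usable), size=n_pairs, p=weights)
    for i in range(n_pairs):
        t = usable[choices[i]]
        L = len(t.seq)
        insert = int(round(rng.normal(insert_mean, insert_sd)))
        insert = max(read_len, min(insert, L))
        start = int(rng.integers(0, L - insert + 1))
        frag = t.seq[start:start + insert]
        r1 = frag[:read_len]
        r2 = reverse_complement(frag[-read_len:])
        if error_rate > 0:
            r1 = _mutate_nt(r1, error_rate, rng)
            r2 = _mutate_nt(r2, error_rate, rng)
        pid = f"r{i:06d}"
        mate1.append(FastqRead(f"{pid}/1", r1, qual))
        mate2.append(FastqRead(f"{pid}/2", r2, qual))
        origin[pid] = (t.id, start, "+")
    return mate1, mate2, origin


def simulate_holobiont(
    n_families: int = 12,
    paralogs_per_family: int = 2,
    n_host: int = 36,
    n_symbiont: int = 8,
    n_pairs: int = 4000,
    length_range: tuple[int, int] = (100, 180),
    host_divergence: float = 0.05,
    symbiont_pool_divergence: float = 0.50,
    error_rate: float = 0.005,
    read_len: int = 75,
    insert_mean: int = 200,
    insert_sd: int = 30,
    expression_sigma: float = 1.0,
    seed: int = 0,
) -> tuple[SimTruth, list[FastqRead], list[FastqRead]]:
    """One call that builds the full synthetic study: proteome, transcripts,
    expression and reads.  Defaults are the desk-scale study conditions used
    throughout the test-suite and the acceptance script."""
    rng = np.random.default_rng(seed)
    proteome, family_of = simulate_reference_proteome(
        n_families, paralogs_per_family, length_range, rng)
    host, symb, pool, info = simulate_holobiont_transcripts(
        proteome, family_of, n_host, n_symbiont,
        host_divergence=host_divergence,
        symbiont_pool_divergence=symbiont_pool_divergence, seed=rng)
    transcripts = host + symb
    expression = simulate_expression([t.id for t in transcripts], rng,
                                     sigma=expression_sigma)
    m1, m2, origin = simulate_reads(transcripts, expression, n_pairs,
                                    read_len=read_len, insert_mean=insert_mean,
                                    insert_sd=insert_sd,
                                    error_rate=error_rate, seed=rng)
    truth = SimTruth(proteome, family_of, host, symb, pool, info,
                     expression, origin)
    return truth, m1, m2


def reference_cds(proteome: Sequence[SeqRecord], seed=0) -> list[SeqRecord]:
    """Nucleotide coding sequences for the reference proteome (one random
    synonymous back-translation per protein).  Serves as the host-side
    nucleotide reference in cross-taxon cutoff calibration."""
    rng = _rng(seed)
    return [SeqRecord(f"{p.id}_cds", back_translate(p.seq, rng)) for p in proteome]


def write_truth_tables(truth: SimTruth, out_dir) -> None:
    """Write FASTA/TSV ground-truth files for a simulated dataset."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(truth.reference_proteome, out / "reference_proteome.faa")
    write_fasta(truth.transcripts, out / "transcripts.fasta")
    write_fasta(truth.symbiont_pool, out / "symbiont_pool.fasta")
    with open(out / "transcript_truth.tsv", "w") as fh:
        fh.write("transcript_id\torigin\tsource_id\tfamily\tcds_start\tcds_end\texpression\n")
        for tid, ti in truth.transcript_info.items():
            fh.write(f"{tid}\t{ti.origin}\t{ti.source_id}\t{ti.family}\t"
                     f"{ti.cds_start}\t{ti.cds_end}\t{truth.expression.get(tid, 0.0):.8g}\n")
    with open(out / "read_origin.tsv", "w") as fh:
        fh.write("pair_id\ttranscript_id\tfragment_start0\tstrand\n")
        for pid, (tid, start, strand) in truth.read_origin.items():
            fh.write(f"{pid}\t{tid}\t{start}\t{strand}\n")
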