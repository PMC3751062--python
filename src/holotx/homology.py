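"""Pairwise local alignment with E-value statistics, database search,
best-hit logic, the proteome-completeness metric and the pre-clustering
graph.

Alignment is optimal Smith–Waterman under affine gaps (a gap of length g
costs ``gap_open + g * gap_extend``), computed by Biopython's
``PairwiseAligner``.  Significance follows the Karlin–Altschul formula
``E = K * m * n * exp(-lambda * S)`` with fixed published parameter sets
per scoring scheme; lengths m and n are used raw (no edge-effect
correction), which keeps the bias consistent across comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .orffinder import translate
from .seqio import SeqRecord, reverse_complement

__all__ = [
    "ScoringScheme",
    "PROTEIN_SCHEME",
    "NUCLEOTIDE_SCHEME",
    "LocalAlignment",
    "align_local",
    "evalue",
    "search",
    "best_hits",
    "completeness",
    "build_precluster_graph",
    "write_hits",
    "read_hits",
    "HIT_COLUMNS",
]

_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZXJUO*")
_NUCLEOTIDE_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scores, affine gap penalties and Karlin–Altschul
    parameters for one search mode.

    ``substitution`` is a matrix name (protein mode) or a
    (match, mismatch) pair (nucleotide mode); gap penalties are positive
    costs in the BLAST convention.
    """

    mode: str                        # "protein" | "nucleotide"
    substitution: object
    gap_open: float
    gap_extend: float
    lambda_: float
    k_const: float

    def __post_init__(self):
        if self.mode not in ("protein", "nucleotide"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lambda_ <= 0 or self.k_const <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    @property
    def alphabet(self) -> set[str]:
        return _PROTEIN_ALPHABET if self.mode == "protein" else _NUCLEOTIDE_ALPHABET


# standard gapped BLASTP constants; blastn-style nucleotide scheme
PROTEIN_SCHEME = ScoringScheme("protein", "BLOSUM62", 11, 1, 0.267, 0.041)
NUCLEOTIDE_SCHEME = ScoringScheme("nucleotide", (1, -2), 5, 2, 1.28, 0.46)


@lru_cache(maxsize=8)
def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    if scheme.mode == "protein":
        aligner.substitution_matrix = substitution_matrices.load(scheme.substitution)
    else:
        match, mismatch = scheme.substitution
        alphabet = "ACGTN"
        m = substitution_matrices.Array(alphabet, dims=2)
        for a in alphabet:
            for b in alphabet:
                m[a, b] = match if (a == b and a != "N") else mismatch
        aligner.substitution_matrix = m
    # BLAST convention: gap of length g costs open + g*extend
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


@dataclass
class LocalAlignment:
    """One optimal local alignment: score, 1-based end-inclusive coordinates
    on query and subject, and identity over aligned columns."""

    score: float
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0
    identity: float = 0.0
    n_ident: int = 0
    length: int = 0                  # aligned columns including gaps


def _check_alphabet(seq: str, scheme: ScoringScheme, label: str) -> None:
    bad = set(seq.upper()) - scheme.alphabet
    if bad:
        raise ValueError(
            f"{label} contains characters {sorted(bad)} outside the "
            f"{scheme.mode} alphabet")


def align_score(a: str, b: str, scheme: ScoringScheme = PROTEIN_SCHEME) -> float:
    """Optimal local alignment score only (no traceback)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    _check_alphabet(a, scheme, "query")
    _check_alphabet(b, scheme, "subject")
    return float(_aligner(scheme).score(a.upper(), b.upper()))


def align_local(a: str, b: str, scheme: ScoringScheme = PROTEIN_SCHEME) -> LocalAlignment:
    """Optimal Smith–Waterman local alignment of *a* (query) and *b*
    (subject) with one deterministic traceback.  A pair with no
    positive-scoring alignment returns score 0 and an empty alignment."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    _check_alphabet(a, scheme, "query")
    _check_alphabet(b, scheme, "subject")
    a, b = a.upper(), b.upper()
    aligner = _aligner(scheme)
    score = float(aligner.score(a, b))
    if score <= 0:
        return LocalAlignment(0.0)
    aln = aligner.align(a, b)[0]
    qblocks, sblocks = aln.aligned
    n_ident = 0
    aligned_cols = 0
    prev_qe = prev_se = None
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        if prev_qe is not None:
            aligned_cols += (qs - prev_qe) + (ss - prev_se)   # gap columns
        for x, y in zip(a[qs:qe], b[ss:se]):
            if x == y:
                n_ident += 1
        aligned_cols += qe - qs
        prev_qe, prev_se = qe, se
    q_start = int(qblocks[0][0]) + 1
    q_end = int(qblocks[-1][1])
    s_start = int(sblocks[0][0]) + 1
    s_end = int(sblocks[-1][1])
    identity = n_ident / aligned_cols if aligned_cols else 0.0
    return LocalAlignment(score, q_start, q_end, s_start, s_end,
                          identity, n_ident, aligned_cols)


def evalue(score: float, m: int, n: int,
           scheme: ScoringScheme = PROTEIN_SCHEME) -> float:
    """Karlin–Altschul expectation ``E = K * m * n * exp(-lambda * S)``."""
    if score < 0:
        raise ValueError("score must be >= 0")
    # work in log space; underflow to 0.0 is acceptable (capped downstream)
    log_e = math.log(scheme.k_const) + math.log(m) + math.log(n) \
        - scheme.lambda_ * score
    if log_e < -745:
        return 0.0
    return math.exp(log_e)


HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "qstart", "qend",
               "sstart", "send", "evalue", "score", "qcov", "scov"]


def _frame_fragments(seq: str, min_aa: int = 15):
    """Stop-delimited peptide fragments of all six frames of a nucleotide
    query (for translated search)."""
    L = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for off in range(3):
            pep = translate(s[off:])
            for frag in pep.split("*"):
                frag = frag.strip()
                if len(frag) >= min_aa:
                    yield frag


def _shares_word(a: str, b: str, w: int) -> bool:
    words = {a[i:i + w] for i in range(len(a) - w + 1)}
    return any(b[j:j + w] in words for j in range(len(b) - w + 1))


def search(queries: Sequence[SeqRecord], database: Sequence[SeqRecord],
           scheme: ScoringScheme = PROTEIN_SCHEME,
           evalue_max: float = 2e-30, mode: str | None = None,
           seed_filter_word: int | None = None) -> pd.DataFrame:
    """All-vs-all local-alignment search of *queries* against *database*.

    Reports every query–subject pair with E <= *evalue_max*, sorted per
    query by ascending E (ties: higher score, then subject id).  The
    database size n for E-values is the total residue count of the
    database.  ``mode='translated'`` six-frame-translates each nucleotide
    query, searches the stop-delimited peptide fragments in protein mode
    and reports the best frame per pair.  *seed_filter_word* enables an
    optional shared-word prefilter (skips pairs sharing no exact word);
    full dynamic programming is the default.
    """
    if not database:
        raise ValueError("database must be non-empty")
    mode = mode or scheme.mode
    translated = mode == "translated"
    if translated and scheme.mode != "protein":
        raise ValueError("translated search requires a protein scheme")
    n_db = sum(len(s.seq) for s in database)
    aligner_scheme = scheme
    rows = []
    for q in queries:
        variants: list[tuple[str, int]]
        if translated:
            variants = [(frag, max(len(q.seq) // 3, 1))
                        for frag in _frame_fragments(q.seq.upper())]
        else:
            variants = [(q.seq.upper(), len(q.seq))]
        per_subject: dict[str, dict] = {}
        for qseq, m_len in variants:
            if not qseq:
                continue
            for s in database:
                if seed_filter_word and not _shares_word(qseq, s.seq.upper(),
                                                         seed_filter_word):
                    continue
                score = align_score(qseq, s.seq, aligner_scheme)
                if score <= 0:
                    continue
                e = evalue(score, m_len, n_db, aligner_scheme)
                if e > evalue_max:
                    continue
                prev = per_subject.get(s.id)
                if prev is not None and (prev["evalue"], -prev["score"]) <= (e, -score):
                    continue
                aln = align_local(qseq, s.seq, aligner_scheme)
                per_subject[s.id] = {
                    "qseqid": q.id, "sseqid": s.id,
                    "pident": round(100.0 * aln.identity, 2),
                    "length": aln.length,
                    "qstart": aln.q_start, "qend": aln.q_end,
                    "sstart": aln.s_start, "send": aln.s_end,
                    "evalue": e, "score": score,
                    "qcov": (aln.q_end - aln.q_start + 1) / len(qseq),
                    "scov": (aln.s_end - aln.s_start + 1) / len(s.seq),
                }
        hits = sorted(per_subject.values(),
                      key=lambda r: (r["evalue"], -r["score"], r["sseqid"]))
        rows.extend(hits)
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """One hit per query: minimum E, ties broken by higher score then
    lexicographic subject id."""
    if hits.empty:
        return hits.copy()
    ordered = hits.sort_values(
        ["qseqid", "evalue", "score", "sseqid"],
        ascending=[True, True, False, True], kind="mergesort")
    return ordered.groupby("qseqid", as_index=False, sort=True).head(1) \
                  .reset_index(drop=True)


def reciprocal_best_hits(forward: pd.DataFrame,
                         backward: pd.DataFrame) -> pd.DataFrame:
    """Strict reciprocal-best-hit filter: keep forward best hits whose
    subject's best hit (in the backward search) is the query.  Optional —
    the default annotation path uses one-directional best hits."""
    fb = best_hits(forward)
    bb = best_hits(backward)
    back_map = dict(zip(bb["qseqid"], bb["sseqid"]))
    keep = [back_map.get(s) == q for q, s in zip(fb["qseqid"], fb["sseqid"])]
    return fb[keep].reset_index(drop=True)


def completeness(hits: pd.DataFrame, reference_lengths: Mapping[str, int],
                 min_cov: float = 0.8, evalue_max: float = 2e-30) -> float:
    """Percentage of the reference proteome with at least one hit at
    E <= *evalue_max* covering at least *min_cov* of the reference protein's
    length (boundary inclusive)."""
    if not reference_lengths:
        raise ValueError("reference proteome is empty")
    if hits.empty:
        return 0.0
    unknown = set(hits["sseqid"]) - set(reference_lengths)
    if unknown:
        raise ValueError(f"hits reference unknown subjects: {sorted(unknown)[:5]}")
    ok = hits[(hits["evalue"] <= evalue_max) & (hits["scov"] >= min_cov)]
    return 100.0 * ok["sseqid"].nunique() / len(reference_lengths)


def build_precluster_graph(hits: pd.DataFrame,
                           weight_cap: float = 200.0) -> nx.Graph:
    """Weighted undirected graph over ORF ids and reference ids.

    Edge weight is ``min(-log10(E), weight_cap)`` (E = 0 maps to the cap);
    duplicate pairs keep the best E.  Input hits are expected to be
    pre-filtered at the annotation threshold.
    """
    g = nx.Graph()
    for row in hits.itertuples(index=False):
        e = row.evalue
        w = weight_cap if e <= 0 else min(-math.log10(e), weight_cap)
        u, v = row.qseqid, row.sseqid
        if g.has_edge(u, v):
            if g[u][v]["weight"] >= w:
                continue
        g.add_edge(u, v, weight=w)
    return g


def write_hits(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False)


def read_hits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_graph_abc(graph: nx.Graph, path) -> None:
    """Three-column (node, node, weight) edge list."""
    with open(path, "w") as fh:
        for u, v, d in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['weight']:.6g}\n")
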