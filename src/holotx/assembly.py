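"""Multi-k de Bruijn assembly, N-statistics, k-selection/filtering rules and
a greedy overlap-consensus merge of the combined assemblies.

The assembler is a strand-merged (canonical k-mer) unitig assembler: nodes
are canonical k-mers with a count floor, edges are observed (k+1)-mers, and
contigs are maximal non-branching paths.  No tip clipping or bubble popping
is performed — the intended inputs are error-free or low-error reads where
a k-mer count floor removes sequencing-error nodes.

The merge step is an overlap-layout-consensus surrogate: ungapped
suffix-prefix overlaps (both orientations) above a length and identity
floor are merged greedily, best overlap first, and contained contigs are
absorbed.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from statistics import mean, median
from typing import Iterable, Mapping, Sequence

from .seqio import FastqRead, SeqRecord, reverse_complement

__all__ = [
    "Contig",
    "NStats",
    "DeBruijnGraph",
    "build_debruijn",
    "assemble_unitigs",
    "n_statistic",
    "compute_nstats",
    "assemble_multik",
    "select_and_filter",
    "merge_assemblies",
]


@dataclass
class Contig:
    """An assembled sequence with provenance."""

    id: str
    seq: str
    k_origin: object = None          # int k value or "merged"
    member_ids: tuple = ()

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class NStats:
    """Length-distribution summary of one assembly (N10..N90, median, mean)."""

    n_contigs: int
    total_length: int
    nx: dict[int, int]
    median_length: float
    mean_length: float

    @property
    def n50(self) -> int:
        return self.nx[50]


def _canon(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _seqs(reads: Iterable) -> list[str]:
    out = []
    for r in reads:
        s = r.seq if hasattr(r, "seq") else str(r)
        out.append(s.upper())
    return out


@dataclass
class DeBruijnGraph:
    """Canonical-k-mer de Bruijn graph: node counts plus observed (k+1)-mer
    edges.  Nodes below the count floor are dropped along with their edges."""

    k: int
    counts: dict[str, int]
    edges: set[str]                  # canonical (k+1)-mers
    min_kmer_count: int = 1

    @property
    def nodes(self) -> set[str]:
        return {km for km, c in self.counts.items() if c >= self.min_kmer_count}


def build_debruijn(reads: Iterable, k: int, min_kmer_count: int = 1) -> DeBruijnGraph:
    """Count canonical k-mers and observed (k+1)-mer edges over *reads*.

    k must be odd (no reverse-complement-palindromic k-mers) and smaller
    than the longest read.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if k < 11:
        raise ValueError("k must be >= 11")
    if min_kmer_count < 1:
        raise ValueError("min_kmer_count must be >= 1")
    seqs = _seqs(reads)
    if not seqs:
        return DeBruijnGraph(k, {}, set(), min_kmer_count)
    if k >= max(len(s) for s in seqs):
        raise ValueError(f"k={k} is not smaller than the read length")
    counts: Counter[str] = Counter()
    edges: set[str] = set()
    ok = set("ACGT")
    for s in seqs:
        n = len(s)
        for i in range(n - k + 1):
            km = s[i:i + k]
            if set(km) <= ok:
                counts[_canon(km)] += 1
        for i in range(n - k):
            e = s[i:i + k + 1]
            if set(e) <= ok:
                edges.add(_canon(e))
    return DeBruijnGraph(k, dict(counts), edges, min_kmer_count)


def assemble_unitigs(graph: DeBruijnGraph) -> list[Contig]:
    """Emit maximal non-branching paths of the graph, once per canonical
    orientation, in lexicographic sequence order."""
    k = graph.k
    kept = graph.nodes
    nodes: set[str] = set()
    for km in kept:
        nodes.add(km)
        nodes.add(reverse_complement(km))
    succ: dict[str, set[str]] = defaultdict(set)
    pred: dict[str, set[str]] = defaultdict(set)
    for e in graph.edges:
        for s in (e, reverse_complement(e)):
            u, v = s[:-1], s[1:]
            if u in nodes and v in nodes:
                succ[u].add(v)
                pred[v].add(u)

    def one_in_one_out(v: str) -> bool:
        return len(succ[v]) == 1 and len(pred[v]) == 1

    paths: list[list[str]] = []
    on_path: set[str] = set()
    for u in nodes:
        if not one_in_one_out(u) and succ[u]:
            for v0 in succ[u]:
                path = [u, v0]
                v = v0
                while one_in_one_out(v):
                    v = next(iter(succ[v]))
                    path.append(v)
                paths.append(path)
                on_path.update(path)
    # isolated cycles of 1-in-1-out nodes
    seen = set(on_path)
    for u in nodes:
        if u not in seen and one_in_one_out(u):
            path = [u]
            v = next(iter(succ[u]))
            while v != u:
                path.append(v)
                seen.add(v)
                v = next(iter(succ[v]))
            path.append(u)
            seen.add(u)
            paths.append(path)
    # isolated nodes (no edges at all)
    for u in nodes:
        if not succ[u] and not pred[u]:
            paths.append([u])

    uniq: dict[str, str] = {}
    for path in paths:
        seq = path[0] + "".join(v[-1] for v in path[1:])
        rc = reverse_complement(seq)
        canon = seq if seq <= rc else rc
        uniq[canon] = canon
    ordered = sorted(uniq)
    return [Contig(f"k{k}_c{i:05d}", s, k) for i, s in enumerate(ordered)]


def n_statistic(lengths: Sequence[int], x: float = 50) -> int:
    """Nx: the largest L such that contigs of length >= L sum to >= x% of
    the total assembly length."""
    if not lengths:
        raise ValueError("empty length collection")
    if not (0 < x < 100):
        raise ValueError("x must be in (0, 100)")
    total = sum(lengths)
    cum = 0
    for L in sorted(lengths, reverse=True):
        cum += L
        if 100 * cum >= x * total:
            return L
    return min(lengths)              # unreachable for valid x


def compute_nstats(contigs: Sequence) -> NStats:
    lengths = [len(c) for c in contigs]
    if not lengths:
        raise ValueError("cannot compute N statistics of an empty assembly")
    nx = {x: n_statistic(lengths, x) for x in range(10, 100, 10)}
    return NStats(len(lengths), sum(lengths), nx,
                  float(median(lengths)), float(mean(lengths)))


def assemble_multik(reads: Sequence, k_values: Sequence[int],
                    min_kmer_count: int = 1) -> dict[int, list[Contig]]:
    """One unitig assembly per k value; duplicate k values are an error."""
    ks = list(k_values)
    if not ks:
        raise ValueError("need at least one k value")
    if len(set(ks)) != len(ks):
        raise ValueError("duplicate k values")
    out: dict[int, list[Contig]] = {}
    for k in ks:
        out[k] = assemble_unitigs(build_debruijn(reads, k, min_kmer_count))
    return out


def select_and_filter(assemblies: Mapping[int, Sequence[Contig]],
                      top_n: int = 3, min_len: int = 150) -> list[Contig]:
    """Rank assemblies by N50 (ties broken toward larger k) and keep the top
    *top_n*.  Of the kept assemblies, the one with the longest median contig
    length contributes all of its contigs; the others lose contigs strictly
    shorter than *min_len*.  Returns the combined pool."""
    if len(assemblies) < top_n:
        raise ValueError(f"need at least top_n={top_n} assemblies")
    stats = {k: compute_nstats(c) for k, c in assemblies.items() if c}
    if len(stats) < top_n:
        raise ValueError("too many empty assemblies to select from")
    ranked = sorted(stats, key=lambda k: (stats[k].n50, k), reverse=True)
    kept = ranked[:top_n]
    keeper = max(kept, key=lambda k: (stats[k].median_length, k))
    pool: list[Contig] = []
    for k in kept:
        for c in assemblies[k]:
            if k == keeper or len(c) >= min_len:
                pool.append(c)
    return pool


# ---------------------------------------------------------------------------
# overlap merge

_ANCHOR = 16


def _kmer_index(seq: str, w: int = _ANCHOR) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - w + 1):
        idx.setdefault(seq[i:i + w], []).append(i)
    return idx


def _candidate_offsets(a_idx: dict[str, list[int]], b: str,
                       w: int = _ANCHOR) -> set[int]:
    offs: set[int] = set()
    for j in range(len(b) - w + 1):
        for i in a_idx.get(b[j:j + w], ()):
            offs.add(i - j)
    return offs


def _evaluate_offset(a: str, b: str, d: int, min_overlap: int,
                     min_identity: float):
    """Ungapped placement of b at offset d relative to a.  Returns
    (matches, overlap_len) if the overlap passes the floors, else None."""
    s = max(0, d)
    e = min(len(a), d + len(b))
    ov = e - s
    if ov < min_overlap:
        return None
    matches = 0
    for p in range(s, e):
        if a[p] == b[p - d]:
            matches += 1
    if matches < min_identity * ov:
        return None
    return matches, ov


def _best_placement(a: str, a_idx, b: str, b_rc: str, min_overlap: int,
                    min_identity: float):
    """Best ungapped overlap of b (either orientation) against a.
    Returns (matches, overlap, d, orient) or None."""
    best = None
    for orient, bseq in (("+", b), ("-", b_rc)):
        for d in _candidate_offsets(a_idx, bseq):
            r = _evaluate_offset(a, bseq, d, min_overlap, min_identity)
            if r is None:
                continue
            cand = (r[0], r[1], d, orient)
            if best is None or cand[:2] > best[:2]:
                best = cand
    return best


def _merge_seq(a: str, b: str, d: int) -> str:
    """Combine a and b given b's ungapped offset d relative to a.  In the
    overlap, the base of the longer sequence wins (deterministic consensus
    for pairwise merges)."""
    if d >= 0 and d + len(b) <= len(a):
        return a                     # b contained in a
    if d <= 0 and d + len(b) >= len(a):
        return b                     # a contained in b
    if d < 0:
        a, b, d = b, a, -d
    s, e = d, len(a)
    ov_a = a[s:e]
    ov_b = b[:e - s]
    cons = ov_a if len(a) >= len(b) else ov_b
    return a[:s] + cons + b[e - s:]


def merge_assemblies(contig_pool: Sequence[Contig], min_overlap: int = 40,
                     min_identity: float = 0.90) -> list[Contig]:
    """Greedy overlap-layout-consensus merge of a contig pool.

    Suffix-prefix overlaps (both orientations) of at least *min_overlap*
    bases at *min_identity* or better are merged, best (most matching
    bases) first; contained and duplicate contigs are absorbed.  Merged
    contigs carry the ids of their members.
    """
    if min_overlap < 16:
        raise ValueError("min_overlap must be >= 16")
    if not (0.8 <= min_identity <= 1.0):
        raise ValueError("min_identity must be in [0.8, 1.0]")

    # mutable working set: idx -> [seq, members, original_contig_or_None]
    items: dict[int, list] = {}
    for i, c in enumerate(contig_pool):
        items[i] = [c.seq, {c.id}, c]
    next_idx = len(items)

    cache: dict[int, dict] = {}

    def idx_of(i: int):
        if i not in cache:
            cache[i] = _kmer_index(items[i][0])
        return cache[i]

    def pair_best(i: int, j: int):
        a, b = items[i][0], items[j][0]
        if len(a) < len(b):          # anchor index on the longer sequence
            i, j = j, i
            a, b = b, a
        return _best_placement(a, idx_of(i), b, reverse_complement(b),
                               min_overlap, min_identity), i, j

    best: dict[tuple[int, int], tuple] = {}

    def update_pair(i: int, j: int) -> None:
        key = (min(i, j), max(i, j))
        placement, ai, bi = pair_best(i, j)
        if placement is not None:
            best[key] = (placement, ai, bi)
        else:
            best.pop(key, None)

    ids = list(items)
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            update_pair(ids[x], ids[y])

    while best:
        key = max(best, key=lambda kk: (best[kk][0][0], best[kk][0][1], -kk[0], -kk[1]))
        (matches, ov, d, orient), ai, bi = best[key]
        a_seq, a_mem, _ = items[ai]
        b_seq, b_mem, _ = items[bi]
        if orient == "-":
            b_seq = reverse_complement(b_seq)
        merged = _merge_seq(a_seq, b_seq, d)
        for dead in (ai, bi):
            del items[dead]
            cache.pop(dead, None)
        best = {k: v for k, v in best.items() if ai not in k and bi not in k}
        items[next_idx] = [merged, a_mem | b_mem, None]
        for other in list(items):
            if other != next_idx:
                update_pair(next_idx, other)
        next_idx += 1

    out: list[Contig] = []
    finals = sorted(items.values(), key=lambda it: it[0])
    m = 0
    for seq, members, original in finals:
        if original is not None:
            out.append(original)
        else:
            rc = reverse_complement(seq)
            canon = seq if seq <= rc else rc
            out.append(Contig(f"m{m:05d}", canon, "merged", tuple(sorted(members))))
            m += 1
    return out
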