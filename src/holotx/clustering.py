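"""Markov clustering of the pre-clustering graph, annotation transfer and
family screening.

The Markov cluster algorithm alternates expansion (matrix squaring) and
inflation (entrywise power r with column renormalisation) on a
column-stochastic matrix built from the similarity graph.  Self-loops are
set per node to its maximum incident edge weight before normalisation, the
standard guard against parity artifacts.  Clusters are the weakly connected
components of the converged (attractor) matrix.  The default inflation
r = 2.5 controls cluster granularity: higher r, finer clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MclResult",
    "IsoformCluster",
    "mcl",
    "make_isoform_clusters",
    "transfer_annotation",
    "screen_family",
    "group_by_reference",
    "read_annotation",
    "write_clusters",
]


@dataclass
class MclResult:
    """Raw MCL output: the node partition plus convergence diagnostics."""

    clusters: list[frozenset]
    nodes: list
    n_iter: int
    converged: bool
    max_colsum_dev: float            # worst |column sum - 1| seen after renormalisation


def mcl(graph: nx.Graph, inflation: float = 2.5, prune: float = 1e-5,
        max_iter: int = 200, tol: float = 1e-8) -> MclResult:
    """Markov clustering of a weighted undirected graph.

    Iterates expansion and inflation with entry pruning until the matrix
    changes by less than *tol* (max absolute entry change between
    successive inflation steps) or *max_iter* is reached; non-convergence
    returns the current interpretation with ``converged=False`` and a
    warning.  Deterministic given the (sorted) node ordering; singleton
    clusters are allowed.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v, d in graph.edges(data=True):
        w = float(d.get("weight", 1.0))
        a[index[u], index[v]] = w
        a[index[v], index[u]] = w
    # self-loops: max incident weight (1.0 for isolated nodes)
    incident_max = a.max(axis=0)
    incident_max[incident_max <= 0] = 1.0
    np.fill_diagonal(a, incident_max)

    def _normalise(m: np.ndarray) -> tuple[np.ndarray, float]:
        sums = m.sum(axis=0)
        dead = sums <= 0
        if dead.any():               # a fully pruned column: park on the diagonal
            idx = np.where(dead)[0]
            m[idx, idx] = 1.0
            sums = m.sum(axis=0)
        m = m / sums
        return m, float(np.abs(m.sum(axis=0) - 1.0).max())

    m, dev = _normalise(a)
    max_dev = dev
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        expanded = m @ m
        inflated = expanded ** inflation
        inflated[inflated < prune] = 0.0
        inflated, dev = _normalise(inflated)
        max_dev = max(max_dev, dev)
        diff = float(np.abs(inflated - m).max())
        m = inflated
        if diff < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"MCL did not converge within {max_iter} iterations")

    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > prune)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    comps = [frozenset(nodes[i] for i in comp)
             for comp in nx.connected_components(support)]
    comps.sort(key=lambda c: sorted(map(str, c))[0])
    return MclResult(comps, nodes, it, converged, max_dev)


@dataclass
class IsoformCluster:
    """A homologous isoform cluster: ORF members, reference members and
    transferred annotation labels."""

    cluster_id: str
    member_orf_ids: frozenset
    member_reference_ids: frozenset
    gene_name: str = ""
    go_terms: tuple = ()
    kog_terms: tuple = ()
    interpro_terms: tuple = ()

    @property
    def members(self) -> frozenset:
        return self.member_orf_ids | self.member_reference_ids


def make_isoform_clusters(result: MclResult,
                          reference_ids: Iterable) -> list[IsoformCluster]:
    """Split each MCL cluster into ORF vs reference membership."""
    refs = set(reference_ids)
    out = []
    for i, comp in enumerate(result.clusters):
        out.append(IsoformCluster(
            f"C{i:04d}",
            frozenset(m for m in comp if m not in refs),
            frozenset(m for m in comp if m in refs)))
    return out


def read_annotation(path) -> pd.DataFrame:
    """Reference annotation table: protein_id, gene_name, go_terms,
    kog_terms, interpro_terms (';'-joined, GO terms as 'category:term')."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"protein_id", "gene_name", "go_terms", "kog_terms",
                "interpro_terms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df


def _split(labels: str) -> tuple:
    return tuple(t for t in labels.split(";") if t) if labels else ()


def transfer_annotation(clusters: Sequence[IsoformCluster],
                        annotation: pd.DataFrame,
                        hits: pd.DataFrame | None = None
                        ) -> tuple[list[IsoformCluster], pd.DataFrame]:
    """Transfer reference labels onto clusters and tally categories.

    Each cluster inherits the union of the labels of its reference members.
    The gene name comes from the reference member supported by the best
    (lowest-E) hit from the cluster's ORFs (lexicographic fallback when no
    hit table is given).  Returns the annotated clusters and a tally table
    (category, label, count, percentage) over clusters, mirroring a
    GO/KOG/InterPro census.
    """
    ann = annotation.set_index("protein_id")
    best_e: dict[tuple, float] = {}
    if hits is not None and not hits.empty:
        for row in hits.itertuples(index=False):
            key = (row.qseqid, row.sseqid)
            if best_e.get(key, np.inf) > row.evalue:
                best_e[key] = row.evalue

    annotated: list[IsoformCluster] = []
    for cl in clusters:
        go, kog, ipr = set(), set(), set()
        candidates = []              # (best E support, ref id, gene name)
        for ref in sorted(cl.member_reference_ids):
            if ref not in ann.index:
                continue
            rec = ann.loc[ref]
            go.update(_split(rec["go_terms"]))
            kog.update(_split(rec["kog_terms"]))
            ipr.update(_split(rec["interpro_terms"]))
            if rec["gene_name"]:
                support = min((best_e.get((o, ref), np.inf)
                               for o in cl.member_orf_ids), default=np.inf)
                candidates.append((support, ref, rec["gene_name"]))
        name = min(candidates)[2] if candidates else ""
        annotated.append(IsoformCluster(
            cl.cluster_id, cl.member_orf_ids, cl.member_reference_ids,
            name, tuple(sorted(go)), tuple(sorted(kog)), tuple(sorted(ipr))))

    n_clusters = len(annotated)
    counts: dict[tuple[str, str], int] = {}
    for cl in annotated:
        for term in cl.go_terms:
            cat, _, label = term.partition(":")
            counts[(cat, label)] = counts.get((cat, label), 0) + 1
        for label in cl.kog_terms:
            counts[("KOG", label)] = counts.get(("KOG", label), 0) + 1
        for label in cl.interpro_terms:
            counts[("InterPro", label)] = counts.get(("InterPro", label), 0) + 1
    n_unannotated = sum(1 for cl in annotated if not (
        cl.go_terms or cl.kog_terms or cl.interpro_terms or cl.gene_name))
    rows = [{"category": cat, "label": label, "count": c,
             "percentage": round(100.0 * c / n_clusters, 2)}
            for (cat, label), c in sorted(counts.items())]
    rows.append({"category": "summary", "label": "unannotated",
                 "count": n_unannotated,
                 "percentage": round(100.0 * n_unannotated / n_clusters, 2)})
    return annotated, pd.DataFrame(rows,
                                   columns=["category", "label", "count",
                                            "percentage"])


def screen_family(clusters: Sequence[IsoformCluster], hits: pd.DataFrame,
                  family_reference_ids: Iterable,
                  evalue_primary: float = 2e-30,
                  evalue_relaxed: float = 2e-10) -> pd.DataFrame:
    """Screen clusters for a target gene family.

    Clusters containing any of *family_reference_ids* are reported with
    their ORF members qualifying at *evalue_primary*; members qualifying
    only at *evalue_relaxed* appear in a second tier flagged ``relaxed``.
    Returns a table (cluster_id, orf_id, best_evalue, tier).
    """
    fam = set(family_reference_ids)
    if not fam:
        raise ValueError("family_reference_ids must be non-empty")
    best_e: dict[str, float] = {}
    for row in hits.itertuples(index=False):
        if row.sseqid in fam:
            if best_e.get(row.qseqid, np.inf) > row.evalue:
                best_e[row.qseqid] = row.evalue
    rows = []
    for cl in clusters:
        if not (cl.member_reference_ids & fam):
            continue
        for orf in sorted(cl.member_orf_ids):
            e = best_e.get(orf, np.inf)
            if e <= evalue_primary:
                tier = "primary"
            elif e <= evalue_relaxed:
                tier = "relaxed"
            else:
                continue
            rows.append({"cluster_id": cl.cluster_id, "orf_id": orf,
                         "best_evalue": e, "tier": tier})
    return pd.DataFrame(rows, columns=["cluster_id", "orf_id", "best_evalue",
                                       "tier"])


def group_by_reference(best_hit_table: pd.DataFrame) -> dict[str, frozenset]:
    """Alternative grouping keyed by best-hit reference protein (one group
    per matched reference id), complementing the MCL partition."""
    groups: dict[str, set] = {}
    for row in best_hit_table.itertuples(index=False):
        groups.setdefault(row.sseqid, set()).add(row.qseqid)
    return {ref: frozenset(orfs) for ref, orfs in groups.items()}


def write_clusters(clusters: Sequence[IsoformCluster], path) -> None:
    """MCL-native convention: one cluster per line, tab-separated members."""
    with open(path, "w") as fh:
        for cl in clusters:
            fh.write("\t".join(sorted(map(str, cl.members))) + "\n")
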