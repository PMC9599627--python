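"""Ortholog grouping by Markov clustering and cluster-level DE aggregation.

The similarity graph is either supplied as an edge list (e.g. derived from an
all-vs-all search) or built from shared peptide k-mers as a lightweight proxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.sparse.csgraph import connected_components

log = logging.getLogger(__name__)


class ClusteringError(ValueError):
    pass


class SimilarityGraph:
    """Undirected weighted graph over ORF/peptide ids (weights >= 0)."""

    def __init__(self) -> None:
        self.nodes: set[str] = set()
        self.edges: dict[tuple[str, str], float] = {}

    def add_node(self, node: str) -> None:
        self.nodes.add(node)

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if weight < 0:
            raise ClusteringError(f"negative edge weight {weight} on ({a},{b})")
        if a == b:
            return  # self-loops are added at clustering time
        self.nodes.update((a, b))
        key = (a, b) if a < b else (b, a)
        self.edges[key] = weight

    @classmethod
    def from_edge_list(cls, df: pd.DataFrame) -> "SimilarityGraph":
        g = cls()
        for a, b, w in df.itertuples(index=False):
            g.add_edge(str(a), str(b), float(w))
        return g

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            {"orf_a": a, "orf_b": b, "weight": w} for (a, b), w in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["orf_a", "orf_b", "weight"])


def translate_orfs(references: Mapping[str, str]) -> dict[str, str]:
    """Frame-1 peptides (trailing stop removed)."""
    peptides = {}
    for orf_id, seq in references.items():
        aa = str(Seq(seq[: len(seq) - len(seq) % 3]).translate())
        peptides[orf_id] = aa.rstrip("*")
    return peptides


def kmer_similarity_graph(
    peptides: Mapping[str, str], k: int = 4, min_shared: int = 3
) -> SimilarityGraph:
    """Edge weight = number of distinct shared k-mers; weak edges dropped.

    Peptides shorter than ``k`` become isolated nodes.
    """
    g = SimilarityGraph()
    kmer_sets: dict[str, frozenset[str]] = {}
    index: dict[str, list[str]] = {}
    for name in sorted(peptides):
        g.add_node(name)
        seq = peptides[name]
        kmers = frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))
        kmer_sets[name] = kmers
        for km in kmers:
            index.setdefault(km, []).append(name)

    candidate_pairs: set[tuple[str, str]] = set()
    for names in index.values():
        if len(names) < 2:
            continue
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                candidate_pairs.add((names[i], names[j]))
    for a, b in candidate_pairs:
        shared = len(kmer_sets[a] & kmer_sets[b])
        if shared >= min_shared:
            g.add_edge(a, b, float(shared))
    return g


@dataclass
class MclResult:
    clusters: list[list[str]]  # each sorted; list sorted by (-size, first member)
    converged: bool
    n_iterations: int

    def membership(self) -> dict[str, int]:
        return {node: i for i, cl in enumerate(self.clusters) for node in cl}


def mcl(
    graph: SimilarityGraph,
    inflation: float = 1.5,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-5,
) -> MclResult:
    """Markov clustering: alternate expansion (matrix square) and inflation.

    Nodes are sorted before the matrix is built, so the partition is invariant
    to input order. Self-loops of weight equal to the maximum incident edge
    weight are added internally. Non-convergence returns the current partition
    with ``converged=False`` and a warning.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return MclResult(clusters=[], converged=True, n_iterations=0)
    idx = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n))
    for (u, v), w in graph.edges.items():
        a[idx[u], idx[v]] = w
        a[idx[v], idx[u]] = w
    loop = a.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(a, loop)

    m = a / a.sum(axis=0, keepdims=True)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        expanded = m @ m
        inflated = np.power(expanded, inflation)
        inflated[inflated < prune] = 0.0
        col_sums = inflated.sum(axis=0, keepdims=True)
        col_sums[col_sums == 0] = 1.0
        inflated /= col_sums
        change = float(np.abs(inflated - m).max())
        m = inflated
        if change < tol:
            converged = True
            break
    if not converged:
        log.warning("MCL did not converge in %d iterations; returning current partition", max_iter)

    support = (m > 0) | (m.T > 0)
    n_comp, labels = connected_components(support, directed=False)
    clusters: list[list[str]] = [[] for _ in range(n_comp)]
    for v, lab in zip(nodes, labels):
        clusters[lab].append(v)
    clusters = [sorted(c) for c in clusters]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return MclResult(clusters=clusters, converged=converged, n_iterations=it)


@dataclass
class ClusterRecord:
    cluster_id: int
    members: list[str]
    n_members: int
    mean_log2fc: dict[str, float | None] = field(default_factory=dict)  # contrast -> mean
    n_significant: int = 0
    n_untested: int = 0
    function_label: str = ""
    retained: bool = False


def cluster_de(
    clusters: MclResult | list[list[str]],
    de_by_contrast: Mapping[str, pd.DataFrame],
    annotation: pd.DataFrame | None = None,
    min_members: int = 11,
    fc_threshold: float = 2.5,
    alpha: float = 0.05,
) -> list[ClusterRecord]:
    """Cluster-average DE with the published retention filter.

    Retained iff the cluster has more than 10 ORFs (``min_members`` >= 11 by
    default, strict reading of ">10"), at least one member significant in any
    contrast (FDR < ``alpha``), and |mean log2FC| > ``fc_threshold`` in at
    least one contrast. Members without a DE value are excluded from means and
    counted in ``n_untested``.
    """
    member_lists = clusters.clusters if isinstance(clusters, MclResult) else clusters
    de_indexed = {
        contrast: df.drop_duplicates("orf_id").set_index("orf_id")
        for contrast, df in de_by_contrast.items()
    }
    label_of = {}
    if annotation is not None:
        label_of = annotation.set_index("orf_id")["functional_label"].to_dict()

    records: list[ClusterRecord] = []
    for cid, members in enumerate(member_lists):
        rec = ClusterRecord(cluster_id=cid, members=list(members), n_members=len(members))
        sig_orfs: set[str] = set()
        tested_any: set[str] = set()
        for contrast, de in de_indexed.items():
            vals = []
            for orf in members:
                if orf in de.index:
                    tested_any.add(orf)
                    vals.append(float(de.loc[orf, "log2fc"]))
                    if float(de.loc[orf, "fdr"]) < alpha:
                        sig_orfs.add(orf)
            rec.mean_log2fc[contrast] = float(np.mean(vals)) if vals else None
        rec.n_significant = len(sig_orfs)
        rec.n_untested = len([m for m in members if m not in tested_any])
        labels = [label_of.get(m, "") for m in members if label_of.get(m, "")]
        if labels:
            counts = pd.Series(labels).value_counts()
            top = counts[counts == counts.max()].index.tolist()
            rec.function_label = top[0] if len(top) == 1 else "+".join(sorted(top))
        passes_fc = any(
            v is not None and abs(v) > fc_threshold for v in rec.mean_log2fc.values()
        )
        rec.retained = (
            rec.n_members >= min_members and rec.n_significant >= 1 and passes_fc
        )
        records.append(rec)
    return records


def cluster_frame(records: list[ClusterRecord]) -> pd.DataFrame:
    contrasts = sorted({c for r in records for c in r.mean_log2fc})
    rows = []
    for r in records:
        row = {
            "cluster_id": r.cluster_id,
            "n_members": r.n_members,
            "n_significant": r.n_significant,
            "n_untested": r.n_untested,
            "function_label": r.function_label,
            "retained": r.retained,
            "members": ",".join(r.members),
        }
        for c in contrasts:
            v = r.mean_log2fc.get(c)
            row[f"mean_log2fc_{c}"] = np.nan if v is None else v
        rows.append(row)
    return pd.DataFrame(rows)
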