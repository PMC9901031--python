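"""Gene-module discovery from colocalization maps and per-cell proximity graphs.

Two complementary routes:

* **GCC** (global colocalization clustering) clusters the genes of the
  global map: the map is represented as an n x n matrix of -log10(p + 1e-64)
  values and hierarchically clustered (Ward linkage, Euclidean metric on
  rows). Flat clusters whose internal significant-pair density passes a
  threshold are reported as modules.

* **FSM** (frequent subgraph mining) looks for gene networks whose *every*
  edge is a proximal pair in the same cell, in many cells. Because each gene
  appears at most once per cell graph, labeled-subgraph mining reduces
  exactly to frequent itemset mining over per-cell edge sets with a
  connectivity (or clique) constraint; support of an edge set is the number
  of cells containing all its edges. The miner is level-wise with Apriori
  pruning and reports closed frequent edge sets (no superset with equal
  support), so both a frequent clique and its more-frequent individual
  edges surface.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger("proximap")

#: Added to p-values before taking logarithms (handles exact zeros).
LOG_OFFSET = 1e-64

Edge = tuple[str, str]


def _canonical_edge(a: str, b: str) -> Edge:
    return (a, b) if a < b else (b, a)


def build_coloc_matrix(gmap: pd.DataFrame, genes: list[str] | None = None):
    """Symmetric -log10(p + 1e-64) matrix of the global map (diagonal 0)."""
    if genes is None:
        genes = sorted(set(gmap["gene_a"]) | set(gmap["gene_b"]))
    idx = {g: i for i, g in enumerate(genes)}
    mat = np.zeros((len(genes), len(genes)))
    for a, b, p in zip(gmap["gene_a"], gmap["gene_b"], gmap["pvalue"]):
        v = -np.log10(p + LOG_OFFSET)
        mat[idx[a], idx[b]] = v
        mat[idx[b], idx[a]] = v
    return mat, genes


@dataclass
class Module:
    """A gene module with its supporting evidence."""

    module_id: int
    genes: list[str]
    density: float | None = None   # GCC: internal significant-pair fraction
    support: int | None = None     # FSM: number of supporting cells
    edges: list[Edge] = field(default_factory=list)
    region: str | None = None


def gcc_cluster(
    gmap: pd.DataFrame,
    n_clusters: int,
    min_density: float = 0.7,
    alpha: float = 1e-3,
) -> list[Module]:
    """Global colocalization clustering.

    Rows of the -log10 p-value matrix are Ward-clustered and cut into
    ``n_clusters`` flat clusters; clusters of >= 2 genes whose internal
    significant-pair density (fraction of within-cluster pairs with map
    p-value < ``alpha``) reaches ``min_density`` are reported. Module region
    = most frequent primary region among its significant internal pairs.
    """
    genes = sorted(set(gmap["gene_a"]) | set(gmap["gene_b"]))
    if len(genes) < 3:
        raise ValueError("need >= 3 genes for clustering")
    mat, genes = build_coloc_matrix(gmap, genes)
    if not mat.any():
        return []
    with warnings.catch_warnings():
        # Rows of the symmetric map matrix are deliberately treated as
        # observation vectors, not as a pre-computed distance matrix.
        warnings.simplefilter("ignore")
        Z = linkage(mat, method="ward", metric="euclidean")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")

    pval = {
        _canonical_edge(a, b): p
        for a, b, p in zip(gmap["gene_a"], gmap["gene_b"], gmap["pvalue"])
    }
    has_regions = "primary_region" in gmap.columns
    region = (
        {
            _canonical_edge(a, b): r
            for a, b, r in zip(gmap["gene_a"], gmap["gene_b"], gmap["primary_region"])
        }
        if has_regions
        else {}
    )
    modules = []
    for lab in sorted(set(labels)):
        members = [g for g, l in zip(genes, labels) if l == lab]
        if len(members) < 2:
            continue
        pairs = [_canonical_edge(a, b) for a, b in combinations(members, 2)]
        sig = [e for e in pairs if pval.get(e, 1.0) < alpha]
        density = len(sig) / len(pairs)
        if density < min_density:
            continue
        regs = [region[e] for e in sig if region.get(e)]
        dominant = max(sorted(set(regs)), key=regs.count) if regs else None
        modules.append(
            Module(
                module_id=len(modules) + 1,
                genes=members,
                density=density,
                edges=sig,
                region=dominant,
            )
        )
    modules.sort(key=lambda m: (-len(m.genes), m.genes))
    for i, m in enumerate(modules):
        m.module_id = i + 1
    return modules


def cell_graphs_from_pp(
    pp_results: pd.DataFrame, edge_alpha: float = 0.05
) -> dict[object, set[Edge]]:
    """Per-cell colocalization graphs: edges = proximal pairs at ``edge_alpha``.

    The FSM edge threshold is deliberately independent of the indicator
    threshold used for the aggregation tests.
    """
    sig = pp_results[pp_results["pvalue"] < edge_alpha]
    graphs: dict[object, set[Edge]] = {}
    for cell, a, b in zip(sig["cell"], sig["gene_a"], sig["gene_b"]):
        graphs.setdefault(cell, set()).add(_canonical_edge(a, b))
    return graphs


def _edge_set_nodes(edges: frozenset) -> set[str]:
    return {g for e in edges for g in e}


def _is_connected(edges: frozenset) -> bool:
    g = nx.Graph(list(edges))
    return nx.is_connected(g)


def _is_clique(edges: frozenset) -> bool:
    nodes = _edge_set_nodes(edges)
    return len(edges) == len(nodes) * (len(nodes) - 1) // 2


def _frequent_edge_sets(
    transactions: list[frozenset], min_support: int, max_edges: int | None
):
    """Level-wise Apriori over edge itemsets; yields (edge_set, support).

    Transactions are per-cell edge sets; tid-lists are kept as bitmasks so
    support counting is a popcount of an AND.
    """
    tid: dict[Edge, int] = {}
    for c, edges in enumerate(transactions):
        for e in edges:
            tid[e] = tid.get(e, 0) | (1 << c)
    current = {
        frozenset([e]): m for e, m in tid.items() if m.bit_count() >= min_support
    }
    level = 1
    while current:
        for itemset, mask in current.items():
            yield itemset, mask.bit_count()
        if max_edges is not None and level >= max_edges:
            break
        # Apriori join: union pairs of k-sets sharing k-1 edges.
        items = sorted(current, key=lambda s: sorted(s))
        nxt: dict[frozenset, int] = {}
        for a_idx in range(len(items)):
            for b_idx in range(a_idx + 1, len(items)):
                cand = items[a_idx] | items[b_idx]
                if len(cand) != level + 1 or cand in nxt:
                    continue
                # All k-subsets must be frequent (Apriori pruning).
                if any(cand - {e} not in current for e in cand):
                    continue
                mask = current[items[a_idx]] & current[items[b_idx]]
                if mask.bit_count() >= min_support:
                    nxt[cand] = mask
        current = nxt
        level += 1


def fsm_mine(
    graphs: dict[object, set[Edge]] | list[set],
    min_nodes: int = 3,
    min_support: int = 1,
    clique_only: bool = False,
    max_edges: int | None = None,
    closed_only: bool = True,
) -> list[Module]:
    """Mine frequently co-occurring gene networks across cells.

    Finds edge sets supported by (contained in) at least ``min_support``
    per-cell graphs, keeps those forming a connected graph (a clique when
    ``clique_only``) on at least ``min_nodes`` genes, and by default reports
    the closed ones (no frequent superset has the same support);
    ``closed_only=False`` reports every qualifying frequent edge set.
    Sorted by support descending, then size, then gene names.
    """
    if min_nodes < 2:
        raise ValueError("min_nodes must be >= 2")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    transactions = [
        frozenset(edges)
        for edges in (graphs.values() if isinstance(graphs, dict) else graphs)
    ]
    if min_support > len(transactions):
        return []
    found = dict(_frequent_edge_sets(transactions, min_support, max_edges))

    kept = []
    for edges, support in found.items():
        nodes = _edge_set_nodes(edges)
        if len(nodes) < min_nodes:
            continue
        if clique_only:
            if not _is_clique(edges):
                continue
        elif not _is_connected(edges):
            continue
        kept.append((edges, support))

    # Closed-set filter: drop results having a found superset of equal support.
    closed = kept
    if closed_only:
        closed = [
            (edges, support)
            for edges, support in kept
            if not any(
                edges < other and support == osup for other, osup in found.items()
            )
        ]

    closed.sort(key=lambda es: (-es[1], -len(_edge_set_nodes(es[0])),
                                sorted(_edge_set_nodes(es[0]))))
    return [
        Module(
            module_id=i + 1,
            genes=sorted(_edge_set_nodes(edges)),
            support=support,
            edges=sorted(edges),
        )
        for i, (edges, support) in enumerate(closed)
    ]


def support_histogram(
    graphs: dict[object, set[Edge]] | list[set], k: int
) -> dict[frozenset, int]:
    """Support (number of cells) of every k-gene clique occurring in >= 1 cell.

    Cliques are enumerated per cell from its maximal cliques, so the scan
    stays cheap on sparse graphs.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts: dict[frozenset, int] = {}
    edge_iter = graphs.values() if isinstance(graphs, dict) else graphs
    for edges in edge_iter:
        if not edges:
            continue
        g = nx.Graph(list(edges))
        seen: set[frozenset] = set()
        for maximal in nx.find_cliques(g):
            if len(maximal) < k:
                continue
            for sub in combinations(sorted(maximal), k):
                seen.add(frozenset(sub))
        for clique in seen:
            counts[clique] = counts.get(clique, 0) + 1
    return counts
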