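"""Cell-type specificity and tissue-level spatial modulation of d-colocalized pairs.

Cell-type specificity asks whether the cells supporting a pair's
colocalization (set O) are enriched in one cell type (set M) within the set
U of all cells — an ordinary hypergeometric tail — and, when they are,
whether the enrichment goes beyond what either gene's expression specificity
explains. The latter is a conditional test: the overlap |M ∩ O'| of M with a
random set O' of size |O| is examined conditional on the observed overlaps
with E, the set of highest-expression cells of one gene (|E| forced to |M|).
With gamma = |M ∩ E|, alpha = |E ∩ O| and lambda = |M ∩ O| the conditional
upper tail is a double sum of multivariate-hypergeometric terms over the
four blocks (M ∩ E, M \\ E, E \\ M, rest).

Spatial modulation asks whether the supporting cells are non-randomly
placed in the tissue. On a fixed-radius neighbor graph of cell centroids,
the per-cell support indicator s_c is modelled as Bernoulli; under H0 the
rate is a global constant, under H1 it is w * p_local_c + (1 - w) * p_global
where p_local_c is the supporting fraction among c's neighbors. The
log-likelihood ratio at the maximum-likelihood parameters scores the pair;
the significance threshold is the highest LLR observed on label-permuted
data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.stats import hypergeom

from .proximal_pairs import IndicatorMatrix

logger = logging.getLogger("proximap")

_EPS = 1e-9


# ---------------------------------------------------------------------------
# Cell-type specificity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SetAssocInstance:
    """Counts for the conditional set-association test.

    U is the universe of cells, M the cells of one type, O the cells where
    the pair is a proximal pair, E the high-expression cells of one gene
    (|E| = |M| by construction).
    """

    U_size: int
    M_size: int
    E_size: int
    O_size: int
    gamma: int  # |M ∩ E|
    lam: int    # |M ∩ O|
    alpha: int  # |E ∩ O|

    def validate(self) -> None:
        checks = [
            (0 <= self.gamma <= min(self.M_size, self.E_size), "0 <= gamma <= min(|M|,|E|)"),
            (0 <= self.lam <= min(self.M_size, self.O_size), "0 <= lambda <= min(|M|,|O|)"),
            (0 <= self.alpha <= min(self.E_size, self.O_size), "0 <= alpha <= min(|E|,|O|)"),
            (max(self.M_size, self.E_size, self.O_size) <= self.U_size, "|M|,|E|,|O| <= |U|"),
            (self.O_size - self.alpha <= self.U_size - self.E_size, "|O|-alpha <= |U|-|E|"),
        ]
        for ok, rule in checks:
            if not ok:
                raise ValueError(f"inconsistent counts: violated {rule}")


def _comb(n: int, k: int) -> int:
    if k < 0 or n < 0 or k > n:
        return 0
    return math.comb(n, k)


def conditional_hypergeom_pvalue(inst: SetAssocInstance) -> float:
    """P(|M ∩ O'| >= lambda) for a random O' of size |O| with |O' ∩ E| = alpha.

    Exact double sum over k (the overlap with M) and beta (its part inside
    M ∩ E), evaluated in exact integer arithmetic. Reduces to the ordinary
    hypergeometric tail of M versus O' on U \\ E when gamma = alpha = 0.
    """
    inst.validate()
    U, M, E, O = inst.U_size, inst.M_size, inst.E_size, inst.O_size
    g, lam, a = inst.gamma, inst.lam, inst.alpha
    if lam <= 0:
        return 1.0
    rest = U - M - E + g
    denom = _comb(E, a) * _comb(U - E, O - a)
    if denom == 0:
        raise ValueError("inconsistent counts: conditioning event has zero probability")
    num = 0
    for k in range(lam, min(M, O) + 1):
        for beta in range(0, k + 1):
            num += (
                _comb(g, beta)
                * _comb(M - g, k - beta)
                * _comb(E - g, a - beta)
                * _comb(rest, O - a - k + beta)
            )
    return float(Fraction(num, denom))


def celltype_association(
    ind: IndicatorMatrix, meta: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Hypergeometric association of each gene pair with each cell type.

    For pair p and type t: U = all cells, M = cells of type t, O = cells
    where p is a significant proximal pair; the upper-tail p-value of
    |M ∩ O| is Bonferroni-corrected over pairs x types. Only pairs with
    support > 0 are tested. Every cell must carry a type label.
    """
    meta = meta.set_index("cell_id")
    try:
        types_by_cell = meta.loc[ind.cells, "cell_type"]
    except KeyError as exc:
        raise ValueError(f"metadata missing cells: {exc}") from exc
    if types_by_cell.isna().any():
        raise ValueError("every cell must have a cell_type label")
    type_masks = {
        t: (types_by_cell == t).to_numpy() for t in sorted(types_by_cell.unique())
    }
    U = ind.n_cells
    support = ind.X.sum(axis=1)
    pair_list = list(ind.pairs())
    n_tests = int((support > 0).sum()) * len(type_masks)
    rows = []
    for k, (a, b) in enumerate(pair_list):
        if support[k] == 0:
            continue
        o_mask = ind.X[k].astype(bool)
        O = int(o_mask.sum())
        for t, m_mask in type_masks.items():
            M = int(m_mask.sum())
            lam = int((o_mask & m_mask).sum())
            p = float(hypergeom.sf(lam - 1, U, M, O)) if lam > 0 else 1.0
            rows.append(
                {
                    "gene_a": a,
                    "gene_b": b,
                    "cell_type": t,
                    "overlap": lam,
                    "n_type": M,
                    "n_support": O,
                    "pvalue": p,
                    "pvalue_bonf": min(1.0, p * n_tests),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_a", "gene_b", "cell_type", "overlap", "n_type",
            "n_support", "pvalue", "pvalue_bonf",
        ],
    )
    if len(out):
        out["significant"] = out["pvalue_bonf"] < alpha
    else:
        out["significant"] = pd.Series(dtype=bool)
    return out


def gene_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell per-gene transcript counts (summed over z-planes)."""
    return table.groupby(["cell", "gene"]).size().unstack(fill_value=0)


def high_expression_cells(
    counts: pd.DataFrame, gene: str, size: int
) -> list:
    """The ``size`` cells with highest counts of ``gene`` (ties by cell id)."""
    sub = counts[gene] if gene in counts.columns else pd.Series(0, index=counts.index)
    order = sorted(counts.index, key=lambda c: (-sub.loc[c], str(c)))
    return order[:size]


def find_markers(
    table: pd.DataFrame, meta: pd.DataFrame, top_k: int = 10
) -> dict[str, list[str]]:
    """Marker genes per cell type: the ``top_k`` genes whose high-expression
    cell set E (|E| = |M|, cells ranked by that gene's count) overlaps the
    type's cells M most significantly (hypergeometric tail). All-zero genes
    are excluded.
    """
    counts = gene_counts(table)
    meta = meta.set_index("cell_id")
    counts = counts.loc[[c for c in counts.index if c in meta.index]]
    types = meta.loc[counts.index, "cell_type"]
    U = len(counts)
    markers: dict[str, list[str]] = {}
    active = [g for g in counts.columns if counts[g].sum() > 0]
    for t in sorted(types.unique()):
        m_cells = set(counts.index[types == t])
        M = len(m_cells)
        scored = []
        for g in active:
            e_cells = high_expression_cells(counts, g, M)
            gamma = len(m_cells.intersection(e_cells))
            p = float(hypergeom.sf(gamma - 1, U, M, M)) if gamma > 0 else 1.0
            scored.append((p, g))
        scored.sort(key=lambda pg: (pg[0], pg[1]))
        markers[t] = [g for _, g in scored[: max(top_k, 0)]]
    return markers


def categorize_pair(
    pair: tuple[str, str],
    ind: IndicatorMatrix,
    meta: pd.DataFrame,
    counts: pd.DataFrame,
    markers: dict[str, list[str]],
    assoc: pd.DataFrame,
    alpha: float = 0.05,
    swap_category_labels: bool = False,
) -> tuple[int, str | None]:
    """Classify a d-colocalized pair's cell-type specificity.

    Category 3: not associated with any type. Category 2: associated with a
    type, the association survives conditioning on the high-expression cells
    of *each* gene, and neither gene is a marker of that type — i.e. the
    specificity goes beyond either gene's expression. Category 1: associated
    but explainable by expression or marker status. ``swap_category_labels``
    exchanges the 1/2 labels for compatibility with the alternative naming.

    Returns ``(category, associated_type)``; the type is the most
    significantly associated one (None for category 3).
    """
    a, b = pair
    sub = assoc[
        (assoc["gene_a"] == a) & (assoc["gene_b"] == b) & assoc["significant"]
    ]
    if sub.empty:
        return 3, None
    best = sub.sort_values(["pvalue_bonf", "cell_type"], kind="mergesort").iloc[0]
    t = best["cell_type"]

    meta_idx = meta.set_index("cell_id")
    types = meta_idx.loc[ind.cells, "cell_type"].to_numpy()
    m_mask = types == t
    o_mask = ind.X[ind.pair_index(a, b)].astype(bool)
    cells = np.asarray(ind.cells, dtype=object)
    M = int(m_mask.sum())
    conditional_ok = True
    for gene in (a, b):
        e_cells = set(high_expression_cells(counts.loc[list(cells)], gene, M))
        e_mask = np.array([c in e_cells for c in cells])
        inst = SetAssocInstance(
            U_size=len(cells),
            M_size=M,
            E_size=int(e_mask.sum()),
            O_size=int(o_mask.sum()),
            gamma=int((m_mask & e_mask).sum()),
            lam=int((m_mask & o_mask).sum()),
            alpha=int((e_mask & o_mask).sum()),
        )
        if conditional_hypergeom_pvalue(inst) >= alpha:
            conditional_ok = False
            break
    is_marker = a in markers.get(t, []) or b in markers.get(t, [])
    stringent = conditional_ok and not is_marker
    category = 2 if stringent else 1
    if swap_category_labels:
        category = 3 - category
    return category, t


def categorize_map(
    gmap: pd.DataFrame,
    ind: IndicatorMatrix,
    table: pd.DataFrame,
    meta: pd.DataFrame,
    alpha_map: float = 1e-3,
    alpha: float = 0.05,
    top_k_markers: int = 10,
    swap_category_labels: bool = False,
) -> pd.DataFrame:
    """Categorize every d-colocalized pair (map p-value < ``alpha_map``)."""
    markers = find_markers(table, meta, top_k=top_k_markers)
    counts = gene_counts(table)
    assoc = celltype_association(ind, meta, alpha=alpha)
    sig = gmap[gmap["pvalue"] < alpha_map]
    rows = []
    for a, b in zip(sig["gene_a"], sig["gene_b"]):
        cat, t = categorize_pair(
            (a, b), ind, meta, counts, markers, assoc,
            alpha=alpha, swap_category_labels=swap_category_labels,
        )
        rows.append({"gene_a": a, "gene_b": b, "category": cat, "cell_type": t})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "category", "cell_type"])


# ---------------------------------------------------------------------------
# Spatial modulation
# ---------------------------------------------------------------------------

class NeighborGraph:
    """Fixed-radius adjacency over cell centroids (symmetric, no self-edges)."""

    def __init__(self, cells: list, centroids: np.ndarray, radius: float):
        self.cells = list(cells)
        self.centroids = np.asarray(centroids, dtype=float)
        self.radius = float(radius)
        n = len(self.cells)
        neighbors: list[list[int]] = [[] for _ in range(n)]
        if radius > 0 and n > 1:
            pairs = cKDTree(self.centroids).query_pairs(radius, output_type="ndarray")
            for i, j in pairs:
                neighbors[i].append(j)
                neighbors[j].append(i)
        self.neighbors = [np.array(sorted(nb), dtype=int) for nb in neighbors]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def degree(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=int)


def build_neighbor_graph(meta: pd.DataFrame, radius: float = 100.0) -> NeighborGraph:
    """Neighbor graph of cells whose centroids lie within ``radius`` μm."""
    if not {"centroid_x", "centroid_y"} <= set(meta.columns):
        raise ValueError("metadata must provide centroid_x and centroid_y")
    return NeighborGraph(
        list(meta["cell_id"]),
        meta[["centroid_x", "centroid_y"]].to_numpy(dtype=float),
        radius,
    )


@dataclass
class SpatialModel:
    """Fitted spatial-modulation model for one binary support vector."""

    llr: float
    w: float
    p_global: float
    p_global_h0: float
    p_local: np.ndarray


def _bernoulli_loglik(s: np.ndarray, q: np.ndarray) -> float:
    q = np.clip(q, _EPS, 1.0 - _EPS)
    return float(np.sum(s * np.log(q) + (1 - s) * np.log1p(-q)))


def spatial_modulation_llr(s: np.ndarray, graph: NeighborGraph) -> SpatialModel:
    """Log-likelihood ratio of the neighbor-weighted model over the global one.

    H0: s_c ~ Ber(p_global) with p_global at its MLE (the support fraction).
    H1: s_c ~ Ber(w * p_local_c + (1 - w) * p_global) with p_local_c the
    supporting fraction among c's neighbors; cells without neighbors use
    p_global in place of p_local. (w, p_global) are fitted by bounded
    maximum likelihood from four multistarts, and the H0 solution (w = 0) is
    always included as a candidate, so llr >= 0. A constant s gives llr 0.
    """
    s = np.asarray(s, dtype=float)
    if len(s) != graph.n_cells:
        raise ValueError("support vector length must match the graph")
    p0 = float(s.mean())
    if p0 in (0.0, 1.0):
        return SpatialModel(0.0, 0.0, p0, p0, np.full(len(s), p0))

    p_local = np.empty(len(s))
    no_nb = np.zeros(len(s), dtype=bool)
    for c, nb in enumerate(graph.neighbors):
        if len(nb) == 0:
            no_nb[c] = True
            p_local[c] = 0.0  # replaced by p_global inside the likelihood
        else:
            p_local[c] = s[nb].mean()

    def success_prob(w, pg):
        q = w * p_local + (1.0 - w) * pg
        if no_nb.any():
            q = np.where(no_nb, pg, q)
        return q

    def negloglik(theta):
        w, pg = theta
        return -_bernoulli_loglik(s, success_prob(w, pg))

    ll0 = _bernoulli_loglik(s, np.full(len(s), p0))
    best = (ll0, 0.0, p0)  # (loglik, w, pg): H0 is a candidate
    bounds = [(0.0, 1.0), (_EPS, 1.0 - _EPS)]
    for w0 in (0.1, 0.9):
        for pg0 in (0.1, 0.9):
            res = minimize(
                negloglik, x0=[w0, pg0], method="L-BFGS-B", bounds=bounds
            )
            if -res.fun > best[0]:
                best = (-res.fun, float(res.x[0]), float(res.x[1]))
    ll1, w_hat, pg_hat = best
    return SpatialModel(max(0.0, ll1 - ll0), w_hat, pg_hat, p0, p_local)


def spatial_modulation_scan(
    ind: IndicatorMatrix,
    gmap: pd.DataFrame,
    graph: NeighborGraph,
    n_perm: int = 10,
    seed: int = 0,
    alpha_map: float = 1e-3,
    assoc: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Scan d-colocalized pairs for tissue-level spatial modulation.

    Each pair's per-cell support vector s is scored by
    :func:`spatial_modulation_llr`. The detection threshold is the highest
    LLR seen over ``n_perm`` independent full permutations of each pair's s
    vector (destroying spatial structure while preserving the support
    count); pairs scoring strictly above it are flagged. When a cell-type
    association table is supplied, flagged pairs carry their best-associated
    type. Deterministic under a fixed seed.
    """
    if not set(graph.cells) >= set(ind.cells):
        raise ValueError("neighbor graph must cover all indicator cells")
    cell_pos = {c: i for i, c in enumerate(graph.cells)}
    order = np.array([cell_pos[c] for c in ind.cells], dtype=int)
    sub_graph = graph
    if len(graph.cells) != len(ind.cells) or (order != np.arange(len(order))).any():
        sub_graph = NeighborGraph(
            list(ind.cells), graph.centroids[order], graph.radius
        )

    sig = gmap[gmap["pvalue"] < alpha_map]
    rng = np.random.default_rng(seed)
    rows = []
    vectors = {}
    for a, b in zip(sig["gene_a"], sig["gene_b"]):
        s = ind.X[ind.pair_index(a, b)].astype(float)
        vectors[(a, b)] = s
        model = spatial_modulation_llr(s, sub_graph)
        rows.append(
            {"gene_a": a, "gene_b": b, "llr": model.llr, "w": model.w,
             "support_rate": model.p_global_h0}
        )
    threshold = 0.0
    for _ in range(n_perm):
        for s in vectors.values():
            perm = spatial_modulation_llr(rng.permutation(s), sub_graph)
            threshold = max(threshold, perm.llr)
    out = pd.DataFrame(rows, columns=["gene_a", "gene_b", "llr", "w", "support_rate"])
    out["threshold"] = threshold
    out["flagged"] = out["llr"] > threshold if len(out) else pd.Series(dtype=bool)
    if assoc is not None and len(out):
        best_type = []
        for a, b in zip(out["gene_a"], out["gene_b"]):
            sub = assoc[
                (assoc["gene_a"] == a) & (assoc["gene_b"] == b) & assoc["significant"]
            ]
            if sub.empty:
                best_type.append(None)
            else:
                best_type.append(
                    sub.sort_values(["pvalue_bonf", "cell_type"]).iloc[0]["cell_type"]
                )
        out["cell_type"] = best_type
    return out
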