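"""Per-cell Proximal Pair (PP) test.

For each cell, the PP test asks whether transcripts of a gene pair
(g_i, g_j) lie within distance ``d`` of each other more often than expected
from the cell's overall spatial texture. The null probability ``p`` is the
fraction of *all* unordered transcript pairs in the cell (gene identities
ignored) separated by at most ``d``. With t_i, t_j the transcript counts of
the two genes, T = t_i * t_j cross-gene transcript pairs are possible and K
of them are proximal; the p-value is the exact binomial upper tail
P(X >= K | T, p).

The multi-plane (3D) variant treats z-planes as independent samples of the
same cell: per-plane statistics are pooled as p = sum_z l_z p_z / sum_z l_z
(l_z = transcripts in plane z), T = sum_z T_z, K = sum_z K_z, and pairs are
never formed across planes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import binom

from .io import REGIONS

logger = logging.getLogger("proximap")

_REGION_PRIORITY = {r: i for i, r in enumerate(REGIONS)}  # Nuc > PN > Cyt > CP


class UndefinedNullError(ValueError):
    """The cell has too few transcripts to estimate a null proximity rate."""


@dataclass(frozen=True)
class PPConfig:
    """Parameters of the PP test.

    ``d`` is the proximity scale in micrometres; a useful starting point is
    ~5% of a typical cell diameter. ``mode`` selects the
    single-plane (``"2d"``) or pooled multi-plane (``"3d"``) test.
    ``nucleus_only`` restricts both the pair counting and the null estimate
    to transcripts located inside the nucleus.
    """

    d: float
    mode: str = "2d"
    nucleus_only: bool = False
    alpha_pp: float = 0.01
    min_transcripts: int = 2

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("d must be > 0")
        if not 0 < self.alpha_pp < 1:
            raise ValueError("alpha_pp must be in (0, 1)")
        if self.mode not in ("2d", "3d"):
            raise ValueError("mode must be '2d' or '3d'")


def estimate_null_prob(coords: np.ndarray, d: float) -> float:
    """Fraction of unordered transcript pairs within distance ``d``.

    All distinct transcript pairs count, regardless of gene identity
    (same-gene pairs included; a transcript is never paired with itself).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise UndefinedNullError("need >= 2 transcripts to estimate null probability")
    tree = cKDTree(coords)
    n_prox = len(tree.query_pairs(d, output_type="ndarray"))
    return n_prox / (n * (n - 1) // 2)


def count_pair_proximity(
    coords: np.ndarray,
    genes: np.ndarray,
    d: float,
    regions: np.ndarray | None = None,
    brute_force: bool = False,
):
    """Count proximal cross-gene transcript pairs for every gene pair.

    Returns ``(pairs, tallies)`` where ``pairs`` maps each unordered gene
    pair ``(a, b)`` (a < b, both expressed) to ``(K, T)`` and ``tallies``
    maps it to per-region proximal-pair counts (empty dict when ``regions``
    is None). Each cross-gene transcript pair is counted once, so K <= T.

    ``brute_force`` switches to an all-pairs scan; it must give identical
    results to the spatial-index path and exists as an oracle.
    """
    coords = np.asarray(coords, dtype=float)
    genes = np.asarray(genes, dtype=object)
    n = len(coords)
    if n < 1:
        raise ValueError("need >= 1 transcript")

    if brute_force:
        prox_pairs = [
            (i, j)
            for i, j in combinations(range(n), 2)
            if np.hypot(*(coords[i] - coords[j])) <= d
        ]
        idx = np.array(prox_pairs, dtype=int).reshape(-1, 2)
    else:
        idx = cKDTree(coords).query_pairs(d, output_type="ndarray")

    uniq, counts = np.unique(genes, return_counts=True)
    t_counts = dict(zip(uniq, counts))

    K: dict[tuple, int] = {}
    tallies: dict[tuple, dict] = {}
    ga, gb = genes[idx[:, 0]], genes[idx[:, 1]]
    cross = ga != gb
    for i0, i1 in idx[cross]:
        a, b = genes[i0], genes[i1]
        key = (a, b) if a < b else (b, a)
        K[key] = K.get(key, 0) + 1
        if regions is not None:
            r0, r1 = regions[i0], regions[i1]
            reg = r0 if r0 == r1 else min(r0, r1, key=_REGION_PRIORITY.__getitem__)
            tal = tallies.setdefault(key, dict.fromkeys(REGIONS, 0))
            tal[reg] += 1

    pairs = {}
    for a, b in combinations(sorted(uniq), 2):
        pairs[(a, b)] = (K.get((a, b), 0), t_counts[a] * t_counts[b])
        if regions is not None:
            tallies.setdefault((a, b), dict.fromkeys(REGIONS, 0))
    return pairs, tallies


def _binom_sf(K: int, T: int, p: float) -> float:
    """Exact upper-tail P(X >= K | T, p) with the degenerate conventions."""
    if K <= 0:
        return 1.0
    if p <= 0.0:
        logger.warning("proximal pairs observed under a zero null probability")
        return 0.0
    if T <= 0:
        return 1.0
    return float(binom.sf(K - 1, T, p))


def pp_test_cell(cell: pd.DataFrame, cfg: PPConfig) -> pd.DataFrame:
    """Run the PP test on one cell's transcripts.

    Returns a long-format frame with one row per expressed gene pair:
    ``gene_a, gene_b, K, T, p_null, pvalue`` plus per-region proximal-pair
    tallies (``n_nuc, n_pn, n_cyt, n_cp``) when regions are assigned.

    In 3D mode, planes with fewer than two transcripts contribute nothing;
    if every plane is skipped an :class:`UndefinedNullError` is raised.
    """
    if cfg.nucleus_only:
        if "in_nucleus" not in cell.columns:
            raise ValueError("nucleus_only requires region-assigned transcripts")
        cell = cell[cell["in_nucleus"]]
    if len(cell) < max(cfg.min_transcripts, 2):
        raise UndefinedNullError("cell has too few transcripts for the PP test")

    has_regions = "region" in cell.columns
    coords_all = cell[["x", "y"]].to_numpy(dtype=float)
    genes_all = cell["gene"].to_numpy(dtype=object)
    regions_all = cell["region"].to_numpy(dtype=object) if has_regions else None

    if cfg.mode == "2d":
        plane_slices = [np.arange(len(cell))]
    else:
        z = cell["z"].to_numpy()
        plane_slices = [np.flatnonzero(z == zi) for zi in np.unique(z)]

    # Pool per-plane statistics; in 2D there is a single "plane".
    num_p, den_l = 0.0, 0
    K_tot: dict[tuple, int] = {}
    T_tot: dict[tuple, int] = {}
    tal_tot: dict[tuple, dict] = {}
    any_plane = False
    for sl in plane_slices:
        if len(sl) < 2:
            continue
        any_plane = True
        l_z = len(sl)
        p_z = estimate_null_prob(coords_all[sl], cfg.d)
        num_p += l_z * p_z
        den_l += l_z
        pairs, tallies = count_pair_proximity(
            coords_all[sl],
            genes_all[sl],
            cfg.d,
            regions_all[sl] if has_regions else None,
        )
        for key, (K, T) in pairs.items():
            K_tot[key] = K_tot.get(key, 0) + K
            T_tot[key] = T_tot.get(key, 0) + T
            if has_regions:
                tal = tal_tot.setdefault(key, dict.fromkeys(REGIONS, 0))
                for r in REGIONS:
                    tal[r] += tallies[key][r]
    if not any_plane:
        raise UndefinedNullError("no z-plane with >= 2 transcripts")
    p_null = num_p / den_l

    # Every gene pair co-expressed in the cell gets a row, even when the two
    # genes never share a plane (T = 0 -> p-value 1).
    expressed = sorted(set(genes_all))
    rows = []
    for a, b in combinations(expressed, 2):
        K = K_tot.get((a, b), 0)
        T = T_tot.get((a, b), 0)
        row = {
            "gene_a": a,
            "gene_b": b,
            "K": K,
            "T": T,
            "p_null": p_null,
            "pvalue": _binom_sf(K, T, p_null),
        }
        if has_regions:
            tal = tal_tot.get((a, b), dict.fromkeys(REGIONS, 0))
            row.update(n_nuc=tal["Nuc"], n_pn=tal["PN"], n_cyt=tal["Cyt"], n_cp=tal["CP"])
        rows.append(row)
    return pd.DataFrame(rows)


class IndicatorMatrix:
    """Binary proximal-pair indicators X_ij^c over gene pairs x cells.

    ``X[p, c] = 1`` when gene pair ``p`` (unordered, i < j over ``genes``)
    was significant in cell ``c`` at the PP threshold; ``E[g, c] = 1`` when
    gene ``g`` is expressed (>= 1 transcript) in cell ``c``. ``N_c`` is the
    per-cell count of significant pairs.
    """

    def __init__(self, genes: list[str], cells: list, X: np.ndarray, E: np.ndarray):
        self.genes = list(genes)
        self.cells = list(cells)
        self.X = np.asarray(X, dtype=np.uint8)
        self.E = np.asarray(E, dtype=bool)
        n = len(self.genes)
        self._pair_idx = {
            pair: k for k, pair in enumerate(combinations(range(n), 2))
        }
        if self.X.shape != (len(self._pair_idx), len(self.cells)):
            raise ValueError("X has wrong shape")
        if self.E.shape != (n, len(self.cells)):
            raise ValueError("E has wrong shape")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def N_c(self) -> np.ndarray:
        """Per-cell number of significant proximal pairs."""
        return self.X.sum(axis=0).astype(int)

    def pairs(self) -> Iterator[tuple[str, str]]:
        for i, j in combinations(range(self.n_genes), 2):
            yield self.genes[i], self.genes[j]

    def pair_index(self, gene_a: str, gene_b: str) -> int:
        i, j = self.genes.index(gene_a), self.genes.index(gene_b)
        if i > j:
            i, j = j, i
        return self._pair_idx[(i, j)]

    def both_expressed(self, gene_a: str, gene_b: str) -> np.ndarray:
        """Boolean mask over cells where both genes are expressed."""
        i, j = self.genes.index(gene_a), self.genes.index(gene_b)
        return self.E[i] & self.E[j]

    def expressed_pairs_per_cell(self) -> np.ndarray:
        """Number of gene pairs with both genes expressed, per cell."""
        e = self.E.sum(axis=0).astype(int)
        return e * (e - 1) // 2

    def to_frame(self) -> pd.DataFrame:
        """Long-format (gene_a, gene_b, cell, X) rows for significant pairs."""
        rows = []
        pair_list = list(self.pairs())
        for k, c in zip(*np.nonzero(self.X)):
            a, b = pair_list[k]
            rows.append({"gene_a": a, "gene_b": b, "cell": self.cells[c], "X": 1})
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "cell", "X"])


def pp_test_dataset(
    table: pd.DataFrame, cfg: PPConfig, genes: list[str] | None = None
) -> tuple[IndicatorMatrix, pd.DataFrame]:
    """Run the PP test on every cell and binarize at ``cfg.alpha_pp``.

    Returns the indicator matrix and the long-format per-cell results.
    Cells failing the preconditions (too few transcripts, or no usable
    z-plane) are excluded from the matrix and counted in the log.
    """
    if genes is None:
        genes = sorted(table["gene"].unique()) if len(table) else []
    gene_idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    pair_idx = {p: k for k, p in enumerate(combinations(range(n), 2))}

    x_cols, e_cols = [], []
    frames = []
    kept_cells = []
    n_skipped = 0
    for cid, cell_df in table.groupby("cell", sort=False):
        try:
            res = pp_test_cell(cell_df, cfg)
        except UndefinedNullError:
            n_skipped += 1
            continue
        kept_cells.append(cid)
        e_col = np.zeros(n, dtype=bool)
        for g in cell_df["gene"].unique():
            if g in gene_idx:
                e_col[gene_idx[g]] = True
        e_cols.append(e_col)
        x_col = np.zeros(len(pair_idx), dtype=np.uint8)
        sig = res[res["pvalue"] < cfg.alpha_pp]
        for a, b in zip(sig["gene_a"], sig["gene_b"]):
            i, j = gene_idx[a], gene_idx[b]
            x_col[pair_idx[(min(i, j), max(i, j))]] = 1
        x_cols.append(x_col)
        res.insert(0, "cell", cid)
        frames.append(res)
    if n_skipped:
        logger.info("pp_test_dataset: skipped %d cells (undefined null)", n_skipped)
    X = (
        np.stack(x_cols, axis=1)
        if x_cols
        else np.zeros((len(pair_idx), 0), dtype=np.uint8)
    )
    E = np.stack(e_cols, axis=1) if e_cols else np.zeros((n, 0), dtype=bool)
    results = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["cell", "gene_a", "gene_b", "K", "T", "p_null", "pvalue"])
    )
    return IndicatorMatrix(genes, kept_cells, X, E), results
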