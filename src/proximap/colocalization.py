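"""Aggregation of per-cell proximal-pair indicators into d-colocalization maps.

A gene pair is *d-colocalized* when it is a significant proximal pair in
significantly many cells. The number of supporting cells is modelled as a
Poisson-Binomial sum of per-cell Bernoulli indicators. Two variants:

* **UPB** (unconditional): every expressed pair in cell c shares the same
  success probability p_0^c = N_c / (#expressed pairs in c).
* **CPB** (conditional): the success probability is gene-pair dependent.
  With z_i the total number of proximal pairs involving gene i across all
  cells, the prior that a detected proximal pair is (g_i, g_j) is
  Pi_ij = z_i z_j / sum_{i<j} z_i z_j, and
  p_ij^c = 1 - (1 - Pi_ij)^{N_c}. This de-emphasizes pairs of genes that
  are promiscuously proximal across the dataset.

The convolution runs over all cells, including cells where one of the
genes is unexpressed (their modelled success probability is still positive
whenever the cell has proximal pairs, although the indicator can never fire
there). This keeps the test deliberately conservative for sparsely
co-expressed pairs; see the methods note for the discussion.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import binom, false_discovery_control, hypergeom, norm

from .io import REGIONS
from .proximal_pairs import IndicatorMatrix

logger = logging.getLogger("proximap")

#: Smallest reportable p-value in map outputs.
PVALUE_FLOOR = 1e-300


def poisson_binomial_sf(probs: Iterable[float], k: int) -> float:
    """Exact upper tail P(sum_c Bernoulli(p_c) >= k).

    Computed by dynamic-programming convolution of the probability mass
    function; all intermediate quantities stay in [0, 1] and the tail is
    accumulated with compensated summation, so the result is accurate down
    to the underflow limit. ``k <= 0`` gives 1.0, ``k > len(probs)`` gives 0.
    """
    probs = np.asarray(list(probs), dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    m = len(probs)
    if k <= 0:
        return 1.0
    if k > m:
        return 0.0
    pmf = np.zeros(m + 1)
    pmf[0] = 1.0
    for i, p in enumerate(probs):
        pmf[1 : i + 2] = pmf[1 : i + 2] * (1.0 - p) + pmf[: i + 1] * p
        pmf[0] *= 1.0 - p
    return float(min(1.0, math.fsum(pmf[k:])))


def _pair_pvalues(ind: IndicatorMatrix, probs_for_pair) -> pd.DataFrame:
    """Shared UPB/CPB driver: convolve per-cell probabilities per pair.

    The convolution includes every cell; ``n_cells`` reports how many cells
    co-express the pair (where the indicator could actually fire).
    """
    support = ind.X.sum(axis=1).astype(int)
    rows = []
    for k, (a, b) in enumerate(ind.pairs()):
        n_co = int(ind.both_expressed(a, b).sum())
        if n_co == 0 and support[k] == 0:
            pval = 1.0
        else:
            pval = poisson_binomial_sf(probs_for_pair(k), int(support[k]))
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "support": int(support[k]),
                "n_cells": n_co,
                "pvalue": max(pval, PVALUE_FLOOR),
            }
        )
    return pd.DataFrame(rows)


def upb_test(ind: IndicatorMatrix) -> pd.DataFrame:
    """Unconditional Poisson-Binomial test.

    Per cell, p_0^c is the fraction of expressed gene pairs that are
    significant proximal pairs; a pair's p-value convolves p_0^c over all
    cells (0 for cells with no expressed pair), at k = its support.
    """
    n_pairs_cell = ind.expressed_pairs_per_cell()
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = np.where(n_pairs_cell > 0, ind.N_c / np.maximum(n_pairs_cell, 1), 0.0)
    return _pair_pvalues(ind, lambda k: p0)


def upb_cell_rates(ind: IndicatorMatrix) -> np.ndarray:
    """Per-cell UPB success probabilities p_0^c (0 where no expressed pair)."""
    n_pairs_cell = ind.expressed_pairs_per_cell()
    return np.where(n_pairs_cell > 0, ind.N_c / np.maximum(n_pairs_cell, 1), 0.0)


def cpb_priors(ind: IndicatorMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene totals z_i and per-pair priors Pi_ij (flat, pair order)."""
    support = ind.X.sum(axis=1).astype(np.int64)
    n = ind.n_genes
    z = np.zeros(n, dtype=np.int64)
    for k, (i, j) in enumerate(combinations(range(n), 2)):
        z[i] += support[k]
        z[j] += support[k]
    pi = np.array(
        [z[i] * z[j] for i, j in combinations(range(n), 2)], dtype=float
    )
    total = pi.sum()
    if total > 0:
        pi /= total
    return z, pi


def cpb_test(ind: IndicatorMatrix) -> pd.DataFrame:
    """Conditional Poisson-Binomial test producing the global map.

    Returns one row per gene pair: ``gene_a, gene_b, support, n_cells,
    pvalue`` (floored at 1e-300), with region columns left for
    :func:`annotate_map`. When no proximal pair exists anywhere all p-values
    are 1 (warned).
    """
    _, pi = cpb_priors(ind)
    if pi.sum() == 0:
        logger.warning("cpb_test: no proximal pairs anywhere; all p-values are 1")
    N_c = ind.N_c

    def probs(k):
        return 1.0 - (1.0 - pi[k]) ** N_c

    gmap = _pair_pvalues(ind, probs)
    gmap["primary_region"] = None
    gmap["secondary_region"] = None
    return gmap


def annotate_map(gmap: pd.DataFrame, pp_results: pd.DataFrame) -> pd.DataFrame:
    """Attach primary/secondary region annotations to a global map.

    Region tallies of each pair's proximal transcript pairs are summed over
    all cells; the most and second-most frequent regions become the
    primary/secondary annotation. Ties are broken by the fixed region order
    Nuc > PN > Cyt > CP and logged. Pairs with no proximal pair anywhere
    stay unassigned.
    """
    tally_cols = {"Nuc": "n_nuc", "PN": "n_pn", "Cyt": "n_cyt", "CP": "n_cp"}
    missing = [c for c in tally_cols.values() if c not in pp_results.columns]
    if missing:
        raise ValueError("pp_results lack region tallies; run assign_regions first")
    agg = pp_results.groupby(["gene_a", "gene_b"])[list(tally_cols.values())].sum()

    out = gmap.copy()
    primary, secondary = [], []
    n_ties = 0
    for a, b in zip(out["gene_a"], out["gene_b"]):
        if (a, b) not in agg.index:
            primary.append(None)
            secondary.append(None)
            continue
        tal = agg.loc[(a, b)]
        counts = [(int(tal[tally_cols[r]]), r) for r in REGIONS]
        if sum(c for c, _ in counts) == 0:
            primary.append(None)
            secondary.append(None)
            continue
        # REGIONS order is the tie-break: stable sort keeps Nuc first.
        ranked = sorted(counts, key=lambda cr: -cr[0])
        if ranked[0][0] == ranked[1][0]:
            n_ties += 1
        primary.append(ranked[0][1])
        secondary.append(ranked[1][1] if ranked[1][0] > 0 else None)
    if n_ties:
        logger.info("annotate_map: %d pairs had tied region tallies", n_ties)
    out["primary_region"] = primary
    out["secondary_region"] = secondary
    return out


def rank_map(gmap: pd.DataFrame) -> pd.DataFrame:
    """Sort a map by (pvalue asc, support desc, gene names) — canonical order."""
    return gmap.sort_values(
        ["pvalue", "support", "gene_a", "gene_b"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


def estimate_fpr(
    real: pd.DataFrame, permuted: pd.DataFrame, thresholds: Iterable[float]
) -> pd.DataFrame:
    """False-positive-rate curve from a real and a label-permuted map.

    FPR(t) = (#pairs with p < t on permuted data) / (#pairs with p < t on
    real data); NaN (flagged undefined) when the real count is zero. Both
    maps must cover the same gene panel.
    """
    panel_real = set(real["gene_a"]) | set(real["gene_b"])
    panel_perm = set(permuted["gene_a"]) | set(permuted["gene_b"])
    if panel_real != panel_perm:
        raise ValueError("real and permuted maps cover different gene panels")
    rows = []
    for t in thresholds:
        n_real = int((real["pvalue"] < t).sum())
        n_perm = int((permuted["pvalue"] < t).sum())
        rows.append(
            {
                "threshold": t,
                "real_detections": n_real,
                "permuted_detections": n_perm,
                "fpr": (n_perm / n_real) if n_real > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def blank_probe_fpr(
    gmap: pd.DataFrame, blank_genes: set, threshold: float
) -> tuple[float, float]:
    """Observed and expected fraction of significant pairs involving a blank.

    Blank probes target no real RNA, so any significant pair involving one
    is a known false positive. The expected fraction under random pair
    selection from an n-gene panel with b blanks is 1 - C(n-b,2)/C(n,2).
    Observed is NaN when no pair is significant.
    """
    panel = sorted(set(gmap["gene_a"]) | set(gmap["gene_b"]))
    if not blank_genes <= set(panel):
        raise ValueError("blank genes must be part of the gene panel")
    n, b = len(panel), len(blank_genes)
    expected = 1.0 - math.comb(n - b, 2) / math.comb(n, 2) if n >= 2 else float("nan")
    sig = gmap[gmap["pvalue"] < threshold]
    if len(sig) == 0:
        return float("nan"), expected
    has_blank = sig["gene_a"].isin(blank_genes) | sig["gene_b"].isin(blank_genes)
    return float(has_blank.mean()), expected


def coexpression_map(table: pd.DataFrame, top_k: int) -> list[tuple[str, str]]:
    """Top gene pairs by Pearson correlation of whole-cell transcript counts.

    Counts are aggregated over z-planes per cell. Zero-variance genes are
    excluded with a warning. Returns ``top_k`` pairs ordered by decreasing
    correlation (ties by gene names).
    """
    counts = table.groupby(["cell", "gene"]).size().unstack(fill_value=0)
    if counts.shape[0] < 3:
        raise ValueError("need >= 3 cells for a co-expression map")
    variances = counts.var(axis=0)
    dropped = variances.index[variances == 0]
    if len(dropped):
        logger.warning(
            "coexpression_map: excluded %d zero-variance genes", len(dropped)
        )
    counts = counts.loc[:, variances > 0]
    genes = list(counts.columns)
    if top_k <= 0 or len(genes) < 2:
        return []
    r = np.corrcoef(counts.to_numpy(dtype=float), rowvar=False)
    scored = [
        (r[i, j], genes[i], genes[j])
        for i, j in combinations(range(len(genes)), 2)
    ]
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [(a, b) for _, a, b in scored[:top_k]]


def overlap_enrichment(
    set_a: set, set_b: set, universe_size: int
) -> float:
    """Upper-tail hypergeometric p-value of the overlap of two pair sets.

    Used e.g. to test whether d-colocalized pairs overlap functionally
    related pairs (same pathway / shared annotation terms) more than chance
    within the universe of all C(n, 2) gene pairs.
    """
    overlap = len(set_a & set_b)
    if overlap > min(len(set_a), len(set_b)) or max(len(set_a), len(set_b)) > universe_size:
        raise ValueError("inconsistent set sizes for the overlap test")
    return float(hypergeom.sf(overlap - 1, universe_size, len(set_a), len(set_b)))


def rri_enrichment(
    gmap: pd.DataFrame,
    rri_scores: Mapping[tuple[str, str], float],
    score_threshold: float = 35.0,
    top_k: int = 10,
    background_p_cutoff: float = 0.01,
    fdr: float = 0.2,
) -> pd.DataFrame:
    """Gene-centric enrichment of high RNA-RNA interaction scores among a
    gene's best-colocalized partners.

    For each gene: a Gaussian background is fitted to the precomputed RRI
    scores of its *non*-colocalized pairs (map p-value above
    ``background_p_cutoff``); the Gaussian tail beyond ``score_threshold``
    is the success probability of an exact binomial test on how many of the
    gene's ``top_k`` best-ranked partners exceed the threshold. BH q-values
    are computed across genes; ``significant`` flags q < ``fdr``. Genes with
    fewer than 3 background pairs or a degenerate (zero-spread) background
    are skipped with a warning.
    """

    def score(a, b):
        key = (a, b) if (a, b) in rri_scores else (b, a)
        return rri_scores[key]

    genes = sorted(set(gmap["gene_a"]) | set(gmap["gene_b"]))
    rows = []
    for g in genes:
        sub = gmap[(gmap["gene_a"] == g) | (gmap["gene_b"] == g)].copy()
        if sub.empty:
            continue
        sub["partner"] = np.where(sub["gene_a"] == g, sub["gene_b"], sub["gene_a"])
        sub["rri"] = [score(g, p) for p in sub["partner"]]
        background = sub.loc[sub["pvalue"] > background_p_cutoff, "rri"].to_numpy()
        if len(background) < 3:
            logger.warning("rri_enrichment: gene %s skipped (<3 background pairs)", g)
            continue
        mu, sd = float(np.mean(background)), float(np.std(background, ddof=1))
        if sd == 0:
            logger.warning("rri_enrichment: gene %s skipped (degenerate background)", g)
            continue
        success_p = float(norm.sf(score_threshold, loc=mu, scale=sd))
        top = sub.sort_values(
            ["pvalue", "partner"], kind="mergesort"
        ).head(top_k)
        n_hits = int((top["rri"] > score_threshold).sum())
        pval = float(binom.sf(n_hits - 1, len(top), success_p)) if n_hits > 0 else 1.0
        rows.append({"gene": g, "n_hits": n_hits, "success_prob": success_p, "pvalue": pval})
    out = pd.DataFrame(rows, columns=["gene", "n_hits", "success_prob", "pvalue"])
    if len(out):
        out["qvalue"] = false_discovery_control(out["pvalue"].to_numpy(), method="bh")
        out["significant"] = out["qvalue"] < fdr
    return out
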