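"""Aggregation tests: Poisson-Binomial tails, UPB/CPB, annotation, FPR, enrichment."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, hypergeom

from proximap import (
    IndicatorMatrix,
    annotate_map,
    blank_probe_fpr,
    coexpression_map,
    cpb_priors,
    cpb_test,
    estimate_fpr,
    overlap_enrichment,
    poisson_binomial_sf,
    rank_map,
    rri_enrichment,
    upb_test,
)


def enumerate_pb_sf(probs, k):
    """Oracle: P(sum Bernoulli >= k) by summing over all 2^m outcomes."""
    total = 0.0
    for outcome in itertools.product([0, 1], repeat=len(probs)):
        if sum(outcome) >= k:
            w = 1.0
            for o, p in zip(outcome, probs):
                w *= p if o else (1 - p)
            total += w
    return total


def make_indicators(genes, cells, x_entries, unexpressed=()):
    """Build an IndicatorMatrix from explicit (gene_a, gene_b, cell) marks."""
    from itertools import combinations

    gi = {g: i for i, g in enumerate(genes)}
    ci = {c: i for i, c in enumerate(cells)}
    pair_idx = {p: k for k, p in enumerate(combinations(range(len(genes)), 2))}
    X = np.zeros((len(pair_idx), len(cells)), dtype=np.uint8)
    E = np.ones((len(genes), len(cells)), dtype=bool)
    for g, c in unexpressed:
        E[gi[g], ci[c]] = False
    for a, b, c in x_entries:
        i, j = sorted((gi[a], gi[b]))
        X[pair_idx[(i, j)], ci[c]] = 1
    return IndicatorMatrix(genes, cells, X, E)


class TestPoissonBinomialSF:
    def test_worked_example(self):
        assert poisson_binomial_sf([0.1, 0.2, 0.3], 2) == pytest.approx(0.098, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = int(rng.integers(1, 13))
            probs = rng.uniform(0, 0.99, size=m)
            k = int(rng.integers(0, m + 2))
            assert poisson_binomial_sf(probs, k) == pytest.approx(
                enumerate_pb_sf(probs, k), abs=1e-12
            )

    def test_reduces_to_binomial(self):
        p, n = 0.37, 25
        for k in (0, 1, 5, 24, 25):
            assert poisson_binomial_sf([p] * n, k) == pytest.approx(
                float(binom.sf(k - 1, n, p)), abs=1e-12
            )

    def test_edges(self):
        assert poisson_binomial_sf([0.5, 0.5], 0) == 1.0
        assert poisson_binomial_sf([0.5, 0.5], 3) == 0.0

    def test_monotone_in_k(self):
        probs = [0.2, 0.4, 0.9, 0.05]
        vals = [poisson_binomial_sf(probs, k) for k in range(6)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestUPB:
    def test_formula_substitution(self):
        # One cell, 4 genes expressed (6 pairs), 2 significant: p_0^c = 1/3.
        ind = make_indicators(
            ["A", "B", "C", "D"], ["c1"], [("A", "B", "c1"), ("C", "D", "c1")]
        )
        from proximap.colocalization import upb_cell_rates

        assert upb_cell_rates(ind)[0] == pytest.approx(1 / 3)

    def test_three_cell_enumeration(self):
        # Support 2 with per-cell rates (0.1, 0.2, 0.3) -> same oracle as above.
        # Rates are induced via 5 expressed genes (10 pairs) marked 1, 2, 3 times.
        genes = ["A", "B", "C", "D", "E"]
        marks = [
            ("A", "B", "c1"),
            ("A", "B", "c2"), ("C", "D", "c2"),
            ("A", "B", "c3"), ("C", "D", "c3"), ("C", "E", "c3"),
        ]
        ind = make_indicators(genes, ["c1", "c2", "c3"], marks)
        res = upb_test(ind).set_index(["gene_a", "gene_b"])
        # pair (A,B): support 3, probs (0.1, 0.2, 0.3)
        assert res.loc[("A", "B"), "pvalue"] == pytest.approx(
            enumerate_pb_sf([0.1, 0.2, 0.3], 3), abs=1e-12
        )
        # pair (C,D): support 2
        assert res.loc[("C", "D"), "pvalue"] == pytest.approx(0.098, abs=1e-12)

    def test_zero_support_gives_one(self):
        ind = make_indicators(["A", "B", "C"], ["c1", "c2"], [("A", "B", "c1")])
        res = upb_test(ind).set_index(["gene_a", "gene_b"])
        assert res.loc[("B", "C"), "pvalue"] == 1.0


class TestCPB:
    def test_prior_formula(self):
        # z = (A:2, B:1, C:1): Pi_AB = 2*1 / (2*1 + 2*1 + 1*1) = 0.4
        ind = make_indicators(
            ["A", "B", "C"],
            ["c1", "c2"],
            [("A", "B", "c1"), ("A", "C", "c2")],
        )
        z, pi = cpb_priors(ind)
        assert list(z) == [2, 1, 1]
        assert pi[0] == pytest.approx(0.4)  # pair (A,B)

    def test_cell_probability_closed_form(self):
        # p_ij^c = 1 - (1 - 0.4)^3 = 0.784 for N_c = 3.
        assert 1 - (1 - 0.4) ** 3 == pytest.approx(0.784)
        genes = ["A", "B", "C", "D"]
        # One cell with three significant pairs, all involving A->{B,C,D}.
        ind = make_indicators(
            genes, ["c1"], [("A", "B", "c1"), ("A", "C", "c1"), ("A", "D", "c1")]
        )
        _, pi = cpb_priors(ind)
        res = cpb_test(ind).set_index(["gene_a", "gene_b"])
        k = 0  # pair (A,B)
        expected = enumerate_pb_sf([1 - (1 - pi[k]) ** 3], 1)
        assert res.loc[("A", "B"), "pvalue"] == pytest.approx(expected, abs=1e-12)

    def test_zero_prior_pair_gets_one(self):
        ind = make_indicators(["A", "B", "C"], ["c1"], [("A", "B", "c1")])
        res = cpb_test(ind).set_index(["gene_a", "gene_b"])
        assert res.loc[("B", "C"), "pvalue"] == 1.0

    def test_all_zero_indicators_warns_all_one(self, caplog):
        ind = make_indicators(["A", "B", "C"], ["c1"], [])
        res = cpb_test(ind)
        assert (res["pvalue"] == 1.0).all()

    def test_support_bounded_by_coexpressed_cells(self):
        ind = make_indicators(
            ["A", "B", "C"],
            ["c1", "c2"],
            [("A", "B", "c1")],
            unexpressed=[("C", "c1")],
        )
        res = cpb_test(ind)
        assert (res["support"] <= res["n_cells"]).all()

    def test_convolution_spans_all_cells_and_reports_coexpression(self):
        """The Poisson-Binomial runs over every cell (cells without both
        genes expressed keep a positive modelled rate, adding conservatism),
        while n_cells reports where the indicator could actually fire."""
        ind = make_indicators(
            ["A", "B", "C"],
            ["c1", "c2"],
            [("A", "B", "c1"), ("A", "C", "c2")],
            unexpressed=[("B", "c2")],
        )
        res = cpb_test(ind).set_index(["gene_a", "gene_b"])
        assert res.loc[("B", "C"), "n_cells"] == 1
        # Oracle: convolve p_ij^c = 1-(1-Pi)^{N_c} over both cells at k=0.
        _, pi = cpb_priors(ind)
        k_bc = ind.pair_index("B", "C")
        probs = [1 - (1 - pi[k_bc]) ** n for n in ind.N_c]
        assert res.loc[("B", "C"), "pvalue"] == pytest.approx(
            enumerate_pb_sf(probs, 0), abs=1e-12
        )

    def test_adding_supporting_cell_never_raises_pvalue(self):
        genes = ["A", "B", "C", "D"]
        cells = [f"c{i}" for i in range(6)]
        base_marks = [("A", "B", "c0"), ("C", "D", "c1"), ("A", "C", "c2")]
        ind0 = make_indicators(genes, cells, base_marks)
        p0 = cpb_test(ind0).set_index(["gene_a", "gene_b"]).loc[("A", "B"), "pvalue"]
        # Flip X_AB^c 0 -> 1 in a fresh cell, everything else fixed: recompute
        # the convolution with the same priors and rates but support + 1.
        from proximap import poisson_binomial_sf

        _, pi = cpb_priors(ind0)
        N_c = ind0.N_c.copy()
        k_ab = ind0.pair_index("A", "B")
        probs = 1 - (1 - pi[k_ab]) ** N_c
        assert poisson_binomial_sf(probs, 2) <= poisson_binomial_sf(probs, 1) <= p0 + 1e-15

    def test_cpb_matches_upb_ranking_under_equal_totals(self):
        """With all z_i equal the prior is uniform and the two tests order
        pairs identically."""
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(6)]
        cells = [f"c{i}" for i in range(30)]  # two full cycles of the 15 pairs
        # Rotate a fixed mark pattern so every gene accrues the same z_i.
        marks = []
        pair_cycle = list(itertools.combinations(genes, 2))
        for i, c in enumerate(cells):
            a, b = pair_cycle[i % len(pair_cycle)]
            marks.append((a, b, c))
        ind = make_indicators(genes, cells, marks)
        z, _ = cpb_priors(ind)
        assert len(set(z)) == 1
        r_cpb = rank_map(cpb_test(ind))[["gene_a", "gene_b"]]
        r_upb = rank_map(upb_test(ind))[["gene_a", "gene_b"]]
        pd.testing.assert_frame_equal(r_cpb, r_upb)


class TestAnnotateMap:
    @staticmethod
    def _pp_results(tallies):
        rows = []
        for (a, b), t in tallies.items():
            rows.append(
                {
                    "cell": "c1", "gene_a": a, "gene_b": b, "K": sum(t.values()),
                    "T": 10, "p_null": 0.1, "pvalue": 0.5,
                    "n_nuc": t.get("Nuc", 0), "n_pn": t.get("PN", 0),
                    "n_cyt": t.get("Cyt", 0), "n_cp": t.get("CP", 0),
                }
            )
        return pd.DataFrame(rows)

    @staticmethod
    def _gmap(pairs):
        return pd.DataFrame(
            [{"gene_a": a, "gene_b": b, "support": 1, "n_cells": 1, "pvalue": 0.01}
             for a, b in pairs]
        )

    def test_argmax_and_secondary(self):
        out = annotate_map(
            self._gmap([("A", "B")]),
            self._pp_results({("A", "B"): {"Nuc": 10, "PN": 3}}),
        )
        assert out.loc[0, "primary_region"] == "Nuc"
        assert out.loc[0, "secondary_region"] == "PN"

    def test_tie_broken_by_fixed_region_order(self):
        out = annotate_map(
            self._gmap([("A", "B")]),
            self._pp_results({("A", "B"): {"PN": 5, "Nuc": 5}}),
        )
        assert out.loc[0, "primary_region"] == "Nuc"

    def test_all_zero_tallies_unassigned(self):
        out = annotate_map(
            self._gmap([("A", "B")]), self._pp_results({("A", "B"): {}})
        )
        assert out.loc[0, "primary_region"] is None


class TestFPR:
    @staticmethod
    def _map(pvals):
        return pd.DataFrame(
            [{"gene_a": "A", "gene_b": f"B{i}", "support": 1, "n_cells": 1, "pvalue": p}
             for i, p in enumerate(pvals)]
        )

    def test_ratio(self):
        real = self._map([1e-6] * 100)
        perm = self._map([1e-6] + [0.9] * 99)
        out = estimate_fpr(real, perm, [1e-3])
        assert out.loc[0, "fpr"] == pytest.approx(0.01)

    def test_zero_permuted_detections(self):
        out = estimate_fpr(self._map([1e-6] * 100), self._map([0.9] * 100), [1e-3])
        assert out.loc[0, "fpr"] == 0.0

    def test_zero_real_detections_flagged_undefined(self):
        out = estimate_fpr(self._map([0.9] * 10), self._map([0.9] * 10), [1e-3])
        assert math.isnan(out.loc[0, "fpr"])

    def test_mismatched_panels_rejected(self):
        other = self._map([0.5])
        other.loc[0, "gene_a"] = "Z"
        with pytest.raises(ValueError):
            estimate_fpr(self._map([0.5, 0.5]), other, [0.1])


class TestBlankProbeFPR:
    @staticmethod
    def _map_with_blanks():
        rows = []
        genes = [f"G{i}" for i in range(6)] + ["Blank1", "Blank2"]
        for a, b in itertools.combinations(genes, 2):
            rows.append({"gene_a": a, "gene_b": b, "support": 1, "n_cells": 1,
                         "pvalue": 0.5})
        return pd.DataFrame(rows), {"Blank1", "Blank2"}

    def test_expected_closed_form(self):
        gmap, blanks = self._map_with_blanks()
        _, expected = blank_probe_fpr(gmap, blanks, 0.01)
        n, b = 8, 2
        assert expected == pytest.approx(1 - math.comb(n - b, 2) / math.comb(n, 2))

    def test_panel_size_140_with_10_blanks(self):
        # Closed form at the reference panel scale: 1 - C(130,2)/C(140,2).
        n, b = 140, 10
        expected = 1 - math.comb(130, 2) / math.comb(140, 2)
        assert expected == pytest.approx(1 - (130 * 129) / (140 * 139))
        assert math.comb(130, 2) == 8385  # ~8,400 gene pairs with 130 genes

    def test_no_significant_pairs_observed_undefined(self):
        gmap, blanks = self._map_with_blanks()
        obs, _ = blank_probe_fpr(gmap, blanks, 1e-9)
        assert math.isnan(obs)

    def test_blank_free_detections_give_zero(self):
        gmap, blanks = self._map_with_blanks()
        gmap.loc[
            (gmap["gene_a"] == "G0") & (gmap["gene_b"] == "G1"), "pvalue"
        ] = 1e-9
        obs, _ = blank_probe_fpr(gmap, blanks, 1e-6)
        assert obs == 0.0


class TestCoexpressionMap:
    def test_identical_count_vectors_rank_first(self):
        rng = np.random.default_rng(1)
        rows = []
        for c in range(10):
            n = int(rng.integers(2, 6))
            for g in ("A", "B"):
                rows += [{"cell": f"c{c}", "gene": g, "x": 0.0, "y": 0.0, "z": 0}] * n
            rows += [{"cell": f"c{c}", "gene": "C", "x": 0.0, "y": 0.0, "z": 0}] * int(
                rng.integers(1, 8)
            )
        top = coexpression_map(pd.DataFrame(rows), top_k=1)
        assert top == [("A", "B")]

    def test_top_zero_empty(self, null_dataset):
        table, _, _, _ = null_dataset
        assert coexpression_map(table, 0) == []

    def test_independent_counts_do_not_recover_planted(self, planted_dataset):
        """Whole-cell co-expression is blind to subcellular colocalization."""
        (table, _, _, truth), planted = planted_dataset
        top = set(map(tuple, coexpression_map(table, top_k=10)))
        hits = len(top & truth.planted_keys())
        assert hits <= 2  # chance-level overlap


class TestOverlapEnrichment:
    def test_enumeration_oracle_small_universe(self):
        rng = np.random.default_rng(4)
        universe = list(range(12))
        A = set(rng.choice(universe, size=5, replace=False).tolist())
        B = set(rng.choice(universe, size=4, replace=False).tolist())
        # Oracle: enumerate all subsets of size |B| as the random draw.
        hits = total = 0
        k_obs = len(A & B)
        for comb in itertools.combinations(universe, len(B)):
            total += 1
            if len(A & set(comb)) >= k_obs:
                hits += 1
        assert overlap_enrichment(A, B, 12) == pytest.approx(hits / total, abs=1e-12)

    def test_identical_sets_extreme(self):
        A = set(range(10))
        p = overlap_enrichment(A, A, 100)
        assert p == pytest.approx(1 / math.comb(100, 10), rel=1e-9)

    def test_disjoint_sets_give_one(self):
        assert overlap_enrichment({1, 2}, {3, 4}, 10) == 1.0

    def test_impossible_overlap_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment({1}, {1}, 0)


class TestRRIEnrichment:
    @staticmethod
    def _gmap_scores(seed=0, n_genes=12, hot_gene="G00"):
        rng = np.random.default_rng(seed)
        genes = [f"G{i:02d}" for i in range(n_genes)]
        rows, scores = [], {}
        for a, b in itertools.combinations(genes, 2):
            involves_hot = hot_gene in (a, b)
            p = rng.uniform(0.02, 1.0)
            score = rng.normal(10, 5)
            rows.append({"gene_a": a, "gene_b": b, "support": 1, "n_cells": 5,
                         "pvalue": p})
            scores[(a, b)] = score
        return pd.DataFrame(rows), scores

    def test_no_hits_gives_one(self):
        gmap, scores = self._gmap_scores()
        out = rri_enrichment(gmap, scores, score_threshold=1e6)
        assert (out["pvalue"] == 1.0).all()

    def test_hits_match_binomial_oracle(self):
        gmap, scores = self._gmap_scores()
        # Make 3 of one gene's top partners score above threshold.
        g = "G00"
        sub = gmap[(gmap["gene_a"] == g) | (gmap["gene_b"] == g)]
        top3 = sub.sort_values("pvalue").head(3)
        for _, row in top3.iterrows():
            scores[(row["gene_a"], row["gene_b"])] = 60.0
            gmap.loc[row.name, "pvalue"] = 1e-8  # colocalized: not background
        out = rri_enrichment(gmap, scores, score_threshold=35.0, top_k=10)
        row = out.set_index("gene").loc[g]
        assert row["n_hits"] == 3
        expected = float(binom.sf(2, 10, row["success_prob"]))
        assert row["pvalue"] == pytest.approx(expected, rel=1e-9)

    def test_degenerate_background_skipped(self):
        gmap, scores = self._gmap_scores()
        scores = {k: 5.0 for k in scores}
        out = rri_enrichment(gmap, scores)
        assert len(out) == 0
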