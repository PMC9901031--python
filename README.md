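# proximap

Statistical toolkit for **subcellular RNA colocalization** in
single-molecule spatial transcriptomics (MERFISH-style data). Given a table
of detected transcripts — cell id, gene, x/y coordinates in micrometres,
optional z-plane — proximap identifies gene pairs whose transcripts sit
unusually close together inside single cells, aggregates that evidence
across cells into a global *d*-colocalization map, and characterizes the
detected pairs by subcellular region, cell-type specificity, tissue-level
spatial modulation, and module membership. It is written for analysts of
imaging-based spatial transcriptomics who want transcript-level (not
cell-level) spatial statistics.

## The statistics

**Proximal-pair (PP) test, per cell.** For a cell with transcript set
indexed by gene, the null probability *p* is the fraction of all unordered
transcript pairs (gene identities ignored) separated by at most *d* μm —
the cell's own spatial texture. For genes *g_i*, *g_j* with *t_i*, *t_j*
transcripts, *T = t_i·t_j* cross-gene pairs are possible and *K* of them
are within *d*; the p-value is the exact binomial upper tail

    p-value(g_i, g_j) = P(X ≥ K),  X ~ Binomial(T, p).

Multi-plane data pool per-plane statistics (planes treated as i.i.d.
samples): *p = Σ_z l_z p_z / Σ_z l_z*, *T = Σ_z T_z*, *K = Σ_z K_z*, and
pairs are never formed across planes.

**Conditional Poisson-Binomial (CPB) test, across cells.** Let *X_ij^c*
indicate that (*g_i*, *g_j*) is a significant proximal pair in cell *c*
(PP p-value < α) and *N_c = Σ_{i<j} X_ij^c*. With *z_i* the number of
proximal pairs involving gene *i* over all cells, the prior that a detected
proximal pair is (*g_i*, *g_j*) is

    Π_ij = z_i z_j / Σ_{i<j} z_i z_j,   p_ij^c = 1 − (1 − Π_ij)^{N_c},

and the number of supporting cells *Σ_c X_ij^c* is tested against the
Poisson-Binomial distribution of the *p_ij^c* (exact dynamic-programming
tail). The prior de-emphasizes pairs of genes that are promiscuously
proximal everywhere; the unconditional variant (UPB) instead uses each
cell's overall rate *p_0^c* = *N_c* / (#expressed pairs). Downstream:
region annotation (Nucleus / Peri-Nucleus / Cytosol / Cell-Periphery),
permutation and blank-probe false-positive rates, a conditional
multivariate-hypergeometric test of cell-type specificity, a
likelihood-ratio test of tissue-level spatial modulation on a fixed-radius
cell-neighbor graph, and gene-module discovery by Ward clustering of the
−log p-value matrix (GCC) and frequent edge-set mining of per-cell
proximity graphs (FSM). A synthetic-data generator with planted ground
truth makes every stage testable without external data.

## Worked example

```python
from proximap import (PPConfig, PlantedPair, SimConfig,
                      cpb_test, pp_test_dataset, rank_map, simulate_dataset)

cfg = SimConfig(n_cells=100, n_genes=20, n_blanks=2,
                planted_pairs=[PlantedPair("G001", "G002", rho=0.6, sigma=0.5)],
                mean_transcripts_per_cell=150, seed=0)
table, geometry, meta, truth = simulate_dataset(cfg)      # 15176 transcripts

ind, per_cell = pp_test_dataset(table, PPConfig(d=2.0, alpha_pp=0.01))
gmap = rank_map(cpb_test(ind))
print(gmap.head(3)[["gene_a", "gene_b", "support", "n_cells", "pvalue"]])
```

```
gene_a gene_b  support  n_cells       pvalue
  G001   G002       24      100 3.039375e-12
  G003   G007        4      100 2.550785e-02
  G005   G014        3       99 5.425943e-02
```

The planted pair G001–G002 (60% of the rarer gene's transcripts placed
within a Gaussian displacement of scale 0.5 μm of a partner transcript) is
a significant proximal pair in 24 of 100 cells and tops the map at
p ≈ 3e-12; the best unplanted pair sits three orders of magnitude behind
and would not survive any sensible map threshold (e.g. 1e-3).

The same workflow runs from the shell:

```sh
proximap simulate --config sim.yaml --out-dir sim1/
proximap pp --input sim1/transcripts.csv --d 2.0 --alpha 0.01
proximap cpb --indicators pp_indicators.tsv --out map.tsv
proximap run --config run.yaml        # full pipeline with manifest
```

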