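# Methods

This note documents the statistical models implemented in proximap, the
parameters that matter, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Per-cell proximal-pair (PP) test

A cell is a finite point pattern labelled by gene. The test asks, for each
gene pair, whether cross-gene transcript pairs within distance *d* are more
frequent than the cell's own background proximity rate.

- **Null probability.** *p* = (# unordered transcript pairs with Euclidean
  distance ≤ *d*) / C(N, 2), over *all* transcripts regardless of gene
  (same-gene pairs included; a transcript is never paired with itself).
  Estimating the null from the cell itself absorbs cell-level confounders:
  transcript density, cell size and shape, and any global spatial
  organisation shared by all genes.
- **Counting.** For genes with *t_i*, *t_j* transcripts, every cross-gene
  transcript pair is counted once, so *K ≤ T = t_i·t_j*. "Within *d*" is
  closed (≤ *d*): coordinates are continuous so the boundary has measure
  zero, and a fixed convention keeps the fast neighbor-search path
  (`scipy.spatial.cKDTree.query_pairs`) exactly equal to the all-pairs
  scan, which is kept in the code as a testing oracle.
- **P-value.** Exact binomial survival P(X ≥ K | T, p); no normal
  approximation (T stays ≤ ~10^6 at realistic panel sizes). Conventions:
  K = 0 → p-value 1; p = 0 with K > 0 → p-value 0 with a warning.
- **Multi-plane (3D) pooling.** Planes are modelled as independent samples
  of the same cell: per-plane nulls are pooled by transcript count,
  *p = Σ_z l_z p_z / Σ_z l_z*, and *T*, *K* are summed. Transcripts are
  never paired across planes; within-plane distance is 2D. Planes with
  fewer than two transcripts contribute nothing; a cell where every plane
  is skipped is excluded (and counted in the log).
- **Intra-nucleus mode.** Both the pair counting and the null estimate are
  restricted to transcripts inside the nucleus polygon.
- **Expression.** A gene is "expressed" in a cell when it has ≥ 1
  transcript there (the threshold is an argument where it matters).

The significance threshold α_PP defaults to 0.01. The scale parameter *d*
has no default in the library: it is a scientific choice (a useful
heuristic is ~5% of a typical cell diameter — 4 μm for large cultured
cells, 2 μm for denser tissue — and probing several scales probes
different spatial textures).

## Aggregation across cells: UPB and CPB

The per-cell indicators X_ij^c are aggregated per pair. Both tests model
the number of supporting cells as a Poisson-Binomial sum with
cell-specific success probabilities and compute the exact upper tail by
dynamic-programming convolution (all intermediates live in [0, 1]; the
tail is accumulated with compensated summation; reported p-values are
floored at 1e-300).

- **UPB**: every pair in cell *c* shares p_0^c = N_c / (# gene pairs with
  both genes expressed in *c*); cells with no expressed pair have rate 0.
- **CPB**: p_ij^c = 1 − (1 − Π_ij)^{N_c} with Π_ij ∝ z_i z_j as in the
  README. Genes that are frequently in proximal pairs anywhere drag their
  pairs' priors up, demoting promiscuous-abundance artifacts. The prior
  normalisation runs over unordered distinct pairs i < j.

**Which cells enter the convolution.** The convolution runs over *all*
cells, including cells where one gene of the pair is unexpressed — there
the modelled rate is still positive whenever the cell has proximal pairs,
although the indicator can never fire. An alternative is to restrict the
convolution to co-expressed cells, which makes the null nearly calibrated;
we implemented the all-cells form deliberately. The indicator truly cannot
fire in a non-co-expressed cell, so including such cells makes the test
conservative exactly for sparsely co-expressed (typically low-abundance)
pairs — the regime where two chance hits would otherwise produce
astronomically small p-values from a noisy, tiny prior. Measured on
permuted data (50-gene panels, 200 cells) the all-cells form yields zero
detections at p < 1e-3 where the restricted form hovers near the nominal
~1 per 1225 pairs. The output column `n_cells` still reports the number of
co-expressing cells, and pairs never co-expressed anywhere keep p-value 1.

**Ranking.** Map outputs are ordered by (p-value asc, support desc, gene
names) so that ties are deterministic.

## Region annotation

With cell and nucleus boundary polygons (one 2D polygon per cell, applied
to all z-planes, matching how 2D segmentation masks are usually exported),
each transcript is labelled:

- **PN** (peri-nucleus) when its distance to the nuclear membrane is
  ≤ 2.5 μm, on either side of the membrane;
- else **Nuc** when inside the nucleus;
- else **CP** (cell periphery) when within 4 μm of the cell membrane;
- else **Cyt** (cytosol).

The PN band taking precedence makes the four labels a partition. The
2.5/4 μm defaults are the values that put roughly 40% of nuclear
transcripts in the PN band and a third of cytosolic transcripts in the CP
rim at typical cell sizes; both are configurable. Transcripts that fall
outside their cell polygon (segmentation noise) are labelled by the
nearest region (PN band or CP) with a warning.

A *proximal pair* of transcripts is tallied to a single region: the shared
region when its two transcripts agree, otherwise the higher-priority
region in the fixed order Nuc > PN > Cyt > CP. This keeps per-pair region
tallies summing to K. Aggregated over cells, the most and second-most
frequent regions become the pair's primary/secondary annotation; ties use
the same fixed order and are logged.

## False-positive rates

Two complementary estimates:

- **Permutation.** Gene labels are shuffled uniformly within each cell,
  preserving every cell's point pattern and per-gene counts while
  destroying gene-gene relationships. FPR(t) = detections on permuted data
  / detections on real data at the same threshold *t*.
- **Blank probes.** Panels may include barcodes assigned to no real RNA;
  any significant pair involving one is a known false positive. The
  observed blank-involving fraction of detections is compared to the
  chance expectation 1 − C(n−b, 2)/C(n, 2) for *b* blanks among *n* genes.

## Cell-type specificity

For each detected pair and each cell type: U = all cells, M = cells of the
type, O = cells supporting the pair. The first-stage association is the
hypergeometric upper tail of |M ∩ O|, Bonferroni-corrected over
pairs × types (significant below 0.05 after correction).

Associated pairs are then conditioned on expression: E = the |M| cells
with the highest counts of one gene (ties broken by cell id so the set is
deterministic). With γ = |M ∩ E|, α = |E ∩ O|, the conditional p-value is
the probability that a random O′ of size |O| with |O′ ∩ E| = α overlaps M
in at least λ = |M ∩ O| cells — an exact double sum of multivariate
hypergeometric terms over the four blocks (M∩E, M\E, E\M, rest),
evaluated in exact integer arithmetic. The test runs twice, conditioning
on each gene's E.

Markers of a type are the top 10 genes by the hypergeometric association
between their high-expression set E and M.

Categories of a detected pair:

- **Category 3** — not associated with any type;
- **Category 2** — associated, *both* conditional tests significant, and
  neither gene a marker of the type: specificity beyond either gene's
  expression;
- **Category 1** — associated but explainable by expression or marker
  status.

The 1/2 naming follows the flow-chart semantics in which the stringent
class is Category 2; a `swap_category_labels` flag exchanges the labels
for compatibility with the alternative naming that appears in some
descriptions of this scheme. Two-way specificity (one type versus another
rather than one-versus-rest) is obtained by restricting U to the union of
the two types.

## Spatial modulation

Cells are nodes of a fixed-radius graph (neighbors = centroids within
100 μm by default; symmetric, no self-edges). For a pair, s_c ∈ {0, 1}
marks supporting cells. H0: s_c ~ Bernoulli(p_global) with p_global at its
MLE (the support fraction). H1: s_c ~ Bernoulli(w·p_local_c +
(1−w)·p_global) with p_local_c the supporting fraction among c's
neighbors, w ∈ [0, 1], p_global ∈ [ε, 1−ε] free. Numerical choices:

- success probabilities are clamped to [ε, 1−ε], ε = 1e-9;
- cells with no neighbors use p_global in place of p_local, nulling their
  influence on w;
- the H1 likelihood can be multimodal, so it is maximised by L-BFGS-B from
  the four multistarts (w, p_global) ∈ {0.1, 0.9}², with the H0 solution
  (w = 0) always included as a candidate — hence LLR ≥ 0 by construction;
  tests verify the optimum against a dense 200×200 grid;
- a constant s vector returns LLR 0 by convention.

The detection threshold for a map of pairs is the highest LLR observed
over n_perm (default 10) independent full permutations of each pair's s
vector — permutation preserves each pair's support count while destroying
spatial structure, so under exchangeability the observed maximum rarely
exceeds it. Pairs strictly above the threshold are flagged, and carry
their best-associated cell type when type labels are available. The null
LLR distribution is heavy-tailed, so with ~20 null pairs a spurious flag
survives the max-of-(pairs × n_perm) threshold in roughly 5–10% of
datasets; raising n_perm tightens this at linear cost.

## Module discovery

- **GCC.** The map becomes an n×n matrix of −log10(p + 1e-64) (the offset
  handles exact zeros; the base is immaterial since uniform scaling leaves
  Ward merge order unchanged). Rows are Ward-clustered (Euclidean metric)
  and cut into a configurable number of flat clusters; clusters of ≥ 2
  genes whose internal significant-pair density reaches `min_density`
  (default 0.7) are reported with their dominant region. The density
  filter replaces reading modules off a heatmap: the dendrogram itself has
  no intrinsic module boundary, and published example modules have
  internal densities well above this default (≈ 0.8–0.9).
- **FSM.** Per-cell graphs connect genes whose PP p-value beats the edge
  threshold (default 0.05, deliberately independent of the indicator α;
  at stringent thresholds cells support almost no multi-edge subgraph).
  Because a gene occurs at most once per cell, frequent-subgraph mining
  reduces *exactly* to frequent itemset mining over edge sets: a
  level-wise Apriori search with bitmask tid-lists, followed by a
  connectivity (or clique) constraint and a minimum node count. Reported
  sets are the *closed* frequent ones — no superset with equal support —
  so a frequent clique and its more-frequent individual edges both
  surface; `closed_only=False` returns every qualifying frequent set
  (used by the exhaustive-enumeration oracle in tests). Support is
  anti-monotone, which both prunes the search and is asserted over mined
  results.

## Synthetic data

The generator emulates the regimes these statistics are designed for:
disc-shaped cells (radius ~9 ± 0.8 μm) on a jittered 30 μm grid, each with
a concentric nucleus disc (~4.5 μm); per-gene expected counts drawn
log-normally (spread σ = 0.7) and scaled to a target of ~250 transcripts
per cell; Poisson per-cell counts; uniform placement within the cell;
optional uniform assignment across z-planes; blank probes as ordinary
background genes; cell types drawn from configured proportions.

A planted pair (ρ, σ) relocates a Binomial(t_rare, ρ) subset of the rarer
gene's transcripts to a random partner transcript plus an isotropic
Gaussian displacement of scale σ μm (resampled to stay inside the cell; on
the partner's z-plane). Per-type modifiers and spatial hotspot discs scale
ρ. Genes of planted pairs have their expected count floored at
`min_planted_rate` (default 3 per cell): a planted colocalization on a
gene present at ~1 copy per cell yields singleton cross-pairs (T ≈ 1)
that no binomial test can distinguish from background, so without the
floor "planted" would not mean detectable-in-principle. Discs rather than
arbitrary polygons keep region distances analytic for test oracles;
polygon handling is exercised separately. Reproducibility: one master
generator per dataset, with per-cell substreams spawned deterministically.

What the generator does **not** emulate: optical noise and barcode
misidentification (blanks here are pure background, whereas real blank
counts come from decoding errors), nuclear substructure, anisotropic or
z-dependent detection efficiency, irregular cell shapes, and segmentation
errors. Passing the planted-recovery and calibration tests therefore
demonstrates correctness of the statistics under their own model
assumptions, not robustness to imaging artifacts.

## Problem sizes in tests and the acceptance script

The calibration and power experiments run at desk scale, chosen to give
the relevant statistics clear signal: 200 uniform cells (20 genes,
~150 transcripts/cell) for PP calibration; 20 replicates of 50 cells for
CPB null rates; 200 cells / 50 genes / 10 planted pairs (ρ = 0.5,
σ = 0.5 μm, d = 2 μm) for recovery; 20 replicates of 200 cells for the
abundance confound; 400 cells and 21 pairs for the spatial scan; 200 cell
graphs for module mining. All randomness in the acceptance script derives
from its `--seed` argument.

## Known limitations

- The PP test is blind to pairs whose transcripts occur at ~1 copy per
  cell (T ≈ 1 admits no significant outcome), and discreteness makes it
  conservative at small T generally.
- The CPB prior is estimated from the same indicators it then tests;
  for genes with very small z the prior is noisy, which is the reason for
  the conservative all-cells convolution discussed above.
- The spatial-modulation threshold is a max over permutations, so its
  level depends on the number of pairs scanned and n_perm; it controls
  the family-wise error under exchangeability rather than a per-pair
  rate.
- Region annotation uses a single 2D polygon per cell for all z-planes.
- The RNA-RNA-interaction enrichment consumes precomputed interaction
  scores; computing such scores is out of scope.
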