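"""Synthetic single-molecule spatial transcriptomics data with known truth.

The generator emulates the data regimes of single-molecule imaging panels:
disc-shaped cells with a nucleus disc inside, heterogeneous per-cell
transcript counts (hundreds per cell, log-normal gene abundances), optional
multiple z-planes, blank (no-target) probes, planted proximal gene pairs,
cell types with per-type colocalization modifiers, and spatial hotspots
where a pair's colocalization is locally boosted.

A planted pair (a, b, rho, sigma) relocates a fraction ``rho`` of the rarer
gene's transcripts in each cell to a random transcript of the partner gene
plus an isotropic Gaussian displacement with scale ``sigma`` (micrometres),
on the partner's z-plane. Blanks are always background. Everything is
reproducible from the configured seed; each cell draws from its own
deterministically-spawned substream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .io import CellGeometry

logger = logging.getLogger("proximap")


@dataclass(frozen=True)
class PlantedPair:
    """A gene pair with engineered transcript-level colocalization."""

    gene_a: str
    gene_b: str
    rho: float = 0.5     # fraction of the rarer gene's transcripts relocated
    sigma: float = 0.5   # micrometres; Gaussian displacement scale
    region_bias: str | None = None  # "Nuc" places anchor transcripts in nucleus

    def __post_init__(self) -> None:
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must be in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class Hotspot:
    """A disc of tissue where planted pairs colocalize at a boosted rate."""

    x: float
    y: float
    radius: float
    rho_multiplier: float = 1.0
    pairs: tuple = ()  # pair names affected; empty = all planted pairs


@dataclass
class SimConfig:
    """Study conditions of a synthetic dataset.

    Defaults describe a desk-scale imaging panel: 200 cells of radius ~9 μm
    (nucleus ~4.5 μm) on a grid with 30 μm pitch, 50 genes of which 5 are
    blanks, ~250 transcripts per cell with log-normal gene abundances, a
    single z-plane. All rates and sizes are overridable per experiment.
    """

    n_cells: int = 200
    n_genes: int = 50
    n_blanks: int = 5
    mean_transcripts_per_cell: float = 250.0
    abundance_sigma: float = 0.7      # log-normal spread of per-gene rates
    cell_radius: tuple[float, float] = (9.0, 0.8)       # mean, sd (μm)
    nucleus_radius: tuple[float, float] = (4.5, 0.4)    # mean, sd (μm)
    grid_pitch: float = 30.0          # μm between neighboring cell centers
    n_zplanes: int = 1
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    cell_types: dict[str, float] | None = None          # label -> proportion
    type_modifiers: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    hotspots: list[Hotspot] = field(default_factory=list)
    blank_prefix: str = "Blank"
    abundance_multipliers: dict[str, float] = field(default_factory=dict)
    #: Expected per-cell count floor for genes of planted pairs. A planted
    #: colocalization needs transcripts to carry it: a gene drawn at ~1 copy
    #: per cell yields singleton cross-pairs (T ~ 1) that no binomial test
    #: can distinguish from background, so planted genes are kept expressed.
    min_planted_rate: float = 3.0
    seed: int = 0

    def gene_names(self) -> list[str]:
        n_real = self.n_genes - self.n_blanks
        names = [f"G{i:03d}" for i in range(1, n_real + 1)]
        names += [f"{self.blank_prefix}{i:02d}" for i in range(1, self.n_blanks + 1)]
        return names

    def validate(self) -> None:
        if self.n_blanks > self.n_genes:
            raise ValueError("n_blanks cannot exceed n_genes")
        if self.nucleus_radius[0] >= self.cell_radius[0]:
            raise ValueError("infeasible geometry: nucleus radius >= cell radius")
        if self.cell_types is not None:
            total = sum(self.cell_types.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValueError("cell type proportions must sum to 1")
        names = set(self.gene_names())
        for pp in self.planted_pairs:
            if pp.gene_a not in names or pp.gene_b not in names:
                raise ValueError(f"planted pair {pp.gene_a}-{pp.gene_b} not in panel")


@dataclass
class GroundTruth:
    """What was planted; serializable alongside the dataset."""

    planted_pairs: list[PlantedPair]
    cell_types: dict
    hotspot_cells: dict
    seed: int

    def planted_keys(self) -> set[tuple[str, str]]:
        return {
            tuple(sorted((p.gene_a, p.gene_b))) for p in self.planted_pairs
        }

    def to_json(self) -> str:
        doc = {
            "planted_pairs": [dataclasses.asdict(p) for p in self.planted_pairs],
            "cell_types": {str(k): v for k, v in self.cell_types.items()},
            "hotspot_cells": {str(k): v for k, v in self.hotspot_cells.items()},
            "seed": self.seed,
        }
        return json.dumps(doc, indent=2)


def _uniform_in_disc(rng, n, center, radius):
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)])


def simulate_dataset(cfg: SimConfig):
    """Generate one dataset.

    Returns ``(transcripts, geometry, meta, truth)``: the transcript table
    (canonical columns), per-cell :class:`CellGeometry` discs, cell metadata
    (cell_id, cell_type, centroids), and the ground truth.
    """
    cfg.validate()
    master = np.random.default_rng(cfg.seed)
    genes = cfg.gene_names()
    is_blank = np.array([g.startswith(cfg.blank_prefix) for g in genes])

    # Per-gene rates: log-normal, scaled so expected transcripts per cell match.
    rates = master.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=len(genes))
    for g, mult in cfg.abundance_multipliers.items():
        rates[genes.index(g)] *= mult
    rates *= cfg.mean_transcripts_per_cell / rates.sum()
    for pp in cfg.planted_pairs:
        for g in (pp.gene_a, pp.gene_b):
            gi = genes.index(g)
            rates[gi] = max(rates[gi], cfg.min_planted_rate)

    # Cell centers on a jittered grid.
    side = math.ceil(math.sqrt(cfg.n_cells))
    centers = np.array(
        [
            (
                (i % side) * cfg.grid_pitch + master.uniform(-2, 2),
                (i // side) * cfg.grid_pitch + master.uniform(-2, 2),
            )
            for i in range(cfg.n_cells)
        ]
    )

    # Cell types.
    if cfg.cell_types:
        labels = sorted(cfg.cell_types)
        probs = np.array([cfg.cell_types[t] for t in labels])
        type_of = master.choice(labels, size=cfg.n_cells, p=probs / probs.sum())
    else:
        type_of = np.array([None] * cfg.n_cells, dtype=object)

    planted_by_key = {
        tuple(sorted((p.gene_a, p.gene_b))): p for p in cfg.planted_pairs
    }
    hotspot_cells: dict[object, list[int]] = {}

    cell_rngs = master.spawn(cfg.n_cells)
    records = []
    geometry = {}
    meta_rows = []
    for c in range(cfg.n_cells):
        rng = cell_rngs[c]
        cid = f"cell{c:04d}"
        center = centers[c]
        r_cell = max(2.0, rng.normal(*cfg.cell_radius))
        r_nuc = min(
            max(0.5, rng.normal(*cfg.nucleus_radius)), 0.8 * r_cell
        )
        geometry[cid] = CellGeometry(
            cid,
            Point(center).buffer(r_cell, quad_segs=64),
            Point(center).buffer(r_nuc, quad_segs=64),
        )
        meta_rows.append(
            {
                "cell_id": cid,
                "cell_type": type_of[c],
                "centroid_x": center[0],
                "centroid_y": center[1],
            }
        )
        in_spots = [
            h
            for h in cfg.hotspots
            if (center[0] - h.x) ** 2 + (center[1] - h.y) ** 2 <= h.radius**2
        ]
        hotspot_cells[cid] = [cfg.hotspots.index(h) for h in in_spots]

        counts = rng.poisson(rates)
        xy: dict[str, np.ndarray] = {}
        zplane: dict[str, np.ndarray] = {}
        for gi, g in enumerate(genes):
            if counts[gi] == 0:
                continue
            xy[g] = _uniform_in_disc(rng, counts[gi], center, r_cell)
            zplane[g] = rng.integers(0, cfg.n_zplanes, size=counts[gi])

        # Planted colocalization: relocate a fraction of the rarer gene's
        # transcripts near random partner transcripts (same z-plane).
        for key, pp in planted_by_key.items():
            a, b = key
            if a not in xy or b not in xy or is_blank[genes.index(a)] or is_blank[genes.index(b)]:
                continue
            rho = pp.rho
            t = type_of[c]
            if t is not None and t in cfg.type_modifiers:
                rho *= cfg.type_modifiers[t].get(key, 1.0)
            for h in in_spots:
                if not h.pairs or key in {tuple(sorted(p)) for p in h.pairs}:
                    rho *= h.rho_multiplier
            rho = min(rho, 1.0)
            if rho <= 0:
                continue
            rare, anchor = (a, b) if len(xy[a]) <= len(xy[b]) else (b, a)
            if pp.region_bias == "Nuc":
                # Anchor transcripts biased into the nucleus disc.
                xy[anchor] = _uniform_in_disc(rng, len(xy[anchor]), center, r_nuc)
            n_move = rng.binomial(len(xy[rare]), rho)
            if n_move == 0:
                continue
            move_idx = rng.choice(len(xy[rare]), size=n_move, replace=False)
            partner_idx = rng.integers(0, len(xy[anchor]), size=n_move)
            for mi, pi in zip(move_idx, partner_idx):
                for _ in range(20):
                    pos = xy[anchor][pi] + rng.normal(0.0, pp.sigma, size=2)
                    if np.hypot(*(pos - center)) <= r_cell:
                        break
                else:
                    pos = xy[anchor][pi]
                xy[rare][mi] = pos
                zplane[rare][mi] = zplane[anchor][pi]

        for g in genes:
            if g not in xy:
                continue
            for (px, py), z in zip(xy[g], zplane[g]):
                records.append((cid, g, px, py, int(z)))

    transcripts = pd.DataFrame(records, columns=["cell", "gene", "x", "y", "z"])
    meta = pd.DataFrame(meta_rows)
    truth = GroundTruth(
        planted_pairs=list(cfg.planted_pairs),
        cell_types={row["cell_id"]: row["cell_type"] for row in meta_rows},
        hotspot_cells=hotspot_cells,
        seed=cfg.seed,
    )
    return transcripts, geometry, meta, truth


def geometry_to_geojson(geometry: dict[object, CellGeometry]) -> str:
    """Serialize cell geometries to a GeoJSON FeatureCollection string."""
    features = []
    for cid, geom in geometry.items():
        for role, poly in (
            ("cell", geom.cell_boundary),
            ("nucleus", geom.nucleus_boundary),
        ):
            features.append(
                {
                    "type": "Feature",
                    "properties": {"cell_id": cid, "role": role},
                    "geometry": poly.__geo_interface__,
                }
            )
    return json.dumps({"type": "FeatureCollection", "features": features})


def sweep_power(
    cfg_grid: list[SimConfig],
    d: float,
    alpha_pp: float = 0.01,
    alpha_cpb: float = 1e-3,
    permutation_seed_offset: int = 10_000,
) -> pd.DataFrame:
    """Power/FPR table over a grid of simulation configs.

    For each config: fraction of planted pairs detected by the conditional
    aggregation test at ``alpha_cpb``, the blank-involving fraction of
    detections, and the permutation FPR at the same threshold.
    """
    from .colocalization import blank_probe_fpr, cpb_test, estimate_fpr
    from .io import blank_genes, permute_gene_labels
    from .proximal_pairs import PPConfig, pp_test_dataset

    rows = []
    for cfg in cfg_grid:
        transcripts, _, _, truth = simulate_dataset(cfg)
        mode = "3d" if cfg.n_zplanes > 1 else "2d"
        pp_cfg = PPConfig(d=d, mode=mode, alpha_pp=alpha_pp)
        ind, _ = pp_test_dataset(transcripts, pp_cfg)
        gmap = cpb_test(ind)
        perm = permute_gene_labels(transcripts, seed=cfg.seed + permutation_seed_offset)
        ind_perm, _ = pp_test_dataset(perm, pp_cfg)
        gmap_perm = cpb_test(ind_perm)
        fpr = estimate_fpr(gmap, gmap_perm, [alpha_cpb]).iloc[0]
        blanks = blank_genes(cfg.gene_names(), cfg.blank_prefix)
        obs_blank, exp_blank = blank_probe_fpr(gmap, blanks, alpha_cpb)

        planted = truth.planted_keys()
        detected = {
            tuple(sorted((a, b)))
            for a, b, p in zip(gmap["gene_a"], gmap["gene_b"], gmap["pvalue"])
            if p < alpha_cpb
        }
        power = (
            len(planted & detected) / len(planted) if planted else float("nan")
        )
        rows.append(
            {
                "seed": cfg.seed,
                "n_cells": cfg.n_cells,
                "n_genes": cfg.n_genes,
                "n_planted": len(planted),
                "power": power,
                "n_detected": len(detected),
                "fpr_permutation": fpr["fpr"],
                "blank_fraction_observed": obs_blank,
                "blank_fraction_expected": exp_blank,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "seed", "n_cells", "n_genes", "n_planted", "power", "n_detected",
            "fpr_permutation", "blank_fraction_observed", "blank_fraction_expected",
        ],
    )
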