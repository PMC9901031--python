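"""End-to-end workflow: (simulate | load) -> PP -> aggregation -> context -> modules.

One YAML/dict config drives the whole run; every intermediate is written as
a TSV with a commented parameter header, and a machine-readable manifest
records parameters, seeds, package version and per-artifact checksums so a
re-run with the same config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .colocalization import annotate_map, blank_probe_fpr, cpb_test, estimate_fpr, rank_map
from .context import build_neighbor_graph, categorize_map, celltype_association, spatial_modulation_scan
from .io import (
    AnnotationConfig,
    assign_regions,
    blank_genes,
    filter_cells,
    load_cell_meta,
    load_geometry,
    load_transcripts,
    permute_gene_labels,
    write_tsv,
)
from .modules import cell_graphs_from_pp, fsm_mine, gcc_cluster
from .proximal_pairs import PPConfig, pp_test_dataset
from .simulate import Hotspot, PlantedPair, SimConfig, geometry_to_geojson, simulate_dataset

logger = logging.getLogger("proximap")


class ConfigError(ValueError):
    """The run configuration is missing or malforms a required field."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


_DEFAULTS = {
    "mode": "2d",
    "alpha_pp": 0.01,
    "alpha_cpb": 1e-3,
    "min_per_plane": 0,
    "min_total": 0,
    "radius": 100.0,
    "n_perm": 10,
    "seed": 0,
    "blank_prefix": "Blank",
    "gcc": {"n_clusters": 4, "min_density": 0.7},
    "fsm": {"edge_alpha": 0.05, "min_nodes": 3, "min_support": 2, "clique_only": True},
}


def load_run_config(path) -> dict:
    """Load and minimally validate a YAML run config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_run_config(cfg)


def validate_run_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ConfigError("run config must be a mapping")
    if "d" not in cfg:
        raise ConfigError("missing required config field 'd'")
    if "simulate" not in cfg and "input" not in cfg:
        raise ConfigError("config needs a 'simulate' block or an 'input' block")
    merged = {**_DEFAULTS, **cfg}
    for key in ("gcc", "fsm"):
        merged[key] = {**_DEFAULTS[key], **(cfg.get(key) or {})}
    return merged


def _sim_config_from_block(block: dict, seed: int) -> SimConfig:
    block = dict(block)
    planted = [
        PlantedPair(*p) if isinstance(p, (list, tuple)) else PlantedPair(**p)
        for p in block.pop("planted_pairs", [])
    ]
    hotspots = [
        Hotspot(**h) if isinstance(h, dict) else Hotspot(*h)
        for h in block.pop("hotspots", [])
    ]
    block.setdefault("seed", seed)
    return SimConfig(planted_pairs=planted, hotspots=hotspots, **block)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: dict, out_dir) -> dict:
    """Execute the full workflow and write all artifacts under ``out_dir``.

    Returns the manifest dict. Stage failures raise :class:`StageError`
    naming the stage; artifacts written before the failure are retained.
    """
    cfg = validate_run_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    params = {k: v for k, v in cfg.items() if k not in ("simulate", "input")}
    artifacts: list[Path] = []
    stage = "setup"

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        write_tsv(df, path, {"stage": stage, "seed": seed, "d": cfg["d"]})
        artifacts.append(path)

    try:
        stage = "data"
        geometry = None
        meta = None
        if "simulate" in cfg:
            sim_cfg = _sim_config_from_block(cfg["simulate"], seed)
            transcripts, geometry, meta, truth = simulate_dataset(sim_cfg)
            (out / "transcripts.csv").write_text(transcripts.to_csv(index=False))
            (out / "cells.geojson").write_text(geometry_to_geojson(geometry))
            meta.to_csv(out / "cells_meta.csv", index=False)
            (out / "truth.json").write_text(truth.to_json())
            artifacts += [
                out / "transcripts.csv", out / "cells.geojson",
                out / "cells_meta.csv", out / "truth.json",
            ]
        else:
            paths = cfg["input"]
            transcripts = load_transcripts(
                paths["transcripts"], columns=paths.get("columns")
            )
            if "geometry" in paths:
                geometry = load_geometry(paths["geometry"])
            if "meta" in paths:
                meta = load_cell_meta(paths["meta"])

        stage = "filter"
        transcripts = filter_cells(
            transcripts, cfg["min_per_plane"], cfg["min_total"]
        )

        stage = "regions"
        if geometry is not None:
            ann = cfg.get("annotation") or {}
            transcripts = assign_regions(
                transcripts, geometry, AnnotationConfig(**ann)
            )

        stage = "pp"
        pp_cfg = PPConfig(
            d=float(cfg["d"]), mode=cfg["mode"], alpha_pp=float(cfg["alpha_pp"])
        )
        ind, pp_results = pp_test_dataset(transcripts, pp_cfg)
        emit(pp_results, "pp_results.tsv")
        emit(ind.to_frame(), "indicators.tsv")

        stage = "cpb"
        gmap = cpb_test(ind)
        if geometry is not None:
            gmap = annotate_map(gmap, pp_results)
        gmap = rank_map(gmap)
        emit(gmap, "map.tsv")

        stage = "fpr"
        permuted = permute_gene_labels(transcripts, seed=seed + 1)
        ind_perm, _ = pp_test_dataset(permuted, pp_cfg)
        gmap_perm = cpb_test(ind_perm)
        fpr = estimate_fpr(
            gmap, gmap_perm, [float(cfg["alpha_cpb"]), 1e-4, 1e-5]
        )
        blanks = blank_genes(ind.genes, cfg["blank_prefix"])
        if blanks:
            obs, exp = blank_probe_fpr(gmap, blanks, float(cfg["alpha_cpb"]))
            fpr["blank_fraction_observed"] = obs
            fpr["blank_fraction_expected"] = exp
        emit(fpr, "fpr.tsv")

        has_types = meta is not None and meta.get("cell_type") is not None \
            and meta["cell_type"].notna().all()
        if has_types:
            stage = "celltype"
            categories = categorize_map(
                gmap, ind, transcripts, meta, alpha_map=float(cfg["alpha_cpb"])
            )
            emit(categories, "categories.tsv")

        if meta is not None and {"centroid_x", "centroid_y"} <= set(meta.columns):
            stage = "spatial"
            graph = build_neighbor_graph(meta, radius=float(cfg["radius"]))
            assoc = celltype_association(ind, meta) if has_types else None
            spatial = spatial_modulation_scan(
                ind, gmap, graph,
                n_perm=int(cfg["n_perm"]), seed=seed + 2,
                alpha_map=float(cfg["alpha_cpb"]), assoc=assoc,
            )
            emit(spatial, "spatial.tsv")

        stage = "gcc"
        gcc_modules = gcc_cluster(
            gmap,
            n_clusters=int(cfg["gcc"]["n_clusters"]),
            min_density=float(cfg["gcc"]["min_density"]),
            alpha=float(cfg["alpha_cpb"]),
        )
        emit(
            pd.DataFrame(
                [
                    {
                        "module_id": m.module_id,
                        "genes": ",".join(m.genes),
                        "density": m.density,
                        "region": m.region,
                    }
                    for m in gcc_modules
                ],
                columns=["module_id", "genes", "density", "region"],
            ),
            "gcc_modules.tsv",
        )

        stage = "fsm"
        graphs = cell_graphs_from_pp(
            pp_results, edge_alpha=float(cfg["fsm"]["edge_alpha"])
        )
        fsm_modules = fsm_mine(
            graphs,
            min_nodes=int(cfg["fsm"]["min_nodes"]),
            min_support=int(cfg["fsm"]["min_support"]),
            clique_only=bool(cfg["fsm"]["clique_only"]),
        )
        emit(
            pd.DataFrame(
                [
                    {
                        "module_id": m.module_id,
                        "genes": ",".join(m.genes),
                        "support": m.support,
                        "n_edges": len(m.edges),
                    }
                    for m in fsm_modules
                ],
                columns=["module_id", "genes", "support", "n_edges"],
            ),
            "fsm_modules.tsv",
        )
    except (ConfigError, StageError):
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": seed,
        "parameters": params,
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("run_pipeline: wrote %d artifacts to %s", len(artifacts), out)
    return manifest
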