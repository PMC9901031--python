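"""Shared fixtures: hand-built cells, circle geometry, small simulated datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from proximap import CellGeometry, PPConfig, SimConfig, simulate_dataset


@pytest.fixture
def worked_cell() -> pd.DataFrame:
    """The four-transcript cell used in the hand derivations.

    Gene A at (0,0) and (1,0); gene B at (0.5,0) and (10,10). At d=1:
    3 of 6 transcript pairs are proximal (p_null = 0.5); the cross-gene
    pairs (0,0)-(0.5,0) and (1,0)-(0.5,0) are proximal (K = 2, T = 4).
    """
    return pd.DataFrame(
        {
            "cell": ["c1"] * 4,
            "gene": ["A", "A", "B", "B"],
            "x": [0.0, 1.0, 0.5, 10.0],
            "y": [0.0, 0.0, 0.0, 10.0],
            "z": [0, 0, 0, 0],
        }
    )


@pytest.fixture
def circle_geometry() -> dict:
    """Nucleus = circle r=5 at origin inside cell = circle r=12.

    Distances to the two boundary circles are analytic, so region labels
    for test points can be derived by hand.
    """
    return {
        "c1": CellGeometry(
            "c1",
            Point(0, 0).buffer(12, quad_segs=256),
            Point(0, 0).buffer(5, quad_segs=256),
        )
    }


@pytest.fixture(scope="session")
def null_dataset():
    """200 uniform-transcript cells with no planted structure (calibration)."""
    cfg = SimConfig(
        n_cells=200,
        n_genes=20,
        n_blanks=0,
        mean_transcripts_per_cell=150.0,
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_dataset():
    """200 cells, 50 genes, 10 planted proximal pairs (rho=0.5, sigma=0.5)."""
    planted = [
        (f"G{2 * i + 1:03d}", f"G{2 * i + 2:03d}") for i in range(10)
    ]
    from proximap import PlantedPair

    cfg = SimConfig(
        n_cells=200,
        n_genes=50,
        n_blanks=5,
        mean_transcripts_per_cell=250.0,
        planted_pairs=[PlantedPair(a, b, rho=0.5, sigma=0.5) for a, b in planted],
        seed=29,
    )
    return simulate_dataset(cfg), planted


@pytest.fixture
def pp_cfg_d2() -> PPConfig:
    return PPConfig(d=2.0, mode="2d", alpha_pp=0.01)


def random_cell(rng, n, n_genes=5, extent=10.0):
    """Uniform random labelled coordinates for oracle-equivalence tests."""
    coords = rng.uniform(0, extent, size=(n, 2))
    genes = rng.choice([f"g{i}" for i in range(n_genes)], size=n).astype(object)
    return coords, genes
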