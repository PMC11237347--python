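"""Shared fixtures: tiny hand-built communities and seeded synthetic data."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import streamofd as s


def make_unit(reach, season, idx, taxa):
    return s.SampleUnit(reach, season, idx, taxa)


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition synthetic dataset (seeded)."""
    cfg = s.SimConfig(seed=11)
    return cfg, s.generate_community(cfg)


@pytest.fixture(scope="session")
def default_traits():
    cfg = s.SimConfig(seed=11)
    return cfg, s.generate_traits(cfg)


@pytest.fixture()
def tiny_community():
    """2 reaches x 4 seasons x 2 units, 4 taxa; small enough to reason about."""
    seasons = s.io.DEFAULT_SEASONS
    units = []
    for reach in ("R1", "R2"):
        for season in seasons:
            units.append(make_unit(reach, season, 1, {"ubiq": 2, "rare": 1}))
            units.append(make_unit(reach, season, 2, {"ubiq": 1, "mid": 3}))
    hierarchy = s.SiteHierarchy(
        subbasin_of={"R1": "S1", "R2": "S1"},
        basin_of={"R1": "B1", "R2": "B1"},
    )
    return s.CommunityData(units, hierarchy)


@pytest.fixture()
def toy_traits():
    """Six taxa, two traits; trait_a separates the two 3-taxa families."""
    data = pd.DataFrame(
        {
            "trait_a.x": [3, 3, 2, 0, 0, 0],
            "trait_a.y": [0, 0, 1, 3, 3, 3],
            "trait_b.u": [1, 2, 1, 1, 2, 1],
            "trait_b.v": [2, 1, 2, 2, 1, 2],
        },
        index=[f"t{i}" for i in range(6)],
        dtype=float,
    )
    taxonomy = pd.DataFrame(
        {
            "genus": ["g1", "g1", "g2", "g3", "g3", "g4"],
            "family": ["fA", "fA", "fA", "fB", "fB", "fB"],
            "superfamily": ["sf"] * 6,
        },
        index=data.index,
    )
    return s.TraitMatrix(data=data, taxonomy=taxonomy, standardized=False)


def build_srs(presence: np.ndarray, taxon_ids: tuple[str, ...], extent="reach",
              block="R1", index=0) -> s.SRS:
    """Construct an SRS directly from a boolean (n_ars, n_taxa) matrix."""
    seasons = s.io.DEFAULT_SEASONS
    ars_list = tuple(
        s.ARS(
            presence=row.astype(bool),
            reach_id=block,
            draws=tuple((season, 1) for season in seasons),
            taxon_ids=taxon_ids,
        )
        for row in presence
    )
    return s.SRS(extent=extent, block=block, ars_list=ars_list, index=index)
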