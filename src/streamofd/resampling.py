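"""Nested spatial resampling into annually/spatially representative samples.

An ARS (annually representative sample) pools one randomly chosen elementary
sample unit per season from one reach, i.e. an annual snapshot of that reach.
An SRS (spatially representative sample) is a fixed-size collection of ARSs
at one of four nested extents:

========  ==============================  ====
extent    composition                     ARSs
========  ==============================  ====
reach     16 ARSs from 1 reach            16
subbasin  5 ARSs from each of 3 reaches   15
basin     4 ARSs from each of 4 reaches   16
region    2 ARSs from each of 8 reaches   16
========  ==============================  ====

ARSs poorer than a richness threshold (default 10 taxa) are redrawn from the
same reach up to an attempt cap and finally dropped, because sparse samples
do not support a reliable occupancy distribution. Sampling is with
replacement throughout; ensembles use per-(extent, index) substreams of a
master seed so results are order-independent and reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .io import EXTENTS, CommunityData, SiteHierarchy

logger = logging.getLogger("streamofd")

#: Number of ARSs each extent's SRS must contain (before richness drops).
ARS_COUNTS: Mapping[str, int] = {"reach": 16, "subbasin": 15, "basin": 16, "region": 16}

#: ARSs drawn per member reach at each extent.
ARS_PER_REACH: Mapping[str, int] = {"reach": 16, "subbasin": 5, "basin": 4, "region": 2}


@dataclass(frozen=True)
class ResamplingConfig:
    """Knobs of the resampling stage.

    ``min_ars_richness`` discards ARSs with fewer taxa; ``redraw`` replaces a
    discarded ARS from the same reach (up to ``max_attempts``) so SRS size
    stays fixed; with ``redraw=False`` the SRS simply shrinks.
    """

    n_srs: int = 10_000
    min_ars_richness: int = 10
    max_attempts: int = 100
    redraw: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_srs < 1:
            raise ValueError("n_srs must be >= 1")
        if self.min_ars_richness < 0:
            raise ValueError("min_ars_richness must be >= 0")


@dataclass(frozen=True)
class ARS:
    """Annually representative sample: union of one unit per season."""

    presence: np.ndarray  # bool over PresenceCube taxon order
    reach_id: str
    draws: tuple[tuple[str, int], ...]  # (season, unit_index) per season
    taxon_ids: tuple[str, ...] = field(repr=False)

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(np.asarray(self.taxon_ids)[self.presence])

    @property
    def richness(self) -> int:
        return int(self.presence.sum())


@dataclass(frozen=True)
class SRS:
    """Spatially representative sample: ordered ARSs at one extent."""

    extent: str
    block: str
    ars_list: tuple[ARS, ...]
    index: int = -1
    shortfall: int = 0  # ARSs dropped after exhausting redraw attempts

    @property
    def n_ars(self) -> int:
        return len(self.ars_list)

    def presence_matrix(self) -> np.ndarray:
        """(n_ars, n_taxa) boolean stack of the ARS presence vectors."""
        return np.stack([a.presence for a in self.ars_list])

    @property
    def taxon_ids(self) -> tuple[str, ...]:
        return self.ars_list[0].taxon_ids


class PresenceCube:
    """Dense presence view of a community for fast repeated ARS drawing."""

    def __init__(self, community: CommunityData):
        self.taxon_ids: tuple[str, ...] = community.taxon_ids
        self.seasons = community.seasons
        self.hierarchy: SiteHierarchy = community.hierarchy
        tindex = {t: i for i, t in enumerate(self.taxon_ids)}
        n_units = community.units_per_cell
        self.unit_index_of: dict[tuple[str, str], list[int]] = {}
        self._cube: dict[str, np.ndarray] = {
            r: np.zeros((len(self.seasons), n_units, len(self.taxon_ids)), dtype=bool)
            for r in community.reaches
        }
        slot: dict[tuple[str, str], int] = {}
        for u in sorted(community.units, key=lambda u: (u.reach_id, u.season, u.unit_index)):
            s = self.seasons.index(u.season)
            j = slot.setdefault((u.reach_id, u.season), 0)
            slot[(u.reach_id, u.season)] = j + 1
            self.unit_index_of.setdefault((u.reach_id, u.season), []).append(u.unit_index)
            row = self._cube[u.reach_id][s, j]
            for t, n in u.taxa.items():
                if n > 0:
                    row[tindex[t]] = True
        for (r, s), filled in slot.items():
            if filled != n_units:
                raise ValueError(f"reach {r}, season {s}: {filled} units, expected {n_units}")

    @property
    def n_units(self) -> int:
        return next(iter(self._cube.values())).shape[1]

    def reach_block(self, reach_id: str) -> np.ndarray:
        return self._cube[reach_id]


def draw_ars(cube: PresenceCube, reach_id: str, rng: np.random.Generator) -> ARS:
    """Draw one ARS: one uniformly chosen unit per season, presence pooled."""
    block = cube.reach_block(reach_id)
    n_seasons, n_units, _ = block.shape
    picks = rng.integers(0, n_units, size=n_seasons)
    presence = block[np.arange(n_seasons), picks].any(axis=0)
    draws = tuple(
        (season, cube.unit_index_of[(reach_id, season)][int(j)])
        for season, j in zip(cube.seasons, picks)
    )
    return ARS(presence=presence, reach_id=reach_id, draws=draws, taxon_ids=cube.taxon_ids)


def _draw_filtered(
    cube: PresenceCube,
    reach_id: str,
    config: ResamplingConfig,
    rng: np.random.Generator,
) -> ARS | None:
    """Draw an ARS honoring the richness filter; None when finally dropped."""
    ars = draw_ars(cube, reach_id, rng)
    if ars.richness >= config.min_ars_richness:
        return ars
    if config.redraw:
        for _ in range(config.max_attempts - 1):
            ars = draw_ars(cube, reach_id, rng)
            if ars.richness >= config.min_ars_richness:
                return ars
    return None


def srs_plan(extent: str, hierarchy: SiteHierarchy, rng: np.random.Generator) -> tuple[str, list[str]]:
    """Pick the spatial block for one SRS and list the reaches to draw from."""
    if extent not in EXTENTS:
        raise ValueError(f"unknown extent {extent!r}")
    blocks = hierarchy.blocks(extent)
    block = blocks[int(rng.integers(0, len(blocks)))]
    members = hierarchy.members(extent, block)
    per = ARS_PER_REACH[extent]
    return block, [r for r in members for _ in range(per)]


def draw_srs(
    cube: PresenceCube,
    extent: str,
    config: ResamplingConfig,
    rng: np.random.Generator,
    index: int = -1,
) -> SRS | None:
    """Draw one SRS at *extent*; None if a member reach yields no usable ARS."""
    block, reach_plan = srs_plan(extent, cube.hierarchy, rng)
    kept: list[ARS] = []
    dropped_by_reach: dict[str, int] = {}
    for reach_id in reach_plan:
        ars = _draw_filtered(cube, reach_id, config, rng)
        if ars is None:
            dropped_by_reach[reach_id] = dropped_by_reach.get(reach_id, 0) + 1
        else:
            kept.append(ars)
    shortfall = sum(dropped_by_reach.values())
    planned = {r: reach_plan.count(r) for r in set(reach_plan)}
    if any(dropped_by_reach.get(r, 0) == planned[r] for r in planned):
        logger.warning(
            "SRS %d (%s/%s) rejected: a member reach produced no ARS of >= %d taxa",
            index, extent, block, config.min_ars_richness,
        )
        return None
    if shortfall:
        logger.info("SRS %d (%s/%s): %d ARSs dropped for low richness",
                    index, extent, block, shortfall)
    return SRS(extent=extent, block=block, ars_list=tuple(kept), index=index,
               shortfall=shortfall)


def _substream(seed: int, extent: str, i: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([seed, EXTENTS.index(extent), i]))
    )


def generate_ensemble(
    community: CommunityData | PresenceCube,
    extent: str,
    config: ResamplingConfig,
) -> Iterator[SRS]:
    """Yield ``config.n_srs`` SRSs at *extent* (rejected SRSs are skipped).

    SRS *i* depends only on (master seed, extent, i), so ensembles are
    reproducible and order-independent.
    """
    cube = community if isinstance(community, PresenceCube) else PresenceCube(community)
    rejected = 0
    for i in range(config.n_srs):
        srs = draw_srs(cube, extent, config, _substream(config.seed, extent, i), index=i)
        if srs is None:
            rejected += 1
            continue
        yield srs
    if rejected:
        logger.warning("%d of %d %s-extent SRSs rejected", rejected, config.n_srs, extent)


def provenance_table(srss: list[SRS]) -> "pd.DataFrame":  # noqa: F821
    """One row per ARS: srs_index, extent, block, reach, per-season units, richness."""
    import pandas as pd

    rows = []
    for srs in srss:
        for a in srs.ars_list:
            row: dict[str, object] = {
                "srs_index": srs.index, "extent": srs.extent,
                "block": srs.block, "reach": a.reach_id,
            }
            for season, unit in a.draws:
                row[f"{season}_unit"] = unit
            row["richness"] = a.richness
            rows.append(row)
    return pd.DataFrame(rows)
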