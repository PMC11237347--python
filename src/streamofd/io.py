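"""Core domain types and tabular I/O for the occupancy analysis pipeline.

The pipeline works on a nested stream-survey design: elementary sample
units (kick-net samples) collected repeatedly over the seasons of one year
from stream reaches that nest into subbasins, basins and one region.
Everything downstream of I/O uses presence/absence only; abundances are
retained for reporting totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("streamofd")

#: Ordered season labels of the default annual design.
DEFAULT_SEASONS: tuple[str, ...] = ("spring", "summer", "autumn", "winter")

#: Spatial extents from smallest to largest.
EXTENTS: tuple[str, ...] = ("reach", "subbasin", "basin", "region")

#: Default community-table column names.
DEFAULT_SCHEMA: Mapping[str, str] = {
    "reach": "reach",
    "season": "season",
    "unit": "unit",
    "taxon": "taxon",
    "abundance": "abundance",
}

TAXONOMY_LEVELS: tuple[str, ...] = ("genus", "family", "superfamily")


class SchemaError(ValueError):
    """A required column is missing or mislabelled."""


class ParseError(ValueError):
    """A cell cannot be interpreted (e.g. non-integer abundance)."""


class ValidationError(ValueError):
    """Parsed data violate a structural invariant."""


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)


def _delim_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleUnit:
    """One elementary sample unit: the taxa found in a single kick-net sample."""

    reach_id: str
    season: str
    unit_index: int
    taxa: Mapping[str, int]

    def __post_init__(self) -> None:
        for taxon, n in self.taxa.items():
            if n < 0:
                raise ValidationError(f"negative abundance for {taxon!r}: {n}")

    @property
    def presence(self) -> frozenset[str]:
        return frozenset(t for t, n in self.taxa.items() if n > 0)


@dataclass(frozen=True)
class SiteHierarchy:
    """Mapping of stream reaches into subbasins, basins and one region.

    ``subbasin_of`` may omit reaches that do not belong to any subbasin (in
    the default design only 6 of the 8 reaches fall in the two subbasins).
    """

    subbasin_of: Mapping[str, str]
    basin_of: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = set(self.subbasin_of) - set(self.basin_of)
        if missing:
            raise ValidationError(f"reaches with subbasin but no basin: {sorted(missing)}")

    @property
    def reaches(self) -> tuple[str, ...]:
        return tuple(sorted(self.basin_of))

    def blocks(self, extent: str) -> tuple[str, ...]:
        """Names of the selectable spatial blocks at *extent*."""
        if extent == "reach":
            return self.reaches
        if extent == "subbasin":
            return tuple(sorted(set(self.subbasin_of.values())))
        if extent == "basin":
            return tuple(sorted(set(self.basin_of.values())))
        if extent == "region":
            return ("region",)
        raise ValueError(f"unknown extent {extent!r}")

    def members(self, extent: str, block: str) -> tuple[str, ...]:
        """Reaches belonging to *block* at *extent* (sorted, deterministic)."""
        if extent == "reach":
            return (block,)
        if extent == "subbasin":
            return tuple(sorted(r for r, s in self.subbasin_of.items() if s == block))
        if extent == "basin":
            return tuple(sorted(r for r, b in self.basin_of.items() if b == block))
        if extent == "region":
            return self.reaches
        raise ValueError(f"unknown extent {extent!r}")


@dataclass
class CommunityData:
    """All sample units of a survey plus the site hierarchy and taxon registry."""

    units: list[SampleUnit]
    hierarchy: SiteHierarchy
    taxa: dict[str, str] = field(default_factory=dict)  # taxon_id -> display name
    groups: dict[str, str] = field(default_factory=dict)  # taxon_id -> dispersal group
    seasons: tuple[str, ...] = DEFAULT_SEASONS

    def __post_init__(self) -> None:
        if not self.units:
            raise ValidationError("community has no sample units")
        for u in self.units:
            if u.season not in self.seasons:
                raise ValidationError(
                    f"unknown season {u.season!r}; expected one of {self.seasons}"
                )
        if not self.taxa:
            ids = sorted({t for u in self.units for t in u.taxa})
            self.taxa = {t: t for t in ids}
        unknown = {t for u in self.units for t in u.taxa} - set(self.taxa)
        if unknown:
            raise ValidationError(f"taxa absent from the registry: {sorted(unknown)[:5]}")
        counts: dict[tuple[str, str], set[int]] = {}
        for u in self.units:
            key = (u.reach_id, u.season)
            idxs = counts.setdefault(key, set())
            if u.unit_index in idxs:
                raise ValidationError(f"duplicate unit {u.unit_index} in {key}")
            idxs.add(u.unit_index)
        sizes = {len(v) for v in counts.values()}
        if len(sizes) > 1:
            raise ValidationError(
                f"unequal unit counts across (reach, season) cells: {sorted(sizes)}"
            )
        self._units_per_cell = sizes.pop()

    @property
    def reaches(self) -> tuple[str, ...]:
        return self.hierarchy.reaches

    @property
    def units_per_cell(self) -> int:
        return self._units_per_cell

    @property
    def taxon_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.taxa))

    def exclude_taxa(self, excluded: Iterable[str]) -> "CommunityData":
        """Return a copy with *excluded* taxa removed from units and registry."""
        drop = set(excluded)
        units = [
            SampleUnit(
                u.reach_id,
                u.season,
                u.unit_index,
                {t: n for t, n in u.taxa.items() if t not in drop},
            )
            for u in self.units
        ]
        return CommunityData(
            units,
            self.hierarchy,
            {t: n for t, n in self.taxa.items() if t not in drop},
            {t: g for t, g in self.groups.items() if t not in drop},
            self.seasons,
        )


@dataclass
class TraitMatrix:
    """Taxa x trait-category affinities with a taxonomy for imputation.

    Columns of ``data`` are dotted ``trait.category`` labels; raw fuzzy codes
    are integers in {0..3}, standardized values are proportions in [0, 1].
    Missing cells are NaN. A whole trait is *missing* for a taxon when any of
    its categories is NaN or (raw codes only) when all of them are zero.
    """

    data: pd.DataFrame
    taxonomy: pd.DataFrame
    standardized: bool = False

    def __post_init__(self) -> None:
        bad = [c for c in self.data.columns if "." not in c]
        if bad:
            raise SchemaError(f"trait columns must be 'trait.category': {bad}")
        if not self.standardized:
            vals = self.data.to_numpy(dtype=float)
            ok = np.isnan(vals) | np.isin(vals, [0.0, 1.0, 2.0, 3.0])
            if not ok.all():
                where = self.data.columns[np.where(~ok)[1][0]]
                raise ValidationError(f"fuzzy codes must be in {{0,1,2,3}} (column {where})")

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def traits(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.data.columns:
            seen.setdefault(c.split(".", 1)[0])
        return tuple(seen)

    def categories_of(self, trait: str) -> list[str]:
        return [c for c in self.data.columns if c.split(".", 1)[0] == trait]

    def missing_mask(self) -> pd.DataFrame:
        """Boolean taxa x traits frame; True where the trait is missing."""
        out = {}
        for trait in self.traits:
            block = self.data[self.categories_of(trait)]
            miss = block.isna().any(axis=1)
            if not self.standardized:
                miss |= (block.fillna(0) == 0).all(axis=1)
            out[trait] = miss
        return pd.DataFrame(out, index=self.data.index)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_community(
    path: str | Path,
    schema: Mapping[str, str] = DEFAULT_SCHEMA,
    hierarchy: SiteHierarchy | None = None,
    seasons: Sequence[str] = DEFAULT_SEASONS,
    exclude: Iterable[str] = (),
) -> CommunityData:
    """Read a long-format community table (one row per reach/season/unit/taxon).

    Duplicate (reach, season, unit, taxon) rows are summed. If *hierarchy* is
    None a degenerate hierarchy (every reach its own subbasin/basin) is built.
    """
    df = _read_delimited(path)
    if df.empty:
        raise ParseError(f"empty community table: {path}")
    missing = [v for v in schema.values() if v not in df.columns]
    if missing:
        raise SchemaError(f"missing columns {missing} in {path}")
    df = df.rename(columns={v: k for k, v in schema.items()})
    try:
        df["abundance"] = df["abundance"].astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric abundance in {path}: {exc}") from None
    if not (df["abundance"] % 1 == 0).all():
        raise ParseError(f"non-integer abundance in {path}")
    df["abundance"] = df["abundance"].astype(int)
    try:
        df["unit"] = df["unit"].astype(int)
    except ValueError as exc:
        raise ParseError(f"non-integer unit index in {path}: {exc}") from None

    grouped = (
        df.groupby(["reach", "season", "unit", "taxon"], sort=True)["abundance"]
        .sum()
        .reset_index()
    )
    units: dict[tuple[str, str, int], dict[str, int]] = {}
    for row in grouped.itertuples(index=False):
        units.setdefault((row.reach, row.season, row.unit), {})[row.taxon] = row.abundance
    sample_units = [
        SampleUnit(r, s, i, taxa) for (r, s, i), taxa in sorted(units.items())
    ]
    if hierarchy is None:
        reaches = sorted({u.reach_id for u in sample_units})
        hierarchy = SiteHierarchy(
            subbasin_of={r: f"sb_{r}" for r in reaches},
            basin_of={r: f"b_{r}" for r in reaches},
        )
    community = CommunityData(sample_units, hierarchy, seasons=tuple(seasons))
    if exclude:
        community = community.exclude_taxa(exclude)
    return community


def read_hierarchy(path: str | Path) -> SiteHierarchy:
    """Read a ``reach,subbasin,basin`` table; blank subbasin = not in any subbasin."""
    df = _read_delimited(path)
    for col in ("reach", "subbasin", "basin"):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} in {path}")
    sub = {
        r.reach: r.subbasin
        for r in df.itertuples(index=False)
        if isinstance(r.subbasin, str) and r.subbasin
    }
    basin = {r.reach: r.basin for r in df.itertuples(index=False)}
    return SiteHierarchy(subbasin_of=sub, basin_of=basin)


def read_traits(path: str | Path) -> TraitMatrix:
    """Read a fuzzy-coded trait table: ``taxon,genus,family,superfamily,<trait.category>...``."""
    df = _read_delimited(path)
    if "taxon" not in df.columns:
        raise SchemaError(f"missing column 'taxon' in {path}")
    taxo_cols = [c for c in TAXONOMY_LEVELS if c in df.columns]
    trait_cols = [c for c in df.columns if "." in c]
    if not trait_cols:
        raise SchemaError(f"no 'trait.category' columns in {path}")
    df = df.set_index("taxon")
    data = df[trait_cols].apply(pd.to_numeric, errors="raise").astype(float)
    taxonomy = df[taxo_cols].copy() if taxo_cols else pd.DataFrame(index=df.index)
    return TraitMatrix(data=data, taxonomy=taxonomy, standardized=False)


def community_from_wide(
    wide: pd.DataFrame,
    hierarchy: SiteHierarchy | None = None,
    seasons: Sequence[str] = DEFAULT_SEASONS,
) -> CommunityData:
    """Convert a wide taxa matrix (index: reach,season,unit; columns: taxa)."""
    long = (
        wide.reset_index()
        .melt(id_vars=["reach", "season", "unit"], var_name="taxon", value_name="abundance")
    )
    long = long[long["abundance"] > 0]
    units: dict[tuple[str, str, int], dict[str, int]] = {
        (r, s, int(u)): {} for r, s, u in wide.index
    }
    for row in long.itertuples(index=False):
        units[(row.reach, row.season, int(row.unit))][row.taxon] = int(row.abundance)
    sample_units = [SampleUnit(r, s, i, t) for (r, s, i), t in sorted(units.items())]
    if hierarchy is None:
        reaches = sorted({u.reach_id for u in sample_units})
        hierarchy = SiteHierarchy(
            {r: f"sb_{r}" for r in reaches}, {r: f"b_{r}" for r in reaches}
        )
    return CommunityData(sample_units, hierarchy, seasons=tuple(seasons))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _write_table(df: pd.DataFrame, path: str | Path, label: str) -> None:
    path = Path(path)
    if df.empty:
        logger.warning("writing header-only %s table to %s", label, path)
    df.to_csv(path, sep=_delim_for(path), index=False, float_format="%.6g")


def write_summary(table: pd.DataFrame, path: str | Path) -> None:
    """Write the extent x group summary table (6 significant digits)."""
    _write_table(table, path, "summary")


def write_per_srs(records: pd.DataFrame, path: str | Path) -> None:
    """Write per-SRS pattern-probability records (6 significant digits)."""
    _write_table(records, path, "per-SRS")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_summary`/:func:`write_per_srs`."""
    return pd.read_csv(path, sep=_delim_for(Path(path)))


def write_community(community: CommunityData, path: str | Path) -> None:
    """Write a community back to the long delimited layout."""
    rows = [
        (u.reach_id, u.season, u.unit_index, t, n)
        for u in community.units
        for t, n in sorted(u.taxa.items())
        if n > 0
    ]
    df = pd.DataFrame(rows, columns=["reach", "season", "unit", "taxon", "abundance"])
    _write_table(df, path, "community")


def write_hierarchy(hierarchy: SiteHierarchy, path: str | Path) -> None:
    rows = [
        (r, hierarchy.subbasin_of.get(r, ""), hierarchy.basin_of[r])
        for r in hierarchy.reaches
    ]
    _write_table(pd.DataFrame(rows, columns=["reach", "subbasin", "basin"]), path, "hierarchy")


def write_traits(traits: TraitMatrix, path: str | Path) -> None:
    df = traits.taxonomy.join(traits.data).reset_index(names="taxon")
    _write_table(df, path, "traits")
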