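"""Dispersal-group formation from fuzzy-coded traits.

Fuzzy trait affinities (0-3) are merged, standardized to within-trait
proportions, imputed along the taxonomy, turned into a Gower dissimilarity
matrix and clustered with Ward's method. Groups are verified with ANOSIM and
characterized by indicator (multilevel pattern) analysis using the
point-biserial coefficient.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .io import TAXONOMY_LEVELS, TraitMatrix, ValidationError

logger = logging.getLogger("streamofd")


# ---------------------------------------------------------------------------
# Trait-table transforms
# ---------------------------------------------------------------------------

def merge_categories(
    traits: TraitMatrix, merge_map: Mapping[str, Sequence[str]]
) -> TraitMatrix:
    """Merge trait categories into wider super-categories.

    ``merge_map`` maps a new dotted ``trait.category`` name to the original
    category columns it absorbs; all members must belong to the same parent
    trait as the new name. The merged affinity is the highest raw affinity
    among the members (NaN only if every member is NaN).
    """
    if traits.standardized:
        raise ValidationError("merge categories on raw codes, before standardization")
    data = traits.data.copy()
    for new, members in merge_map.items():
        parent = new.split(".", 1)[0]
        for m in members:
            if m not in data.columns:
                raise KeyError(f"unknown category {m!r}")
            if m.split(".", 1)[0] != parent:
                raise ValidationError(
                    f"cannot merge {m!r} into {new!r}: different parent trait"
                )
        merged = data[list(members)].max(axis=1, skipna=True)
        merged[data[list(members)].isna().all(axis=1)] = np.nan
        data = data.drop(columns=list(members))
        data[new] = merged
    return TraitMatrix(data=data, taxonomy=traits.taxonomy, standardized=False)


def standardize_affinities(traits: TraitMatrix) -> TraitMatrix:
    """Convert raw fuzzy codes to within-trait proportions summing to 1.

    A trait whose categories are all zero, or that contains a blank cell, is
    flagged missing (all its categories set to NaN) for that taxon.
    """
    if traits.standardized:
        return traits
    data = traits.data.copy().astype(float)
    for trait in traits.traits:
        cols = traits.categories_of(trait)
        block = data[cols]
        total = block.sum(axis=1, skipna=False)  # NaN propagates: blank => missing
        missing = block.isna().any(axis=1) | (total == 0)
        with np.errstate(invalid="ignore"):
            data[cols] = block.div(total, axis=0)
        data.loc[missing, cols] = np.nan
    return TraitMatrix(data=data, taxonomy=traits.taxonomy, standardized=True)


def impute_missing(
    traits: TraitMatrix,
    level_order: Sequence[str] = TAXONOMY_LEVELS,
) -> TraitMatrix:
    """Fill missing traits with the mean profile of taxonomic relatives.

    For each taxon x missing trait, donors are the other taxa with the trait
    present that share the lowest available rank in *level_order* (genus,
    then family, then superfamily). The imputed profile is re-normalized to
    sum to 1. Taxa without donors at any rank keep the trait missing (a
    warning is logged); drop them before clustering.
    """
    if not traits.standardized:
        raise ValidationError("impute on the standardized matrix")
    data = traits.data.copy()
    mask = traits.missing_mask()
    for trait in traits.traits:
        cols = traits.categories_of(trait)
        present = ~mask[trait]
        for taxon in data.index[mask[trait]]:
            filled = False
            for level in level_order:
                if level not in traits.taxonomy.columns:
                    continue
                rank_val = traits.taxonomy.loc[taxon, level]
                if not isinstance(rank_val, str) or not rank_val:
                    continue
                donors = traits.taxonomy.index[
                    (traits.taxonomy[level] == rank_val) & present
                ].difference([taxon])
                if len(donors):
                    prof = data.loc[donors, cols].mean(axis=0)
                    total = prof.sum()
                    if total > 0:
                        data.loc[taxon, cols] = (prof / total).to_numpy()
                        filled = True
                        break
            if not filled:
                logger.warning(
                    "no donors for taxon %s, trait %s: left missing", taxon, trait
                )
    return TraitMatrix(data=data, taxonomy=traits.taxonomy, standardized=True)


def drop_incomplete(traits: TraitMatrix) -> TraitMatrix:
    """Drop taxa that still have a missing trait (cannot be clustered)."""
    keep = ~traits.missing_mask().any(axis=1)
    dropped = list(traits.data.index[~keep])
    if dropped:
        logger.warning("excluding %d taxa with unimputable traits: %s", len(dropped), dropped)
    return TraitMatrix(
        data=traits.data.loc[keep],
        taxonomy=traits.taxonomy.loc[keep],
        standardized=traits.standardized,
    )


# ---------------------------------------------------------------------------
# Gower dissimilarity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric taxa x taxa dissimilarity in [0, 1]."""

    values: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("dissimilarity shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix not symmetric")
        if np.nanmax(np.abs(np.diag(v))) > 1e-12:
            raise ValidationError("dissimilarity diagonal not zero")
        if np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12:
            raise ValidationError("dissimilarity values outside [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def gower_dissimilarity(traits: TraitMatrix) -> DissimilarityMatrix:
    """Gower dissimilarity over numeric trait-category variables.

    Per variable: range-normalized absolute difference over its observed
    range; the pairwise dissimilarity is the mean over variables non-missing
    in both taxa. Zero-range variables contribute nothing (logged).
    """
    X = traits.data.to_numpy(dtype=float)
    n = X.shape[0]
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for j in range(X.shape[1]):
        col = X[:, j]
        obs = ~np.isnan(col)
        if obs.sum() < 2:
            continue
        rng = np.nanmax(col) - np.nanmin(col)
        if rng == 0:
            logger.debug("zero-range variable %s excluded from Gower", traits.data.columns[j])
            continue
        both = obs[:, None] & obs[None, :]
        diff = np.abs(col[:, None] - col[None, :]) / rng
        num += np.where(both, np.nan_to_num(diff), 0.0)
        den += both
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / den
    d[den == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        raise ValidationError("taxa pairs with no shared non-missing variables")
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(values=d, ids=traits.taxa)


# ---------------------------------------------------------------------------
# Ward clustering and cluster-number selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DispersalGroups:
    """Assignment of taxa to dispersal groups."""

    labels: Mapping[str, str]
    k: int

    def members(self, group: str) -> tuple[str, ...]:
        return tuple(sorted(t for t, g in self.labels.items() if g == group))

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels.values())))

    def sizes(self) -> dict[str, int]:
        return {g: len(self.members(g)) for g in self.group_names}


def _ward_tree(D: DissimilarityMatrix) -> np.ndarray:
    # scipy's 'ward' on a condensed distance matrix reproduces R hclust
    # ward.D2 applied to distances (squared internally via Lance-Williams).
    return linkage(D.condensed(), method="ward")

def _cut(Z: np.ndarray, k: int) -> np.ndarray:
    return fcluster(Z, t=k, criterion="maxclust")


def ward_cluster(D: DissimilarityMatrix, k: int) -> DispersalGroups:
    """Agglomerative Ward clustering of the dissimilarity matrix, cut at *k*.

    Deterministic: merge ties are broken by scipy's fixed candidate ordering.
    Cluster labels ``DG1..DGk`` are assigned by order of first taxon id.
    """
    if not 2 <= k <= D.n:
        raise ValueError(f"k={k} outside [2, {D.n}]")
    flat = _cut(_ward_tree(D), k)
    if len(set(flat)) != k:
        raise ValidationError(f"could not produce {k} clusters (got {len(set(flat))})")
    relabel: dict[int, str] = {}
    for c in flat:  # taxa are in id order; stable group naming
        if c not in relabel:
            relabel[c] = f"DG{len(relabel) + 1}"
    return DispersalGroups({t: relabel[c] for t, c in zip(D.ids, flat)}, k=k)


@dataclass(frozen=True)
class WssCurve:
    """Total within-cluster sum of squares against the number of clusters."""

    ks: tuple[int, ...]
    wss: tuple[float, ...]
    knee: int


def _wss_of(D: DissimilarityMatrix, flat: np.ndarray) -> float:
    # For points embeddable in Euclidean space, within-cluster SS equals
    # sum_{i<j in c} d_ij^2 / n_c (Huygens theorem on pairwise distances).
    total = 0.0
    for c in np.unique(flat):
        idx = np.where(flat == c)[0]
        if len(idx) < 2:
            continue
        sub = D.values[np.ix_(idx, idx)]
        total += (sub**2).sum() / (2.0 * len(idx))
    return total


def wss_curve(D: DissimilarityMatrix, k_max: int) -> WssCurve:
    """WSS for k = 1..k_max cluster cuts of the Ward tree, with a knee suggestion.

    The knee is the k maximizing the second forward difference of WSS
    (the sharpest bend); pin k explicitly to override.
    """
    if k_max > D.n:
        raise ValueError(f"k_max={k_max} exceeds n={D.n}")
    Z = _ward_tree(D)
    ks = tuple(range(1, k_max + 1))
    wss = tuple(_wss_of(D, _cut(Z, k)) for k in ks)
    if len(ks) >= 3:
        second = [wss[i + 1] - 2 * wss[i] + wss[i - 1] for i in range(1, len(ks) - 1)]
        knee = ks[1 + int(np.argmax(second))]
    else:
        knee = ks[-1]
    return WssCurve(ks=ks, wss=wss, knee=knee)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnosimResult:
    R: float
    p: float
    n_perm: int


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = len(ranks)
    r_w = ranks[within].mean()
    r_b = ranks[~within].mean()
    return (r_b - r_w) / (m / 2.0)


def anosim(
    D: DissimilarityMatrix,
    groups: DispersalGroups | Mapping[str, str],
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> AnosimResult:
    """Analysis of similarities: rank-based test of group separation.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairs; the p-value uses the add-one permutation estimator
    p = (1 + #{R_perm >= R_obs}) / (1 + n_perm).
    """
    labels_map = groups.labels if isinstance(groups, DispersalGroups) else groups
    labels = np.asarray([labels_map[t] for t in D.ids])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group must have at least 2 members")
    iu, ju = np.triu_indices(D.n, 1)
    ranks = rankdata(D.condensed())
    codes = np.searchsorted(uniq, labels)
    r_obs = _anosim_r(ranks, codes[iu] == codes[ju])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
    within_perm = perms[:, iu] == perms[:, ju]  # (n_perm, M)
    m = len(ranks)
    r_w = (ranks[None, :] * within_perm).sum(1) / within_perm.sum(1)
    r_b = (ranks[None, :] * ~within_perm).sum(1) / (~within_perm).sum(1)
    r_perm = (r_b - r_w) / (m / 2.0)
    p = (1 + int((r_perm >= r_obs - 1e-12).sum())) / (1 + n_perm)
    return AnosimResult(R=float(r_obs), p=float(p), n_perm=n_perm)


# ---------------------------------------------------------------------------
# Multilevel pattern (indicator) analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndicatorResult:
    category: str
    combination: tuple[str, ...]
    r_pb: float
    p: float
    degenerate: bool = False


def _combinations(group_names: Sequence[str]) -> list[tuple[str, ...]]:
    combos: list[tuple[str, ...]] = []
    for r in range(1, len(group_names)):
        combos.extend(itertools.combinations(group_names, r))
    return combos


def multilevel_pattern(
    traits: TraitMatrix,
    groups: DispersalGroups,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> list[IndicatorResult]:
    """Best group-combination indicator per trait category (point-biserial).

    For each category, r_pb is the Pearson correlation between the
    standardized affinity vector and the 0/1 membership vector of each
    non-empty proper subset of groups; the maximizing subset is reported.
    The permutation p-value permutes group labels and compares the permuted
    maximum r_pb against the observed one (add-one estimator). Constant
    affinity vectors are flagged degenerate with r_pb = 0.
    """
    if not traits.standardized:
        raise ValidationError("multilevel pattern analysis expects standardized traits")
    names = groups.group_names
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    taxa = [t for t in traits.taxa if t in groups.labels]
    X = traits.data.loc[taxa].to_numpy(dtype=float)
    labels = np.asarray([groups.labels[t] for t in taxa])
    combos = _combinations(names)
    member = np.array([np.isin(labels, c) for c in combos], dtype=float)  # (C, n)

    def zscore(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu = A.mean(axis=1, keepdims=True)
        sd = A.std(axis=1, keepdims=True)
        ok = sd[:, 0] > 0
        Z = np.where(sd > 0, (A - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        return Z, ok

    n = len(taxa)
    Mz, _ = zscore(member)
    results: list[IndicatorResult] = []
    rng = np.random.default_rng(seed)
    perm_members = []
    for _ in range(n_perm):
        order = rng.permutation(n)
        perm_members.append(Mz[:, order])
    Pm = np.stack(perm_members) if n_perm else np.empty((0, *Mz.shape))

    for ci, cat in enumerate(traits.data.columns):
        v = X[:, ci]
        if np.isnan(v).any():
            raise ValidationError(f"missing values in category {cat!r}; impute first")
        sd = v.std()
        if sd == 0:
            results.append(IndicatorResult(cat, (), 0.0, 1.0, degenerate=True))
            continue
        vz = (v - v.mean()) / sd
        r_all = Mz @ vz / n  # (C,)
        best = int(np.argmax(r_all))
        r_obs = float(r_all[best])
        if n_perm:
            r_perm_max = (Pm @ vz / n).max(axis=1)  # (n_perm,)
            p = (1 + int((r_perm_max >= r_obs - 1e-12).sum())) / (1 + n_perm)
        else:
            p = float("nan")
        results.append(IndicatorResult(cat, combos[best], r_obs, float(p)))
    return results


# ---------------------------------------------------------------------------
# Dendrogram export
# ---------------------------------------------------------------------------

def to_newick(D: DissimilarityMatrix) -> str:
    """Export the Ward dendrogram as a Newick string (for inspection)."""
    Z = _ward_tree(D)
    n = D.n
    heights = {i: 0.0 for i in range(n)}
    nodes: dict[int, str] = {i: D.ids[i] for i in range(n)}
    for step, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        idx = n + step
        nodes[idx] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[idx] = h
    return nodes[2 * n - 2] + ";"
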