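"""Trait transforms, Gower/Ward clustering, ANOSIM and indicator analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import streamofd as s
from streamofd.io import TraitMatrix, ValidationError
from streamofd.traits import DissimilarityMatrix, drop_incomplete, to_newick


def tm(data: dict, taxonomy: pd.DataFrame | None = None, standardized=False):
    df = pd.DataFrame(data, dtype=float)
    df.index = [f"t{i}" for i in range(len(df))]
    if taxonomy is None:
        taxonomy = pd.DataFrame(index=df.index)
    return TraitMatrix(data=df, taxonomy=taxonomy, standardized=standardized)


class TestMergeCategories:
    def test_max_rule(self):
        t = tm({"sz.a": [1], "sz.b": [3], "sz.c": [0], "dr.x": [2]})
        merged = s.merge_categories(t, {"sz.wide": ["sz.a", "sz.b", "sz.c"]})
        assert merged.data.loc["t0", "sz.wide"] == 3
        assert merged.data.loc["t0", "dr.x"] == 2

    def test_singleton_merge_is_identity(self):
        t = tm({"sz.a": [2]})
        merged = s.merge_categories(t, {"sz.b": ["sz.a"]})
        assert merged.data.loc["t0", "sz.b"] == 2

    def test_all_zero_members_merge_to_zero(self):
        t = tm({"sz.a": [0], "sz.b": [0]})
        merged = s.merge_categories(t, {"sz.w": ["sz.a", "sz.b"]})
        assert merged.data.loc["t0", "sz.w"] == 0

    def test_cross_trait_merge_rejected(self):
        t = tm({"sz.a": [1], "dr.x": [2]})
        with pytest.raises(ValidationError):
            s.merge_categories(t, {"sz.w": ["sz.a", "dr.x"]})


class TestStandardize:
    @pytest.mark.parametrize(
        "raw, expected",
        [((0, 1, 3), (0, 0.25, 0.75)), ((2, 2, 0), (0.5, 0.5, 0.0))],
    )
    def test_proportion_rule(self, raw, expected):
        t = tm({"tr.a": [raw[0]], "tr.b": [raw[1]], "tr.c": [raw[2]]})
        std = s.standardize_affinities(t)
        np.testing.assert_allclose(std.data.loc["t0"].to_numpy(), expected)

    def test_zero_sum_trait_becomes_missing(self):
        t = tm({"tr.a": [0], "tr.b": [0], "other.x": [3]})
        std = s.standardize_affinities(t)
        assert std.data.loc["t0", ["tr.a", "tr.b"]].isna().all()
        assert std.missing_mask().loc["t0", "tr"]
        assert std.data.loc["t0", "other.x"] == 1.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 3), min_size=2, max_size=5))
    def test_categories_sum_to_one_or_missing(self, codes):
        t = tm({f"tr.c{i}": [c] for i, c in enumerate(codes)})
        std = s.standardize_affinities(t)
        row = std.data.loc["t0"].to_numpy()
        if sum(codes) == 0:
            assert np.isnan(row).all()
        else:
            assert abs(row.sum() - 1) < 1e-12


class TestImpute:
    def test_family_mean(self):
        taxonomy = pd.DataFrame(
            {"genus": ["g1", "g2", "g3"], "family": ["f", "f", "f"],
             "superfamily": ["sf"] * 3},
            index=["t0", "t1", "t2"],
        )
        t = tm({"tr.a": [np.nan, 0.2, 0.4], "tr.b": [np.nan, 0.8, 0.6]},
               taxonomy=taxonomy, standardized=True)
        imp = s.impute_missing(t)
        np.testing.assert_allclose(
            imp.data.loc["t0"].to_numpy(), [0.3, 0.7], atol=1e-12
        )

    def test_superfamily_fallback(self):
        taxonomy = pd.DataFrame(
            {"genus": ["g1", "g2"], "family": ["fA", "fB"],
             "superfamily": ["sf", "sf"]},
            index=["t0", "t1"],
        )
        t = tm({"tr.a": [np.nan, 0.25], "tr.b": [np.nan, 0.75]},
               taxonomy=taxonomy, standardized=True)
        imp = s.impute_missing(t)
        np.testing.assert_allclose(imp.data.loc["t0"].to_numpy(), [0.25, 0.75])

    def test_orphan_left_missing_and_dropped(self, caplog):
        taxonomy = pd.DataFrame(
            {"genus": ["g1", "g2"], "family": ["fA", "fB"],
             "superfamily": ["sfA", "sfB"]},
            index=["t0", "t1"],
        )
        t = tm({"tr.a": [np.nan, 0.25], "tr.b": [np.nan, 0.75]},
               taxonomy=taxonomy, standardized=True)
        with caplog.at_level("WARNING", logger="streamofd"):
            imp = s.impute_missing(t)
        assert imp.missing_mask().loc["t0", "tr"]
        assert "no donors" in caplog.text
        assert drop_incomplete(imp).taxa == ("t1",)


def gower_brute_force(X: np.ndarray) -> np.ndarray:
    """Independent double-loop Gower oracle (mirrors the definition, not the code)."""
    n, p = X.shape
    ranges = np.nanmax(X, axis=0) - np.nanmin(X, axis=0)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = den = 0.0
            for k in range(p):
                if np.isnan(X[i, k]) or np.isnan(X[j, k]) or ranges[k] == 0:
                    continue
                num += abs(X[i, k] - X[j, k]) / ranges[k]
                den += 1
            D[i, j] = num / den
    return D


class TestGower:
    def test_identical_profiles_are_zero(self):
        t = tm({"a.x": [0.5, 0.5, 0.1], "b.y": [0.2, 0.2, 0.9]}, standardized=True)
        D = s.gower_dissimilarity(t)
        assert D.values[0, 1] == 0

    def test_opposite_extremes_are_one(self):
        t = tm({"a.x": [0.0, 1.0, 0.3], "b.y": [0.0, 1.0, 0.6]}, standardized=True)
        D = s.gower_dissimilarity(t)
        assert D.values[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((7, 5))
        X[rng.random(X.shape) < 0.15] = np.nan
        X[:, 4] = 0.5  # zero-range column must drop out
        t = tm({f"v{k}.c": X[:, k] for k in range(5)}, standardized=True)
        D = s.gower_dissimilarity(t)
        np.testing.assert_allclose(D.values, gower_brute_force(X), atol=1e-12)

    def test_matrix_properties(self, default_traits):
        _, raw = default_traits
        std = s.impute_missing(s.standardize_affinities(raw))
        D = s.gower_dissimilarity(drop_incomplete(std))
        v = D.values
        assert np.allclose(v, v.T)
        assert np.all(np.diag(v) == 0)
        assert v.min() >= 0 and v.max() <= 1


class TestWardCluster:
    @staticmethod
    def blob_matrix():
        rng = np.random.default_rng(3)
        a = 0.05 + 0.02 * rng.random((5, 3))
        b = 0.9 + 0.02 * rng.random((5, 3))
        X = np.vstack([a, b])
        return tm({f"v{k}.c": X[:, k] for k in range(3)}, standardized=True)

    def test_separated_blobs_recovered(self):
        D = s.gower_dissimilarity(self.blob_matrix())
        groups = s.ward_cluster(D, 2)
        labels = [groups.labels[t] for t in D.ids]
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_k_equals_n_gives_singletons(self):
        D = s.gower_dissimilarity(self.blob_matrix())
        groups = s.ward_cluster(D, D.n)
        assert len(set(groups.labels.values())) == D.n

    def test_duplicate_rows_cluster_together(self):
        t = tm({"a.x": [0.1, 0.1, 0.9, 0.9, 0.5], "b.y": [0.2, 0.2, 0.8, 0.8, 0.5]},
               standardized=True)
        D = s.gower_dissimilarity(t)
        groups = s.ward_cluster(D, 3)
        assert groups.labels["t0"] == groups.labels["t1"]
        assert groups.labels["t2"] == groups.labels["t3"]

    def test_k_out_of_range(self):
        D = s.gower_dissimilarity(self.blob_matrix())
        with pytest.raises(ValueError):
            s.ward_cluster(D, 1)

    def test_deterministic(self):
        D = s.gower_dissimilarity(self.blob_matrix())
        assert s.ward_cluster(D, 3).labels == s.ward_cluster(D, 3).labels


class TestWssCurve:
    def test_three_archetype_knee(self, default_traits):
        _, raw = default_traits
        std = s.impute_missing(s.standardize_affinities(raw))
        D = s.gower_dissimilarity(drop_incomplete(std))
        curve = s.wss_curve(D, 8)
        assert curve.knee == 3

    def test_monotone_and_zero_at_n(self):
        t = TestWardCluster.blob_matrix()
        D = s.gower_dissimilarity(t)
        curve = s.wss_curve(D, D.n)
        w = np.asarray(curve.wss)
        assert np.all(np.diff(w) <= 1e-12)
        assert w[-1] == pytest.approx(0, abs=1e-12)


class TestAnosim:
    def test_hand_ranked_four_taxon_instance(self):
        # 2+2 taxa where all between-group dissimilarities exceed all within:
        # within ranks {1,2}, between {3,4,5,6} -> R = (4.5 - 1.5)/3 = 1.
        v = np.array([
            [0.0, 0.1, 0.8, 0.9],
            [0.1, 0.0, 0.7, 0.85],
            [0.8, 0.7, 0.0, 0.2],
            [0.9, 0.85, 0.2, 0.0],
        ])
        D = DissimilarityMatrix(values=v, ids=("a", "b", "c", "d"))
        res = s.anosim(D, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"},
                       n_perm=99, seed=0)
        assert res.R == pytest.approx(1.0)
        assert 0 < res.p <= 1

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.random((8, 4))
        t = tm({f"v{k}.c": X[:, k] for k in range(4)}, standardized=True)
        D = s.gower_dissimilarity(t)
        g1 = {t_: ("A" if i < 4 else "B") for i, t_ in enumerate(D.ids)}
        g2 = {t_: ("north" if i < 4 else "south") for i, t_ in enumerate(D.ids)}
        assert s.anosim(D, g1, 99, seed=1).R == s.anosim(D, g2, 99, seed=2).R

    def test_small_group_rejected(self):
        v = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        D = DissimilarityMatrix(values=v, ids=("a", "b", "c"))
        with pytest.raises(ValueError):
            s.anosim(D, {"a": "g1", "b": "g2", "c": "g2"}, 9, seed=0)

    def test_matches_scikit_bio(self):
        """Independent oracle: skbio's ANOSIM statistic on the same instance."""
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(7)
        X = np.vstack([rng.random((5, 4)) * 0.4, 0.5 + rng.random((5, 4)) * 0.4])
        t = tm({f"v{k}.c": X[:, k] for k in range(4)}, standardized=True)
        D = s.gower_dissimilarity(t)
        labels = {t_: ("A" if i < 5 else "B") for i, t_ in enumerate(D.ids)}
        ours = s.anosim(D, labels, n_perm=99, seed=0)
        dm = skbio_distance.DistanceMatrix(D.values, ids=D.ids)
        ref = skbio_distance.anosim(
            dm, [labels[i] for i in D.ids], permutations=99
        )
        assert ours.R == pytest.approx(ref["test statistic"], abs=1e-12)


def multilevel_brute_force(values: np.ndarray, labels: list[str]):
    """Exhaustive oracle: best subset and r_pb via plain correlation."""
    import itertools

    names = sorted(set(labels))
    best = (None, -np.inf)
    for r in range(1, len(names)):
        for combo in itertools.combinations(names, r):
            member = np.array([1.0 if l in combo else 0.0 for l in labels])
            r_pb = np.corrcoef(values, member)[0, 1]
            if r_pb > best[1]:
                best = (combo, r_pb)
    return best


class TestMultilevelPattern:
    @staticmethod
    def groups_of(labels):
        return s.DispersalGroups(
            {f"t{i}": g for i, g in enumerate(labels)}, k=len(set(labels))
        )

    def test_perfect_indicator(self):
        t = tm({"tr.a": [1, 1, 1, 0, 0, 0], "tr.b": [0, 0, 0, 1, 1, 1]},
               standardized=True)
        res = s.multilevel_pattern(
            t, self.groups_of(["A", "A", "A", "B", "B", "B"]), n_perm=99, seed=0
        )
        by_cat = {r.category: r for r in res}
        assert by_cat["tr.a"].combination == ("A",)
        assert by_cat["tr.a"].r_pb == pytest.approx(1.0)

    def test_constant_category_flagged(self):
        t = tm({"tr.a": [0.5] * 6, "tr.b": [0.5] * 6}, standardized=True)
        res = s.multilevel_pattern(
            t, self.groups_of(["A", "A", "B", "B", "C", "C"]), n_perm=9, seed=0
        )
        assert all(r.degenerate and r.r_pb == 0 for r in res)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((6, 3))
        t = tm({f"v{k}.c": X[:, k] for k in range(3)}, standardized=True)
        labels = ["A", "A", "B", "B", "C", "C"]
        res = s.multilevel_pattern(t, self.groups_of(labels), n_perm=99, seed=0)
        for k, r in enumerate(res):
            combo, r_pb = multilevel_brute_force(X[:, k], labels)
            assert r.combination == combo
            assert r.r_pb == pytest.approx(r_pb, abs=1e-12)


def test_newick_export_contains_all_taxa():
    D = s.gower_dissimilarity(TestWardCluster.blob_matrix())
    nwk = to_newick(D)
    assert nwk.endswith(";")
    for t_ in D.ids:
        assert t_ in nwk
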