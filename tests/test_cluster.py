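import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform

from morphoscreen.cluster import (
    category_cluster_summary,
    cluster_profiles,
    cluster_signatures,
    cluster_trajectory,
    correlation_distance_matrix,
    entanglement,
    fit_pca_embedding,
    leaf_order,
    match_to_signatures,
    to_newick,
    ward_cluster,
)

from oracles import brute_pearson, brute_uncentered_pca_coords


def profiles_df(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index").astype(float)


class TestCorrelationDistances:
    def test_identical_profiles_distance_zero(self):
        p = profiles_df({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        d = squareform(correlation_distance_matrix(p), checks=False)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_negation_distance_two(self):
        p = profiles_df({"a": [1, 2, 3, 4], "b": [-1, -2, -3, -4]})
        d = squareform(correlation_distance_matrix(p), checks=False)
        assert d[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_hand_made_profiles_match_direct_r(self):
        rows = {"a": [0.0, 1, 2, 5], "b": [1.0, 0, 3, 2], "c": [-1.0, 4, 0, 2]}
        p = profiles_df(rows)
        d = squareform(correlation_distance_matrix(p), checks=False)
        keys = list(rows)
        for i in range(3):
            for j in range(i + 1, 3):
                want = 1 - brute_pearson(rows[keys[i]], rows[keys[j]])
                assert d[i, j] == pytest.approx(want, abs=1e-12)

    def test_zero_variance_profile_named(self):
        p = profiles_df({"a": [1, 2, 3], "flatty": [5, 5, 5]})
        with pytest.raises(ValueError, match="flatty"):
            correlation_distance_matrix(p)


class TestWardCluster:
    def test_two_planted_blobs_recovered(self, rng):
        sig1, sig2 = rng.normal(size=10), rng.normal(size=10)
        rows = {}
        for i in range(6):
            rows[f"x{i}"] = sig1 + rng.normal(0, 0.1, 10)
            rows[f"y{i}"] = sig2 + rng.normal(0, 0.1, 10)
        p = profiles_df(rows)
        model = cluster_profiles(p, k=2)
        labels = model.labels
        xs = {labels[f"x{i}"] for i in range(6)}
        ys = {labels[f"y{i}"] for i in range(6)}
        assert len(xs) == 1 and len(ys) == 1 and xs != ys

    def test_k_equals_n_singletons(self, rng):
        p = profiles_df({f"p{i}": rng.normal(size=5).tolist() for i in range(4)})
        _, labels = ward_cluster(correlation_distance_matrix(p), p.index, k=4)
        assert labels.nunique() == 4

    def test_duplicates_merge_first_at_height_zero(self, rng):
        v = rng.normal(size=6)
        p = profiles_df({"a": v, "b": v, "c": rng.normal(size=6)})
        Z, _ = ward_cluster(correlation_distance_matrix(p), p.index, k=2)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_k_out_of_range(self, rng):
        p = profiles_df({f"p{i}": rng.normal(size=5).tolist() for i in range(3)})
        with pytest.raises(ValueError, match="k must be"):
            ward_cluster(correlation_distance_matrix(p), p.index, k=4)


class TestSignatures:
    def test_singleton_cluster_equals_member(self, rng):
        p = profiles_df({"a": [1.0, 2, 3], "b": [9.0, 8, 7]})
        labels = pd.Series({"a": 1, "b": 2})
        sig = cluster_signatures(p, labels)
        assert sig.loc[1].tolist() == [1, 2, 3]

    def test_two_member_mean(self):
        p = profiles_df({"a": [1.0, 2, 3], "b": [3.0, 2, 1]})
        sig = cluster_signatures(p, pd.Series({"a": 1, "b": 1}))
        assert sig.loc[1].tolist() == [2, 2, 2]

    def test_label_equivariance(self, rng):
        p = profiles_df({f"p{i}": rng.normal(size=6).tolist() for i in range(6)})
        labels = pd.Series({f"p{i}": i % 2 + 1 for i in range(6)})
        sig = cluster_signatures(p, labels)
        perm = p.iloc[::-1]
        sig_perm = cluster_signatures(perm, labels)
        assert np.allclose(sig.sort_index().to_numpy(), sig_perm.sort_index().to_numpy())

    def test_missing_label_rejected(self):
        p = profiles_df({"a": [1.0, 2, 3], "b": [3.0, 2, 1]})
        with pytest.raises(ValueError, match="without a cluster label"):
            cluster_signatures(p, pd.Series({"a": 1}))


class TestMatch:
    def _signatures(self, rng, k=3, p=8):
        return pd.DataFrame(
            rng.normal(size=(k, p)),
            index=range(1, k + 1),
            columns=[f"f{i}" for i in range(p)],
        )

    def test_profile_equal_to_signature_is_hc(self, rng):
        sig = self._signatures(rng)
        profile = sig.loc[3].copy()
        profile.name = "probe"
        m = match_to_signatures(profile, sig, target_cluster=3)
        assert m.best_cluster == 3
        assert m.best_r == pytest.approx(1.0)
        assert m.call == "HC"

    def test_orthogonal_profile_is_nc(self):
        sig = pd.DataFrame(
            [[1.0, -1, 1, -1], [1.0, 1, -1, -1]], index=[1, 2], columns=list("abcd")
        )
        # orthogonal (after centering) to both signatures: r = 0 exactly
        profile = pd.Series([1.0, -1, -1, 1], index=list("abcd"), name="ortho")
        m = match_to_signatures(profile, sig, nc_threshold=0.0, target_cluster=1)
        assert m.correlations.abs().max() == pytest.approx(0.0, abs=1e-12)
        assert m.call == "NC"

    def test_affine_invariance(self, rng):
        sig = self._signatures(rng)
        profile = pd.Series(rng.normal(size=8), index=sig.columns, name="p")
        m1 = match_to_signatures(profile, sig)
        m2 = match_to_signatures(3.7 * profile + 11.0, sig)
        assert np.allclose(m1.correlations, m2.correlations, atol=1e-12)
        assert m1.best_cluster == m2.best_cluster

    def test_shared_feature_restriction(self, rng):
        sig = self._signatures(rng)
        profile = pd.Series(
            rng.normal(size=6), index=[f"f{i}" for i in range(2, 8)], name="partial"
        )
        m = match_to_signatures(profile, sig)
        want = brute_pearson(
            profile.to_numpy(), sig.loc[m.best_cluster, profile.index].to_numpy()
        )
        assert m.best_r == pytest.approx(want, abs=1e-12)

    def test_too_few_shared_features(self, rng):
        sig = self._signatures(rng)
        profile = pd.Series([1.0, 2.0], index=["f0", "f1"], name="tiny")
        with pytest.raises(ValueError, match="shared features"):
            match_to_signatures(profile, sig)


class TestPcaEmbedding:
    def test_projecting_fit_data_is_consistent(self, rng):
        p = pd.DataFrame(rng.normal(size=(10, 6)), columns=[f"f{i}" for i in range(6)])
        emb = fit_pca_embedding(p)
        coords = emb.transform(p)
        X = p.to_numpy() / emb.scales
        assert np.allclose(coords, X @ emb.loadings, atol=1e-12)

    def test_duplicate_profiles_identical_coordinates(self, rng):
        X = rng.normal(size=(5, 4))
        X[4] = X[0]
        p = pd.DataFrame(X, columns=list("abcd"))
        coords = fit_pca_embedding(p).transform(p)
        assert np.allclose(coords[0], coords[4], atol=1e-12)

    def test_matches_eigendecomposition_oracle(self, rng):
        p = pd.DataFrame(rng.normal(size=(3, 3)) + 1, columns=list("abc"))
        coords = fit_pca_embedding(p).transform(p)
        want = brute_uncentered_pca_coords(p.to_numpy())
        # eigenvector sign is arbitrary; compare per-column up to sign
        for j in range(coords.shape[1]):
            assert np.allclose(coords[:, j], want[:, j], atol=1e-8) or np.allclose(
                coords[:, j], -want[:, j], atol=1e-8
            )

    def test_zero_variance_feature_rejected(self, rng):
        p = pd.DataFrame({"a": rng.normal(size=5), "b": np.zeros(5)})
        with pytest.raises(ValueError, match="zero-variance"):
            fit_pca_embedding(p)


def caterpillar(n: int) -> np.ndarray:
    """Manual left-leaning linkage over n leaves, heights 1..n-1."""
    Z = []
    prev = 0
    for i in range(1, n):
        Z.append([prev, i, float(i), i + 1])
        prev = n + i - 1
    return np.array(Z)


class TestEntanglement:
    def test_identical_trees_zero(self):
        Z = caterpillar(5)
        ids = list("abcde")
        assert entanglement(Z, ids, Z, ids) == 0.0

    def test_reversed_leaf_order_one(self):
        Z = caterpillar(6)
        ids = list("abcdef")
        assert entanglement(Z, ids, Z, ids[::-1]) == pytest.approx(1.0)

    def test_adjacent_swap_quarter(self):
        Z = caterpillar(4)
        assert entanglement(Z, list("abcd"), Z, list("bacd"), exponent=1.0) == pytest.approx(
            2.0 / 8.0
        )

    def test_symmetric(self, rng):
        p1 = profiles_df({f"p{i}": rng.normal(size=6).tolist() for i in range(7)})
        p2 = p1 + rng.normal(0, 0.5, p1.shape)
        m1, m2 = cluster_profiles(p1, 3), cluster_profiles(p2, 3)
        e12 = entanglement(m1.linkage, m1.ids, m2.linkage, m2.ids)
        e21 = entanglement(m2.linkage, m2.ids, m1.linkage, m1.ids)
        assert e12 == pytest.approx(e21)
        assert 0.0 <= e12 <= 1.0

    def test_label_mismatch_rejected(self):
        Z = caterpillar(3)
        with pytest.raises(ValueError, match="different label sets"):
            entanglement(Z, list("abc"), Z, list("abd"))


class TestCategorySummary:
    def _inputs(self):
        labels = pd.DataFrame(
            {
                "compound_id": ["A", "A", "B", "C", "D"],
                "concentration_um": [10.0, 20.0, 20.0, 20.0, 20.0],
                "cluster": [1, 1, 1, 2, 2],
            }
        )
        activity = pd.DataFrame(
            {
                "compound_id": ["A", "A", "B", "C", "D"],
                "concentration_um": [10.0, 20.0, 20.0, 20.0, 20.0],
                "activity_score": [2.0, 4.0, 6.0, 8.0, 10.0],
            }
        )
        categories = {"A": "NSE", "B": "NSE", "C": "TE", "D": "TE"}
        return activity, labels, categories

    def test_single_category_single_cluster(self):
        activity, labels, _ = self._inputs()
        out = category_cluster_summary(activity, labels, {c: "only" for c in "ABCD"})
        cell = out.set_index(["category", "cluster"])
        assert cell.loc[("only", 1), "fraction"] == pytest.approx(3 / 5)

    def test_fractions_sum_to_one(self):
        activity, labels, categories = self._inputs()
        out = category_cluster_summary(activity, labels, categories)
        sums = out.groupby("category")["fraction"].sum()
        assert np.allclose(sums, 1.0)

    def test_hand_computed_means(self):
        activity, labels, categories = self._inputs()
        out = category_cluster_summary(activity, labels, categories).set_index(
            ["category", "cluster"]
        )
        assert out.loc[("NSE", 1), "mean_activity"] == pytest.approx((2 + 4 + 6) / 3)
        assert out.loc[("TE", 2), "mean_activity"] == pytest.approx(9.0)
        assert out.loc[("NSE", 2), "n"] == 0
        assert out.loc[("NSE", 2), "mean_activity"] == 0.0

    def test_missing_category_rejected(self):
        activity, labels, categories = self._inputs()
        del categories["D"]
        with pytest.raises(ValueError, match="without a category"):
            category_cluster_summary(activity, labels, categories)


class TestTrajectory:
    def _activity(self, scores, actives):
        return pd.DataFrame(
            {
                "compound_id": "X",
                "concentration_um": [20.0, 0.625, 5.0][: len(scores)],
                "activity_score": scores,
                "active": actives,
            }
        )

    def test_inactive_withholds_cluster(self):
        labels = pd.DataFrame(
            {"compound_id": ["X"], "concentration_um": [20.0], "cluster": [3]}
        )
        out = cluster_trajectory("X", self._activity([1.0, 0.5, 0.7], [False] * 3), labels)
        assert out["cluster"].isna().all()
        assert out["concentration_um"].is_monotonic_increasing

    def test_active_gets_cluster_sorted_by_dose(self):
        labels = pd.DataFrame(
            {"compound_id": ["X"], "concentration_um": [20.0], "cluster": [9]}
        )
        out = cluster_trajectory("X", self._activity([5.0, 0.5, 0.7], [True, False, False]), labels)
        assert out["concentration_um"].tolist() == [0.625, 5.0, 20.0]
        assert out["cluster"].tolist()[-1] == 9
        assert pd.isna(out["cluster"].iloc[0])

    def test_single_concentration(self):
        out = cluster_trajectory("X", self._activity([5.0], [True]), None)
        assert len(out) == 1

    def test_unknown_compound_rejected(self):
        with pytest.raises(ValueError, match="no scored concentrations"):
            cluster_trajectory("nope", self._activity([1.0], [True]), None)


class TestNewick:
    def test_parses_with_dendropy_and_keeps_leaves(self, rng):
        dendropy = pytest.importorskip("dendropy")
        p = profiles_df({f"p{i}": rng.normal(size=6).tolist() for i in range(5)})
        model = cluster_profiles(p, 2)
        nwk = to_newick(model.linkage, model.ids)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        taxa = {t.label for t in tree.taxon_namespace}
        assert taxa == set(model.ids)
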