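"""Phenotype clustering, cluster signatures, signature matching, embedding,
dendrogram comparison, and category summaries.

Treatment profiles (replicate-averaged, reduced feature set) are clustered
hierarchically with ``1 - Pearson r`` pairwise distances and Ward linkage
(the sum-of-squares-minimizing update applied to squared input distances).
Each cluster's phenotype signature is the feature-wise mean of its member
profiles; external profiles are matched to signatures by Pearson
correlation over the shared features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import FeatureMatrix

__all__ = [
    "ClusterModel",
    "SignatureMatch",
    "PCAEmbedding",
    "correlation_distance_matrix",
    "ward_cluster",
    "cluster_signatures",
    "cluster_profiles",
    "aggregate_treatments",
    "match_to_signatures",
    "fit_pca_embedding",
    "entanglement",
    "leaf_order",
    "category_cluster_summary",
    "cluster_trajectory",
    "to_newick",
]


@dataclass
class ClusterModel:
    """Linkage tree, k-cluster labels, and per-cluster mean signatures."""

    ids: list[str]
    distances: np.ndarray  # condensed 1 - r distances
    linkage: np.ndarray
    k: int
    labels: pd.Series  # id -> cluster in 1..k
    signatures: pd.DataFrame  # clusters x features


@dataclass
class SignatureMatch:
    """Correlation of one profile to each cluster signature."""

    profile_id: str
    correlations: pd.Series  # cluster -> Pearson r
    best_cluster: int
    best_r: float
    call: str  # HC | NC | intermediate
    target_cluster: int
    hc_threshold: float
    nc_threshold: float


def correlation_distance_matrix(profiles: pd.DataFrame) -> np.ndarray:
    """Condensed pairwise ``1 - Pearson r`` distances between profile rows."""
    X = profiles.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    if X.shape[1] < 3:
        raise ValueError("need at least 3 features")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = [str(profiles.index[i]) for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance profile(s), correlation undefined: {bad[:10]}")
    d = 1.0 - np.corrcoef(X)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return squareform(d, checks=False)


def ward_cluster(condensed: np.ndarray, ids, k: int) -> tuple[np.ndarray, pd.Series]:
    """Ward-linkage tree from condensed distances, cut to exactly k clusters."""
    ids = [str(i) for i in ids]
    n = len(ids)
    if squareform(condensed, checks=False).shape[0] != n:
        raise ValueError("condensed distances do not match the number of ids")
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}, got {k}")
    Z = hierarchy.linkage(condensed, method="ward")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    found = len(np.unique(flat))
    if found != k:
        raise ValueError(
            f"tree cut produced {found} clusters instead of {k} "
            "(tied merge heights); pick a different k"
        )
    labels = pd.Series(flat, index=ids, name="cluster")
    return Z, labels


def cluster_signatures(profiles: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Feature-wise arithmetic mean of member profiles per cluster."""
    missing = [i for i in profiles.index if str(i) not in labels.index]
    if missing:
        raise ValueError(f"profiles without a cluster label: {missing[:10]}")
    lab = labels.loc[[str(i) for i in profiles.index]].to_numpy()
    sig = profiles.groupby(lab).mean()
    sig.index.name = "cluster"
    empty = set(labels.unique()) - set(sig.index)
    if empty:
        raise ValueError(f"empty cluster(s): {sorted(empty)}")
    return sig


def aggregate_treatments(
    matrix: FeatureMatrix,
    activity_results: pd.DataFrame | None = None,
    include_roles: tuple[str, ...] = ("treatment", "positive_control"),
    active_only: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate-average wells into per-treatment (compound x dose) profiles.

    If *activity_results* (with an ``active`` column) is given and
    *active_only* is set, inactive treatments are excluded — clustering
    noise profiles would be meaningless.  Returns (profiles indexed by
    ``compound@dose`` ids, index table with compound_id / concentration_um
    per id).
    """
    meta = matrix.meta
    sel = meta["role"].isin(include_roles)
    sub_meta = meta.loc[sel]
    sub_vals = matrix.values.loc[sel.to_numpy()]

    keep: set[tuple[str, float]] | None = None
    if activity_results is not None and active_only:
        act = activity_results.loc[activity_results["active"]]
        keep = {
            (str(c), float(u))
            for c, u in zip(act["compound_id"], act["concentration_um"])
        }

    rows, index_rows = [], []
    grouped = sub_meta.groupby(["compound_id", "concentration_um"], sort=True).groups
    for (compound, conc), idx in grouped.items():
        if keep is not None and (str(compound), float(conc)) not in keep:
            continue
        tid = f"{compound}@{float(conc):g}"
        rows.append(sub_vals.loc[idx].mean(axis=0).rename(tid))
        index_rows.append(
            {"id": tid, "compound_id": compound, "concentration_um": float(conc)}
        )
    if not rows:
        raise ValueError("no treatments to aggregate (nothing active?)")
    profiles = pd.DataFrame(rows)
    index = pd.DataFrame(index_rows).set_index("id")
    return profiles, index


def cluster_profiles(profiles: pd.DataFrame, k: int = 9) -> ClusterModel:
    """Build a full cluster model (distances, tree, labels, signatures)."""
    condensed = correlation_distance_matrix(profiles)
    Z, labels = ward_cluster(condensed, profiles.index, k)
    signatures = cluster_signatures(profiles, labels)
    return ClusterModel(
        ids=[str(i) for i in profiles.index],
        distances=condensed,
        linkage=Z,
        k=k,
        labels=labels,
        signatures=signatures,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.sqrt((xc**2).sum()), np.sqrt((yc**2).sum())
    if nx == 0 or ny == 0:
        raise ValueError("zero-variance vector, correlation undefined")
    return float(xc @ yc / (nx * ny))


def match_to_signatures(
    profile: pd.Series,
    signatures: pd.DataFrame,
    hc_threshold: float = 0.5,
    nc_threshold: float = 0.2,
    target_cluster: int | None = None,
) -> SignatureMatch:
    """Correlate one profile with each cluster signature over shared features.

    The HC/NC call is made on the correlation to *target_cluster* (default:
    the best-matching cluster): HC when ``r >= hc_threshold``, NC when
    ``|r| <= nc_threshold``, else intermediate.
    """
    shared = [f for f in signatures.columns if f in profile.index]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared features; need at least 3")
    p = profile[shared].to_numpy(dtype=float)
    if p.std() == 0:
        raise ValueError(
            f"profile {profile.name!r} has zero variance over the shared features"
        )
    corr = pd.Series(
        {c: _pearson(p, signatures.loc[c, shared].to_numpy(dtype=float)) for c in signatures.index},
        name="r",
    )
    best_cluster = int(corr.idxmax())
    best_r = float(corr.max())
    target = int(target_cluster) if target_cluster is not None else best_cluster
    if target not in corr.index:
        raise ValueError(f"target cluster {target} not among signatures {list(corr.index)}")
    r_t = float(corr.loc[target])
    if r_t >= hc_threshold:
        call = "HC"
    elif abs(r_t) <= nc_threshold:
        call = "NC"
    else:
        call = "intermediate"
    return SignatureMatch(
        profile_id=str(profile.name),
        correlations=corr,
        best_cluster=best_cluster,
        best_r=best_r,
        call=call,
        target_cluster=target,
        hc_threshold=hc_threshold,
        nc_threshold=nc_threshold,
    )


@dataclass
class PCAEmbedding:
    """Uncentered, scaled PCA fit once; subsets/aggregates project through it."""

    feature_names: list[str]
    scales: np.ndarray
    loadings: np.ndarray  # features x components
    explained_variance_ratio: np.ndarray

    def transform(self, profiles: pd.DataFrame, n_components: int | None = None) -> np.ndarray:
        if list(profiles.columns) != self.feature_names:
            profiles = profiles[self.feature_names]
        X = profiles.to_numpy(dtype=float) / self.scales
        coords = X @ self.loadings
        return coords[:, :n_components] if n_components else coords


def fit_pca_embedding(profiles: pd.DataFrame) -> PCAEmbedding:
    """Fit PCA on non-aggregated profiles: columns scaled, not mean-centered."""
    X = profiles.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 profiles to fit the embedding")
    scales = np.sqrt((X**2).sum(axis=0) / (n - 1))
    zero = np.flatnonzero(scales == 0)
    if len(zero):
        bad = [profiles.columns[i] for i in zero]
        raise ValueError(f"zero-variance feature(s); pre-filter before embedding: {bad[:10]}")
    Xs = X / scales
    _, s, vt = np.linalg.svd(Xs, full_matrices=False)
    return PCAEmbedding(
        feature_names=list(profiles.columns),
        scales=scales,
        loadings=vt.T,
        explained_variance_ratio=s**2 / (s**2).sum(),
    )


def leaf_order(linkage: np.ndarray, ids) -> list[str]:
    """Labels in the tree's natural (merge-order) dendrogram leaf order."""
    ids = [str(i) for i in ids]
    return [ids[i] for i in hierarchy.leaves_list(linkage)]


def entanglement(
    linkage1: np.ndarray,
    ids1,
    linkage2: np.ndarray,
    ids2,
    exponent: float = 1.5,
) -> float:
    """Leaf-order disagreement of two dendrograms over the same labels, in [0, 1].

    With ``r1``, ``r2`` the leaf ranks of each label in the two trees,
    ``sum(|r1 - r2|**L)`` is normalized by its value for fully reversed
    ranks.  0 means identical leaf orders; 1 the worst case.
    """
    order1, order2 = leaf_order(linkage1, ids1), leaf_order(linkage2, ids2)
    if set(order1) != set(order2):
        raise ValueError("the two trees are over different label sets")
    n = len(order1)
    if n < 2:
        raise ValueError("need at least 2 labels")
    rank2 = {lab: i for i, lab in enumerate(order2)}
    r1 = np.arange(n, dtype=float)
    r2 = np.array([rank2[lab] for lab in order1], dtype=float)
    numerator = float(np.abs(r1 - r2) ** exponent @ np.ones(n))
    worst = float(np.abs(r1 - r1[::-1]) ** exponent @ np.ones(n))
    return numerator / worst


def category_cluster_summary(
    activity_results: pd.DataFrame,
    labels: pd.DataFrame,
    categories: dict[str, str] | pd.Series,
) -> pd.DataFrame:
    """Per (category, cluster): member count, fraction of category, mean activity.

    *labels* is a treatment-level table with ``compound_id``,
    ``concentration_um`` and ``cluster``; *categories* maps compound to a
    category.  Empty (category, cluster) cells are emitted with zeros.
    """
    cat = pd.Series(categories)
    merged = labels.merge(
        activity_results[["compound_id", "concentration_um", "activity_score"]],
        on=["compound_id", "concentration_um"],
        how="left",
    )
    missing = sorted(set(merged["compound_id"]) - set(cat.index))
    if missing:
        raise ValueError(f"compound(s) without a category: {missing[:10]}")
    merged["category"] = merged["compound_id"].map(cat)

    all_cats = sorted(merged["category"].unique())
    all_clusters = sorted(merged["cluster"].unique())
    grp = merged.groupby(["category", "cluster"])
    counts = grp.size()
    means = grp["activity_score"].mean()
    totals = merged.groupby("category").size()

    rows = []
    for c in all_cats:
        for k in all_clusters:
            n = int(counts.get((c, k), 0))
            rows.append(
                {
                    "category": c,
                    "cluster": k,
                    "n": n,
                    "fraction": n / int(totals[c]),
                    "mean_activity": float(means.get((c, k), 0.0)) if n else 0.0,
                }
            )
    return pd.DataFrame(rows)


def cluster_trajectory(
    compound_id: str,
    activity_results: pd.DataFrame,
    labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Concentration-ordered (cluster, activity, active) trajectory of a compound.

    The cluster label is withheld (missing) at inactive concentrations.
    Trajectories need not pass through intermediate clusters.
    """
    sub = activity_results.loc[activity_results["compound_id"] == compound_id]
    if sub.empty:
        raise ValueError(f"no scored concentrations for compound {compound_id!r}")
    sub = sub.sort_values("concentration_um").reset_index(drop=True)
    out = sub[["concentration_um", "activity_score", "active"]].copy()
    clusters = pd.Series([pd.NA] * len(out), dtype="Int64")
    if labels is not None:
        lab = labels.loc[labels["compound_id"] == compound_id]
        lookup = {float(c): int(k) for c, k in zip(lab["concentration_um"], lab["cluster"])}
        for i, (conc, active) in enumerate(zip(out["concentration_um"], out["active"])):
            if active and float(conc) in lookup:
                clusters.iloc[i] = lookup[float(conc)]
    out["cluster"] = clusters
    out.insert(0, "compound_id", compound_id)
    return out


def to_newick(linkage: np.ndarray, ids) -> str:
    """Serialize a linkage tree as Newick with merge heights as branch lengths."""
    ids = [str(i) for i in ids]
    tree = hierarchy.to_tree(linkage)

    def esc(label: str) -> str:
        return label.replace(" ", "_").replace(",", "_").replace("(", "_").replace(")", "_").replace(":", "_").replace(";", "_")

    def walk(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{esc(ids[node.id])}:{length:g}"
        left = walk(node.get_left(), node.dist)
        right = walk(node.get_right(), node.dist)
        return f"({left},{right}):{length:g}"

    return walk(tree, tree.dist) + ";"
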