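"""Mahalanobis-distance activity scoring and active calling.

A treatment's activity score is the Mahalanobis distance between the
treatment-well centroid and the vehicle-well centroid, computed in a
truncated principal-component space:

1. stack treatment and vehicle well profiles into one matrix;
2. PCA (columns scaled, not mean-centered by default) and keep the first
   ``q`` components explaining at least 90% of the variance;
3. pool the two group covariances weighted by group size,
   ``S = (n_t*S_t + n_c*S_c) / (n_t + n_c)``;
4. ``score = sqrt((mu_t - mu_c)' S^-1 (mu_t - mu_c))``.

The activity cutoff is ``mean + 3*SD`` of a null distribution obtained by
scoring seeded pseudo-groups of vehicle wells against the remaining
vehicle wells; a treatment is active when its score strictly exceeds the
cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .io import FeatureMatrix

__all__ = [
    "MahalanobisScore",
    "ActivityThreshold",
    "ScreenActivity",
    "select_pcs",
    "pooled_covariance",
    "mahalanobis_activity",
    "vehicle_null_distances",
    "call_actives",
    "relative_cell_number",
    "score_screen",
]


@dataclass
class MahalanobisScore:
    score: float
    q: int
    ridge_used: bool


@dataclass
class ActivityThreshold:
    """Vehicle-derived null distances and the resulting activity cutoff."""

    null_distances: np.ndarray
    mean: float
    sd: float
    sd_multiplier: float

    @property
    def cutoff(self) -> float:
        return self.mean + self.sd_multiplier * self.sd


@dataclass
class ScreenActivity:
    """Per-treatment activity table plus the screen's threshold."""

    results: pd.DataFrame
    threshold: ActivityThreshold


def select_pcs(fractions, variance_target: float = 0.90) -> int:
    """Smallest prefix of explained-variance fractions summing to the target.

    If even all components fall short of the target, all are used and a
    warning is emitted.
    """
    frac = np.asarray(fractions, dtype=float)
    if frac.ndim != 1 or len(frac) == 0:
        raise ValueError("explained-variance fractions must be a non-empty 1-D sequence")
    if (frac < 0).any():
        raise ValueError("explained-variance fractions must be non-negative")
    if frac.sum() > 1 + 1e-6:
        raise ValueError(f"explained-variance fractions sum to {frac.sum():.6f} > 1")
    cum = np.cumsum(frac)
    reached = np.flatnonzero(cum >= variance_target - 1e-12)
    if len(reached) == 0:
        warnings.warn(
            f"total explained variance {cum[-1]:.4f} < target {variance_target}; "
            "using all components",
            stacklevel=2,
        )
        return len(frac)
    return int(reached[0]) + 1


def _scaled_pca(
    X: np.ndarray, center: bool = False, scale: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Return (component scores, explained-variance fractions).

    Scaling divides each column by its root mean square about the origin
    (sample SD when centering), with an n-1 denominator; variance is
    measured about the origin when uncentered, matching the R ``prcomp``
    convention for ``center = FALSE``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if center:
        X = X - X.mean(axis=0)
    if scale:
        denom = np.sqrt((X**2).sum(axis=0) / (n - 1))
        zero = np.flatnonzero(denom == 0)
        if len(zero):
            raise ValueError(
                f"zero-scale feature column(s) at indices {zero[:10].tolist()}; "
                "pre-filter constant features"
            )
        X = X / denom
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    total = (s**2).sum()
    fractions = s**2 / total if total > 0 else np.zeros_like(s)
    return u * s, fractions


def pooled_covariance(
    treat_scores: np.ndarray, control_scores: np.ndarray, ridge_eps: float = 1e-6
) -> tuple[np.ndarray, bool]:
    """Sample-size-weighted pooled covariance of two score matrices.

    ``S = (n_t*S_t + n_c*S_c) / (n_t + n_c)`` with each part the ordinary
    sample covariance of its group.  If the pooled matrix is numerically
    singular, a ridge ``ridge_eps * mean(diag(S)) * I`` is added and the
    use reported via the returned flag.
    """
    t = np.atleast_2d(np.asarray(treat_scores, dtype=float))
    c = np.atleast_2d(np.asarray(control_scores, dtype=float))
    if t.shape[0] < 2 or c.shape[0] < 2:
        raise ValueError("each group needs at least 2 rows to estimate a covariance")
    if t.shape[1] != c.shape[1]:
        raise ValueError("group score matrices have differing dimensionality")
    n_t, n_c = t.shape[0], c.shape[0]
    cov_t = np.cov(t, rowvar=False).reshape(t.shape[1], t.shape[1])
    cov_c = np.cov(c, rowvar=False).reshape(c.shape[1], c.shape[1])
    sigma = (n_t * cov_t + n_c * cov_c) / (n_t + n_c)
    if _is_spd(sigma):
        return sigma, False
    ridge = ridge_eps * float(np.mean(np.diag(sigma)))
    if ridge <= 0:
        ridge = ridge_eps
    return sigma + ridge * np.eye(sigma.shape[0]), True


def _is_spd(m: np.ndarray) -> bool:
    try:
        cho_factor(m, check_finite=False)
        return True
    except LinAlgError:
        return False


def mahalanobis_activity(
    treatment_wells,
    vehicle_wells,
    variance_target: float = 0.90,
    center: bool = False,
    scale: bool = True,
    ridge_eps: float = 1e-6,
) -> MahalanobisScore:
    """Score one treatment group against a vehicle group.

    Both arguments are (wells x features) arrays over the same feature
    set.  See module docstring for the algorithm.
    """
    t = np.atleast_2d(np.asarray(treatment_wells, dtype=float))
    c = np.atleast_2d(np.asarray(vehicle_wells, dtype=float))
    if t.shape[1] != c.shape[1]:
        raise ValueError("treatment and vehicle wells have differing feature sets")
    if t.shape[0] < 2:
        raise ValueError("need at least 2 treatment wells")
    if c.shape[0] < 2:
        raise ValueError("need at least 2 vehicle wells")
    n_t = t.shape[0]
    scores, fractions = _scaled_pca(np.vstack([t, c]), center=center, scale=scale)
    q = select_pcs(fractions, variance_target)
    s_t, s_c = scores[:n_t, :q], scores[n_t:, :q]
    sigma, ridge_used = pooled_covariance(s_t, s_c, ridge_eps=ridge_eps)
    diff = s_t.mean(axis=0) - s_c.mean(axis=0)
    try:
        factor = cho_factor(sigma, check_finite=False)
    except LinAlgError as exc:
        raise LinAlgError("pooled covariance singular even after ridge") from exc
    d2 = float(diff @ cho_solve(factor, diff, check_finite=False))
    return MahalanobisScore(score=float(np.sqrt(max(d2, 0.0))), q=q, ridge_used=ridge_used)


def vehicle_null_distances(
    vehicle_wells,
    group_size: int = 4,
    seed: int = 0,
    variance_target: float = 0.90,
    center: bool = False,
    scale: bool = True,
    ridge_eps: float = 1e-6,
) -> np.ndarray:
    """Null activity distances from seeded pseudo-groups of vehicle wells.

    Vehicle wells are shuffled (seeded) and split into consecutive groups
    of *group_size*; each group is scored against all remaining vehicle
    wells.  Returns one distance per group.
    """
    v = np.atleast_2d(np.asarray(vehicle_wells, dtype=float))
    n = v.shape[0]
    if group_size < 2:
        raise ValueError("group_size must be at least 2")
    if n < 2 * group_size:
        raise ValueError(
            f"need at least {2 * group_size} vehicle wells for pseudo-groups of "
            f"{group_size}, got {n}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_groups = n // group_size
    out = np.empty(n_groups, dtype=float)
    mask = np.ones(n, dtype=bool)
    for g in range(n_groups):
        grp = perm[g * group_size : (g + 1) * group_size]
        mask[:] = True
        mask[grp] = False
        out[g] = mahalanobis_activity(
            v[grp],
            v[mask],
            variance_target=variance_target,
            center=center,
            scale=scale,
            ridge_eps=ridge_eps,
        ).score
    return out


def call_actives(
    results: pd.DataFrame,
    null_distances,
    sd_multiplier: float = 3.0,
    min_null: int = 8,
) -> tuple[pd.DataFrame, ActivityThreshold]:
    """Flag treatments whose score strictly exceeds ``mean + k*SD`` of the null."""
    null = np.asarray(null_distances, dtype=float)
    if len(null) < min_null:
        raise ValueError(f"need at least {min_null} null distances, got {len(null)}")
    sd = float(null.std(ddof=1))
    if sd == 0:
        raise ValueError("null distances have zero variance")
    threshold = ActivityThreshold(
        null_distances=null, mean=float(null.mean()), sd=sd, sd_multiplier=sd_multiplier
    )
    out = results.copy()
    out["cutoff"] = threshold.cutoff
    out["active"] = out["activity_score"] > threshold.cutoff
    return out, threshold


def relative_cell_number(treat_meta: pd.DataFrame, vehicle_meta: pd.DataFrame) -> float:
    """Treatment cell count as % of same-plate vehicle mean, averaged over plates."""
    for frame, what in ((treat_meta, "treatment"), (vehicle_meta, "vehicle")):
        if frame["cell_count"].isna().any():
            raise ValueError(f"missing cell counts in {what} wells")
    ratios = []
    for plate, grp in treat_meta.groupby("plate_id", sort=False):
        veh = vehicle_meta.loc[vehicle_meta["plate_id"] == plate, "cell_count"]
        if veh.empty or veh.mean() <= 0:
            raise ValueError(f"plate {plate!r} lacks vehicle wells with positive cell counts")
        ratios.append(100.0 * grp["cell_count"].mean() / veh.mean())
    if not ratios:
        raise ValueError("no treatment wells supplied")
    return float(np.mean(ratios))


def score_screen(
    matrix: FeatureMatrix,
    variance_target: float = 0.90,
    sd_multiplier: float = 3.0,
    null_group_size: int | None = None,
    seed: int = 0,
    center: bool = False,
    scale: bool = True,
    ridge_eps: float = 1e-6,
    min_vehicle_wells: int = 8,
    include_roles: tuple[str, ...] = ("treatment", "positive_control"),
) -> ScreenActivity:
    """Score every compound x concentration of a normalized screen.

    Replicate wells of a treatment are pooled across plates and scored
    against all vehicle wells on the same plates.  The null is built from
    pseudo-groups of vehicle wells (group size defaulting to the number of
    replicate plates) and used to set the activity cutoff.
    """
    meta = matrix.meta
    values = matrix.values.to_numpy(dtype=float)
    veh_mask = (meta["role"] == "vehicle").to_numpy()
    if veh_mask.sum() < min_vehicle_wells:
        raise ValueError(
            f"screen has {int(veh_mask.sum())} vehicle wells; need {min_vehicle_wells}"
        )
    sel = meta["role"].isin(include_roles).to_numpy()
    plates_all = meta["plate_id"].to_numpy()

    rows = []
    groups = (
        meta.loc[sel]
        .groupby(["compound_id", "concentration_um"], sort=True)
        .groups
    )
    for (compound, conc), idx in groups.items():
        idx = np.asarray(idx)
        plates = set(plates_all[idx])
        vmask = veh_mask & np.isin(plates_all, list(plates))
        score = mahalanobis_activity(
            values[idx],
            values[vmask],
            variance_target=variance_target,
            center=center,
            scale=scale,
            ridge_eps=ridge_eps,
        )
        rcn = relative_cell_number(meta.loc[idx], meta.loc[vmask])
        rows.append(
            {
                "compound_id": compound,
                "concentration_um": float(conc),
                "activity_score": score.score,
                "q": score.q,
                "n_treatment_wells": len(idx),
                "n_vehicle_wells": int(vmask.sum()),
                "relative_cell_number": rcn,
            }
        )
    results = pd.DataFrame(rows)

    if null_group_size is None:
        null_group_size = int(meta["plate_id"].nunique())
    null = vehicle_null_distances(
        values[veh_mask],
        group_size=null_group_size,
        seed=seed,
        variance_target=variance_target,
        center=center,
        scale=scale,
        ridge_eps=ridge_eps,
    )
    results, threshold = call_actives(results, null, sd_multiplier=sd_multiplier)
    return ScreenActivity(results=results, threshold=threshold)
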