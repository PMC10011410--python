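"""Per-plate robust normalization and redundant-feature removal.

Feature values are normalized per plate against that plate's vehicle
wells: ``z = (x - median) / (1.4826 * MAD)``.  Features whose vehicle MAD
is zero on any plate are dropped and reported.  Redundancy is removed by
greedy worst-pair elimination until no retained pair of features exceeds
the absolute-Pearson threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FIELD_COLUMN, META_COLUMNS, FeatureMatrix, ProfileValidationError

__all__ = [
    "MAD_SCALE",
    "NormalizationParams",
    "ReductionResult",
    "aggregate_fields_to_wells",
    "robust_z_normalize",
    "reduce_redundant_features",
]

#: Consistency factor making the MAD estimate the SD of a Gaussian.
MAD_SCALE = 1.4826


@dataclass
class NormalizationParams:
    """Per-plate, per-feature robust location/scale derived from vehicle wells."""

    location: pd.DataFrame  # plates x retained features: vehicle medians
    scale: pd.DataFrame  # plates x retained features: 1.4826 * MAD
    dropped: pd.DataFrame  # columns: feature, plate, reason
    min_vehicle_wells: int

    @property
    def retained_features(self) -> list[str]:
        return list(self.location.columns)


@dataclass
class ReductionResult:
    """Outcome of greedy correlation-based feature elimination."""

    retained: list[str]
    dropped: pd.DataFrame  # columns: feature, paired_with, abs_r
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return self.dropped.copy()


def aggregate_fields_to_wells(matrix: FeatureMatrix) -> FeatureMatrix:
    """Collapse a field-level table to well level.

    Per well, each feature becomes the arithmetic mean over its fields and
    ``cell_count`` the sum over fields.  Other metadata must be constant
    within a well.
    """
    if not matrix.is_field_level:
        raise ProfileValidationError("field column missing: table is not field-level")
    meta, values = matrix.meta, matrix.values
    key = ["plate_id", "well"]
    grouped = values.groupby([meta[k] for k in key], sort=False)
    agg_values = grouped.mean().reset_index(drop=True)

    meta_rows = []
    for (_, _), idx in meta.groupby(key, sort=False).groups.items():
        sub = meta.loc[idx]
        rec = {c: sub[c].iloc[0] for c in META_COLUMNS}
        const_cols = [c for c in META_COLUMNS if c != "cell_count"]
        for c in const_cols:
            if sub[c].nunique(dropna=False) > 1:
                raise ProfileValidationError(
                    f"inconsistent {c!r} across fields of well "
                    f"({rec['plate_id']!r}, {rec['well']!r})"
                )
        rec["cell_count"] = sub["cell_count"].sum()
        meta_rows.append(rec)
    agg_meta = pd.DataFrame(meta_rows, columns=list(META_COLUMNS))
    return FeatureMatrix(agg_meta, agg_values, provenance=matrix.provenance)


def robust_z_normalize(
    matrix: FeatureMatrix, min_vehicle_wells: int = 8
) -> tuple[FeatureMatrix, NormalizationParams]:
    """Robust z-score each feature per plate against the plate's vehicle wells.

    Returns the normalized matrix (features with zero vehicle MAD on any
    plate removed) and the parameters used.
    """
    meta, values = matrix.meta, matrix.values
    plates = list(dict.fromkeys(meta["plate_id"]))
    features = matrix.feature_names

    loc_rows: dict[object, pd.Series] = {}
    scale_rows: dict[object, pd.Series] = {}
    dropped: list[dict] = []
    for plate in plates:
        on_plate = meta["plate_id"] == plate
        veh = on_plate & (meta["role"] == "vehicle")
        n_veh = int(veh.sum())
        if n_veh == 0:
            raise ProfileValidationError(f"plate {plate!r} has no vehicle wells")
        if n_veh < min_vehicle_wells:
            raise ProfileValidationError(
                f"plate {plate!r} has only {n_veh} vehicle wells "
                f"(minimum {min_vehicle_wells})"
            )
        v = values.loc[veh.to_numpy()]
        med = v.median(axis=0)
        mad = (v - med).abs().median(axis=0) * MAD_SCALE
        loc_rows[plate] = med
        scale_rows[plate] = mad
        for f in np.asarray(features)[(mad == 0).to_numpy()]:
            dropped.append({"feature": f, "plate": plate, "reason": "zero vehicle MAD"})

    dropped_df = pd.DataFrame(dropped, columns=["feature", "plate", "reason"])
    bad = set(dropped_df["feature"])
    keep = [f for f in features if f not in bad]
    if not keep:
        raise ProfileValidationError("all features dropped: zero vehicle spread everywhere")

    location = pd.DataFrame(loc_rows).T[keep]
    scale = pd.DataFrame(scale_rows).T[keep]
    location.index.name = scale.index.name = "plate_id"

    z = values[keep].copy()
    for plate in plates:
        on_plate = (meta["plate_id"] == plate).to_numpy()
        z.loc[on_plate] = (
            z.loc[on_plate] - location.loc[plate]
        ) / scale.loc[plate]
    out = matrix.with_values(z, provenance="normalized")
    params = NormalizationParams(location, scale, dropped_df, min_vehicle_wells)
    return out, params


def reduce_redundant_features(
    matrix: FeatureMatrix, threshold: float = 0.9
) -> tuple[FeatureMatrix, ReductionResult]:
    """Greedy elimination of highly correlated features.

    While any retained pair has ``|Pearson r| > threshold``, the worst
    (largest ``|r|``) pair is located and the member with the larger mean
    absolute correlation to all remaining features is dropped; ties drop
    the lexicographically later feature name.  Deterministic, and the
    output satisfies pairwise ``|r| <= threshold`` (hence idempotent).
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if matrix.n_wells < 2:
        raise ProfileValidationError("need at least 2 wells to estimate correlations")

    X = matrix.values.to_numpy(dtype=float)
    names = matrix.feature_names
    sd = X.std(axis=0)
    if (sd == 0).any():
        zeros = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ProfileValidationError(f"zero-variance feature(s), cannot correlate: {zeros[:10]}")

    A = np.abs(np.corrcoef(X, rowvar=False))
    A = (A + A.T) / 2.0  # corrcoef is asymmetric at the last-ulp level
    np.fill_diagonal(A, 0.0)
    alive = np.ones(len(names), dtype=bool)
    drops: list[dict] = []
    while True:
        idx = np.flatnonzero(alive)
        if len(idx) < 2:
            break
        sub = A[np.ix_(idx, idx)]
        worst = float(sub.max())
        if worst <= threshold:
            break
        i_s, j_s = np.unravel_index(int(sub.argmax()), sub.shape)
        i, j = int(idx[i_s]), int(idx[j_s])
        mean_i = A[i, idx].sum() / (len(idx) - 1)
        mean_j = A[j, idx].sum() / (len(idx) - 1)
        if mean_i > mean_j:
            drop, keep = i, j
        elif mean_j > mean_i:
            drop, keep = j, i
        else:  # tie: drop the lexicographically later name
            drop, keep = (i, j) if names[i] > names[j] else (j, i)
        drops.append(
            {"feature": names[drop], "paired_with": names[keep], "abs_r": worst}
        )
        alive[drop] = False

    retained = [n for n, a in zip(names, alive) if a]
    reduced = matrix.select_features(retained, provenance="reduced")
    result = ReductionResult(
        retained=retained,
        dropped=pd.DataFrame(drops, columns=["feature", "paired_with", "abs_r"]),
        threshold=threshold,
    )
    return reduced, result
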