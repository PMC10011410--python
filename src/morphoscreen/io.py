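"""Well-level profile tables, plate maps, and feature-space alignment.

A profile table is delimited text (CSV) whose header starts with the
reserved metadata columns

    plate_id, well, compound_id, concentration_um, replicate, role, cell_count

optionally followed by a ``field`` column (for field-level, pre-aggregation
tables), then any number of numeric feature columns.  Wells are 384-well
positions, rows ``A``-``P`` and zero-padded columns ``01``-``24``
(e.g. ``A01``, ``P24``).  Concentrations are micromolar throughout; vehicle
wells carry concentration 0 and the compound id ``VEHICLE``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "META_COLUMNS",
    "FIELD_COLUMN",
    "ROLES",
    "VEHICLE",
    "FeatureMatrix",
    "ProfileValidationError",
    "PlateMapReport",
    "read_profiles",
    "write_profiles",
    "align_shared_features",
    "validate_platemap",
    "well_coordinates",
    "well_label",
    "is_valid_well",
]

META_COLUMNS = (
    "plate_id",
    "well",
    "compound_id",
    "concentration_um",
    "replicate",
    "role",
    "cell_count",
)
FIELD_COLUMN = "field"
ROLES = frozenset(
    {"treatment", "vehicle", "positive_control", "reagent_free", "cell_free", "standard"}
)
VEHICLE = "VEHICLE"

_WELL_RE = re.compile(r"^([A-P])([0-9]{2})$")
_PLATE_ROWS = "ABCDEFGHIJKLMNOP"


class ProfileValidationError(ValueError):
    """A profile table or plate map violates the schema contract."""


def is_valid_well(label: object) -> bool:
    """True if *label* is a valid 384-well position such as ``B07``."""
    if not isinstance(label, str):
        return False
    m = _WELL_RE.match(label)
    return bool(m) and 1 <= int(m.group(2)) <= 24


def well_coordinates(label: str) -> tuple[int, int]:
    """Map a well label to 0-based (row, column) coordinates."""
    if not is_valid_well(label):
        raise ProfileValidationError(f"invalid 384-well position label: {label!r}")
    m = _WELL_RE.match(label)
    assert m is not None
    return _PLATE_ROWS.index(m.group(1)), int(m.group(2)) - 1


def well_label(row: int, col: int) -> str:
    """Map 0-based (row, column) coordinates to a label like ``A01``."""
    if not (0 <= row < 16 and 0 <= col < 24):
        raise ProfileValidationError(f"coordinates out of 384-well range: ({row}, {col})")
    return f"{_PLATE_ROWS[row]}{col + 1:02d}"


class FeatureMatrix:
    """A rectangular wells x features table with per-well metadata.

    Parameters
    ----------
    meta:
        DataFrame holding the reserved metadata columns (plus an optional
        ``field`` column for field-level tables).
    values:
        Numeric DataFrame, one row per well (aligned with *meta*), one
        column per feature.  Feature names must be unique and disjoint
        from the reserved names.
    provenance:
        One of ``raw``, ``normalized``, ``reduced``.
    """

    PROVENANCES = ("raw", "normalized", "reduced")

    def __init__(
        self,
        meta: pd.DataFrame,
        values: pd.DataFrame,
        provenance: str = "raw",
        validate: bool = True,
    ):
        if provenance not in self.PROVENANCES:
            raise ProfileValidationError(f"unknown provenance: {provenance!r}")
        self.meta = meta.reset_index(drop=True)
        self.values = values.reset_index(drop=True)
        self.provenance = provenance
        if validate:
            self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "raw") -> "FeatureMatrix":
        """Split a combined table into metadata and feature parts."""
        missing = [c for c in META_COLUMNS if c not in frame.columns]
        if missing:
            raise ProfileValidationError(f"missing reserved column(s): {missing}")
        meta_cols = list(META_COLUMNS)
        if FIELD_COLUMN in frame.columns:
            meta_cols.append(FIELD_COLUMN)
        feats = [c for c in frame.columns if c not in meta_cols]
        return cls(frame[meta_cols], frame[feats], provenance=provenance)

    def _validate(self) -> None:
        if len(self.meta) != len(self.values):
            raise ProfileValidationError(
                f"metadata ({len(self.meta)} rows) and values ({len(self.values)} rows) disagree"
            )
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ProfileValidationError(f"missing reserved column(s): {missing}")
        feats = list(self.values.columns)
        if len(set(feats)) != len(feats):
            dupes = sorted({f for f in feats if feats.count(f) > 1})
            raise ProfileValidationError(f"duplicate feature name(s): {dupes}")
        clash = sorted(set(feats) & set(self.meta.columns))
        if clash:
            raise ProfileValidationError(f"feature name(s) clash with reserved columns: {clash}")

        bad_wells = sorted({w for w in self.meta["well"] if not is_valid_well(w)})
        if bad_wells:
            raise ProfileValidationError(f"invalid well position label(s): {bad_wells[:10]}")
        bad_roles = sorted(set(self.meta["role"]) - ROLES)
        if bad_roles:
            raise ProfileValidationError(f"unknown role(s): {bad_roles}")

        conc = pd.to_numeric(self.meta["concentration_um"], errors="coerce")
        if conc.isna().any() or (conc < 0).any():
            bad = self.meta.loc[conc.isna() | (conc < 0), ["plate_id", "well"]]
            raise ProfileValidationError(
                f"negative or unparseable concentration at wells: {bad.values.tolist()[:10]}"
            )
        veh = self.meta["role"] == "vehicle"
        if (conc[veh] != 0).any():
            bad = self.meta.loc[veh & (conc != 0), ["plate_id", "well"]]
            raise ProfileValidationError(
                f"vehicle wells must have concentration 0: {bad.values.tolist()[:10]}"
            )

        key_cols = ["plate_id", "well"]
        if FIELD_COLUMN in self.meta.columns:
            key_cols.append(FIELD_COLUMN)
        dup = self.meta.duplicated(subset=key_cols, keep=False)
        if dup.any():
            pairs = self.meta.loc[dup, key_cols].drop_duplicates().values.tolist()
            raise ProfileValidationError(f"duplicate well record(s): {pairs[:10]}")

        all_na = [c for c in self.values.columns if self.values[c].isna().all()]
        if all_na:
            raise ProfileValidationError(f"feature column(s) with all values missing: {all_na}")
        for c in self.values.columns:
            col = pd.to_numeric(self.values[c], errors="coerce")
            if col.isna().any():
                row = int(np.flatnonzero(col.isna().to_numpy())[0])
                raise ProfileValidationError(
                    f"unparseable or missing value in feature {c!r} at row {row} "
                    f"(plate {self.meta['plate_id'].iloc[row]!r}, well {self.meta['well'].iloc[row]!r})"
                )
            self.values[c] = col.astype(float)

    # -- basic accessors ---------------------------------------------------

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_wells(self) -> int:
        return len(self.meta)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def is_field_level(self) -> bool:
        return FIELD_COLUMN in self.meta.columns

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.meta.copy(), self.values.copy(), self.provenance, validate=False
        )

    def subset(self, mask: Sequence[bool] | pd.Series) -> "FeatureMatrix":
        """Row-subset by boolean mask, preserving feature order."""
        mask = np.asarray(mask, dtype=bool)
        return FeatureMatrix(
            self.meta.loc[mask], self.values.loc[mask], self.provenance, validate=False
        )

    def select_features(
        self, names: Iterable[str], provenance: str | None = None
    ) -> "FeatureMatrix":
        names = list(names)
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise ProfileValidationError(f"unknown feature(s): {missing[:10]}")
        return FeatureMatrix(
            self.meta.copy(),
            self.values[names].copy(),
            provenance or self.provenance,
            validate=False,
        )

    def with_values(self, values: pd.DataFrame, provenance: str) -> "FeatureMatrix":
        """Same wells, new feature values (used by normalization stages)."""
        return FeatureMatrix(self.meta.copy(), values, provenance, validate=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.meta.reset_index(drop=True), self.values.reset_index(drop=True)], axis=1
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.meta.equals(other.meta)
            and self.values.equals(other.values)
            and self.provenance == other.provenance
        )

    def __repr__(self) -> str:
        return (
            f"FeatureMatrix({self.n_wells} wells x {self.n_features} features, "
            f"provenance={self.provenance!r})"
        )


def read_profiles(path: str | Path, provenance: str = "raw") -> FeatureMatrix:
    """Read a profile table from delimited text.

    Raises :class:`ProfileValidationError` naming the offending row or
    column for duplicate wells, ragged rows, unparseable numbers, or
    all-missing feature columns.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ProfileValidationError(f"ragged or malformed row in {path}: {exc}") from exc
    if frame.empty:
        raise ProfileValidationError(f"empty profile table: {path}")
    return FeatureMatrix.from_frame(frame, provenance=provenance)


def write_profiles(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a profile table as CSV (lossless float round-trip)."""
    matrix.to_frame().to_csv(path, index=False)


def align_shared_features(
    a: FeatureMatrix, b: FeatureMatrix
) -> tuple[FeatureMatrix, FeatureMatrix, list[str]]:
    """Restrict two matrices to their shared features, identically ordered.

    The intersection keeps the feature order of *a*.  Returns the two
    restricted matrices and the shared feature names.
    """
    b_set = set(b.feature_names)
    shared = [f for f in a.feature_names if f in b_set]
    if not shared:
        raise ProfileValidationError("no shared features between the two matrices")
    return a.select_features(shared), b.select_features(shared), shared


@dataclass
class PlateMapReport:
    """Validation summary for a plate layout table."""

    role_counts: pd.DataFrame  # plates x roles well counts
    issues: list[str] = field(default_factory=list)
    fatal: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_platemap(platemap: pd.DataFrame) -> PlateMapReport:
    """Check a plate layout table; report-only (never raises on content).

    Expects columns ``plate_id``, ``well``, ``role`` and optionally
    ``compound_id``/``concentration_um``.  Plates without vehicle wells are
    flagged fatal because per-plate normalization is impossible without
    them.
    """
    issues: list[str] = []
    fatal: list[str] = []
    required = {"plate_id", "well", "role"}
    missing = sorted(required - set(platemap.columns))
    if missing:
        fatal.append(f"missing plate-map column(s): {missing}")
        return PlateMapReport(pd.DataFrame(), issues, fatal)

    bad_wells = sorted({w for w in platemap["well"] if not is_valid_well(w)})
    if bad_wells:
        issues.append(f"invalid well position label(s): {bad_wells[:10]}")
    bad_roles = sorted(set(platemap["role"]) - ROLES)
    if bad_roles:
        issues.append(f"unknown role(s): {bad_roles}")
    dup = platemap.duplicated(subset=["plate_id", "well"], keep=False)
    if dup.any():
        pairs = platemap.loc[dup, ["plate_id", "well"]].drop_duplicates().values.tolist()
        issues.append(f"duplicate well(s): {pairs[:10]}")

    counts = (
        platemap.groupby(["plate_id", "role"]).size().unstack(fill_value=0).sort_index()
    )
    for plate in counts.index:
        n_veh = int(counts.loc[plate].get("vehicle", 0))
        if n_veh == 0:
            fatal.append(f"plate {plate!r} has no vehicle wells (normalization impossible)")
    return PlateMapReport(counts, issues, fatal)
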