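"""Live-cell time-course summarization and glutathione quantification.

Time courses arrive in long format (one row per plate/well/metric/time)
with confluence and injury metrics sampled on a fixed grid; fluorescence
metrics are background-corrected against reagent-free wells on the same
plate and summarized as trapezoid AUCs over time.

Glutathione plates carry triplicate 10-point GSH standards (2-fold from
6.4 uM), cell-free background wells, and total/GSSG luminescence per
treatment.  Concentrations are recovered by inverting a least-squares
standard curve; GSH = total - 2*GSSG (two reduced equivalents per
oxidized dimer), and the ratio GSH:GSSG is withheld with a flag when
computed GSH is negative, when GSSG exceeds 200% of vehicle, or when
GSSG is non-positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TIMECOURSE_COLUMNS",
    "FLUORESCENCE_METRICS",
    "StandardCurve",
    "trapezoid_auc",
    "background_correct",
    "summarize_health",
    "fit_standard_curve",
    "invert_standard_curve",
    "quantify_glutathione",
    "quantify_glutathione_plate",
]

TIMECOURSE_COLUMNS = (
    "plate_id",
    "well",
    "compound_id",
    "concentration_um",
    "replicate",
    "role",
    "metric",
    "time_h",
    "value",
)
#: Metrics corrected against reagent-free wells (cellular auto-fluorescence).
FLUORESCENCE_METRICS = ("caspase_count", "membrane_count", "overlap_count")


def trapezoid_auc(times, values) -> float:
    """Composite trapezoid AUC over the recorded grid (metric-units x hours)."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError("times and values must be equal-length 1-D sequences")
    if len(t) < 2:
        raise ValueError("need at least 2 time points")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(v, t))


def background_correct(
    timecourses: pd.DataFrame,
    metrics: tuple[str, ...] = FLUORESCENCE_METRICS,
) -> tuple[pd.DataFrame, int]:
    """Subtract the per-plate reagent-free mean from fluorescence metrics.

    Correction is applied per plate, metric and time point.  Negative
    corrected values are clipped to 0; the clip count is returned so
    callers can log it.  Raises if a plate lacks reagent-free wells.
    """
    df = timecourses.copy()
    reagent_free = df["role"] == "reagent_free"
    n_clipped = 0
    for plate in df["plate_id"].unique():
        on_plate = df["plate_id"] == plate
        if not (on_plate & reagent_free).any():
            raise ValueError(f"plate {plate!r} has no reagent-free wells for background")
        for metric in metrics:
            sel = on_plate & (df["metric"] == metric)
            if not sel.any():
                continue
            bg = (
                df.loc[sel & reagent_free]
                .groupby("time_h")["value"]
                .mean()
            )
            target = sel & ~reagent_free
            corrected = df.loc[target, "value"] - df.loc[target, "time_h"].map(bg).fillna(0.0)
            n_clipped += int((corrected < 0).sum())
            df.loc[target, "value"] = corrected.clip(lower=0.0)
    return df, n_clipped


def summarize_health(
    timecourses: pd.DataFrame,
    exclusions: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per compound x concentration x metric trapezoid AUC.

    AUCs are computed per well and averaged over replicate wells.
    Compounds listed in *exclusions* (e.g. auto-fluorescent) stay in the
    table with ``excluded=True`` so downstream aggregates can skip them.
    """
    excl = set(exclusions)
    rows = []
    treatable = timecourses.loc[~timecourses["role"].isin(["reagent_free", "cell_free"])]
    grouped = treatable.groupby(["compound_id", "concentration_um", "metric"], sort=True)
    for (compound, conc, metric), sub in grouped:
        aucs = []
        for (_, _), trace in sub.groupby(["plate_id", "well"], sort=False):
            trace = trace.sort_values("time_h")
            aucs.append(trapezoid_auc(trace["time_h"], trace["value"]))
        rows.append(
            {
                "compound_id": compound,
                "concentration_um": float(conc),
                "metric": metric,
                "auc": float(np.mean(aucs)),
                "n_wells": len(aucs),
                "excluded": compound in excl,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class StandardCurve:
    """Least-squares line through background-corrected standards."""

    concentrations_um: np.ndarray
    mean_luminescence: np.ndarray
    slope: float
    intercept: float
    residual_sd: float
    recovery_max_rel_err: float  # recovery check on the standards themselves


def fit_standard_curve(concentrations_um, luminescence) -> StandardCurve:
    """Fit ``lum = slope * conc + intercept`` on background-corrected standards.

    Requires at least 5 distinct standard levels and a positive slope.
    Replicate readings at a level are averaged first.
    """
    conc = np.asarray(concentrations_um, dtype=float)
    lum = np.asarray(luminescence, dtype=float)
    if conc.shape != lum.shape:
        raise ValueError("concentrations and luminescence must be the same length")
    levels = pd.DataFrame({"conc": conc, "lum": lum}).groupby("conc")["lum"].mean()
    if len(levels) < 5:
        raise ValueError(f"need at least 5 standard levels, got {len(levels)}")
    x, y = levels.index.to_numpy(), levels.to_numpy()
    fit = stats.linregress(x, y)
    if fit.slope <= 0:
        raise ValueError(f"non-positive standard-curve slope: {fit.slope:g}")
    predicted = fit.intercept + fit.slope * x
    residual_sd = float(np.sqrt(np.mean((y - predicted) ** 2)))
    recovered = (y - fit.intercept) / fit.slope
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(recovered - x) / np.where(x > 0, x, np.nan)
    return StandardCurve(
        concentrations_um=x,
        mean_luminescence=y,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residual_sd=residual_sd,
        recovery_max_rel_err=float(np.nanmax(rel)),
    )


def invert_standard_curve(curve: StandardCurve, luminescence) -> np.ndarray:
    """Recover concentration (uM) from background-corrected luminescence."""
    lum = np.asarray(luminescence, dtype=float)
    return (lum - curve.intercept) / curve.slope


def quantify_glutathione(
    measurements: pd.DataFrame,
    curve: StandardCurve,
    gssg_curve: StandardCurve | None = None,
    gssg_outlier_pct: float = 200.0,
) -> pd.DataFrame:
    """Quantify GSH/GSSG per treatment and apply the outlier rules.

    *measurements* needs one row per compound x concentration with columns
    ``compound_id``, ``concentration_um``, ``role``, ``total_lum``,
    ``gssg_lum`` (background-corrected, replicate-averaged).  Vehicle rows
    (``role == 'vehicle'``) define the percent-of-vehicle reference.

    GSSG luminescence is inverted through *gssg_curve* (default: same
    curve as total).  ``GSH = total - 2*GSSG``; flags:

    - ``gsh_negative``: computed GSH < 0, ratio withheld;
    - ``outlier_gssg``: GSSG above ``gssg_outlier_pct`` % of vehicle;
    - ``gssg_zero``: GSSG <= 0 with GSH > 0, ratio undefined-high;
    - ``ok`` otherwise (the only flag with a reported ratio).
    """
    req = {"compound_id", "concentration_um", "role", "total_lum", "gssg_lum"}
    missing = sorted(req - set(measurements.columns))
    if missing:
        raise ValueError(f"missing measurement column(s): {missing}")
    df = measurements.copy()
    df["total_um"] = invert_standard_curve(curve, df["total_lum"])
    df["gssg_um"] = invert_standard_curve(gssg_curve or curve, df["gssg_lum"])
    df["gsh_um"] = df["total_um"] - 2.0 * df["gssg_um"]

    veh = df.loc[df["role"] == "vehicle"]
    if veh.empty:
        raise ValueError("no vehicle reference rows in the measurements")
    veh_total = float(veh["total_um"].mean())
    veh_gssg = float(veh["gssg_um"].mean())
    if veh_total <= 0 or veh_gssg <= 0:
        raise ValueError("vehicle reference concentrations must be positive")
    df["total_pct"] = 100.0 * df["total_um"] / veh_total
    df["gssg_pct"] = 100.0 * df["gssg_um"] / veh_gssg

    flags, ratios = [], []
    for gsh, gssg, gssg_pct in zip(df["gsh_um"], df["gssg_um"], df["gssg_pct"]):
        if gsh < 0:
            flags.append("gsh_negative")
            ratios.append(np.nan)
        elif gssg_pct > gssg_outlier_pct:
            flags.append("outlier_gssg")
            ratios.append(np.nan)
        elif gssg <= 0:
            flags.append("gssg_zero")
            ratios.append(np.nan)
        else:
            flags.append("ok")
            ratios.append(gsh / gssg)
    df["ratio"] = ratios
    df["flag"] = flags
    return df


def quantify_glutathione_plate(
    plate: pd.DataFrame,
    gssg_outlier_pct: float = 200.0,
) -> tuple[pd.DataFrame, StandardCurve]:
    """End-to-end quantification of a long-format glutathione plate table.

    Expects columns ``compound_id``, ``concentration_um``, ``role``,
    ``assay`` (``total``/``gssg``), ``standard_um`` and ``lum``.  Cell-free
    wells define the background per assay; standards (on the total assay)
    define the curve; treatment and vehicle wells are replicate-averaged
    and passed to :func:`quantify_glutathione`.
    """
    req = {"compound_id", "concentration_um", "role", "assay", "standard_um", "lum"}
    missing = sorted(req - set(plate.columns))
    if missing:
        raise ValueError(f"missing glutathione plate column(s): {missing}")
    bg = plate.loc[plate["role"] == "cell_free"].groupby("assay")["lum"].mean()
    if bg.empty:
        raise ValueError("no cell-free background wells on the glutathione plate")
    corrected = plate.copy()
    corrected["lum"] = corrected["lum"] - corrected["assay"].map(bg).fillna(float(bg.mean()))

    std = corrected.loc[(corrected["role"] == "standard") & (corrected["assay"] == "total")]
    if std.empty:
        raise ValueError("no GSH standard wells on the glutathione plate")
    curve = fit_standard_curve(std["standard_um"], std["lum"])

    samples = corrected.loc[corrected["role"].isin(["treatment", "vehicle", "positive_control"])]
    wide = (
        samples.pivot_table(
            index=["compound_id", "concentration_um", "role"],
            columns="assay",
            values="lum",
            aggfunc="mean",
        )
        .reset_index()
        .rename(columns={"total": "total_lum", "gssg": "gssg_lum"})
    )
    results = quantify_glutathione(wide, curve, gssg_outlier_pct=gssg_outlier_pct)
    return results, curve
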