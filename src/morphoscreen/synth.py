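"""Seeded synthetic screens with ground truth for recovery testing.

The generator emits 384-well plate layouts with vehicle wells, positive
controls, and compounds in six-dose concentration response across
replicate plates.  Treatment well profiles follow

    value = plate_offset + m(c) * signature + noise
    m(c)  = effect_max * c**h / (c**h + ec50**h)

on a latent (normalized) scale, mapped to a raw scale through per-feature
location/scale so that robust per-plate normalization has real work to do.
Noise is drawn in correlated blocks (shared block factor + idiosyncratic
part) so redundancy removal has real work to do; planted phenotype
signatures are block-constant unit vectors with bounded pairwise cosine.
Expected cell count decays log-linearly with effect magnitude
(``baseline * exp(coupling * m)``) with Poisson sampling.

Everything is driven by one master seed; identical configs produce
byte-identical serialized outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import VEHICLE, FeatureMatrix, well_label

__all__ = [
    "SynthConfig",
    "generate_signatures",
    "generate_screen",
    "generate_timecourses",
    "generate_glutathione_plate",
    "hill_effect",
]

#: sampling grid of the live-cell imager: every 4 h for 60 h
TIMECOURSE_HOURS = tuple(range(0, 61, 4))
#: 10-point GSH standard series, 2-fold dilutions from 6.4 uM
GSH_STANDARDS_UM = tuple(6.4 / 2**i for i in range(10))


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic screen; see module docstring for the model."""

    n_features: int = 120
    n_clusters: int = 9
    n_compounds_per_cluster: int = 2
    n_inert_compounds: int = 6
    concentrations: tuple[float, ...] = (0.625, 1.25, 2.5, 5.0, 10.0, 20.0)
    n_replicate_plates: int = 4
    n_vehicle_wells_per_plate: int = 116
    plate_rows: int = 16
    plate_cols: int = 24
    n_positive_controls: int = 4
    effect_ec50: float = 2.5
    hill_slope: float = 2.0
    effect_max: float = 3.0
    noise_sd: float = 1.0
    block_size: int = 4
    block_correlation: float = 0.95
    plate_noise_sd: float = 0.25
    cellcount_coupling: float = -0.7
    baseline_cells_per_well: int = 1500
    active_m_min: float | None = None  # default: 2 * noise_sd
    seed: int = 0

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        if len(conc) == 0 or (conc <= 0).any() or not np.all(np.diff(conc) > 0):
            raise ValueError("concentrations must be strictly increasing and positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 <= self.block_correlation < 1):
            raise ValueError("block_correlation must be in [0, 1)")
        if self.block_size < 1 or self.n_features % self.block_size:
            raise ValueError("block_size must divide n_features")
        if self.n_blocks < self.n_clusters:
            raise ValueError(
                f"{self.n_clusters} signatures cannot fit in {self.n_blocks} feature blocks"
            )
        capacity = self.plate_rows * self.plate_cols
        needed = (
            self.n_vehicle_wells_per_plate
            + (self.n_positive_controls + self.n_treatment_compounds) * len(conc)
        )
        if needed > capacity:
            raise ValueError(
                f"plate layout needs {needed} wells but capacity is {capacity}"
            )

    @property
    def n_blocks(self) -> int:
        return self.n_features // self.block_size

    @property
    def n_treatment_compounds(self) -> int:
        return self.n_clusters * self.n_compounds_per_cluster + self.n_inert_compounds

    @property
    def active_threshold(self) -> float:
        return 2.0 * self.noise_sd if self.active_m_min is None else self.active_m_min


def hill_effect(conc, effect_max: float, ec50: float, hill_slope: float) -> np.ndarray:
    """Effect magnitude ``m(c) = effect_max * c**h / (c**h + ec50**h)``."""
    c = np.asarray(conc, dtype=float)
    ch = c**hill_slope
    return effect_max * ch / (ch + ec50**hill_slope)


def generate_signatures(
    k: int,
    n_features: int,
    seed: int,
    block_size: int = 1,
    max_cosine: float = 0.3,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Draw k unit-norm phenotype signatures with bounded pairwise cosine.

    Signatures are drawn in block space (constant within each correlated
    feature block) and expanded to feature space, preserving norms and
    cosines.  Vectors violating the cosine bound against already-accepted
    ones are redrawn; impossible geometry (k too large for the bound)
    fails explicitly.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if n_features < k:
        raise ValueError("need n_features >= k")
    if block_size < 1 or n_features % block_size:
        raise ValueError("block_size must divide n_features")
    n_blocks = n_features // block_size
    if n_blocks < k:
        raise ValueError(
            f"impossible geometry: {k} signatures in {n_blocks} feature blocks"
        )
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    for i in range(k):
        for _ in range(max_tries):
            v = rng.standard_normal(n_blocks)
            v /= np.linalg.norm(v)
            if all(abs(v @ u) <= max_cosine for u in accepted):
                accepted.append(v)
                break
        else:
            raise ValueError(
                f"impossible geometry: could not place signature {i + 1}/{k} in "
                f"{n_blocks} blocks at cosine bound {max_cosine}"
            )
    block_sig = np.vstack(accepted)
    return np.repeat(block_sig, block_size, axis=1) / np.sqrt(block_size)


def _compound_table(config: SynthConfig) -> pd.DataFrame:
    rows = []
    i = 0
    for cluster in range(1, config.n_clusters + 1):
        for _ in range(config.n_compounds_per_cluster):
            rows.append(
                {
                    "compound_id": f"C{i:03d}",
                    "role": "treatment",
                    "cluster": cluster,
                    "effect_max": config.effect_max,
                }
            )
            i += 1
    for j in range(config.n_inert_compounds):
        rows.append(
            {"compound_id": f"I{j:03d}", "role": "treatment", "cluster": 0, "effect_max": 0.0}
        )
    for j in range(config.n_positive_controls):
        rows.append(
            {
                "compound_id": f"CTRL{j + 1}",
                "role": "positive_control",
                "cluster": (j % config.n_clusters) + 1,
                "effect_max": config.effect_max,
            }
        )
    return pd.DataFrame(rows)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def generate_screen(config: SynthConfig) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Generate a seeded multi-plate screen and its ground truth.

    Returns the raw-scale well x feature matrix and a ground-truth table
    with one row per compound x concentration: planted cluster (0 for
    inert), effect magnitude ``m(c)``, and the true-active flag
    (``m(c) >= active_threshold``).
    """
    k, p = config.n_clusters, config.n_features
    conc = np.asarray(config.concentrations, dtype=float)
    signatures = generate_signatures(k, p, seed=config.seed, block_size=config.block_size)
    sig_rows = np.vstack([np.zeros(p), signatures])  # row 0: no phenotype

    compounds = _compound_table(config)
    effects = {
        row.compound_id: hill_effect(conc, row.effect_max, config.effect_ec50, config.hill_slope)
        for row in compounds.itertuples()
    }

    rng_feat = _rng(config.seed, 1)
    feat_loc = rng_feat.normal(5.0, 2.0, size=p)
    feat_scale = rng_feat.lognormal(mean=0.0, sigma=0.3, size=p)
    feature_names = [
        f"feat_{b:03d}_{j:02d}"
        for b in range(config.n_blocks)
        for j in range(config.block_size)
    ]
    block_of = np.repeat(np.arange(config.n_blocks), config.block_size)

    rng_layout = _rng(config.seed, 2)
    rng_noise = _rng(config.seed, 3)
    rng_counts = _rng(config.seed, 4)

    all_positions = [
        well_label(r, c) for r in range(config.plate_rows) for c in range(config.plate_cols)
    ]
    rho = config.block_correlation

    meta_frames, value_blocks = [], []
    for plate_idx in range(config.n_replicate_plates):
        plate_id = f"P{plate_idx + 1:02d}"
        positions = np.array(all_positions)
        rng_layout.shuffle(positions)

        recs: list[dict] = []
        cursor = 0
        for _ in range(config.n_vehicle_wells_per_plate):
            recs.append(
                {
                    "compound_id": VEHICLE,
                    "concentration_um": 0.0,
                    "role": "vehicle",
                    "cluster": 0,
                    "m": 0.0,
                }
            )
        for row in compounds.itertuples():
            for ci, c in enumerate(conc):
                recs.append(
                    {
                        "compound_id": row.compound_id,
                        "concentration_um": float(c),
                        "role": row.role,
                        "cluster": int(row.cluster),
                        "m": float(effects[row.compound_id][ci]),
                    }
                )
        n_wells = len(recs)
        wells = positions[cursor : cursor + n_wells]

        m = np.array([r["m"] for r in recs])
        cluster_idx = np.array([r["cluster"] for r in recs])
        plate_offset = rng_noise.normal(0.0, config.plate_noise_sd, size=p)
        z = rng_noise.standard_normal((n_wells, config.n_blocks))
        eps = rng_noise.standard_normal((n_wells, p))
        noise = config.noise_sd * (
            np.sqrt(rho) * z[:, block_of] + np.sqrt(1.0 - rho) * eps
        )
        latent = plate_offset + m[:, None] * sig_rows[cluster_idx] + noise
        raw = feat_loc + feat_scale * latent

        lam = config.baseline_cells_per_well * np.exp(config.cellcount_coupling * m)
        counts = rng_counts.poisson(lam)

        meta = pd.DataFrame(
            {
                "plate_id": plate_id,
                "well": wells,
                "compound_id": [r["compound_id"] for r in recs],
                "concentration_um": [r["concentration_um"] for r in recs],
                "replicate": plate_idx + 1,
                "role": [r["role"] for r in recs],
                "cell_count": counts,
            }
        )
        meta_frames.append(meta)
        value_blocks.append(raw)

    meta = pd.concat(meta_frames, ignore_index=True)
    values = pd.DataFrame(np.vstack(value_blocks), columns=feature_names)
    matrix = FeatureMatrix(meta, values, provenance="raw")

    gt_rows = []
    for row in compounds.itertuples():
        for ci, c in enumerate(conc):
            m_c = float(effects[row.compound_id][ci])
            gt_rows.append(
                {
                    "compound_id": row.compound_id,
                    "role": row.role,
                    "cluster": int(row.cluster),
                    "concentration_um": float(c),
                    "effect_m": m_c,
                    "true_active": bool(m_c >= config.active_threshold),
                }
            )
    ground_truth = pd.DataFrame(gt_rows)
    return matrix, ground_truth


# -- live-cell time courses -------------------------------------------------

_TC_BACKGROUND = {"caspase_count": 5.0, "membrane_count": 4.0, "overlap_count": 2.0}
_TC_AMPLITUDE = {"caspase_count": 60.0, "membrane_count": 45.0, "overlap_count": 25.0}
_TC_TAU = {"caspase_count": 20.0, "membrane_count": 16.0, "overlap_count": 18.0}


def _confluence(t: np.ndarray, m: float) -> np.ndarray:
    c0, cap = 10.0, 95.0
    g = 0.12 * np.exp(-m)
    e = np.exp(g * t)
    return cap * c0 * e / (cap + c0 * (e - 1.0))


def _injury(t: np.ndarray, m: float, metric: str) -> np.ndarray:
    return _TC_BACKGROUND[metric] + _TC_AMPLITUDE[metric] * m * (
        1.0 - np.exp(-t / _TC_TAU[metric])
    )


def generate_timecourses(
    config: SynthConfig,
    ground_truth: pd.DataFrame,
    noise_sd: float = 0.5,
    n_replicates: int = 3,
    n_vehicle_wells: int = 8,
    n_reagent_free_wells: int = 8,
) -> pd.DataFrame:
    """Simulate 60-h live-cell traces sampled every 4 h, in long format.

    Confluence follows logistic growth whose rate is damped by the planted
    effect magnitude; caspase/membrane-integrity/overlap object counts rise
    saturably with it.  Reagent-free wells carry only the auto-fluorescence
    background (for background correction) but grow normally.
    """
    times = np.asarray(TIMECOURSE_HOURS, dtype=float)
    rng = _rng(config.seed, 5)
    effect = {
        (r.compound_id, r.concentration_um): r.effect_m for r in ground_truth.itertuples()
    }
    treatments = ground_truth[["compound_id", "concentration_um", "role"]].drop_duplicates()

    rows: list[pd.DataFrame] = []

    def emit(plate_id, well, compound, conc, replicate, role, metric, trace):
        noisy = trace + rng.normal(0.0, noise_sd, size=len(trace)) if noise_sd > 0 else trace
        rows.append(
            pd.DataFrame(
                {
                    "plate_id": plate_id,
                    "well": well,
                    "compound_id": compound,
                    "concentration_um": conc,
                    "replicate": replicate,
                    "role": role,
                    "metric": metric,
                    "time_h": times,
                    "value": np.clip(noisy, 0.0, None),
                }
            )
        )

    for rep in range(1, n_replicates + 1):
        plate_id = f"TC{rep:02d}"
        slot = 0

        def next_well():
            nonlocal slot
            w = well_label(slot // config.plate_cols, slot % config.plate_cols)
            slot += 1
            return w

        for _ in range(n_vehicle_wells):
            w = next_well()
            emit(plate_id, w, VEHICLE, 0.0, rep, "vehicle", "confluence", _confluence(times, 0.0))
            for metric in _TC_BACKGROUND:
                emit(plate_id, w, VEHICLE, 0.0, rep, "vehicle", metric, _injury(times, 0.0, metric))
        for _ in range(n_reagent_free_wells):
            w = next_well()
            emit(plate_id, w, "NONE", 0.0, rep, "reagent_free", "confluence", _confluence(times, 0.0))
            for metric in _TC_BACKGROUND:
                bg = np.full_like(times, _TC_BACKGROUND[metric])
                emit(plate_id, w, "NONE", 0.0, rep, "reagent_free", metric, bg)
        for t in treatments.itertuples():
            w = next_well()
            m = effect[(t.compound_id, t.concentration_um)]
            emit(
                plate_id, w, t.compound_id, t.concentration_um, rep, t.role,
                "confluence", _confluence(times, m),
            )
            for metric in _TC_BACKGROUND:
                emit(
                    plate_id, w, t.compound_id, t.concentration_um, rep, t.role,
                    metric, _injury(times, m, metric),
                )
    return pd.concat(rows, ignore_index=True)


# -- glutathione plates -----------------------------------------------------

def generate_glutathione_plate(
    config: SynthConfig,
    ground_truth: pd.DataFrame,
    gain: float = 1500.0,
    background: float = 100.0,
    noise_frac: float = 0.01,
    vehicle_total_um: float = 5.0,
    vehicle_gssg_um: float = 0.5,
    depletion: float = 0.6,
    gssg_rise: float = 0.5,
    n_replicates: int = 5,
    n_cell_free_wells: int = 6,
    n_vehicle_wells: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate total/GSSG luminescence plates with standards and background.

    Luminescence is linear in concentration (``gain * conc + background``)
    with optional proportional noise.  Compounds planted in the highest
    cluster (gross injury) behave like electrophiles: their reduced
    glutathione is depleted with dose while GSSG rises mildly.  Returns
    (long plate table, ground-truth concentration table).
    """
    rng = _rng(config.seed, 6)
    injury_cluster = config.n_clusters
    veh_gsh = vehicle_total_um - 2.0 * vehicle_gssg_um
    if veh_gsh <= 0:
        raise ValueError("vehicle GSH must be positive (total > 2*GSSG)")

    def lum(conc_um: float) -> float:
        base = gain * conc_um + background
        return base * (1.0 + noise_frac * rng.standard_normal()) if noise_frac > 0 else base

    rows: list[dict] = []
    slot = {"i": 0}
    capacity = config.plate_rows * config.plate_cols

    def next_well() -> tuple[int, str]:
        page, offset = divmod(slot["i"], capacity)
        slot["i"] += 1
        return page + 1, well_label(offset // config.plate_cols, offset % config.plate_cols)

    def emit(assay, page_well, compound, conc, rep, role, standard_um, true_um):
        page, well = page_well
        rows.append(
            {
                "plate_id": f"GSH_{assay}_{page}",
                "well": well,
                "compound_id": compound,
                "concentration_um": conc,
                "replicate": rep,
                "role": role,
                "assay": assay,
                "standard_um": standard_um,
                "lum": lum(true_um),
            }
        )

    truth_rows: list[dict] = []
    per_compound = ground_truth.drop_duplicates(["compound_id", "concentration_um"])
    for assay in ("total", "gssg"):
        slot["i"] = 0
        for rep in range(1, 4):  # triplicate standards
            for s in GSH_STANDARDS_UM:
                emit(assay, next_well(), "STANDARD", 0.0, rep, "standard", s, s)
        for _ in range(n_cell_free_wells):
            emit(assay, next_well(), "NONE", 0.0, 1, "cell_free", 0.0, 0.0)
        for rep in range(1, n_replicates + 1):
            for _ in range(n_vehicle_wells):
                true = vehicle_total_um if assay == "total" else vehicle_gssg_um
                emit(assay, next_well(), VEHICLE, 0.0, rep, "vehicle", 0.0, true)
        for t in per_compound.itertuples():
            frac = t.effect_m / config.effect_max if config.effect_max > 0 else 0.0
            if t.cluster == injury_cluster:
                gsh = veh_gsh * (1.0 - depletion * frac)
                gssg = vehicle_gssg_um * (1.0 + gssg_rise * frac)
            else:
                gsh, gssg = veh_gsh, vehicle_gssg_um
            total = gsh + 2.0 * gssg
            true = total if assay == "total" else gssg
            for rep in range(1, n_replicates + 1):
                emit(assay, next_well(), t.compound_id, t.concentration_um, rep, t.role, 0.0, true)
            if assay == "total":
                truth_rows.append(
                    {
                        "compound_id": t.compound_id,
                        "concentration_um": t.concentration_um,
                        "true_total_um": total,
                        "true_gssg_um": gssg,
                        "true_gsh_um": gsh,
                        "true_ratio": gsh / gssg,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
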