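import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from morphoscreen.io import FeatureMatrix
from morphoscreen.synth import SynthConfig, generate_screen


def make_matrix(
    values: dict[str, list[float]],
    roles: list[str] | None = None,
    plate_ids: list[str] | None = None,
    cell_counts: list[int] | None = None,
) -> FeatureMatrix:
    """Small single-plate FeatureMatrix with sequential wells."""
    n = len(next(iter(values.values())))
    roles = roles or ["treatment"] * n
    plate_ids = plate_ids or ["P01"] * n
    wells, seen = [], {}
    for p in plate_ids:
        i = seen.get(p, 0)
        seen[p] = i + 1
        wells.append(f"{'ABCDEFGHIJKLMNOP'[i // 24]}{i % 24 + 1:02d}")
    meta = pd.DataFrame(
        {
            "plate_id": plate_ids,
            "well": wells,
            "compound_id": ["VEHICLE" if r == "vehicle" else f"CMP{i}" for i, r in enumerate(roles)],
            "concentration_um": [0.0 if r == "vehicle" else 10.0 for r in roles],
            "replicate": 1,
            "role": roles,
            "cell_count": cell_counts if cell_counts is not None else [1000] * n,
        }
    )
    return FeatureMatrix(meta, pd.DataFrame(values))


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(
        n_features=24,
        block_size=2,
        n_compounds_per_cluster=1,
        n_inert_compounds=2,
        effect_ec50=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_screen(small_config):
    return generate_screen(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
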