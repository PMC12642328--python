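import warnings

import numpy as np
import pandas as pd
import pytest

from glandscape import SimCoreConfig, simulate_core, CellTable
from glandscape.synthetic import MarkerModel
from glandscape.io_qc import ALL_MARKERS

# gland-stage warnings about tiny point sets are expected on small fixtures
warnings.filterwarnings("ignore", message="only .* points")


def four_sd_markers() -> dict:
    """Marker models at exactly 4 pooled-sd separation (the stress floor of
    the classifier's well-separated regime)."""
    return {m: MarkerModel(bg_mean=2.0, bg_sd=1.0, fg_mean=6.0, fg_sd=1.0)
            for m in ALL_MARKERS}


@pytest.fixture(scope="session")
def small_core():
    """One deterministic small core with ground truth (fast fixture)."""
    cfg = SimCoreConfig(seed=42, n_glands=3, image_size=(900, 900),
                        n_stromal=150,
                        immune_density={"T_H": 25, "T_reg": 10, "macrophage": 40})
    return simulate_core(cfg)


@pytest.fixture(scope="session")
def default_core():
    """A default-condition core (realistic scale, 5 glands)."""
    return simulate_core(SimCoreConfig(seed=7))


def make_cell_table(n: int = 10, compartment: str = "epithelial",
                    seed: int = 0) -> CellTable:
    """Minimal hand-constructed cell table for unit tests."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "x": rng.uniform(0, 100, n),
        "y": rng.uniform(0, 100, n),
        "compartment": compartment,
        "nucleus_count": 1,
        "nucleus_area": 100.0,
        "membrane_area": 100.0,
        "cytoplasm_area": 100.0,
        "cell_area": 500.0,
        "quality_score": 0.95,
    })
    for m in ALL_MARKERS:
        df[m] = rng.uniform(0, 50, n)
    return CellTable(df=df)
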