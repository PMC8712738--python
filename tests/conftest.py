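import numpy as np
import pandas as pd
import pytest

from bsrmap import synthetic


@pytest.fixture(scope="session")
def f2_model():
    return synthetic.PopulationModel(kind="F2", n_per_bulk=42)


@pytest.fixture(scope="session")
def small_dataset():
    """Two linkage groups, one planted block QTL, fixed depth."""
    model = synthetic.PopulationModel(kind="F2", n_per_bulk=42)
    qtl = synthetic.QtlSpec(linkage_group="LG1", start=8_000_000,
                            end=11_000_000, delta_af=0.4)
    markers, truth = synthetic.generate_dataset(
        model, [qtl], n_markers_per_lg=800, n_linkage_groups=2,
        depth_model=synthetic.DepthModel(min_depth=60, max_depth=60),
        seed=11, lg_length=20_000_000)
    return markers, truth


@pytest.fixture()
def stats_frame():
    """Hand-built sorted per-marker table for region-calling tests."""
    rng = np.random.default_rng(0)
    n = 60
    pos = np.sort(rng.choice(np.arange(1, 10_001), size=n, replace=False))
    return pd.DataFrame({
        "linkage_group": "LG1", "position": pos,
        "ref_high": 30, "alt_high": 30, "ref_low": 30, "alt_low": 30,
        "delta_index": 0.0, "ed5": 0.0, "q_value": 1.0,
    })
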