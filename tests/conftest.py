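import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import yieldstab as ys

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# the generator logs every truncation; keep test output readable
logging.getLogger("yieldstab.synthetic").setLevel(logging.ERROR)


@pytest.fixture
def small_panel() -> ys.YieldPanel:
    """3 treatments x 4 environments, both sources, noise-free structure."""
    rows = []
    for source, offset in (("observed", 0.0), ("predicted", 0.1)):
        for i, tid in enumerate(["A", "B", "C"]):
            for j, eid in enumerate(["E1", "E2", "E3", "E4"]):
                rows.append({
                    "dataset_id": "demo", "source": source, "treatment_id": tid,
                    "environment_id": eid, "grain_yield": 1.0 + i + 0.25 * j + offset,
                })
    return ys.YieldPanel(pd.DataFrame(rows))


@pytest.fixture
def rice_summary() -> pd.DataFrame:
    return ys.load_stability_summary("ndiaye_rice")


@pytest.fixture
def millet_summary() -> pd.DataFrame:
    return ys.load_stability_summary("sadore_millet")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
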