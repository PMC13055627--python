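import numpy as np
import pandas as pd
import pytest

from hatrial.datamodel import GroupSummary, default_registry
from hatrial.simulate import default_study_config, generate_trial

TREATMENTS = ("CK", "HA3", "HA7.5", "HA15")

# printed yield-component summaries (means, SDs, n=3) used across tests
TABLE2 = {
    "spike_number": ([161.21, 172.52, 179.42, 182.02], [4.73, 3.85, 1.46, 2.49]),
    "grain_number": ([26.06, 29.03, 34.18, 34.44], [1.06, 1.93, 1.58, 2.26]),
    "thousand_grain_weight": ([4.31, 4.54, 4.80, 4.81], [0.21, 0.39, 0.13, 0.13]),
}

YIELD_MEANS = {"CK": 2.72, "HA3": 2.81, "HA7.5": 3.04, "HA15": 3.08}


def table2_summaries(component: str) -> list[GroupSummary]:
    means, sds = TABLE2[component]
    return [
        GroupSummary(g, 3, m, s) for g, m, s in zip(TREATMENTS, means, sds)
    ]


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def trial():
    """One calibrated synthetic trial, shared across tests."""
    return generate_trial(default_study_config(seed=42))


@pytest.fixture
def small_plot_frame():
    """4 treatments x 3 blocks x 1 indicator, noise-free."""
    rows = []
    for t, mean in YIELD_MEANS.items():
        for b in (1, 2, 3):
            rows.append(
                {
                    "plot_id": f"{t}-B{b}",
                    "block": b,
                    "treatment": t,
                    "layer": "plant",
                    "indicator": "yield",
                    "value": mean,
                }
            )
    return pd.DataFrame(rows)


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Euclidean distances between random points (valid metric matrix)."""
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(rng.normal(size=(n, 2))))
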