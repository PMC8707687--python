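import numpy as np
import pandas as pd
import pytest

from plasmacv.datatypes import POOL, ReporterMatrix, SampleMap
from plasmacv.synthetic import SimulationConfig, simulate_dataset


def make_toy_map(n_plexes: int = 1, n_subjects: int = 4) -> SampleMap:
    """Minimal valid sample map: subjects spread over the 8 sample channels."""
    sample_channels = ["127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C"]
    rows = []
    slots = [(f"P{p + 1:02d}", c) for p in range(n_plexes) for c in sample_channels]
    k = 0
    for s in range(n_subjects):
        for rep in (1, 2):
            plex, channel = slots[k]
            rows.append({"plex": plex, "channel": channel, "subject_id": f"S{s + 1:02d}", "replicate": rep})
            k += 1
    for p in range(n_plexes):
        for ctrl in ("126", "131"):
            rows.append({"plex": f"P{p + 1:02d}", "channel": ctrl, "subject_id": POOL, "replicate": 0})
    return SampleMap(pd.DataFrame(rows))


def make_matrix(sample_map: SampleMap, fill: float = 1.0, rng=None) -> ReporterMatrix:
    cols = list(sample_map.table.index)
    n = 5
    if rng is None:
        data = np.full((n, len(cols)), fill)
    else:
        data = rng.uniform(0.5, 2.0, size=(n, len(cols)))
    values = pd.DataFrame(data, index=pd.Index([f"PR{i}" for i in range(n)], name="accession"), columns=cols)
    return ReporterMatrix(values)


@pytest.fixture(scope="session")
def default_sim():
    """Small full-layout simulated dataset shared across tests."""
    config = SimulationConfig(
        n_proteins=60, cv_biological=20.0, cv_analytical=5.0, missing_rate=0.05, seed=11
    )
    matrix, sample_map, truth = simulate_dataset(config)
    return config, matrix, sample_map, truth


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free-missingness dataset for closed-form checks."""
    config = SimulationConfig(
        n_proteins=40, cv_biological=20.0, cv_analytical=5.0, missing_rate=0.0, seed=3
    )
    matrix, sample_map, truth = simulate_dataset(config)
    return config, matrix, sample_map, truth
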