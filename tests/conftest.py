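"""Shared fixtures: prepared molecules and seeded synthetic datasets."""

import numpy as np
import pytest

import hydramol as hm
from hydramol.datasets import generate_synthetic_dataset


@pytest.fixture(scope="session")
def water():
    return hm.prepare_record(hm.from_smiles("O", "water"))


@pytest.fixture(scope="session")
def calibration():
    return hm.calibrate_water()


@pytest.fixture(scope="session")
def calibrated_params(calibration):
    d, a = calibration
    return hm.ParameterSet(strength=hm.StrengthParams(D=d, A=a))


@pytest.fixture(scope="session")
def synthetic_pool():
    """100 prepared synthetic molecules with charges, for property tests."""
    return [rec for rec, _ in generate_synthetic_dataset(100, seed=7)]


@pytest.fixture(scope="session")
def noise_free_dataset(calibrated_params):
    """50 molecules labelled by the model itself (zero noise)."""
    return generate_synthetic_dataset(50, seed=11, params=calibrated_params)


def bfs_distances(n_atoms: int, bonds, source: int) -> np.ndarray:
    """Independent breadth-first topological distances over the bond list."""
    adj = {i: [] for i in range(n_atoms)}
    for i, j, _ in bonds:
        adj[i].append(j)
        adj[j].append(i)
    dist = np.full(n_atoms, -1)
    dist[source] = 0
    queue = [source]
    while queue:
        cur = queue.pop(0)
        for nb in adj[cur]:
            if dist[nb] < 0:
                dist[nb] = dist[cur] + 1
                queue.append(nb)
    return dist
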