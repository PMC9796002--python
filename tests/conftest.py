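from datetime import datetime

import numpy as np
import pytest

from sensorbar import BinarySensorSeries, HouseholdSeries, ModelParams

GRID_START = datetime(2024, 1, 1)


def make_household(y, Z=None, start=GRID_START, ids=None):
    """Build a HouseholdSeries from a 0/1 array y and optional (T, J) matrix Z."""
    y = np.asarray(y)
    target = BinarySensorSeries("y", y, start)
    covs = []
    if Z is not None:
        Z = np.asarray(Z)
        ids = ids or [f"z{j}" for j in range(Z.shape[1])]
        covs = [BinarySensorSeries(sid, Z[:, j], start) for j, sid in enumerate(ids)]
    return HouseholdSeries(target, covs)


def random_instance(rng, T, J=1, include_seasonal=True):
    """Random (params, household) pair with moderate spikes and |decay| < 1."""
    y = rng.integers(0, 2, T)
    Z = rng.integers(0, 2, (T, J)) if J else None
    spikes = rng.uniform(-1.0, 1.0, 2 + J)
    decays = rng.uniform(-0.95, 0.95, 2 + J)
    params = ModelParams(
        a=rng.uniform(-3.0, 0.0),
        ar=(spikes[0], decays[0]),
        sensors=[(spikes[2 + j], decays[2 + j]) for j in range(J)],
        seasonal=(spikes[1], decays[1]) if include_seasonal else None,
    )
    return params, make_household(y, Z)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
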