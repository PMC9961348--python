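import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from carrierdyn.structio import HelixDefinition
from carrierdyn.synthgen import (
    BundleSpec,
    PlantedInteraction,
    TwoStateSpec,
    build_bundle,
    generate_trajectory,
    generate_two_state,
    helix_definitions,
)


@pytest.fixture(scope="session")
def bundle_spec():
    return BundleSpec(seed=42)


@pytest.fixture(scope="session")
def bundle(bundle_spec):
    return build_bundle(bundle_spec)


@pytest.fixture(scope="session")
def bundle_helices(bundle_spec):
    return helix_definitions(bundle_spec)


@pytest.fixture(scope="session")
def salt_bridge_fixture(bundle_spec):
    """500-frame bundle with a salt bridge planted at 60% occupancy."""
    plant = PlantedInteraction(
        "salt_bridge", res_a=8, res_b=52, occupancy=0.60, bound_distance=2.9
    )
    traj, truth = generate_trajectory(
        bundle_spec, [plant], n_frames=500, seed=42, jitter_sigma=0.05
    )
    return traj, truth, plant


@pytest.fixture(scope="session")
def two_state_fixture():
    """Two-state bundle: helices 6, 1, 2 displaced by 1.8 Å, jitter 0.1 Å."""
    spec = TwoStateSpec(
        base=BundleSpec(seed=11), moved_helices=(6, 1, 2),
        translation=1.8, jitter_sigma=0.1,
    )
    traj_a, traj_b, truth = generate_two_state(spec, n_frames=5, seed=11)
    return spec, traj_a, traj_b, truth


def random_rotation(rng):
    """A uniformly random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
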