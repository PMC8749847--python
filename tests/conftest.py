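import numpy as np
import pytest

from gaitmood import (
    FeatureConfig,
    GaitDataset,
    GaitSequence,
    SkeletonTopology,
)


@pytest.fixture
def topology():
    return SkeletonTopology()


@pytest.fixture
def tiny_topology():
    return SkeletonTopology(
        joint_names=("a", "b", "c", "d"), n_coords=3, relative_joint=0, fps=30.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_sequence(topology, rng):
    coords = rng.normal(0.0, 1.0, size=(240, topology.n_joints, topology.n_coords))
    return GaitSequence(coords=coords, label="happy", sequence_id="rand0")


def make_labeled_dataset(topology, counts, n_frames=8, seed=0):
    """Dataset with the given per-class counts and random coordinates."""
    rng = np.random.default_rng(seed)
    class_names = ("angry", "happy", "sad", "neutral")
    sequences = []
    for label, n in zip(class_names, counts):
        for k in range(n):
            coords = rng.normal(size=(n_frames, topology.n_joints, topology.n_coords))
            sequences.append(GaitSequence(coords, label=label,
                                          sequence_id=f"{label}_{k:04d}"))
    return GaitDataset(topology=topology, sequences=sequences,
                       class_names=class_names)


@pytest.fixture
def small_dataset(topology):
    return make_labeled_dataset(topology, (10, 10, 10, 10))


@pytest.fixture
def feature_config():
    return FeatureConfig()
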