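import numpy as np
import pytest

from motionaug.fixtures import ObjectSpec, SceneSpec, generate_sequence
from motionaug.sequence_io import FrameSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_sequence(rng):
    """A small random sequence for oracle-equivalence checks."""
    return FrameSequence(frames=rng.uniform(0, 1, size=(7, 8, 8, 3)))


@pytest.fixture
def moving_square_scene():
    """One grey square moving right over a darker uniform background."""
    obj = ObjectSpec(size=(10, 10), colour=(0.7, 0.7, 0.7), position=(4, 20), trajectory=[(2, 0)] * 10)
    spec = SceneSpec(height=48, width=48, n_frames=9, noise_sd=0.0, objects=[obj], seed=7)
    return generate_sequence(spec)
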