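import numpy as np
import pytest

import paddycount as pc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_fields():
    """Three deterministic 256x256 synthetic fields with annotations."""
    from dataclasses import replace
    spec = pc.FieldSpec(seed=1)
    return [pc.generate_field(replace(spec, seed=100 + i)) for i in range(3)]


@pytest.fixture
def square_points():
    """Four points at the corners of a 10-px square."""
    return pc.PointSet(np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]]))
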