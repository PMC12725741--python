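import numpy as np
import pytest

from condenseq.engine import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_trajectory(frames, n_monomers, box=(40.0, 40.0, 40.0), times=None,
                    n_protein_types: int = 1):
    """Wrap raw frame arrays in a Trajectory (monomers first, then proteins)."""
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[1]
    if times is None:
        times = np.arange(1.0, frames.shape[0] + 1.0)
    types = np.concatenate([np.zeros(n_monomers, dtype=int),
                            np.ones(n - n_monomers, dtype=int)])
    return Trajectory(frames, np.asarray(times, dtype=float), types,
                      ["M2", "P"], n_monomers, np.asarray(box, dtype=float))


@pytest.fixture
def trajectory_factory():
    return make_trajectory
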