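import numpy as np
import pytest

from ssematch import SSEVector, VectorSet


def make_vec(index, start, end, side="A", kind="helix"):
    return SSEVector(index=index, side=side, start=np.asarray(start, float),
                     end=np.asarray(end, float), kind=kind)


def random_vector_set(n, seed, side="A"):
    rng = np.random.default_rng(seed)
    vecs = []
    for i in range(1, n + 1):
        mid = rng.uniform(-30, 30, 3)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        length = rng.uniform(8, 40)
        vecs.append(SSEVector(index=i, side=side, start=mid - length / 2 * d,
                              end=mid + length / 2 * d))
    return VectorSet(side, vecs)


def random_rigid(rng):
    """Random rotation matrix + translation."""
    from scipy.spatial.transform import Rotation
    return Rotation.random(rng=rng).as_matrix(), rng.uniform(-50, 50, 3)


@pytest.fixture
def square_pair():
    """Two A-side vectors along x, offset in y (hand-computable features)."""
    u = make_vec(1, (0, 0, 0), (2, 0, 0))
    v = make_vec(2, (0, 2, 0), (2, 2, 0))
    return u, v
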