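import numpy as np
import pytest

from epibin.geometry import DistanceMatrix, LengthGroup
from epibin.io import RegionScheme
from epibin.synthetic import SceneParams, generate_scene


@pytest.fixture(scope="session")
def scheme():
    return RegionScheme()


@pytest.fixture(scope="session")
def default_scene():
    """Planted scene under the standard study conditions (4 x 6, 0.2 A, 5 A)."""
    return generate_scene(SceneParams())


def make_dm(matrix, ids=None):
    """Wrap a raw symmetric matrix as a DistanceMatrix with a dummy group."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    ids = tuple(ids) if ids is not None else tuple(f"m{i}" for i in range(n))
    group = LengthGroup(cdrs=("CDRH3",), lengths=(10,), members=ids)
    return DistanceMatrix(group=group, rmsd=matrix)


def random_dm(rng, n, scale=3.0):
    """Random symmetric distance matrix with zero diagonal."""
    m = rng.uniform(0.05, scale, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return make_dm(m)


def partition_sets(clusters, members=None):
    """Canonical form of a partition for label-free comparison."""
    if members is not None:
        return frozenset(frozenset(members[i] for i in c) for c in clusters)
    return frozenset(frozenset(c) for c in clusters)


def labels_to_sets(labels):
    out = {}
    for idx, lab in enumerate(labels):
        out.setdefault(lab, set()).add(idx)
    return frozenset(frozenset(v) for v in out.values())
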