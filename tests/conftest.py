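import itertools

import numpy as np
import pytest

import ligphore as lp
from ligphore.hypothesis_engine import superpose


@pytest.fixture(scope="session")
def training_table():
    return lp.published_fixtures()[0]


@pytest.fixture(scope="session")
def test_table():
    return lp.published_fixtures()[1]


@pytest.fixture()
def engine_cfg():
    return lp.EngineConfig()


def cloud_from(h: lp.Hypothesis, compound_id="c", extra=()):
    """A feature cloud that copies a hypothesis' features exactly."""
    feats = [lp.Feature(f.ftype, f.centroid.copy()) for f in h.features]
    feats += [lp.Feature(t, np.asarray(p, float)) for t, p in extra]
    return lp.FeatureCloud(compound_id, 0, feats)


def square_hypothesis(side=4.0, types=("HBA", "HBD", "HY", "RA"), **kw):
    """Four coplanar features on the corners of a square."""
    pts = np.array(
        [[0, 0, 0], [side, 0, 0], [side, side, 0], [0, side, 0]], dtype=float
    )
    return lp.Hypothesis(
        [lp.PharmacophoreFeature(t, p, **kw) for t, p in zip(types, pts)]
    )


def typed_rmsd_to(planted: lp.Hypothesis, other: lp.Hypothesis) -> float:
    """Best superposed centroid RMSD over type-preserving permutations."""
    at = [f.ftype for f in other.features]
    bt = [f.ftype for f in planted.features]
    if sorted(at) != sorted(bt):
        return np.inf
    a, b = other.centroids(), planted.centroids()
    best = np.inf
    for perm in itertools.permutations(range(len(bt))):
        if [bt[i] for i in perm] != at:
            continue
        _t, r = superpose(a, b[list(perm)])
        best = min(best, r)
    return best
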