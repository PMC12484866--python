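import numpy as np
import pytest

from varimap.varifold import FeatureSpace, ParticleMeasure


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def space_ab():
    return FeatureSpace(("A", "B"))


def random_measure(rng, n, space, normalized=True, scale=1.0):
    """Small random particle measure for metric tests."""
    pos = scale * rng.random((n, 3))
    w = rng.random(n) + 0.1
    p = rng.random((n, len(space)))
    if normalized:
        p = p / p.sum(axis=1, keepdims=True)
    return ParticleMeasure(pos, w, p, space, normalized=normalized)


def brute_inner(mu, nu, ks):
    """Literal quadruple-sum oracle for the varifold inner product."""
    total = 0.0
    nf = len(mu.feature_space)
    for i in range(len(mu)):
        for j in range(len(nu)):
            k = ks(np.sum((mu.positions[i] - nu.positions[j]) ** 2))
            for f in range(nf):
                for g in range(nf):
                    if f == g:  # identity feature kernel
                        total += (mu.weights[i] * nu.weights[j] * k
                                  * mu.feature_dists[i, f]
                                  * nu.feature_dists[j, g])
    return total


@pytest.fixture
def grid_measure(space_ab):
    g = (np.arange(3) + 0.5) / 3
    xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
    pos = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    labels = (pos[:, 0] < 0.5).astype(int)
    return ParticleMeasure(pos, np.ones(len(pos)), np.eye(2)[labels], space_ab)
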