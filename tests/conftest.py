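import numpy as np
import pytest

from geomrep import features, stimuli


@pytest.fixture(scope="session")
def reference_shapes():
    return stimuli.make_reference_shapes(1.0)


@pytest.fixture(scope="session")
def feature_model_rdm(reference_shapes):
    return features.feature_rdm(reference_shapes)


@pytest.fixture(scope="session")
def regularity_scores(reference_shapes):
    return {
        name: features.regularity_score(features.feature_vector(q))
        for name, q in reference_shapes.items()
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def segments_properly_intersect(p, q, r, s):
    """Exhaustive segment-intersection predicate used as an independent
    simplicity oracle in several tests."""
    p, q, r, s = (np.asarray(v, dtype=float) for v in (p, q, r, s))

    def cross(a, b):
        return a[0] * b[1] - a[1] * b[0]

    d1 = cross(q - p, r - p)
    d2 = cross(q - p, s - p)
    d3 = cross(s - r, p - r)
    d4 = cross(s - r, q - r)
    return d1 * d2 < 0 and d3 * d4 < 0


def is_simple_oracle(vertices):
    """Pairwise edge-intersection check over all non-adjacent edge pairs."""
    v = np.asarray(vertices, dtype=float)
    edges = [(v[i], v[(i + 1) % 4]) for i in range(4)]
    return not (
        segments_properly_intersect(*edges[0], *edges[2])
        or segments_properly_intersect(*edges[1], *edges[3])
    )
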