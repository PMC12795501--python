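"""Discrete geometric-feature coding of quadrilaterals.

Each shape is encoded by 22 boolean regularity features, evaluated up to
a dimensionless tolerance (default 12.5%): 4 right angles (one per
vertex), 6 pairs of equal angles, 6 pairs of equal sides, and 6 pairs of
parallel sides.  All predicates are invariant under translation, rotation
and uniform scaling, and reduce to exact predicates as the tolerance
shrinks to zero.  The regularity score of a shape is its feature count;
shape dissimilarity is the Hamming distance between feature vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .rsa import RDM
from .stimuli import Quadrilateral

DEFAULT_TOLERANCE = 0.125

_PAIRS = list(combinations(range(4), 2))  # (0,1) (0,2) (0,3) (1,2) (1,3) (2,3)

FEATURE_NAMES = (
    [f"right_angle_{i}" for i in range(4)]
    + [f"equal_angles_{i}{j}" for i, j in _PAIRS]
    + [f"equal_sides_{i}{j}" for i, j in _PAIRS]
    + [f"parallel_sides_{i}{j}" for i, j in _PAIRS]
)


@dataclass(frozen=True)
class FeatureVector:
    """22 boolean geometric regularities plus the tolerance used."""

    right_angle: tuple
    equal_angles: tuple
    equal_sides: tuple
    parallel_sides: tuple
    tolerance: float

    def __post_init__(self):
        if len(self.right_angle) != 4 or any(
            len(t) != 6 for t in (self.equal_angles, self.equal_sides, self.parallel_sides)
        ):
            raise ValueError("feature vector must have 4 + 6 + 6 + 6 entries")
        if not (0 < self.tolerance < 1):
            raise ValueError("tolerance must lie in (0, 1)")

    def as_array(self) -> np.ndarray:
        return np.array(
            self.right_angle + self.equal_angles + self.equal_sides + self.parallel_sides,
            dtype=bool,
        )

    def __len__(self) -> int:
        return 22


def interior_angles(q: Quadrilateral) -> np.ndarray:
    """Interior angles in degrees, one per vertex; they sum to 360."""
    v = q.vertices
    angles = np.empty(4)
    for i in range(4):
        u = v[(i - 1) % 4] - v[i]
        w = v[(i + 1) % 4] - v[i]
        # counterclockwise storage: the interior lies to the left of w
        cross = w[0] * u[1] - w[1] * u[0]
        a = math.degrees(math.atan2(cross, float(np.dot(w, u)))) % 360.0
        if a == 0.0:
            raise ValueError(f"degenerate (collinear) vertex {i}")
        angles[i] = a
    return angles


def _side_directions(q: Quadrilateral) -> np.ndarray:
    v = q.vertices
    e = np.roll(v, -1, axis=0) - v
    return np.degrees(np.arctan2(e[:, 1], e[:, 0])) % 180.0


def feature_vector(q: Quadrilateral, tolerance: float = DEFAULT_TOLERANCE) -> FeatureVector:
    """Evaluate the 22 regularity predicates at the given tolerance.

    Right angles are tested against 90 degrees with a relative band of
    tolerance x 90; pairwise equalities relative to the pair mean;
    parallelism as an undirected direction difference (mod 180) within
    tolerance x 90.  Sides sharing a vertex meet, hence are never counted
    as parallel.
    """
    if not (0 < tolerance < 1):
        raise ValueError("tolerance must lie in (0, 1)")
    theta = interior_angles(q)
    sides = q.side_lengths()
    dirs = _side_directions(q)

    right = tuple(bool(abs(t - 90.0) <= tolerance * 90.0) for t in theta)
    eq_ang = tuple(
        bool(abs(theta[i] - theta[j]) <= tolerance * 0.5 * (theta[i] + theta[j]))
        for i, j in _PAIRS
    )
    eq_side = tuple(
        bool(abs(sides[i] - sides[j]) <= tolerance * 0.5 * (sides[i] + sides[j]))
        for i, j in _PAIRS
    )

    def parallel(i, j):
        if (j - i) % 4 != 2:  # adjacent sides share a vertex
            return False
        d = abs(dirs[i] - dirs[j])
        d = min(d, 180.0 - d)
        return bool(d <= tolerance * 90.0)

    par = tuple(parallel(i, j) for i, j in _PAIRS)
    return FeatureVector(right, eq_ang, eq_side, par, tolerance)


def regularity_score(fv: FeatureVector) -> int:
    """Number of true features, in [0, 22]."""
    return int(fv.as_array().sum())


def feature_dissimilarity(
    a: FeatureVector, b: FeatureVector, metric: str = "hamming"
) -> int:
    """Dissimilarity between two feature vectors.

    "hamming" (default) counts features not in common (symmetric
    difference); "count-difference" is the absolute difference of the two
    regularity scores.  Both coincide on nested feature sets.
    """
    if a.tolerance != b.tolerance:
        raise ValueError("feature vectors computed at different tolerances")
    if metric == "hamming":
        return int(np.sum(a.as_array() != b.as_array()))
    if metric == "count-difference":
        return abs(regularity_score(a) - regularity_score(b))
    raise ValueError(f"unknown feature dissimilarity metric {metric!r}")


def feature_rdm(
    shapes: dict[str, Quadrilateral] | list[Quadrilateral],
    tolerance: float = DEFAULT_TOLERANCE,
    metric: str = "hamming",
) -> RDM:
    """RDM over shape labels under the feature-coding model."""
    if isinstance(shapes, dict):
        labels = list(shapes)
        quads = [shapes[l] for l in labels]
    else:
        quads = list(shapes)
        labels = [q.family_name for q in quads]
    if len(quads) < 2:
        raise ValueError("need at least 2 shapes")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate shape labels")
    fvs = [feature_vector(q, tolerance) for q in quads]
    vals = [
        feature_dissimilarity(fvs[i], fvs[j], metric=metric)
        for i, j in combinations(range(len(fvs)), 2)
    ]
    tag = "hamming-features" if metric == "hamming" else "countdiff-features"
    return RDM(labels=labels, values=np.array(vals, dtype=float), metric=tag)


def feature_table(
    shapes: dict[str, Quadrilateral], tolerance: float = DEFAULT_TOLERANCE
):
    """Feature matrix as a pandas DataFrame: one row per shape, 22 named
    boolean columns plus the regularity score."""
    import pandas as pd

    rows = {}
    for name, q in shapes.items():
        fv = feature_vector(q, tolerance)
        rows[name] = list(fv.as_array()) + [regularity_score(fv)]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(FEATURE_NAMES) + ["score"]
    )
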