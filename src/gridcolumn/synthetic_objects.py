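"""Synthetic objects, feature encodings, and sensorimotor traversals.

Objects are sets of feature-bearing points on a small integer grid: at
baseline, 10 distinct points drawn from a 4x4 grid, with a feature at each
point drawn with replacement from a fixed pool, so features repeat within and
across objects.  A feature encoding maps each feature id to a fixed random
sparse set of sensory mini-columns.  A traversal visits every point of an
object in random order; the movement into each point is the coordinate
difference from the previous point (grid spacing = 1 length unit), with a
null movement before the first sensation.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ObjectSpec",
    "FeatureEncoding",
    "SensorimotorSequence",
    "generate_objects",
    "make_feature_encoding",
    "make_traversal",
    "feature_occurrence_counts",
    "rarest_feature_counts",
    "objects_to_json",
    "objects_from_json",
]


@dataclass(frozen=True)
class ObjectSpec:
    """An object: distinct grid points, one feature id per point."""

    id: int
    points: tuple  # of (x, y) int pairs
    features: tuple  # of int feature ids, parallel to points

    def __post_init__(self) -> None:
        pts = tuple((int(x), int(y)) for x, y in self.points)
        feats = tuple(int(f) for f in self.features)
        if len(pts) != len(set(pts)):
            raise ValueError("object points must be distinct")
        if len(pts) != len(feats):
            raise ValueError("points and features must be parallel")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "features", feats)

    @property
    def num_points(self) -> int:
        return len(self.points)

    @property
    def feature_at(self) -> dict:
        return dict(zip(self.points, self.features))


@dataclass(frozen=True)
class FeatureEncoding:
    """Fixed feature -> mini-column mapping, stable across train and test."""

    columns: dict  # feature id -> tuple of column indices

    def __getitem__(self, feature: int) -> tuple:
        return self.columns[feature]


@dataclass(frozen=True)
class SensorimotorSequence:
    """A traversal: parallel movements, features, and visited points.

    ``movements[0]`` is the null vector (the first sensation has no preceding
    movement); ``movements[t]`` is the coordinate difference from point
    ``t - 1`` to point ``t``.
    """

    movements: tuple  # of (dx, dy) float pairs
    features: tuple  # of feature ids
    points: tuple  # of (x, y) pairs actually visited

    def __len__(self) -> int:
        return len(self.features)


def _feature_probabilities(pool_size: int, distribution: str) -> np.ndarray:
    if distribution == "uniform":
        p = np.ones(pool_size)
    elif distribution == "zipf":
        # representative skew: p_i proportional to 1 / rank
        p = 1.0 / np.arange(1, pool_size + 1)
    elif distribution == "two_tier":
        # representative skew: the first fifth of the pool carries 80% of mass
        n_common = max(1, pool_size // 5)
        p = np.full(pool_size, 0.2 / max(1, pool_size - n_common))
        p[:n_common] = 0.8 / n_common
    else:
        raise ValueError(f"unknown feature distribution: {distribution!r}")
    return p / p.sum()


def generate_objects(
    num_objects: int,
    points_per_object: int = 10,
    grid_size: int = 4,
    pool_size: int = 40,
    feature_distribution: str = "uniform",
    rng: np.random.Generator | None = None,
) -> list:
    """Draw a random object set with the simulation's object statistics.

    Points are sampled without replacement from the ``grid_size x grid_size``
    grid; features with replacement from the pool under the chosen
    distribution (uniform baseline; 'zipf' and 'two_tier' are representative
    skewed alternatives).
    """
    if points_per_object > grid_size**2:
        raise ValueError("more points requested than grid positions")
    if num_objects < 1 or pool_size < 1:
        raise ValueError("num_objects and pool_size must be positive")
    rng = np.random.default_rng() if rng is None else rng
    coords = [(x, y) for y in range(grid_size) for x in range(grid_size)]
    probs = _feature_probabilities(pool_size, feature_distribution)
    objects = []
    for oid in range(num_objects):
        idx = rng.choice(len(coords), size=points_per_object, replace=False)
        feats = rng.choice(pool_size, size=points_per_object, replace=True, p=probs)
        objects.append(
            ObjectSpec(
                id=oid,
                points=tuple(coords[i] for i in idx),
                features=tuple(int(f) for f in feats),
            )
        )
    return objects


def make_feature_encoding(
    pool_size: int,
    num_minicolumns: int = 150,
    sparsity: int = 10,
    rng: np.random.Generator | None = None,
) -> FeatureEncoding:
    """Fixed random ``sparsity``-of-``num_minicolumns`` code per feature."""
    if sparsity > num_minicolumns:
        raise ValueError("sparsity exceeds the number of mini-columns")
    rng = np.random.default_rng() if rng is None else rng
    return FeatureEncoding(
        columns={
            f: tuple(
                int(c)
                for c in sorted(rng.choice(num_minicolumns, size=sparsity, replace=False))
            )
            for f in range(pool_size)
        }
    )


def make_traversal(
    obj: ObjectSpec, rng: np.random.Generator | None = None, passes: int = 1
) -> SensorimotorSequence:
    """Visit every point of ``obj`` once per pass, in fresh random orders.

    Movements are successive coordinate differences, continuing across pass
    boundaries; the very first movement is null.
    """
    rng = np.random.default_rng() if rng is None else rng
    order: list[int] = []
    for _ in range(passes):
        order.extend(rng.permutation(obj.num_points).tolist())
    points = [obj.points[i] for i in order]
    features = [obj.features[i] for i in order]
    movements = [(0.0, 0.0)]
    for prev, cur in zip(points[:-1], points[1:]):
        movements.append((float(cur[0] - prev[0]), float(cur[1] - prev[1])))
    return SensorimotorSequence(
        movements=tuple(movements), features=tuple(features), points=tuple(points)
    )


def feature_occurrence_counts(objects) -> Counter:
    """Total occurrences of each feature across all (object, point) pairs."""
    counts: Counter = Counter()
    for obj in objects:
        counts.update(obj.features)
    return counts


def rarest_feature_counts(objects) -> dict:
    """Per-object k: the total occurrence count of the object's rarest feature.

    An object's recognizability is governed by its rarest feature -- the one
    that recalls the smallest union of locations when sensed.
    """
    totals = feature_occurrence_counts(objects)
    return {obj.id: min(totals[f] for f in obj.features) for obj in objects}


# -- serialization -----------------------------------------------------


def objects_to_json(objects, encoding: FeatureEncoding | None = None) -> str:
    payload = {
        "objects": [
            {"id": o.id, "points": [list(p) for p in o.points], "features": list(o.features)}
            for o in objects
        ]
    }
    if encoding is not None:
        payload["encoding"] = {str(f): list(c) for f, c in encoding.columns.items()}
    return json.dumps(payload, indent=1)


def objects_from_json(text: str):
    payload = json.loads(text)
    objects = [
        ObjectSpec(
            id=o["id"],
            points=tuple(tuple(p) for p in o["points"]),
            features=tuple(o["features"]),
        )
        for o in payload["objects"]
    ]
    encoding = None
    if "encoding" in payload:
        encoding = FeatureEncoding(
            columns={int(f): tuple(c) for f, c in payload["encoding"].items()}
        )
    return objects, encoding
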