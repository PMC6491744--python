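"""Reference detectors: ideal observer and bag-of-features.

The ideal observer is an exhaustive candidate-tracking localizer (Markov
localization over the learned feature maps): the first sensed feature
initialises the candidate set with every (object, point) bearing that
feature; each movement shifts every candidate, and candidates that fall off
their object or mismatch the newly sensed feature are pruned.  Inference
completes as soon as exactly one candidate remains.  It upper-bounds how fast
any detector using features and relative locations can recognize an object.

The bag-of-features detector ignores arrangement entirely: it tracks the set
of unique features sensed so far and completes when exactly one learned
object's feature set contains them all.  Objects that are different
arrangements of identical feature sets can never be told apart.
"""

from __future__ import annotations

from .synthetic_objects import ObjectSpec, SensorimotorSequence

__all__ = ["IdealObserver", "BagOfFeatures", "ideal_observer_infer", "bag_of_features_infer"]


class IdealObserver:
    """Candidate-pruning localizer over learned 2D feature arrays."""

    def __init__(self, objects):
        self.feature_maps = {obj.id: obj.feature_at for obj in objects}

    def infer(self, sequence: SensorimotorSequence) -> int | None:
        """Sensations until a unique (object, location) remains; None if the
        sequence ends while several candidates survive."""
        candidates: set = set()
        for t, (movement, feature) in enumerate(
            zip(sequence.movements, sequence.features), start=1
        ):
            if t == 1:
                candidates = {
                    (oid, point)
                    for oid, fmap in self.feature_maps.items()
                    for point, f in fmap.items()
                    if f == feature
                }
            else:
                dx, dy = int(round(movement[0])), int(round(movement[1]))
                moved = {(oid, (p[0] + dx, p[1] + dy)) for oid, p in candidates}
                candidates = {
                    (oid, p)
                    for oid, p in moved
                    if self.feature_maps[oid].get(p) == feature
                }
            if not candidates:
                raise ValueError("sensorimotor sequence matches no learned object")
            if len(candidates) == 1:
                return t
        return None


class BagOfFeatures:
    """Set-of-unique-features detector (no location information)."""

    def __init__(self, objects):
        self.feature_sets = {obj.id: frozenset(obj.features) for obj in objects}

    def infer(self, sequence: SensorimotorSequence) -> int | None:
        """Sensations until exactly one object's feature set covers the
        sensed set; None if ambiguity remains at the end."""
        sensed: set = set()
        for t, feature in enumerate(sequence.features, start=1):
            sensed.add(feature)
            matching = [
                oid for oid, fs in self.feature_sets.items() if sensed <= fs
            ]
            if len(matching) == 1:
                return t
        return None


def ideal_observer_infer(objects, sequence: SensorimotorSequence) -> int | None:
    return IdealObserver(objects).infer(sequence)


def bag_of_features_infer(objects, sequence: SensorimotorSequence) -> int | None:
    return BagOfFeatures(objects).infer(sequence)
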