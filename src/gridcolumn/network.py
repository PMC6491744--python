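"""Two-layer network: the four-stage timestep, training, and recognition.

Each timestep processes one (movement, feature) pair through four stages:

1. the movement path-integrates every bump in the location layer;
2. the updated location activity drives dendritic predictions in the sensory
   layer;
3. the sensed feature activates its mini-columns, gated by the predictions
   (predicted cells fire sparsely, unpredicted columns burst);
4. the sensory activity recalls location cells, and each module's bump set is
   replaced by bumps on the recalled cells.

No further recurrent settling happens within a timestep.  During training the
network visits every point of an object once, starting from random per-module
phases that define the object's location space, and stores the per-point
winner-cell code in a classifier.  During inference it traverses the points
in random order and is considered to have recognized the object when the
location representation collapses to a single bump per module whose
winner-cell code matches the stored code for the current point and is unique
to the object.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .location_layer import LocationLayer, LocationLayerParams
from .sensory_layer import SensoryInput, SensoryLayer, SensoryLayerParams
from .synthetic_objects import FeatureEncoding, ObjectSpec, SensorimotorSequence, make_traversal

__all__ = [
    "NetworkConfig",
    "LocationClassifier",
    "RecognitionStatus",
    "RecognitionOutcome",
    "Network",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Cross-layer configuration; segment vectors match the opposite layer."""

    location: LocationLayerParams
    sensory: SensoryLayerParams
    max_passes: int = 4

    @staticmethod
    def default(
        num_modules: int = 10,
        cells_per_axis: int = 10,
        scale: float = 1.5,
        num_minicolumns: int = 150,
        cells_per_column: int = 16,
        theta_loc: int = 8,
        theta_in_fraction: float = 0.8,
        max_passes: int = 4,
    ) -> "NetworkConfig":
        theta_in = int(np.ceil(num_modules * theta_in_fraction))
        return NetworkConfig(
            location=LocationLayerParams.default(
                num_modules=num_modules,
                cells_per_axis=cells_per_axis,
                scale=scale,
                dendrite_threshold=theta_loc,
            ),
            sensory=SensoryLayerParams(
                num_minicolumns=num_minicolumns,
                cells_per_column=cells_per_column,
                dendrite_threshold=theta_in,
            ),
            max_passes=max_passes,
        )


class LocationClassifier:
    """Stored winner-cell codes per trained (object, point), with a reverse
    index from code to the set of (object, point) pairs that produced it."""

    def __init__(self) -> None:
        self._codes: dict = {}  # (object id, point) -> code tuple
        self._reverse: dict = {}  # code tuple -> set of (object id, point)

    def store(self, object_id: int, point, code: tuple) -> None:
        key = (object_id, tuple(point))
        old = self._codes.get(key)
        if old is not None and old != code:
            self._reverse[old].discard(key)
        self._codes[key] = code
        self._reverse.setdefault(code, set()).add(key)

    def code_for(self, object_id: int, point) -> tuple | None:
        return self._codes.get((object_id, tuple(point)))

    def entries_for(self, code: tuple) -> set:
        return set(self._reverse.get(code, set()))

    def objects_for(self, code: tuple) -> set:
        return {obj for obj, _ in self._reverse.get(code, set())}

    @property
    def num_entries(self) -> int:
        return len(self._codes)


class RecognitionStatus(enum.Enum):
    RECOGNIZED = "recognized"
    WRONG_LOCATION = "wrong_location"
    NO_CONVERGENCE = "no_convergence"
    CONVERGED_NONUNIQUE = "converged_nonunique"


@dataclass(frozen=True)
class RecognitionOutcome:
    """Result of one inference episode.

    ``sensations_to_recognition`` counts sensations up to and including the
    one at which the network converged (None if it never did).
    """

    status: RecognitionStatus
    sensations_to_recognition: int | None = None
    densities: tuple = ()

    @property
    def recognized(self) -> bool:
        return self.status is RecognitionStatus.RECOGNIZED


class Network:
    """The full two-layer model plus classifier bookkeeping."""

    def __init__(self, config: NetworkConfig, encoding: FeatureEncoding):
        self.config = config
        self.encoding = encoding
        self.location = LocationLayer(config.location, config.sensory.num_cells)
        self.sensory = SensoryLayer(config.sensory, config.location.num_cells)
        self.classifier = LocationClassifier()
        self._origins: dict = {}  # object id -> per-module origin phases

    # -- single timestep ----------------------------------------------

    def timestep(
        self,
        movement,
        feature: int,
        learn: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Run the four stages for one (movement, feature) pair.

        Returns the sensory layer's active cells.  In learning mode the
        caller is responsible for having initialised the object space; the
        reciprocal segment learning itself is done by ``train_object``.
        """
        self.location.move_update(movement)                       # Stage 1
        self.sensory.predict(self.location.state.active_move)     # Stage 2
        a_in = self.sensory.activate(                             # Stage 3
            SensoryInput(self.encoding[feature])
        )
        if learn:
            self.location.sense_update(learning=True)             # Stage 4 bypass
        else:
            self.location.predict(a_in)                           # Stage 4
            self.location.sense_update()
        return a_in

    # -- training ------------------------------------------------------

    def train_object(
        self,
        obj: ObjectSpec,
        rng: np.random.Generator,
        sequence: SensorimotorSequence | None = None,
    ) -> None:
        """Learn one object by visiting each of its points once.

        A new object gets a fresh random location space (one random phase per
        module); retraining a known object restores its stored origin, so the
        deterministic winner cells and idempotent OR learning leave the
        synapses unchanged.  Each visit forms reciprocal connections between
        the per-module winner cells and the per-column sensory learning
        cells, and stores the winner-cell code in the classifier.
        """
        if sequence is None:
            points = list(obj.points)
            features = list(obj.features)
            movements = [(0.0, 0.0)] + [
                (float(b[0] - a[0]), float(b[1] - a[1]))
                for a, b in zip(points[:-1], points[1:])
            ]
        else:
            points = list(sequence.points)
            features = list(sequence.features)
            movements = list(sequence.movements)

        if obj.id in self._origins:
            self.location.set_bumps(self._origins[obj.id])
        else:
            self._origins[obj.id] = self.location.init_object_space(rng)

        for movement, feature, point in zip(movements, features, points):
            a_in = self.timestep(movement, feature, learn=True, rng=rng)
            learn_cells = self.sensory.select_learning_cells(
                SensoryInput(self.encoding[feature]), rng
            )
            loc_set = self.location.learning_cells()
            self.sensory.learn(learn_cells, loc_set)
            self.location.learn(loc_set, learn_cells)
            self.classifier.store(obj.id, point, loc_set)

    def train(self, objects, rng: np.random.Generator) -> None:
        for obj in objects:
            self.train_object(obj, rng)

    # -- inference -----------------------------------------------------

    def _winner_code(self) -> tuple:
        return self.location.learning_cells()

    def infer_sequence(
        self, obj: ObjectSpec, sequence: SensorimotorSequence, record_density: bool = False
    ) -> RecognitionOutcome:
        """Run one inference episode over a prepared sensorimotor sequence.

        The network starts stateless.  After each sensation, if every module
        holds exactly one bump the representation is a single location: it is
        compared with the classifier's stored code for the current point of
        the true object.  A match unique to the object is a recognition; a
        match shared with other objects is convergence to a non-object-
        specific location; a mismatch is convergence to a wrong location.
        """
        self.location.reset()
        densities: list[float] = []
        for t, (movement, feature, point) in enumerate(
            zip(sequence.movements, sequence.features, sequence.points), start=1
        ):
            self.timestep(movement, feature, learn=False)
            if record_density:
                densities.append(self.location.activation_density())
            if self.location.converged():
                code = self._winner_code()
                stored = self.classifier.code_for(obj.id, point)
                if code == stored:
                    if self.classifier.objects_for(code) == {obj.id}:
                        status = RecognitionStatus.RECOGNIZED
                    else:
                        status = RecognitionStatus.CONVERGED_NONUNIQUE
                else:
                    status = RecognitionStatus.WRONG_LOCATION
                return RecognitionOutcome(status, t, tuple(densities))
        return RecognitionOutcome(
            RecognitionStatus.NO_CONVERGENCE, None, tuple(densities)
        )

    def infer(
        self,
        obj: ObjectSpec,
        rng: np.random.Generator,
        record_density: bool = False,
    ) -> RecognitionOutcome:
        """Infer with fresh random traversal orders, up to ``max_passes``
        complete passes over the object's points."""
        sequence = make_traversal(obj, rng, passes=self.config.max_passes)
        return self.infer_sequence(obj, sequence, record_density=record_density)

    # -- diagnostics ---------------------------------------------------

    @property
    def num_synapses(self) -> int:
        return self.location.segments.num_synapses + self.sensory.segments.num_synapses
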