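"""Multi-module location layer.

The layer concatenates ``n`` independent grid-cell modules, each with its own
orientation (evenly spaced over the 60-degree range) but a shared scale.
Movement shifts every bump of every module through that module's transform
(Stage 1); sensory activity recalls locations by driving cells whose segments
match the sensory code, replacing each module's bump set with bumps centered
on the recalled cells (Stage 4).  During learning the layer ignores sensory
recall and tracks a single path-integrated bump per module, and the
per-module winner cells form the learning set associated with the sensed
feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import grid_modules as gm
from .segments import SegmentStore

__all__ = [
    "LocationLayerParams",
    "MovementVector",
    "LocationLayerState",
    "LocationLayer",
]


@dataclass(frozen=True)
class MovementVector:
    """Sensor displacement in the object's reference frame, length units."""

    displacement: tuple

    def __post_init__(self) -> None:
        d = tuple(float(x) for x in self.displacement)
        if len(d) != 2 or not all(np.isfinite(d)):
            raise ValueError("displacement must be a finite 2D vector")
        object.__setattr__(self, "displacement", d)


@dataclass(frozen=True)
class LocationLayerParams:
    """Module list and the location-side dendritic threshold (theta^loc)."""

    module_params: tuple
    dendrite_threshold: int = 8

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_params", tuple(self.module_params))
        if len(self.module_params) < 1:
            raise ValueError("need at least one module")
        if self.dendrite_threshold < 1:
            raise ValueError("dendrite_threshold must be positive")

    @property
    def num_modules(self) -> int:
        return len(self.module_params)

    @property
    def num_cells(self) -> int:
        return sum(p.num_cells for p in self.module_params)

    @staticmethod
    def default(
        num_modules: int = 10,
        cells_per_axis: int = 10,
        scale: float = 1.5,
        dendrite_threshold: int = 8,
        base_sigma: float = 0.18172,
        base_delta_phi: float = 1.0 / 3.0,
    ) -> "LocationLayerParams":
        """Evenly oriented modules with a common scale.

        Orientations are ``i * 60 / n`` degrees; sigma and delta_phi follow
        the fixed-bump-size-relative-to-cells scaling from the w=6 baseline.
        """
        mods = tuple(
            gm.GridModuleParams.baseline(
                cells_per_axis=cells_per_axis,
                scale=scale,
                orientation=i * 60.0 / num_modules,
                base_sigma=base_sigma,
                base_delta_phi=base_delta_phi,
            )
            for i in range(num_modules)
        )
        return LocationLayerParams(mods, dendrite_threshold)


@dataclass
class LocationLayerState:
    """Bump sets and the two per-timestep activity snapshots."""

    bumps: list = field(default_factory=list)  # one ModuleBumpState per module
    active_move: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    active_sense: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    predictions: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


class LocationLayer:
    """Stateful location layer bound to a sensory layer of known size."""

    def __init__(self, params: LocationLayerParams, num_sensory_cells: int):
        self.params = params
        self.grids = [gm.CellPhaseGrid(p.cells_per_axis) for p in params.module_params]
        self.transforms = [gm.make_transform(p) for p in params.module_params]
        self.segments = SegmentStore(params.num_cells, num_sensory_cells)
        offsets = np.cumsum([0] + [p.num_cells for p in params.module_params])
        self.offsets = offsets[:-1]
        self.state = LocationLayerState(
            bumps=[gm.ModuleBumpState() for _ in params.module_params],
            active_move=np.zeros(params.num_cells, dtype=bool),
            active_sense=np.zeros(params.num_cells, dtype=bool),
            predictions=np.zeros(params.num_cells, dtype=bool),
        )

    # -- helpers -------------------------------------------------------

    def module_slice(self, i: int) -> slice:
        return slice(
            int(self.offsets[i]), int(self.offsets[i]) + self.params.module_params[i].num_cells
        )

    def _activity(self) -> np.ndarray:
        """Concatenated thresholded readout of all modules' bump sets."""
        out = np.zeros(self.params.num_cells, dtype=bool)
        for i, p in enumerate(self.params.module_params):
            act = gm.module_activation(p, self.grids[i], self.state.bumps[i])
            out[self.module_slice(i)] = act.binary
        return out

    def reset(self) -> None:
        """Clear all bumps (stateless network, as before touching an object)."""
        self.state.bumps = [gm.ModuleBumpState() for _ in self.params.module_params]
        self.state.active_move[:] = False
        self.state.active_sense[:] = False
        self.state.predictions[:] = False

    def activation_density(self) -> float:
        """Fraction of location-layer cells active in the current readout."""
        return float(np.mean(self._activity()))

    def bump_counts(self) -> list:
        return [s.num_bumps for s in self.state.bumps]

    def converged(self) -> bool:
        """Single location representation: exactly one bump in every module."""
        return all(s.num_bumps == 1 for s in self.state.bumps)

    # -- stages --------------------------------------------------------

    def move_update(self, movement) -> np.ndarray:
        """Stage 1: path-integrate every bump of every module."""
        if isinstance(movement, MovementVector):
            movement = movement.displacement
        movement = np.asarray(movement, dtype=float)
        self.state.bumps = [
            gm.path_integrate(s, movement, self.transforms[i])
            for i, s in enumerate(self.state.bumps)
        ]
        self.state.active_move = self._activity()
        return self.state.active_move

    def predict(self, sensory_active: np.ndarray) -> np.ndarray:
        """Stage 4a: location cells recalled by the sensory code (pi^loc)."""
        pi = self.segments.predicted(sensory_active, self.params.dendrite_threshold)
        self.state.predictions = pi
        return pi

    def sense_update(self, predictions: np.ndarray | None = None, learning: bool = False) -> np.ndarray:
        """Stage 4b: replace each module's bumps with recalled-cell bumps.

        In any module with at least one recalled cell, the bump set becomes
        bumps centered on those cells' phases (deduplicated at delta_phi / 4);
        a module with no recall keeps its path-integrated bumps.  During
        learning the sensory recall is bypassed entirely.
        """
        if learning:
            self.state.active_sense = self.state.active_move.copy()
            return self.state.active_sense
        pi = self.state.predictions if predictions is None else np.asarray(predictions, dtype=bool)
        for i, p in enumerate(self.params.module_params):
            flagged = np.flatnonzero(pi[self.module_slice(i)])
            if len(flagged):
                phases = gm.dedup_phases(
                    self.grids[i].phases[flagged], p.readout_resolution / 4.0
                )
                self.state.bumps[i] = gm.ModuleBumpState(phases)
        self.state.active_sense = self._activity()
        return self.state.active_sense

    # -- learning ------------------------------------------------------

    def learning_cells(self) -> tuple:
        """One winner cell per module (global indices), the learning set.

        Requires every module to hold at least one bump; with the single bump
        maintained during learning this is the bump's nearest cell.
        """
        winners = []
        for i, p in enumerate(self.params.module_params):
            scalar = gm.bump_activation(
                self.grids[i], self.state.bumps[i], p.bump_sigma
            )
            winners.append(int(self.offsets[i]) + gm.winner_cell(scalar))
        return tuple(winners)

    def learn(self, learning_set, sensory_learning_cells: np.ndarray) -> None:
        """Associate each winner cell with the sensory learning code (OR)."""
        presyn = np.flatnonzero(sensory_learning_cells)
        for cell in learning_set:
            self.segments.learn(int(cell), presyn, self.params.dendrite_threshold)

    def init_object_space(self, rng: np.random.Generator) -> list:
        """Start learning a new object: one uniform-random bump per module.

        The random starting phases implicitly define a unique location space
        for the object; across modules the joint code is almost surely unique.
        Returns the origin phases so a trained object can be revisited.
        """
        origins = [rng.random(2) for _ in self.params.module_params]
        self.set_bumps(origins)
        return origins

    def set_bumps(self, phases_per_module) -> None:
        self.state.bumps = [
            gm.ModuleBumpState(np.atleast_2d(p)) for p in phases_per_module
        ]
        self.state.active_move = self._activity()
        self.state.active_sense = self.state.active_move.copy()
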