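"""Mini-column sensory layer.

The layer is organised into mini-columns; all cells of a mini-column share a
feedforward receptive field, and each sensory feature drives a fixed sparse
subset of the columns.  Location input arrives on modulatory dendritic
segments: a predicted cell that receives feedforward input fires and inhibits
its column-mates, while a column with feedforward input but no predicted cell
*bursts* (every cell fires), encoding the feature at an unknown location.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segments import SegmentStore

__all__ = [
    "SensoryLayerParams",
    "SensoryInput",
    "SensoryLayerState",
    "SensoryLayer",
    "predict_cells",
    "activate_cells",
    "select_learning_cells",
]


@dataclass(frozen=True)
class SensoryLayerParams:
    """Sizes and dendritic threshold of the sensory layer.

    ``dendrite_threshold`` is the number of active presynaptic location cells
    a segment needs in order to fire (theta^in, ceil(0.8 n) for n location
    modules at baseline).
    """

    num_minicolumns: int = 150
    cells_per_column: int = 16
    dendrite_threshold: int = 8

    def __post_init__(self) -> None:
        if min(self.num_minicolumns, self.cells_per_column, self.dendrite_threshold) < 1:
            raise ValueError("all sensory-layer parameters must be positive")

    @property
    def num_cells(self) -> int:
        return self.num_minicolumns * self.cells_per_column


@dataclass(frozen=True)
class SensoryInput:
    """The sparse set of mini-columns driven by the current feature (W^in)."""

    active_columns: tuple

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "active_columns", tuple(int(c) for c in self.active_columns)
        )


@dataclass
class SensoryLayerState:
    """Per-timestep activity snapshot of the layer."""

    predictions: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    active: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    learning_cells: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def predict_cells(
    location_active: np.ndarray, segments: SegmentStore, threshold: int
) -> np.ndarray:
    """Cells with at least one segment matching the location activity (pi^in)."""
    return segments.predicted(location_active, threshold)


def activate_cells(
    input_: SensoryInput, predictions: np.ndarray, params: SensoryLayerParams
) -> np.ndarray:
    """Feedforward activation with modulatory gating.

    In each active column: predicted cells fire and suppress the rest; if no
    cell is predicted, the whole column bursts.  Cells outside the active
    columns stay silent even if predicted, which is what narrows the set of
    candidate objects.
    """
    cols = input_.active_columns
    if not cols:
        raise ValueError("empty sensory input: no active mini-columns")
    cpc = params.cells_per_column
    pred = np.asarray(predictions, dtype=bool).reshape(params.num_minicolumns, cpc)
    active = np.zeros_like(pred)
    col_idx = np.asarray(cols)
    col_predicted = pred[col_idx].any(axis=1)
    active[col_idx[col_predicted]] = pred[col_idx[col_predicted]]
    active[col_idx[~col_predicted]] = True
    return active.ravel()


def select_learning_cells(
    input_: SensoryInput,
    predictions: np.ndarray,
    params: SensoryLayerParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Learning-cell selection for one sensation.

    In each active column, the predicted cells learn if there are any;
    otherwise a single uniformly random cell is chosen to represent this
    feature at this (new) location.
    """
    cpc = params.cells_per_column
    pred = np.asarray(predictions, dtype=bool).reshape(params.num_minicolumns, cpc)
    learn = np.zeros_like(pred)
    for col in input_.active_columns:
        if pred[col].any():
            learn[col] = pred[col]
        else:
            learn[col, rng.integers(cpc)] = True
    return learn.ravel()


class SensoryLayer:
    """Stateful sensory layer bound to a location layer of known size."""

    def __init__(self, params: SensoryLayerParams, num_location_cells: int):
        self.params = params
        self.segments = SegmentStore(params.num_cells, num_location_cells)
        self.state = SensoryLayerState(
            predictions=np.zeros(params.num_cells, dtype=bool),
            active=np.zeros(params.num_cells, dtype=bool),
            learning_cells=np.zeros(params.num_cells, dtype=bool),
        )

    def predict(self, location_active: np.ndarray) -> np.ndarray:
        pi = predict_cells(location_active, self.segments, self.params.dendrite_threshold)
        self.state.predictions = pi
        return pi

    def activate(self, input_: SensoryInput) -> np.ndarray:
        a = activate_cells(input_, self.state.predictions, self.params)
        self.state.active = a
        return a

    def select_learning_cells(
        self, input_: SensoryInput, rng: np.random.Generator
    ) -> np.ndarray:
        learn = select_learning_cells(input_, self.state.predictions, self.params, rng)
        self.state.learning_cells = learn
        return learn

    def learn(self, learning_cells: np.ndarray, location_learning_set) -> None:
        """Associate each learning cell with the active location code (OR)."""
        presyn = list(location_learning_set)
        for cell in np.flatnonzero(learning_cells):
            self.segments.learn(int(cell), presyn, self.params.dendrite_threshold)
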