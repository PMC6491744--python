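"""Single grid-cell module: phase lattice, path integration, bump readout.

A module is a population of ``w * w`` cells sharing one lattice scale and
orientation.  Its state is a finite set of activity *bumps*, each a 2D phase in
the unit square ``[0, 1) x [0, 1)``.  Because the two lattice basis vectors are
separated by 60 degrees, the unit square of phases maps onto a rhombus in
physical space and the cells pack hexagonally.  Movement of the sensor shifts
every bump through the module's transform matrix (path integration); a
Gaussian readout converts bump phases into scalar cell activations, which are
thresholded into the module's binary output.

Multiple simultaneous bumps (a *union*) encode a set of candidate locations
under ambiguity; their activations combine like probabilities of independent
events (a probabilistic OR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridModuleParams",
    "CellPhaseGrid",
    "ModuleBumpState",
    "ModuleActivation",
    "RHOMBUS_BASIS",
    "COVERING_FACTOR",
    "make_transform",
    "path_integrate",
    "rhombus_distance",
    "pairwise_rhombus_distance",
    "bump_activation",
    "activation_threshold",
    "active_cells",
    "winner_cell",
    "module_activation",
    "dedup_phases",
    "pairwise_rhombus_distance_sq",
    "sweep_active_cell_counts",
    "joint_state_count",
    "readout_position_count",
]

#: Physical basis of the unit-period rhombus; columns are the two lattice
#: vectors, separated by 60 degrees.
RHOMBUS_BASIS = np.array([[1.0, 0.5], [0.0, math.sqrt(3.0) / 2.0]])

#: Hexagonal covering factor: expands the readout circles so that circles
#: packed hexagonally overlap and cover the plane (covering/packing radius
#: ratio of the triangular lattice).
COVERING_FACTOR = 2.0 / math.sqrt(3.0)

# Integer wrap offsets for the toroidal rhombus metric, shape (9, 2).
_WRAP_OFFSETS = np.array([[i, j] for i in (-1, 0, 1) for j in (-1, 0, 1)], dtype=float)


@dataclass(frozen=True)
class GridModuleParams:
    """Geometry of one grid-cell module.

    Parameters
    ----------
    scale : float
        Lattice period in length units (distance the sensor travels along a
        basis vector to shift the bump by a full phase).
    orientation : float
        Lattice orientation in degrees, in ``[0, 60)``.
    cells_per_axis : int
        ``w``; the module has ``w * w`` cells.
    bump_sigma : float
        Width of the Gaussian activity bump, in phase units.
    readout_resolution : float
        ``delta_phi``; approximate diameter of the phase range encoded by one
        bump's active-cell set, in phase units, in ``(0, 1]``.
    """

    scale: float
    orientation: float
    cells_per_axis: int
    bump_sigma: float
    readout_resolution: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError(f"scale must be finite and positive, got {self.scale}")
        if not (np.isfinite(self.orientation) and 0.0 <= self.orientation < 60.0):
            raise ValueError(
                f"orientation must be in [0, 60) degrees, got {self.orientation}"
            )
        if self.cells_per_axis < 1:
            raise ValueError("cells_per_axis must be >= 1")
        if not (np.isfinite(self.bump_sigma) and self.bump_sigma > 0):
            raise ValueError("bump_sigma must be finite and positive")
        if not (0.0 < self.readout_resolution <= 1.0):
            raise ValueError("readout_resolution must be in (0, 1]")

    @property
    def num_cells(self) -> int:
        return self.cells_per_axis**2

    @staticmethod
    def baseline(
        cells_per_axis: int = 6,
        scale: float = 1.5,
        orientation: float = 0.0,
        base_sigma: float = 0.18172,
        base_delta_phi: float = 1.0 / 3.0,
        base_cells_per_axis: int = 6,
    ) -> "GridModuleParams":
        """Baseline parameters, rescaled so the bump stays a fixed size
        relative to the cells.

        At ``w = 6`` this is the entorhinal-sparsity baseline
        (``sigma = 0.18172``, ``delta_phi = 1/3``); with more cells per axis,
        ``sigma`` and ``delta_phi`` shrink proportionally so that a single
        bump always activates the same 4-7 cells.
        """
        ratio = base_cells_per_axis / cells_per_axis
        return GridModuleParams(
            scale=scale,
            orientation=orientation,
            cells_per_axis=cells_per_axis,
            bump_sigma=base_sigma * ratio,
            readout_resolution=base_delta_phi * ratio,
        )


class CellPhaseGrid:
    """Fixed phases of the ``w * w`` cells of a module.

    Cell ``c`` has phase ``((c % w + 0.5) / w, (c // w + 0.5) / w)`` -- the
    centers of a ``w x w`` equal-area partition of the unit square.
    """

    def __init__(self, cells_per_axis: int):
        if cells_per_axis < 1:
            raise ValueError("cells_per_axis must be >= 1")
        self.cells_per_axis = int(cells_per_axis)
        w = self.cells_per_axis
        c = np.arange(w * w)
        self.phases = np.column_stack(((c % w + 0.5) / w, (c // w + 0.5) / w))

    @property
    def num_cells(self) -> int:
        return self.cells_per_axis**2


@dataclass
class ModuleBumpState:
    """The set of active bump phases of one module (a union of locations)."""

    bumps: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        self.bumps = np.atleast_2d(np.asarray(self.bumps, dtype=float))
        if self.bumps.size == 0:
            self.bumps = np.empty((0, 2))
        if self.bumps.ndim != 2 or self.bumps.shape[1] != 2:
            raise ValueError("bumps must be an (k, 2) array of phases")
        if self.bumps.size and not (
            np.all(self.bumps >= 0.0) and np.all(self.bumps < 1.0)
        ):
            raise ValueError("bump phases must lie in [0, 1)")

    @property
    def num_bumps(self) -> int:
        return len(self.bumps)


@dataclass
class ModuleActivation:
    """Scalar and thresholded-binary activation of a module's cells."""

    scalar: np.ndarray
    binary: np.ndarray


def make_transform(params: GridModuleParams) -> np.ndarray:
    """Movement-to-phase transform matrix ``M``.

    ``M`` is the inverse of the matrix whose columns are the module's two
    lattice basis vectors ``s * (cos t, sin t)`` and
    ``s * (cos(t + 60), sin(t + 60))``.  Multiplying a sensor movement vector
    by ``M`` yields the bump displacement in phase units in the 60-degree
    basis.
    """
    t = math.radians(params.orientation)
    s = params.scale
    a = s * math.cos(t)
    c = s * math.sin(t)
    b = s * math.cos(t + math.pi / 3.0)
    d = s * math.sin(t + math.pi / 3.0)
    det = a * d - b * c
    return np.array([[d, -b], [-c, a]]) / det


def _mod1(phases: np.ndarray) -> np.ndarray:
    """Componentwise mod 1, guaranteed to land in [0, 1)."""
    out = np.mod(phases, 1.0)
    # floating-point rounding can produce exactly 1.0 for tiny negatives
    out[out >= 1.0] -= 1.0
    return out


def path_integrate(
    state: ModuleBumpState, movement: np.ndarray, transform: np.ndarray
) -> ModuleBumpState:
    """Shift every bump by ``transform @ movement``, mod 1.

    The same phase displacement is applied independently to each bump of the
    union; the bump count is unchanged.  The modulo confines phases to
    ``[0, 1) x [0, 1)``.
    """
    movement = np.asarray(movement, dtype=float)
    if not np.all(np.isfinite(movement)):
        raise ValueError("movement vector must be finite")
    if state.num_bumps == 0:
        return ModuleBumpState()
    delta = transform @ movement
    return ModuleBumpState(_mod1(state.bumps + delta))


def pairwise_rhombus_distance_sq(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared toroidal distances on the phase rhombus (see
    :func:`pairwise_rhombus_distance`); the Gaussian readout only needs the
    square, so the sqrt is skipped on the hot path."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    # map through the rhombus basis once: v_phys = B @ v_phase
    ax = RHOMBUS_BASIS[0, 0] * a[:, 0] + RHOMBUS_BASIS[0, 1] * a[:, 1]
    ay = RHOMBUS_BASIS[1, 1] * a[:, 1]
    bx = RHOMBUS_BASIS[0, 0] * b[:, 0] + RHOMBUS_BASIS[0, 1] * b[:, 1]
    by = RHOMBUS_BASIS[1, 1] * b[:, 1]
    dx = ax[:, None] - bx[None, :]
    dy = ay[:, None] - by[None, :]
    best = np.full(dx.shape, np.inf)
    scratch = np.empty_like(best)
    for k in _WRAP_OFFSETS:
        ox = RHOMBUS_BASIS[0, 0] * k[0] + RHOMBUS_BASIS[0, 1] * k[1]
        oy = RHOMBUS_BASIS[1, 1] * k[1]
        np.square(dx + ox, out=scratch)
        scratch += np.square(dy + oy)
        np.minimum(best, scratch, out=best)
    return best


def pairwise_rhombus_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Toroidal distances on the phase rhombus between two sets of phases.

    Both phases are mapped through the 60-degree basis onto the physical
    rhombus; the Euclidean distance is minimized over the 3x3 grid of integer
    wrap offsets.  Returns an ``(len(a), len(b))`` matrix.
    """
    return np.sqrt(pairwise_rhombus_distance_sq(a, b))


def rhombus_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Shortest distance between two phases on the phase rhombus."""
    return float(pairwise_rhombus_distance(a, b)[0, 0])


def _gaussian(d: np.ndarray | float, sigma: float) -> np.ndarray | float:
    return np.exp(-np.square(d) / (2.0 * sigma**2))


def bump_activation(
    grid: CellPhaseGrid, state: ModuleBumpState, sigma: float
) -> np.ndarray:
    """Scalar activation of every cell from the union of bumps.

    Each bump contributes ``a_{c,b} = exp(-d^2 / 2 sigma^2)`` with ``d`` the
    rhombus distance from cell to bump; contributions combine as a
    probabilistic OR, ``a_c = 1 - prod_b (1 - a_{c,b})``.  An empty bump set
    yields all-zero activations (the pre-first-sensation state).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if state.num_bumps == 0:
        return np.zeros(grid.num_cells)
    d_sq = pairwise_rhombus_distance_sq(grid.phases, state.bumps)
    a_cb = np.exp(-d_sq / (2.0 * sigma**2))
    return 1.0 - np.prod(1.0 - a_cb, axis=1)


def activation_threshold(delta_phi: float, sigma: float) -> float:
    """Readout threshold ``a_active``.

    A cell is active when its scalar activation is at least the Gaussian
    evaluated at radius ``(delta_phi / 2) * (2 / sqrt(3))``: half the readout
    resolution, expanded by the hexagonal covering factor so the active-cell
    discs of neighboring bump positions overlap and leave no gaps.
    """
    if not (0.0 < delta_phi <= 1.0):
        raise ValueError("delta_phi must be in (0, 1]")
    r = (delta_phi / 2.0) * COVERING_FACTOR
    return float(_gaussian(r, sigma))


def active_cells(activations: np.ndarray, a_active: float) -> np.ndarray:
    """Binary readout: cell active iff its scalar activation >= threshold."""
    return np.asarray(activations) >= a_active


def winner_cell(activations: np.ndarray) -> int:
    """Index of the most active cell (the learning-time bump representative).

    Ties break to the lowest cell index.  Raises if there is no activity
    (no location to learn).
    """
    activations = np.asarray(activations)
    if activations.size == 0 or np.max(activations) <= 0.0:
        raise ValueError("no active bump: no location to learn")
    return int(np.argmax(activations))


def module_activation(
    params: GridModuleParams, grid: CellPhaseGrid, state: ModuleBumpState
) -> ModuleActivation:
    """Convenience: scalar + thresholded activation of one module."""
    scalar = bump_activation(grid, state, params.bump_sigma)
    thr = activation_threshold(params.readout_resolution, params.bump_sigma)
    return ModuleActivation(scalar=scalar, binary=active_cells(scalar, thr))


def dedup_phases(phases: np.ndarray, tolerance: float) -> np.ndarray:
    """Merge phases closer than ``tolerance`` on the rhombus (keep the first).

    Sense-driven bump resets can place bumps on adjacent cells recalling one
    location; without merging, union-size statistics would be inflated.
    """
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    n = len(phases)
    if n <= 1:
        return phases
    d_sq = pairwise_rhombus_distance_sq(phases, phases)
    tol_sq = tolerance * tolerance
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        if keep[i]:
            close = d_sq[i] < tol_sq
            close[: i + 1] = False  # a kept phase only suppresses later ones
            keep &= ~close
    return phases[keep]


def sweep_active_cell_counts(
    params: GridModuleParams, resolution: int = 200, chunk: int = 2000
) -> np.ndarray:
    """Active-cell counts for a single bump swept over a dense phase grid.

    Places one bump at each point of a ``resolution x resolution`` grid of
    phases and counts the cells active under the thresholded readout.
    Returns the flat array of counts (used to verify the 4-7 active-cell
    bound and readout coverage).
    """
    grid = CellPhaseGrid(params.cells_per_axis)
    thr = activation_threshold(params.readout_resolution, params.bump_sigma)
    axis = np.arange(resolution) / resolution
    xx, yy = np.meshgrid(axis, axis)
    centers = np.column_stack((xx.ravel(), yy.ravel()))
    counts = np.empty(len(centers), dtype=np.int64)
    for start in range(0, len(centers), chunk):
        block = centers[start : start + chunk]
        d_sq = pairwise_rhombus_distance_sq(block, grid.phases)
        a = np.exp(-d_sq / (2.0 * params.bump_sigma**2))
        counts[start : start + len(block)] = np.sum(a >= thr, axis=1)
    return counts


def joint_state_count(num_modules: int, positions_per_module: int) -> int:
    """Number of distinct joint bump states across modules.

    Each module independently encodes one of ``positions_per_module``
    discriminable positions, so the joint code has
    ``positions_per_module ** num_modules`` states (e.g. 25**10 ~ 1e14).
    """
    if num_modules < 1 or positions_per_module < 1:
        raise ValueError("arguments must be positive")
    return positions_per_module**num_modules


def readout_position_count(delta_phi: float) -> int:
    """Approximate number of distinguishable bump positions per module.

    The readout resolution ``delta_phi`` is the diameter of the encoded phase
    range; in 2D a module distinguishes about ``(1 / delta_phi) ** 2``
    positions (16 for ``delta_phi = 1/4``).
    """
    if not (0.0 < delta_phi <= 1.0):
        raise ValueError("delta_phi must be in (0, 1]")
    return round((1.0 / delta_phi) ** 2)
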