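"""Binary dendritic segments with threshold detection.

Both layers use the same neuron model: each cell carries any number of
independent dendritic segments, each a sparse binary connection vector over
the opposite layer's cells.  A segment is active when its overlap with the
presynaptic active set reaches the dendritic threshold; a cell is *predicted*
when at least one of its segments is active.  Synapse weights are 0/1 and
segments only ever grow (bitwise OR), so learning is monotone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

__all__ = ["DendriticSegment", "SegmentStore"]


@dataclass(frozen=True)
class DendriticSegment:
    """Read-only view of one segment: owning cell and its connection set."""

    cell: int
    connections: frozenset


class SegmentStore:
    """All dendritic segments of one layer, over a fixed presynaptic size.

    Overlaps for the whole pool are computed in one sparse matrix-vector
    product (segments x presynaptic cells CSR), rebuilt lazily after growth.
    """

    def __init__(self, num_cells: int, presynaptic_size: int):
        self.num_cells = int(num_cells)
        self.presynaptic_size = int(presynaptic_size)
        self._owners: list[int] = []
        self._conns: list[set] = []
        self._by_cell: dict[int, list[int]] = {}
        self._csr: sparse.csr_matrix | None = None

    # -- bookkeeping ---------------------------------------------------

    @property
    def num_segments(self) -> int:
        return len(self._conns)

    @property
    def num_synapses(self) -> int:
        return sum(len(c) for c in self._conns)

    def segments_of(self, cell: int) -> list[int]:
        return list(self._by_cell.get(cell, ()))

    def get(self, segment: int) -> DendriticSegment:
        return DendriticSegment(
            cell=self._owners[segment], connections=frozenset(self._conns[segment])
        )

    # -- growth --------------------------------------------------------

    def add_segment(self, cell: int, connections) -> int:
        conns = set(int(i) for i in connections)
        if conns and (min(conns) < 0 or max(conns) >= self.presynaptic_size):
            raise ValueError("connection index out of range")
        seg = len(self._conns)
        self._owners.append(int(cell))
        self._conns.append(conns)
        self._by_cell.setdefault(int(cell), []).append(seg)
        self._csr = None
        return seg

    def reinforce(self, segment: int, connections) -> None:
        """Bitwise-OR new connections into a segment (never removes any)."""
        before = len(self._conns[segment])
        self._conns[segment].update(int(i) for i in connections)
        if len(self._conns[segment]) != before:
            self._csr = None

    def learn(self, cell: int, presynaptic_active, threshold: int) -> int:
        """Grow-or-extend policy for one learning cell.

        If the cell already has a segment whose overlap with the presynaptic
        active set reaches ``threshold``, that segment is extended (OR);
        otherwise a new segment is grown.  This keeps distinct contexts on
        distinct segments.  Returns the segment id.
        """
        active = set(int(i) for i in presynaptic_active)
        best = None
        for seg in self._by_cell.get(int(cell), ()):
            if len(self._conns[seg] & active) >= threshold:
                best = seg
                break
        if best is None:
            return self.add_segment(cell, active)
        self.reinforce(best, active)
        return best

    # -- detection -----------------------------------------------------

    def _matrix(self) -> sparse.csr_matrix:
        if self._csr is None:
            lengths = np.array([len(c) for c in self._conns])
            indptr = np.concatenate(([0], np.cumsum(lengths)))
            cols = (
                np.concatenate([np.fromiter(c, dtype=np.int64) for c in self._conns])
                if len(self._conns)
                else np.zeros(0, dtype=np.int64)
            )
            self._csr = sparse.csr_matrix(
                (np.ones(len(cols), dtype=np.int32), cols, indptr),
                shape=(len(self._conns), self.presynaptic_size),
            )
        return self._csr

    def overlaps(self, presynaptic_active: np.ndarray) -> np.ndarray:
        """Per-segment overlap counts with a binary presynaptic vector."""
        if not self._conns:
            return np.zeros(0, dtype=np.int64)
        vec = np.asarray(presynaptic_active)
        if vec.dtype != np.int32:
            vec = vec.astype(np.int32)
        return np.asarray(self._matrix() @ vec, dtype=np.int64)

    def predicted(self, presynaptic_active: np.ndarray, threshold: int) -> np.ndarray:
        """Binary vector over cells: has the cell >=1 active segment?"""
        out = np.zeros(self.num_cells, dtype=bool)
        if not self._conns:
            return out
        hits = self.overlaps(presynaptic_active) >= threshold
        if np.any(hits):
            owners = np.asarray(self._owners)
            out[owners[hits]] = True
        return out
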