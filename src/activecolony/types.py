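"""Core containers for tracked-cell data.

A colony movie reduces, after segmentation and tracking, to an ordered
sequence of frames, each holding the centroid position ``r_i``, pole-to-pole
length ``L_i``, diameter ``W_i`` and orientation ``nu_i`` of every cell.
Orientations are nematic (head-tail symmetric) and stored as angles in
``[0, pi)`` measured from the +x axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = ["RodCell", "ColonyFrame", "ColonyTimeSeries", "fold_angle"]


def fold_angle(angle):
    """Fold orientation angles into ``[0, pi)`` (nematic symmetry)."""
    return np.mod(angle, np.pi)


@dataclass
class RodCell:
    """A single rod-shaped cell.

    Attributes
    ----------
    id : int
        Unique cell identifier within a frame.
    parent_id : int
        Identifier of the mother cell, or ``-1`` if unknown/root.
    x, y : float
        Centroid position in micrometres.
    length : float
        Pole-to-pole length in micrometres (``> 0``).
    width : float
        Cell diameter in micrometres (``> 0``).
    angle : float
        Orientation in radians, folded to ``[0, pi)``.
    """

    id: int
    x: float
    y: float
    length: float
    width: float
    angle: float
    parent_id: int = -1

    def __post_init__(self):
        if self.length <= 0 or self.width <= 0:
            raise ValueError("cell length and width must be positive")
        self.angle = float(fold_angle(self.angle))

    @property
    def nu(self) -> np.ndarray:
        """Unit orientation vector ``(cos angle, sin angle)``."""
        return np.array([np.cos(self.angle), np.sin(self.angle)])


@dataclass
class ColonyFrame:
    """All cells of a colony at one instant, stored as flat arrays."""

    time: float  # minutes
    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    length: np.ndarray
    width: np.ndarray
    angle: np.ndarray
    parent_ids: np.ndarray = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        n = self.ids.size
        for name in ("x", "y", "length", "width", "angle"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"field '{name}' must have shape ({n},)")
            setattr(self, name, arr)
        if self.parent_ids is None:
            self.parent_ids = np.full(n, -1, dtype=np.int64)
        else:
            self.parent_ids = np.asarray(self.parent_ids, dtype=np.int64)
        if np.unique(self.ids).size != n:
            raise ValueError("cell ids must be unique within a frame")
        if np.any(self.length <= 0) or np.any(self.width <= 0):
            raise ValueError("cell lengths and widths must be positive")
        self.angle = fold_angle(self.angle)

    @property
    def n_cells(self) -> int:
        return self.ids.size

    @property
    def nu(self) -> np.ndarray:
        """Unit orientation vectors, shape ``(n, 2)``."""
        return np.column_stack([np.cos(self.angle), np.sin(self.angle)])

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @property
    def cell_area(self) -> np.ndarray:
        """Footprint area of each spherocylinder (shaft + caps), um^2."""
        shaft = np.maximum(self.length - self.width, 0.0)
        return shaft * self.width + 0.25 * np.pi * self.width**2

    def centroid(self) -> np.ndarray:
        """Area-weighted colony centroid."""
        w = self.cell_area
        return np.array([np.average(self.x, weights=w), np.average(self.y, weights=w)])

    def cells(self) -> Iterator[RodCell]:
        for k in range(self.n_cells):
            yield RodCell(
                id=int(self.ids[k]),
                x=float(self.x[k]),
                y=float(self.y[k]),
                length=float(self.length[k]),
                width=float(self.width[k]),
                angle=float(self.angle[k]),
                parent_id=int(self.parent_ids[k]),
            )

    @classmethod
    def from_cells(cls, time: float, cells) -> "ColonyFrame":
        cells = list(cells)
        return cls(
            time=time,
            ids=np.array([c.id for c in cells], dtype=np.int64),
            x=np.array([c.x for c in cells]),
            y=np.array([c.y for c in cells]),
            length=np.array([c.length for c in cells]),
            width=np.array([c.width for c in cells]),
            angle=np.array([c.angle for c in cells]),
            parent_ids=np.array([c.parent_id for c in cells], dtype=np.int64),
        )


@dataclass
class ColonyTimeSeries:
    """Ordered frames of a growing colony plus the division lineage."""

    frames: list = field(default_factory=list)
    lineage: dict = field(default_factory=dict)  # child id -> parent id

    def __post_init__(self):
        times = np.array([f.time for f in self.frames])
        if times.size and (np.any(times < 0) or np.any(np.diff(times) <= 0)):
            raise ValueError("frame times must be non-negative and strictly increasing")
        self._check_lineage()

    def _check_lineage(self):
        # acyclicity: walking parent links must terminate
        for child in self.lineage:
            seen = set()
            node = child
            while node in self.lineage:
                if node in seen:
                    raise ValueError(f"lineage cycle involving cell {child}")
                seen.add(node)
                node = self.lineage[node]

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, k) -> ColonyFrame:
        return self.frames[k]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])
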