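"""Shared in-memory containers for volumes, masks and dynamic series.

Arrays follow the package axis convention: axis 0 = LL, axis 1 = AP,
axis 2 = SI.  Axial slices are therefore planes of constant SI index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical axis order and names.
AXES = ("LL", "AP", "SI")

#: Names of the analysed structures: the whole gland and its k-means segments.
STRUCTURES = ("pancreas", "head", "body", "tail")

#: Integer codes used in segment label maps (0 is background).
SEGMENT_CODES = {"head": 1, "body": 2, "tail": 3}


def axis_index(axis: str) -> int:
    """Map an anatomical axis name (``"LL" | "AP" | "SI"``) to an array axis."""
    try:
        return AXES.index(axis.upper())
    except ValueError:
        raise ValueError(f"unknown axis {axis!r}; expected one of {AXES}") from None


@dataclass
class Mask4D:
    """One binary structure map per breathing phase on a shared grid.

    Parameters
    ----------
    masks
        List of boolean 3D arrays, one per phase, identical shapes.
    spacing_mm
        Voxel size along (LL, AP, SI) in millimetres.
    """

    masks: list[np.ndarray]
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.masks:
            raise ValueError("Mask4D requires at least one phase")
        shape = self.masks[0].shape
        for p, m in enumerate(self.masks):
            if m.shape != shape:
                raise ValueError(
                    f"phase {p + 1} mask shape {m.shape} differs from {shape}"
                )
            if not m.any():
                raise ValueError(f"phase {p + 1} mask is empty")
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def n_phases(self) -> int:
        return len(self.masks)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.masks[0].shape


@dataclass
class DynamicSliceSeries:
    """Time-ordered 2D axial slices from a dynamic multi-slice acquisition.

    ``images[i]`` is the (LL, AP) image acquired at ``time_ms[i]`` at slice
    position ``slice_index[i]``.  ``true_phase`` carries simulator ground
    truth (1-based phase labels) and is ``None`` for real data.
    """

    images: np.ndarray  # (N, nLL, nAP)
    slice_index: np.ndarray  # (N,) int
    time_ms: np.ndarray  # (N,) float
    spacing_mm: tuple[float, float, float]
    n_slices: int
    n_measurements: int
    true_phase: np.ndarray | None = None  # (N,) int, 1-based

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.slice_index = np.asarray(self.slice_index, dtype=int)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        n = len(self.images)
        if len(self.slice_index) != n or len(self.time_ms) != n:
            raise ValueError("images, slice_index and time_ms must align")
        if self.slice_index.min() < 0 or self.slice_index.max() >= self.n_slices:
            raise ValueError("slice_index out of range [0, n_slices)")
        if self.true_phase is not None:
            self.true_phase = np.asarray(self.true_phase, dtype=int)
            if len(self.true_phase) != n:
                raise ValueError("true_phase must align with images")

    def __len__(self) -> int:
        return len(self.images)

    def group(self, slice_idx: int) -> np.ndarray:
        """Indices (time-ordered) of all measurements at one slice position."""
        return np.flatnonzero(self.slice_index == slice_idx)
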