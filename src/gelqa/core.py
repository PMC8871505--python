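"""Shared containers for the QA pipeline.

All spatial quantities use the Leksell stereotactic frame: coordinates in
millimetres, with the unit's focus conventionally at (100, 100, 100) mm.
Arrays are indexed ``[ix, iy, iz]`` matching the (X, Y, Z) axes; ``origin``
is the stereotactic coordinate of the *center* of voxel ``(0, 0, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = ["GridSpec", "DoseGrid", "EchoImagePair", "FilmScan"]

AXES = ("X", "Y", "Z")


@dataclass(frozen=True)
class GridSpec:
    """Regular voxel grid in stereotactic mm coordinates.

    Parameters
    ----------
    shape : tuple of int
        Voxel counts per axis (X, Y, Z).
    spacing : tuple of float
        Voxel size in mm per axis; strictly positive.
    origin : tuple of float
        Stereotactic mm coordinate of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, ...]
    spacing: tuple[float, ...]
    origin: tuple[float, ...]

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if not (len(shape) == len(spacing) == len(origin)):
            raise ValueError("shape, spacing and origin must have equal length")
        if any(n < 1 for n in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    def coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def extent(self, axis: int) -> tuple[float, float]:
        """Min/max voxel-center coordinate along one axis."""
        c = self.coords(axis)
        return float(c[0]), float(c[-1])

    def contains_point(self, point: Sequence[float]) -> bool:
        return all(
            self.extent(a)[0] - 0.5 * self.spacing[a]
            <= float(point[a])
            <= self.extent(a)[1] + 0.5 * self.spacing[a]
            for a in range(self.ndim)
        )

    def nearest_index(self, point: Sequence[float]) -> tuple[int, ...]:
        """Index of the voxel whose center is nearest to a stereotactic point."""
        idx = []
        for a in range(self.ndim):
            i = int(round((float(point[a]) - self.origin[a]) / self.spacing[a]))
            idx.append(min(max(i, 0), self.shape[a] - 1))
        return tuple(idx)

    def meshgrid(self) -> tuple[np.ndarray, ...]:
        return np.meshgrid(*[self.coords(a) for a in range(self.ndim)], indexing="ij")

    def to_dict(self) -> dict:
        return {"shape": list(self.shape), "spacing": list(self.spacing), "origin": list(self.origin)}

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(tuple(d["shape"]), tuple(d["spacing"]), tuple(d["origin"]))


@dataclass
class DoseGrid:
    """Scalar absorbed-dose field (Gy) on a regular stereotactic grid.

    ``valid`` masks voxels carrying a trustworthy dose value; ``saturated``
    flags voxels whose dose was inverted above the calibration's linear
    range (saturated implies valid).
    """

    dose: np.ndarray
    grid: GridSpec
    valid: Optional[np.ndarray] = None
    saturated: Optional[np.ndarray] = None
    provenance: str = "truth"

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != tuple(self.grid.shape):
            raise ValueError(
                f"dose shape {self.dose.shape} does not match grid shape {self.grid.shape}"
            )
        if self.valid is None:
            self.valid = np.ones(self.dose.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.saturated is None:
            self.saturated = np.zeros(self.dose.shape, dtype=bool)
        else:
            self.saturated = np.asarray(self.saturated, dtype=bool)
        if np.any(self.saturated & ~self.valid):
            raise ValueError("saturated voxels must be a subset of valid voxels")
        if np.any(self.dose[self.valid] < 0):
            raise ValueError("valid voxels must carry nonnegative dose")

    @property
    def dmax(self) -> float:
        if not self.valid.any():
            raise ValueError("dose grid has no valid voxels")
        return float(self.dose[self.valid].max())

    def robust_max(self, percentile: float = 99.5) -> float:
        """Robust maximum: high percentile of dose within the half-maximum
        core, so single-voxel noise spikes do not define the 100% level
        while a point field in a large background volume still normalizes
        to its peak."""
        if not self.valid.any():
            raise ValueError("dose grid has no valid voxels")
        values = self.dose[self.valid]
        core = values[values >= 0.5 * values.max()]
        return float(np.percentile(core, percentile))

    def copy(self) -> "DoseGrid":
        return DoseGrid(
            self.dose.copy(), self.grid, self.valid.copy(), self.saturated.copy(), self.provenance
        )


@dataclass
class EchoImagePair:
    """Two co-registered spin-echo magnitude images with their echo times.

    ``s1``/``s2`` hold the signal S(TE1)/S(TE2); echo times are in ms.
    """

    s1: np.ndarray
    s2: np.ndarray
    te1: float
    te2: float
    grid: GridSpec

    def __post_init__(self):
        self.s1 = np.asarray(self.s1, dtype=float)
        self.s2 = np.asarray(self.s2, dtype=float)
        if self.s1.shape != self.s2.shape:
            raise ValueError("echo images must share shape")
        if self.s1.shape != tuple(self.grid.shape):
            raise ValueError("echo image shape does not match grid")
        if self.te1 == self.te2:
            raise ValueError("echo times must differ")


@dataclass
class FilmScan:
    """A scanned radiochromic film: one extracted channel of pixel values.

    ``pixel_spacing`` is in mm (25.4 / dpi).  ``od`` optionally carries the
    net optical density computed against an unexposed reference.
    """

    pixels: np.ndarray
    pixel_spacing: float
    channel: str = "red"
    od: Optional[np.ndarray] = None
    dpi: Optional[float] = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("film scan must be a 2D image")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        if np.any(self.pixels < 0):
            raise ValueError("pixel values must be nonnegative")
        if self.od is not None:
            self.od = np.asarray(self.od, dtype=float)
            if self.od.shape != self.pixels.shape:
                raise ValueError("od array must match pixel array shape")
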