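"""Core in-memory containers for 3D microscopy-style volumes.

Axis order is fixed to (z, y, x) throughout the package, matching the
convention of confocal image stacks stored as multi-page TIFFs.  All
coordinates are 0-based and ranges are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["IntensityVolume", "LabelVolume"]

_DEFAULT_SPACING = (1.0, 1.0, 1.0)


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError("spacing must be a (z, y, x) triple")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive and finite, got {spacing}")
    return spacing


@dataclass
class IntensityVolume:
    """A 3D scalar fluorescence-like signal with physical voxel spacing.

    Parameters
    ----------
    data
        3D array, axis order (z, y, x).  Values must be finite and
        non-negative (fluorescence intensities have no sign).
    spacing
        Physical voxel size in micrometres, (z, y, x).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = _DEFAULT_SPACING

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensity volume contains non-finite values")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensity volume contains negative values")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "IntensityVolume":
        return IntensityVolume(self.data.copy(), self.spacing)


@dataclass
class LabelVolume:
    """A 3D non-negative integer label grid; label 0 is medium/background.

    Labels need not be contiguous.  Used for cell masks, cell-border
    images, binary membranes and nucleus instance labels alike.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = _DEFAULT_SPACING

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={arr.ndim}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)):
                raise ValueError("label volume contains non-finite values")
            rounded = np.rint(arr)
            if not np.array_equal(rounded, arr):
                raise ValueError("label volume contains non-integer values")
            arr = rounded.astype(np.int64)
        if arr.size and arr.min() < 0:
            raise ValueError("label volume contains negative labels")
        self.data = arr.astype(np.int64, copy=False)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the volume."""
        u = np.unique(self.data)
        return u[u > 0]

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), self.spacing)
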