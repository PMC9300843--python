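"""In-memory containers for co-registered photoacoustic volumes.

Axis convention (documented also in the IO sidecar schema): volumes are
3D arrays indexed ``(frame, depth, lateral)``; the depth axis points away
from the transducer face, so depth in mm of voxel ``j`` along that axis
is ``j * voxel_spacing[depth_axis]``.  Voxel indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import AlignmentError, ValidationError

__all__ = ["PAVolumePair", "depth_coordinates"]


@dataclass
class PAVolumePair:
    """Two co-registered photoacoustic amplitude volumes.

    Parameters
    ----------
    vol_lo, vol_hi : ndarray
        Amplitude volumes at the shorter and longer wavelength.
    wavelengths : tuple of float
        (lambda_lo, lambda_hi) in nm.
    voxel_spacing : tuple of float
        Voxel pitch in mm per axis, same axis order as the arrays.
    depth_axis : int
        Array axis pointing away from the transducer.
    meta : dict
        Free-form provenance (seed, spec echo, compensation flags, ...).
    """

    vol_lo: np.ndarray
    vol_hi: np.ndarray
    wavelengths: tuple[float, float] = (750.0, 850.0)
    voxel_spacing: tuple[float, float, float] = (0.15, 0.1, 0.1)
    depth_axis: int = 1
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vol_lo = np.asarray(self.vol_lo, dtype=float)
        self.vol_hi = np.asarray(self.vol_hi, dtype=float)
        if self.vol_lo.shape != self.vol_hi.shape:
            raise AlignmentError(
                f"volume shapes differ: {self.vol_lo.shape} vs {self.vol_hi.shape}"
            )
        if self.vol_lo.ndim != 3:
            raise ValidationError("volumes must be 3D")
        if not 0 <= self.depth_axis < 3:
            raise ValidationError("depth_axis must be 0, 1 or 2")
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValidationError("voxel_spacing must be three positive floats")
        if self.wavelengths[0] >= self.wavelengths[1]:
            raise ValidationError("wavelengths must be (low, high)")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.vol_lo.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_spacing))

    def depth_map(self) -> np.ndarray:
        """Depth (mm) of every voxel, broadcast to the volume shape."""
        return depth_coordinates(
            self.shape, self.voxel_spacing, self.depth_axis, broadcast=True
        )

    def copy(self) -> "PAVolumePair":
        return PAVolumePair(
            self.vol_lo.copy(),
            self.vol_hi.copy(),
            self.wavelengths,
            self.voxel_spacing,
            self.depth_axis,
            dict(self.meta),
        )


def depth_coordinates(shape, voxel_spacing, depth_axis, broadcast=False):
    """1D (or broadcast 3D) array of voxel depths in mm along ``depth_axis``."""
    n = shape[depth_axis]
    z = np.arange(n, dtype=float) * voxel_spacing[depth_axis]
    if not broadcast:
        return z
    expand = [None] * 3
    expand[depth_axis] = slice(None)
    return np.broadcast_to(z[tuple(expand)], shape)
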