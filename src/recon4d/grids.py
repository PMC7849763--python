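"""Core gridded containers: attenuation volumes and displacement fields.

Conventions used throughout the package
---------------------------------------
* Arrays are C-ordered ``[Z, Y, X]``; a displacement field carries a leading
  component axis ``[3, Z, Y, X]`` ordered ``(dz, dy, dx)``.
* World coordinates are millimetres.  ``origin`` is the world position of the
  grid *corner*; the centre of voxel ``(0, 0, 0)`` sits at
  ``origin + spacing / 2``.  The rotation axis of the scanner is the world
  z-axis through ``(x, y) = (0, 0)``, so the default origin centres the
  volume on the axis.
* Displacement fields follow the pull-back convention:
  ``warp(I, v)(x) = I(x + v(x))``.  The field tagged ``0->t`` therefore
  produces the phase-t image when applied to the phase-0 image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume", "DVF"]


def _default_origin(shape, spacing) -> np.ndarray:
    return -(np.asarray(shape, dtype=float) * np.asarray(spacing, dtype=float)) / 2.0


@dataclass
class Volume:
    """A 3-D attenuation grid (mm^-1) with voxel spacing and origin in mm.

    Parameters
    ----------
    data : ndarray, shape (Z, Y, X)
        Attenuation coefficients in mm^-1.
    spacing : 3 floats, (sz, sy, sx) mm
    origin : 3 floats, (oz, oy, ox) mm — world position of the grid corner.
        Defaults to centring the grid on the rotation axis.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.ascontiguousarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got shape {self.data.shape}")
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 positive floats (sz, sy, sx)")
        if self.origin is None:
            self.origin = _default_origin(self.data.shape, self.spacing)
        self.origin = np.asarray(self.origin, dtype=np.float64)

    @property
    def shape(self):
        return self.data.shape

    def same_grid(self, other: "Volume | DVF") -> bool:
        return (
            tuple(self.shape) == tuple(other.grid_shape)
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    @property
    def grid_shape(self):
        return self.data.shape

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing.copy(), self.origin.copy())

    def like(self, data: np.ndarray) -> "Volume":
        """New volume on this grid holding ``data``."""
        return Volume(np.asarray(data, dtype=np.float64), self.spacing.copy(), self.origin.copy())

    def voxel_centers(self):
        """World coordinates (z, y, x) of all voxel centres, as three 1-D axes."""
        nz, ny, nx = self.shape
        z = self.origin[0] + (np.arange(nz) + 0.5) * self.spacing[0]
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.spacing[1]
        x = self.origin[2] + (np.arange(nx) + 0.5) * self.spacing[2]
        return z, y, x


@dataclass
class DVF:
    """Dense displacement field in mm on a volume grid.

    ``data`` has shape ``(3, Z, Y, X)`` with components ``(dz, dy, dx)``.
    ``direction`` tags the mapping the field realises under the pull-back
    convention: ``"0->t"`` deforms the phase-0 image into phase t.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]
    direction: str = "0->t"
    phase: int = 0

    def __post_init__(self):
        self.data = np.ascontiguousarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[0] != 3:
            raise ValueError(f"DVF data must be (3, Z, Y, X), got {self.data.shape}")
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        if self.origin is None:
            self.origin = _default_origin(self.data.shape[1:], self.spacing)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("DVF contains non-finite displacements")

    @property
    def grid_shape(self):
        return self.data.shape[1:]

    @classmethod
    def zeros(cls, grid_shape, spacing, origin=None, direction="0->t", phase=0) -> "DVF":
        return cls(
            np.zeros((3, *grid_shape), dtype=np.float64),
            np.asarray(spacing, dtype=np.float64),
            origin,
            direction,
            phase,
        )

    @classmethod
    def zeros_like(cls, vol: Volume, direction="0->t", phase=0) -> "DVF":
        return cls.zeros(vol.shape, vol.spacing, vol.origin.copy(), direction, phase)

    def copy(self) -> "DVF":
        return DVF(self.data.copy(), self.spacing.copy(), self.origin.copy(), self.direction, self.phase)

    def like(self, data: np.ndarray, direction=None) -> "DVF":
        return DVF(
            np.asarray(data, dtype=np.float64),
            self.spacing.copy(),
            self.origin.copy(),
            self.direction if direction is None else direction,
            self.phase,
        )

    def max_magnitude(self) -> float:
        return float(np.sqrt((self.data**2).sum(axis=0)).max())
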