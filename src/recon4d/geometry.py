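"""Cone-beam acquisition geometry and projection containers.

A circular full-fan trajectory with a flat-panel detector.  The source
rotates in the world (x, y) plane around the z axis; at gantry angle
``theta`` the source sits at ``(SAD cos θ, SAD sin θ, 0)`` and the detector
centre at ``((SAD−SDD) cos θ, (SAD−SDD) sin θ, 0)``.  Detector columns run
along ``û = (−sin θ, cos θ, 0)`` and rows along ``v̂ = (0, 0, 1)`` (world z).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConeBeamGeometry", "ProjectionSet", "phase_interleaved_angles"]


@dataclass
class ConeBeamGeometry:
    """Circular cone-beam geometry.

    Parameters
    ----------
    sad, sdd : float
        Source-to-axis and source-to-detector distances (mm); ``sdd > sad > 0``.
    det_rows, det_cols : int
        Flat-panel grid (rows index z, columns index the in-plane axis).
    det_pitch : float or (float, float)
        Detector pixel pitch in mm, (row, col) if a pair.
    """

    sad: float = 1000.0
    sdd: float = 1500.0
    det_rows: int = 240
    det_cols: int = 300
    det_pitch: tuple = (1.0, 1.0)

    def __post_init__(self):
        if np.isscalar(self.det_pitch):
            self.det_pitch = (float(self.det_pitch), float(self.det_pitch))
        self.det_pitch = (float(self.det_pitch[0]), float(self.det_pitch[1]))
        if not (self.sdd > self.sad > 0):
            raise ValueError("require SDD > SAD > 0")
        if self.det_rows < 1 or self.det_cols < 1:
            raise ValueError("detector grid must be at least 1x1")
        if min(self.det_pitch) <= 0:
            raise ValueError("detector pitch must be positive")

    def source_position(self, angle: float) -> np.ndarray:
        """World (x, y, z) of the source at gantry angle ``angle`` (rad)."""
        return np.array([self.sad * np.cos(angle), self.sad * np.sin(angle), 0.0])

    def detector_frame(self, angle: float):
        """(centre, û, v̂) of the flat panel at ``angle``; all world (x, y, z)."""
        c, s = np.cos(angle), np.sin(angle)
        center = np.array([(self.sad - self.sdd) * c, (self.sad - self.sdd) * s, 0.0])
        u_hat = np.array([-s, c, 0.0])
        v_hat = np.array([0.0, 0.0, 1.0])
        return center, u_hat, v_hat

    def pixel_position(self, row: int, col: int, angle: float) -> np.ndarray:
        center, u_hat, v_hat = self.detector_frame(angle)
        pv, pu = self.det_pitch
        return (
            center
            + (col - (self.det_cols - 1) / 2.0) * pu * u_hat
            + (row - (self.det_rows - 1) / 2.0) * pv * v_hat
        )


@dataclass
class ProjectionSet:
    """Log-transformed line integrals for one breathing phase.

    ``data`` has shape ``(n_views, rows, cols)`` (dimensionless line
    integrals, mm^-1 · mm); ``angles`` is the matching gantry-angle list in
    radians.
    """

    data: np.ndarray
    angles: np.ndarray
    phase: int = 0

    def __post_init__(self):
        self.data = np.ascontiguousarray(self.data, dtype=np.float64)
        self.angles = np.atleast_1d(np.asarray(self.angles, dtype=np.float64))
        if self.data.ndim != 3:
            raise ValueError("projection data must be (views, rows, cols)")
        if self.data.shape[0] != self.angles.shape[0]:
            raise ValueError(
                f"view count {self.data.shape[0]} != angle count {self.angles.shape[0]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("projections contain non-finite values")

    @property
    def n_views(self) -> int:
        return self.data.shape[0]

    def norm_sq(self) -> float:
        return float((self.data**2).sum())

    def copy(self) -> "ProjectionSet":
        return ProjectionSet(self.data.copy(), self.angles.copy(), self.phase)


def phase_interleaved_angles(n_phases: int, views_per_phase: int, start: float = 0.0):
    """Per-phase gantry angles emulating phase-sorted acquisition.

    The ``n_phases * views_per_phase`` views of a full rotation are dealt
    round-robin to the phases, so each phase sees ``views_per_phase`` angles
    roughly evenly spread over 360 degrees — the situation produced by phase
    binning a slow continuous scan.

    Returns a list of ``n_phases`` angle arrays (radians).
    """
    total = n_phases * views_per_phase
    all_angles = start + 2.0 * np.pi * np.arange(total) / total
    return [all_angles[t::n_phases].copy() for t in range(n_phases)]
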