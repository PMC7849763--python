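"""Cone-beam system model: exact ray-driven forward projection and adjoint.

The forward operator ``A`` maps attenuation (mm^-1) to line integrals
(dimensionless): ``p_i = sum_n a_in mu_n`` where ``a_in`` is the exact
intersection length (mm) of ray i with voxel n, from a Siddon-style
traversal.  ``back_project`` applies the transpose ``A^T`` with the same
weights, so the pair satisfies the adjoint identity ``<A x, y> = <x, A^T y>``
to round-off.
"""

from __future__ import annotations

import numpy as np

from . import _kernels as K
from .geometry import ConeBeamGeometry, ProjectionSet
from .grids import Volume

__all__ = ["trace_ray", "forward_project", "back_project", "add_projection_noise"]


def _geom_args(geometry: ConeBeamGeometry, angle: float):
    src = geometry.source_position(angle)
    center, u_hat, v_hat = geometry.detector_frame(angle)
    pv, pu = geometry.det_pitch
    return (
        src[0], src[1], src[2],
        center[0], center[1], center[2],
        u_hat[0], u_hat[1], u_hat[2],
        v_hat[0], v_hat[1], v_hat[2],
        pv, pu,
    )


def trace_ray(geometry: ConeBeamGeometry, volume: Volume, detector_pixel, angle: float):
    """Exact voxel/length decomposition of one source->pixel ray.

    Parameters
    ----------
    detector_pixel : (row, col)
    angle : gantry angle in radians.

    Returns
    -------
    list of ((iz, iy, ix), length_mm); empty if the ray misses the grid.
    """
    row, col = detector_pixel
    if not (0 <= row < geometry.det_rows and 0 <= col < geometry.det_cols):
        raise ValueError(f"detector pixel {detector_pixel} outside "
                         f"{geometry.det_rows}x{geometry.det_cols} panel")
    nz, ny, nx = volume.shape
    hz, hy, hx = volume.spacing
    oz, oy, ox = volume.origin
    src = geometry.source_position(angle)
    pix = geometry.pixel_position(row, col, angle)
    nbuf = nx + ny + nz + 4
    idx_buf = np.empty(nbuf, dtype=np.int64)
    len_buf = np.empty(nbuf, dtype=np.float64)
    m = K._trace_into(src[0], src[1], src[2], pix[0], pix[1], pix[2],
                      ox, oy, oz, hx, hy, hz, nx, ny, nz, idx_buf, len_buf)
    out = []
    for q in range(m):
        flat = idx_buf[q]
        iz, rem = divmod(flat, ny * nx)
        iy, ix = divmod(rem, nx)
        out.append(((int(iz), int(iy), int(ix)), float(len_buf[q])))
    return out


def forward_project(volume: Volume, geometry: ConeBeamGeometry, angles, phase: int = 0) -> ProjectionSet:
    """Forward-project ``volume`` at the given gantry angles (radians)."""
    angles = np.atleast_1d(np.asarray(angles, dtype=np.float64))
    nz, ny, nx = volume.shape
    hz, hy, hx = volume.spacing
    oz, oy, ox = volume.origin
    vol1d = np.ascontiguousarray(volume.data).ravel()
    out = np.zeros((angles.size, geometry.det_rows, geometry.det_cols))
    for w, ang in enumerate(angles):
        K._forward_view(vol1d, ox, oy, oz, hx, hy, hz, nx, ny, nz,
                        *_geom_args(geometry, ang), out[w])
    return ProjectionSet(out, angles, phase=phase)


def back_project(projections: ProjectionSet, geometry: ConeBeamGeometry, grid: Volume) -> Volume:
    """Adjoint ``A^T p`` on the grid described by ``grid`` (data ignored)."""
    if projections.data.shape[1:] != (geometry.det_rows, geometry.det_cols):
        raise ValueError("projection panel shape does not match geometry")
    nz, ny, nx = grid.shape
    hz, hy, hx = grid.spacing
    oz, oy, ox = grid.origin
    acc1d = np.zeros(nz * ny * nx)
    for w, ang in enumerate(projections.angles):
        K._backproject_view(acc1d, projections.data[w],
                            ox, oy, oz, hx, hy, hz, nx, ny, nz,
                            *_geom_args(geometry, ang))
    return grid.like(acc1d.reshape(nz, ny, nx))


def add_projection_noise(projections: ProjectionSet, sigma: float, rng: np.random.Generator) -> ProjectionSet:
    """Gaussian noise on the line integrals (Poisson-derived surrogate)."""
    noisy = projections.data + rng.normal(0.0, sigma, size=projections.data.shape)
    return ProjectionSet(noisy, projections.angles.copy(), projections.phase)
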