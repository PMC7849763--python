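"""Iterative reconstruction: SART, motion-compensated SART, TV initializer.

``sart_pass`` runs one pass of the Simultaneous Algebraic Reconstruction
Technique over a set of views: for each view the voxel update is

    mu_j += lambda * [ sum_i a_ij (p_i - (A mu)_i) / L_i ] / sum_i a_ij

with ``L_i`` the ray chord length (rays with zero chord are skipped, voxels
never hit are left unchanged).

``msart_reconstruct`` is the motion-compensated variant: a single phase-0
volume is updated by the projections of *every* phase.  Each phase-t
residual update is computed in the phase-t frame (against the current
phase-t estimate, the phase-0 volume warped forward) and mapped into the
phase-0 frame through the inverse DVF before being applied, so all phases'
rays sharpen one reference image.  With identity DVFs this degenerates
exactly to pooled SART.

``tv_reconstruct`` alternates SART passes with steepest-descent steps on
isotropic total variation (ASD-POCS style) for a noise/streak-suppressed
per-phase initial image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .geometry import ConeBeamGeometry, ProjectionSet
from .grids import DVF, Volume
from .motion import invert_dvf, warp_volume
from .projector import forward_project

__all__ = ["ReconConfig", "sart_pass", "sart_reconstruct", "msart_reconstruct",
           "tv_reconstruct", "projection_residual_norm"]


@dataclass
class ReconConfig:
    """Iteration controls shared by the SART family."""

    relaxation: float = 0.8        # lambda in (0, 1]
    relaxation_decay: float = 0.95  # per pass
    n_iterations: int = 10
    tv_weight: float = 0.0         # 0 disables the TV steps
    tv_steps: int = 10             # TV descent steps per SART pass
    nonneg: bool = True
    residual_tol: float = 0.0      # stop when the residual norm falls below
    shuffle_seed: int = 1234       # golden-angle-style view shuffle

    def __post_init__(self):
        if not (0.0 < self.relaxation <= 1.0):
            raise ValueError("relaxation must be in (0, 1]")
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")


def _view_order(n_views: int, seed: int) -> np.ndarray:
    """Deterministic shuffle spreading consecutive updates in angle."""
    rng = np.random.default_rng(seed)
    return rng.permutation(n_views)


def _sart_update_view(volume: Volume, p_view, angle, geometry, lam):
    nz, ny, nx = volume.shape
    hz, hy, hx = volume.spacing
    oz, oy, ox = volume.origin
    vol1d = volume.data.ravel()
    num = np.zeros(nz * ny * nx)
    den = np.zeros(nz * ny * nx)
    src = geometry.source_position(angle)
    center, u_hat, v_hat = geometry.detector_frame(angle)
    pv, pu = geometry.det_pitch
    K._sart_view(vol1d, p_view, ox, oy, oz, hx, hy, hz, nx, ny, nz,
                 src[0], src[1], src[2], center[0], center[1], center[2],
                 u_hat[0], u_hat[1], u_hat[2], v_hat[0], v_hat[1], v_hat[2],
                 pv, pu, num, den)
    upd = np.zeros_like(num)
    hit = den > 0
    upd[hit] = lam * num[hit] / den[hit]
    return upd.reshape(nz, ny, nx)


def sart_pass(volume: Volume, projections: ProjectionSet,
              geometry: ConeBeamGeometry, config: ReconConfig,
              relaxation: float | None = None) -> Volume:
    """One SART pass (every view once, shuffled deterministically)."""
    lam = config.relaxation if relaxation is None else relaxation
    out = volume.copy()
    for w in _view_order(projections.n_views, config.shuffle_seed):
        upd = _sart_update_view(out, projections.data[w], projections.angles[w],
                                geometry, lam)
        out.data += upd
        if config.nonneg:
            np.maximum(out.data, 0.0, out=out.data)
    return out


def projection_residual_norm(volume: Volume, projections: ProjectionSet,
                             geometry: ConeBeamGeometry) -> float:
    sim = forward_project(volume, geometry, projections.angles)
    return float(np.linalg.norm(sim.data - projections.data))


def sart_reconstruct(projections: ProjectionSet, geometry: ConeBeamGeometry,
                     config: ReconConfig, grid: Volume,
                     initial: Volume | None = None) -> Volume:
    """Multi-pass SART from (by default) a zero volume on ``grid``."""
    vol = grid.like(np.zeros(grid.shape)) if initial is None else initial.copy()
    lam = config.relaxation
    for _ in range(config.n_iterations):
        vol = sart_pass(vol, projections, geometry, config, relaxation=lam)
        lam *= config.relaxation_decay
        if config.residual_tol > 0 and \
                projection_residual_norm(vol, projections, geometry) < config.residual_tol:
            break
    return vol


def msart_reconstruct(all_projections: list, inverse_dvfs: list,
                      geometry: ConeBeamGeometry, config: ReconConfig,
                      grid: Volume, forward_dvfs: list | None = None,
                      initial: Volume | None = None) -> Volume:
    """Motion-compensated SART: reconstruct phase 0 from all phases.

    Parameters
    ----------
    all_projections : list of ProjectionSet, one per phase (phase 0 first).
    inverse_dvfs : list of DVF or None, the t->0 fields mapping each phase-t
        update into the phase-0 frame; ``None`` means identity (mandatory
        meaning for phase 0).
    forward_dvfs : optional matching 0->t fields used to form the phase-t
        estimate; inverted from ``inverse_dvfs`` when omitted.
    """
    n_phases = len(all_projections)
    if len(inverse_dvfs) != n_phases:
        raise ValueError("need one inverse DVF (or None) per phase")
    if forward_dvfs is None:
        forward_dvfs = [None if d is None else invert_dvf(d) for d in inverse_dvfs]

    vol0 = grid.like(np.zeros(grid.shape)) if initial is None else initial.copy()
    lam = config.relaxation
    # deterministic interleaving of (phase, view) updates
    pairs = [(t, w) for t in range(n_phases)
             for w in range(all_projections[t].n_views)]
    order = _view_order(len(pairs), config.shuffle_seed)

    for _ in range(config.n_iterations):
        for q in order:
            t, w = pairs[q]
            fwd, inv = forward_dvfs[t], inverse_dvfs[t]
            mu_t = vol0 if fwd is None else warp_volume(vol0, fwd)
            upd_t = _sart_update_view(mu_t, all_projections[t].data[w],
                                      all_projections[t].angles[w],
                                      geometry, lam)
            if inv is None:
                upd_0 = upd_t
            else:
                upd_0 = warp_volume(grid.like(upd_t), inv).data
            vol0.data += upd_0
            if config.nonneg:
                np.maximum(vol0.data, 0.0, out=vol0.data)
        lam *= config.relaxation_decay
    return vol0


# ---------------------------------------------------------------------------
# TV-regularized initializer (ASD-POCS style)
# ---------------------------------------------------------------------------

def _tv_value_grad(data, eps=1e-8):
    g = np.zeros_like(data)
    tv = 0.0
    grads = []
    for ax in range(3):
        d = np.diff(data, axis=ax)
        grads.append(d)
    mag = np.zeros_like(data)
    for ax, d in enumerate(grads):
        pad = [(0, 0)] * 3
        pad[ax] = (0, 1)
        mag += np.pad(d, pad) ** 2
    mag = np.sqrt(mag + eps)
    tv = float(mag.sum())
    for ax, d in enumerate(grads):
        pad = [(0, 0)] * 3
        pad[ax] = (0, 1)
        dn = np.pad(d, pad) / mag
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(None, None)
        g -= dn
        shift = np.zeros_like(dn)
        hi[ax] = slice(1, None)
        lo[ax] = slice(None, -1)
        shift[tuple(hi)] = dn[tuple(lo)]
        g += shift
    return tv, g


def tv_reconstruct(projections: ProjectionSet, geometry: ConeBeamGeometry,
                   config: ReconConfig, grid: Volume,
                   initial: Volume | None = None) -> Volume:
    """SART passes interleaved with TV steepest-descent steps.

    With ``tv_weight == 0`` this is byte-for-byte plain SART.  The TV step
    length is tied to the magnitude of the preceding SART update
    (ASD-POCS practice) and shrinks geometrically over the descent steps.
    """
    vol = grid.like(np.zeros(grid.shape)) if initial is None else initial.copy()
    lam = config.relaxation
    for _ in range(config.n_iterations):
        before = vol.data.copy()
        vol = sart_pass(vol, projections, geometry, config, relaxation=lam)
        lam *= config.relaxation_decay
        if config.tv_weight > 0 and config.tv_steps > 0:
            dstep = config.tv_weight * float(np.abs(vol.data - before).max())
            for _s in range(config.tv_steps):
                _, g = _tv_value_grad(vol.data)
                gn = float(np.linalg.norm(g))
                if gn <= 0 or dstep <= 0:
                    break
                vol.data -= dstep * g / (np.abs(g).max() + 1e-30)
                dstep *= 0.8
                if config.nonneg:
                    np.maximum(vol.data, 0.0, out=vol.data)
    return vol
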