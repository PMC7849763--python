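"""Classic additive Demons registration for the initial 4D-DVFs.

Thirion-style intensity-driven non-rigid registration: per iteration the
update force at every voxel is

    f = (m_w - F) * grad(F) / ( |grad F|^2 + alpha^2 (m_w - F)^2 )

with ``F`` the fixed image, ``m_w`` the warped moving image and ``alpha``
an intensity-scale normalizer that bounds the step.  The update field is
Gaussian-smoothed (fluid-like regularization), added to the displacement
field, and the total field is Gaussian-smoothed again (diffusion-like
regularization).  A coarse-to-fine pyramid accelerates convergence for the
multi-centimetre breathing displacements.

The result seeds the projection-matching DVF optimizer; it does not need to
be sliding-aware itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import DVF, Volume
from .motion import warp_volume

__all__ = ["DemonsConfig", "demons_register"]


@dataclass
class DemonsConfig:
    levels: int = 3                     # pyramid ×4, ×2, ×1
    iterations: tuple = (80, 80, 50)    # per level, coarse to fine
    sigma_fluid_mm: float = 1.5         # update-field Gaussian
    sigma_diffusion_mm: float = 1.0     # displacement-field Gaussian
    max_step_mm: float = 2.0            # per-iteration step clamp
    intensity_scale: float = 0.05       # alpha, fraction of intensity range

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("need at least one pyramid level")
        if len(self.iterations) < self.levels:
            raise ValueError("need an iteration count per level")
        if self.sigma_fluid_mm < 0 or self.sigma_diffusion_mm < 0:
            raise ValueError("smoothing sigmas must be >= 0")


def _downsample(data, factor):
    if factor == 1:
        return data
    sl = tuple(slice(None, None, factor) for _ in range(3))
    return ndimage.uniform_filter(data, size=factor, mode="nearest")[sl]


def _upsample_field(field, target_shape):
    out = np.empty((3, *target_shape))
    for c in range(3):
        zoom = [t / s for t, s in zip(target_shape, field.shape[1:])]
        out[c] = ndimage.zoom(field[c], zoom, order=1, mode="nearest",
                              grid_mode=True)
    return out


def _smooth_field(field, sigma_mm, spacing):
    if sigma_mm <= 0:
        return field
    # never drop below ~0.8 voxel of smoothing: on coarse pyramid levels the
    # physical sigma must not vanish relative to the (large) voxel
    sig = [max(sigma_mm / h, 0.8) for h in spacing]
    for c in range(3):
        ndimage.gaussian_filter(field[c], sigma=sig, output=field[c],
                                mode="nearest")
    return field


def demons_register(fixed: Volume, moving: Volume, config: DemonsConfig = None) -> DVF:
    """Displacement field (mm, pull-back) such that ``warp(moving, field)``
    approximates ``fixed``.  Identical inputs yield an exactly zero field."""
    if config is None:
        config = DemonsConfig()
    if fixed.shape != moving.shape:
        raise ValueError(f"grid mismatch: {fixed.shape} vs {moving.shape}")
    if np.array_equal(fixed.data, moving.data):
        return DVF.zeros_like(fixed)

    rng_int = float(fixed.data.max() - fixed.data.min())
    alpha2 = (config.intensity_scale * rng_int) ** 2 + 1e-30

    # skip pyramid levels that would leave fewer than ~8 voxels per axis
    usable = [lev for lev in range(config.levels)
              if min(fixed.shape) // (2 ** lev) >= 8]
    field = None
    for lev in sorted(usable, reverse=True):
        factor = 2 ** lev
        f_data = _downsample(fixed.data, factor)
        m_data = _downsample(moving.data, factor)
        spacing = fixed.spacing * factor
        f_vol = Volume(f_data, spacing)
        m_vol = Volume(m_data, spacing)

        if field is None:
            field = np.zeros((3, *f_data.shape))
        else:
            field = _upsample_field(field, f_data.shape)

        grad_f = np.stack([
            np.gradient(f_data, spacing[ax], axis=ax) for ax in range(3)
        ])
        grad_sq = (grad_f**2).sum(axis=0)

        n_iter = config.iterations[config.levels - 1 - lev]
        for _ in range(n_iter):
            dvf = DVF(field, spacing)
            m_w = warp_volume(m_vol, dvf).data
            diff = m_w - f_vol.data
            denom = grad_sq + alpha2 + diff**2 / (spacing.min() ** 2)
            upd = -diff * grad_f / denom
            mag = np.sqrt((upd**2).sum(axis=0))
            big = mag > config.max_step_mm
            if big.any():
                scale = np.ones_like(mag)
                scale[big] = config.max_step_mm / mag[big]
                upd *= scale
            upd = _smooth_field(upd, config.sigma_fluid_mm, spacing)
            field = field + upd
            field = _smooth_field(field, config.sigma_diffusion_mm, spacing)

    out = DVF(field, fixed.spacing.copy(), fixed.origin.copy())
    if out.grid_shape != fixed.shape:
        out = DVF(_upsample_field(field, fixed.shape), fixed.spacing.copy(),
                  fixed.origin.copy())
    return out
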