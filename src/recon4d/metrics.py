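"""Evaluation criteria: trajectory RMSE/MaxE, Dice overlap, relative error,
and threshold-based feature-trajectory extraction.

Trajectory accuracy over the nine non-reference phases (10%-90%) uses

    RMSE = (1/3) * sqrt( sum_{ph=1..9} (Pos_ph^R - Pos_ph^T)^2 )

which is exactly the root of the 9-phase mean square (1/3 = 1/sqrt(9));
MaxE is the largest absolute per-phase error.

The relative reconstruction error is reported in the root form

    RE = sqrt( sum (u_R - u_T)^2 / sum u_T^2 ) * 100%

with the literal no-root ratio available via ``root=False``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grids import Volume

__all__ = [
    "trajectory_rmse_maxe",
    "dice",
    "relative_error",
    "extract_trajectory",
    "segment_lung",
]


def trajectory_rmse_maxe(recon, truth):
    """RMSE and MaxE (mm) between two 9-entry trajectories (phases 10%-90%).

    Raises if the lengths differ or either trajectory has missing entries.
    """
    recon = np.asarray(recon, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if recon.shape != truth.shape:
        raise ValueError(f"trajectory length mismatch: {recon.shape} vs {truth.shape}")
    if not (np.all(np.isfinite(recon)) and np.all(np.isfinite(truth))):
        raise ValueError("trajectory contains missing values")
    err = recon - truth
    n = err.size
    rmse = float(np.sqrt((err**2).sum() / n))
    return rmse, float(np.abs(err).max())


def dice(mask_a, mask_b) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two binary masks on one grid.

    Both-empty returns 1.0 (perfect agreement convention).
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def relative_error(recon: Volume, truth: Volume, roi=None, root: bool = True) -> float:
    """Relative reconstruction error in percent.

    ``roi`` (boolean mask) restricts both sums.  ``root=True`` (default)
    returns the root form; ``root=False`` the literal squared ratio.
    """
    r = recon.data if isinstance(recon, Volume) else np.asarray(recon)
    t = truth.data if isinstance(truth, Volume) else np.asarray(truth)
    if r.shape != t.shape:
        raise ValueError(f"volume grids differ: {r.shape} vs {t.shape}")
    if roi is not None:
        roi = np.asarray(roi).astype(bool)
        r = r[roi]
        t = t[roi]
    denom = float((t**2).sum())
    if denom <= 0:
        raise ValueError("ground truth has zero norm in the ROI")
    ratio = float(((r - t) ** 2).sum()) / denom
    return 100.0 * (np.sqrt(ratio) if root else ratio)


def extract_trajectory(volumes, roi, threshold: float, axis: str = "z",
                       mode: str = "max", subvoxel: bool = False):
    """Threshold-based feature trajectory from a 4-D set of volumes.

    Per phase the ROI is binarized at the uniform ``threshold`` and the
    feature edge located as the extreme foreground coordinate along
    ``axis`` (``mode`` 'max' or 'min'), converted to the world coordinate
    (mm) of that voxel centre.  With ``subvoxel=True`` the edge is refined
    by linear interpolation of the threshold crossing along the extreme
    voxel's profile, giving a continuous position.

    Parameters
    ----------
    volumes : sequence of Volume
    roi : ((z0, z1), (y0, y1), (x0, x1)) half-open voxel index box.

    Returns
    -------
    positions : list of float (mm); np.nan flags an empty foreground.
    """
    ax_idx = {"z": 0, "y": 1, "x": 2}[axis]
    (z0, z1), (y0, y1), (x0, x1) = roi
    out = []
    for vol in volumes:
        nz, ny, nx = vol.shape
        if not (0 <= z0 < z1 <= nz and 0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
            raise ValueError(f"ROI {roi} outside grid {vol.shape}")
        sub = vol.data[z0:z1, y0:y1, x0:x1]
        fg = sub >= threshold
        if not fg.any():
            out.append(np.nan)
            continue
        sign = 1 if mode == "max" else -1
        coords = np.nonzero(fg)
        ext = coords[ax_idx].max() if mode == "max" else coords[ax_idx].min()
        pos = float(ext)
        if subvoxel:
            # among the columns whose extreme foreground voxel is `ext`,
            # take the furthest interpolated threshold crossing toward the
            # neighbouring background voxel
            sel = coords[ax_idx] == ext
            best = None
            for q in range(sel.sum()):
                idxs = [c[sel][q] for c in coords]
                nb = list(idxs)
                nb[ax_idx] += sign
                if not (0 <= nb[ax_idx] < sub.shape[ax_idx]):
                    frac = 0.0
                else:
                    a = sub[tuple(idxs)]
                    b = sub[tuple(nb)]
                    frac = (a - threshold) / (a - b) if a != b else 0.0
                    frac = float(np.clip(frac, 0.0, 1.0))
                if best is None or frac > best:
                    best = frac
            pos = float(ext) + sign * best
        idx = pos + (z0, y0, x0)[ax_idx]
        out.append(float(vol.origin[ax_idx] + (idx + 0.5) * vol.spacing[ax_idx]))
    return out


def segment_lung(volume: Volume, lung_value: float, body_value: float,
                 min_fraction: float = 0.25) -> np.ndarray:
    """Automatic lung mask for Dice scoring of reconstructions.

    Thresholds at the midpoint between lung and soft-tissue attenuation,
    restricts to the hole-filled body, fills internal holes (vessels,
    tumor) and keeps every connected component at least ``min_fraction`` of
    the largest — both lungs are disjoint components.
    """
    mid = 0.5 * (lung_value + body_value)
    body = ndimage.binary_fill_holes(volume.data > mid)
    cand = body & (volume.data <= mid)
    cand = ndimage.binary_fill_holes(cand)
    labels, n = ndimage.label(cand)
    if n == 0:
        return np.zeros(volume.shape, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_fraction * sizes.max()) + 1
    return np.isin(labels, keep)
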