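"""Numba kernels: Siddon ray traversal, trilinear warping, bilateral sums.

Everything here works on plain ndarrays and scalars so the kernels stay
cacheable; the object-level API lives in :mod:`recon4d.projector` and
:mod:`recon4d.motion`.

Ray/grid conventions: the volume is a box with corner ``(ox, oy, oz)`` and
voxel size ``(hx, hy, hz)``; voxel intervals are half-open ``[low, high)``
so a ray grazing a shared face is attributed to exactly one voxel.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Siddon-style exact ray traversal
# ---------------------------------------------------------------------------

@njit(cache=True)
def _trace_into(sx, sy, sz, px, py, pz,
                ox, oy, oz, hx, hy, hz, nx, ny, nz,
                idx_buf, len_buf):
    """Voxel/length decomposition of the segment source->pixel clipped to the
    grid.  Fills ``idx_buf`` (flat C-order voxel indices) and ``len_buf``
    (intersection lengths, mm); returns the number of entries."""
    dx = px - sx
    dy = py - sy
    dz = pz - sz
    seg = np.sqrt(dx * dx + dy * dy + dz * dz)
    if seg <= 0.0:
        return 0

    tmin = 0.0
    tmax = 1.0
    # slab clipping, half-open boxes
    x0 = ox
    x1 = ox + nx * hx
    if dx != 0.0:
        ta = (x0 - sx) / dx
        tb = (x1 - sx) / dx
        if ta > tb:
            ta, tb = tb, ta
        if ta > tmin:
            tmin = ta
        if tb < tmax:
            tmax = tb
    elif not (x0 <= sx < x1):
        return 0
    y0 = oy
    y1 = oy + ny * hy
    if dy != 0.0:
        ta = (y0 - sy) / dy
        tb = (y1 - sy) / dy
        if ta > tb:
            ta, tb = tb, ta
        if ta > tmin:
            tmin = ta
        if tb < tmax:
            tmax = tb
    elif not (y0 <= sy < y1):
        return 0
    z0 = oz
    z1 = oz + nz * hz
    if dz != 0.0:
        ta = (z0 - sz) / dz
        tb = (z1 - sz) / dz
        if ta > tb:
            ta, tb = tb, ta
        if ta > tmin:
            tmin = ta
        if tb < tmax:
            tmax = tb
    elif not (z0 <= sz < z1):
        return 0

    if tmin >= tmax:
        return 0

    # entry voxel
    ex = sx + tmin * dx
    ey = sy + tmin * dy
    ez = sz + tmin * dz
    ix = int(np.floor((ex - ox) / hx))
    iy = int(np.floor((ey - oy) / hy))
    iz = int(np.floor((ez - oz) / hz))
    if ix < 0:
        ix = 0
    if ix > nx - 1:
        ix = nx - 1
    if iy < 0:
        iy = 0
    if iy > ny - 1:
        iy = ny - 1
    if iz < 0:
        iz = 0
    if iz > nz - 1:
        iz = nz - 1

    big = 1e300
    if dx > 0.0:
        step_x = 1
        t_max_x = (ox + (ix + 1) * hx - sx) / dx
        t_del_x = hx / dx
    elif dx < 0.0:
        step_x = -1
        t_max_x = (ox + ix * hx - sx) / dx
        t_del_x = -hx / dx
    else:
        step_x = 0
        t_max_x = big
        t_del_x = big
    if dy > 0.0:
        step_y = 1
        t_max_y = (oy + (iy + 1) * hy - sy) / dy
        t_del_y = hy / dy
    elif dy < 0.0:
        step_y = -1
        t_max_y = (oy + iy * hy - sy) / dy
        t_del_y = -hy / dy
    else:
        step_y = 0
        t_max_y = big
        t_del_y = big
    if dz > 0.0:
        step_z = 1
        t_max_z = (oz + (iz + 1) * hz - sz) / dz
        t_del_z = hz / dz
    elif dz < 0.0:
        step_z = -1
        t_max_z = (oz + iz * hz - sz) / dz
        t_del_z = -hz / dz
    else:
        step_z = 0
        t_max_z = big
        t_del_z = big

    t = tmin
    n = 0
    tol = _EPS * (1.0 + abs(tmax))
    while t < tmax - tol:
        t_next = t_max_x
        if t_max_y < t_next:
            t_next = t_max_y
        if t_max_z < t_next:
            t_next = t_max_z
        if t_next > tmax:
            t_next = tmax
        if t_next > t:
            idx_buf[n] = (iz * ny + iy) * nx + ix
            len_buf[n] = (t_next - t) * seg
            n += 1
        # advance every axis whose boundary we just hit (ties advance both)
        advanced = False
        if t_max_x <= t_next + tol and step_x != 0:
            ix += step_x
            t_max_x += t_del_x
            advanced = True
            if ix < 0 or ix >= nx:
                break
        if t_max_y <= t_next + tol and step_y != 0:
            iy += step_y
            t_max_y += t_del_y
            advanced = True
            if iy < 0 or iy >= ny:
                break
        if t_max_z <= t_next + tol and step_z != 0:
            iz += step_z
            t_max_z += t_del_z
            advanced = True
            if iz < 0 or iz >= nz:
                break
        if not advanced:
            break
        t = t_next
    return n


@njit(cache=True)
def _forward_view(vol1d, ox, oy, oz, hx, hy, hz, nx, ny, nz,
                  sx, sy, sz, cx, cy, cz, ux, uy, uz, vx, vy, vz,
                  pitch_v, pitch_u, out_view):
    rows, cols = out_view.shape
    nbuf = nx + ny + nz + 4
    idx_buf = np.empty(nbuf, dtype=np.int64)
    len_buf = np.empty(nbuf, dtype=np.float64)
    rc = (rows - 1) / 2.0
    cc = (cols - 1) / 2.0
    for r in range(rows):
        for c in range(cols):
            au = (c - cc) * pitch_u
            av = (r - rc) * pitch_v
            px = cx + au * ux + av * vx
            py = cy + au * uy + av * vy
            pz = cz + au * uz + av * vz
            m = _trace_into(sx, sy, sz, px, py, pz,
                            ox, oy, oz, hx, hy, hz, nx, ny, nz,
                            idx_buf, len_buf)
            acc = 0.0
            for q in range(m):
                acc += len_buf[q] * vol1d[idx_buf[q]]
            out_view[r, c] = acc


@njit(cache=True)
def _backproject_view(acc1d, view, ox, oy, oz, hx, hy, hz, nx, ny, nz,
                      sx, sy, sz, cx, cy, cz, ux, uy, uz, vx, vy, vz,
                      pitch_v, pitch_u):
    rows, cols = view.shape
    nbuf = nx + ny + nz + 4
    idx_buf = np.empty(nbuf, dtype=np.int64)
    len_buf = np.empty(nbuf, dtype=np.float64)
    rc = (rows - 1) / 2.0
    cc = (cols - 1) / 2.0
    for r in range(rows):
        for c in range(cols):
            val = view[r, c]
            if val == 0.0:
                continue
            au = (c - cc) * pitch_u
            av = (r - rc) * pitch_v
            px = cx + au * ux + av * vx
            py = cy + au * uy + av * vy
            pz = cz + au * uz + av * vz
            m = _trace_into(sx, sy, sz, px, py, pz,
                            ox, oy, oz, hx, hy, hz, nx, ny, nz,
                            idx_buf, len_buf)
            for q in range(m):
                acc1d[idx_buf[q]] += len_buf[q] * val


@njit(cache=True)
def _sart_view(vol1d, p_view, ox, oy, oz, hx, hy, hz, nx, ny, nz,
               sx, sy, sz, cx, cy, cz, ux, uy, uz, vx, vy, vz,
               pitch_v, pitch_u, num1d, den1d):
    """Accumulate the SART numerator sum_i a_in (p_i - A mu)_i / L_i and the
    denominator sum_i a_in for one view.  Rays with zero chord are skipped."""
    rows, cols = p_view.shape
    nbuf = nx + ny + nz + 4
    idx_buf = np.empty(nbuf, dtype=np.int64)
    len_buf = np.empty(nbuf, dtype=np.float64)
    rc = (rows - 1) / 2.0
    cc = (cols - 1) / 2.0
    for r in range(rows):
        for c in range(cols):
            au = (c - cc) * pitch_u
            av = (r - rc) * pitch_v
            px = cx + au * ux + av * vx
            py = cy + au * uy + av * vy
            pz = cz + au * uz + av * vz
            m = _trace_into(sx, sy, sz, px, py, pz,
                            ox, oy, oz, hx, hy, hz, nx, ny, nz,
                            idx_buf, len_buf)
            if m == 0:
                continue
            chord = 0.0
            line = 0.0
            for q in range(m):
                chord += len_buf[q]
                line += len_buf[q] * vol1d[idx_buf[q]]
            if chord <= _EPS:
                continue
            resid = (p_view[r, c] - line) / chord
            for q in range(m):
                num1d[idx_buf[q]] += len_buf[q] * resid
                den1d[idx_buf[q]] += len_buf[q]


# ---------------------------------------------------------------------------
# Trilinear warping (pull-back) and its displacement derivative
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sample_prep(p, n):
    """Clamp a fractional index to the grid and snap near-lattice points."""
    if p < 0.0:
        p = 0.0
    elif p > n - 1.0:
        p = n - 1.0
    r = np.rint(p)
    if abs(p - r) < 1e-9:
        p = r
    i0 = int(np.floor(p))
    if i0 > n - 2:
        i0 = n - 2
    if i0 < 0:
        i0 = 0
    f = p - i0
    return i0, f


@njit(cache=True)
def _warp_kernel(vol, dvf, hz, hy, hx, out):
    nz, ny, nx = vol.shape
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                pz = k + dvf[0, k, j, i] / hz
                py = j + dvf[1, k, j, i] / hy
                px = i + dvf[2, k, j, i] / hx
                k0, fz = _sample_prep(pz, nz)
                j0, fy = _sample_prep(py, ny)
                i0, fx = _sample_prep(px, nx)
                c000 = vol[k0, j0, i0]
                c001 = vol[k0, j0, i0 + 1]
                c010 = vol[k0, j0 + 1, i0]
                c011 = vol[k0, j0 + 1, i0 + 1]
                c100 = vol[k0 + 1, j0, i0]
                c101 = vol[k0 + 1, j0, i0 + 1]
                c110 = vol[k0 + 1, j0 + 1, i0]
                c111 = vol[k0 + 1, j0 + 1, i0 + 1]
                c00 = c000 * (1 - fx) + c001 * fx
                c01 = c010 * (1 - fx) + c011 * fx
                c10 = c100 * (1 - fx) + c101 * fx
                c11 = c110 * (1 - fx) + c111 * fx
                c0 = c00 * (1 - fy) + c01 * fy
                c1 = c10 * (1 - fy) + c11 * fy
                out[k, j, i] = c0 * (1 - fz) + c1 * fz


@njit(cache=True)
def _warp_gradient_kernel(vol, dvf, hz, hy, hx, out3):
    """d(warped value)/d(displacement component in mm): the exact gradient of
    the trilinear interpolant, zero where the sample is clamped outside."""
    nz, ny, nx = vol.shape
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                pz = k + dvf[0, k, j, i] / hz
                py = j + dvf[1, k, j, i] / hy
                px = i + dvf[2, k, j, i] / hx
                in_z = 0.0 <= pz <= nz - 1.0
                in_y = 0.0 <= py <= ny - 1.0
                in_x = 0.0 <= px <= nx - 1.0
                k0, fz = _sample_prep(pz, nz)
                j0, fy = _sample_prep(py, ny)
                i0, fx = _sample_prep(px, nx)
                c000 = vol[k0, j0, i0]
                c001 = vol[k0, j0, i0 + 1]
                c010 = vol[k0, j0 + 1, i0]
                c011 = vol[k0, j0 + 1, i0 + 1]
                c100 = vol[k0 + 1, j0, i0]
                c101 = vol[k0 + 1, j0, i0 + 1]
                c110 = vol[k0 + 1, j0 + 1, i0]
                c111 = vol[k0 + 1, j0 + 1, i0 + 1]
                # d/dfz
                gz = ((c100 - c000) * (1 - fy) * (1 - fx)
                      + (c101 - c001) * (1 - fy) * fx
                      + (c110 - c010) * fy * (1 - fx)
                      + (c111 - c011) * fy * fx)
                gy = ((c010 - c000) * (1 - fz) * (1 - fx)
                      + (c011 - c001) * (1 - fz) * fx
                      + (c110 - c100) * fz * (1 - fx)
                      + (c111 - c101) * fz * fx)
                gx = ((c001 - c000) * (1 - fz) * (1 - fy)
                      + (c011 - c010) * (1 - fz) * fy
                      + (c101 - c100) * fz * (1 - fy)
                      + (c111 - c110) * fz * fy)
                out3[0, k, j, i] = gz / hz if in_z else 0.0
                out3[1, k, j, i] = gy / hy if in_y else 0.0
                out3[2, k, j, i] = gx / hx if in_x else 0.0


@njit(cache=True)
def _warp_vec_kernel(field, dvf, hz, hy, hx, out):
    """Sample all three components of ``field`` at x + dvf(x) in one pass
    (same sampling rule as ``_warp_kernel``, shared weights)."""
    nz, ny, nx = field.shape[1:]
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                pz = k + dvf[0, k, j, i] / hz
                py = j + dvf[1, k, j, i] / hy
                px = i + dvf[2, k, j, i] / hx
                k0, fz = _sample_prep(pz, nz)
                j0, fy = _sample_prep(py, ny)
                i0, fx = _sample_prep(px, nx)
                for c in range(3):
                    c000 = field[c, k0, j0, i0]
                    c001 = field[c, k0, j0, i0 + 1]
                    c010 = field[c, k0, j0 + 1, i0]
                    c011 = field[c, k0, j0 + 1, i0 + 1]
                    c100 = field[c, k0 + 1, j0, i0]
                    c101 = field[c, k0 + 1, j0, i0 + 1]
                    c110 = field[c, k0 + 1, j0 + 1, i0]
                    c111 = field[c, k0 + 1, j0 + 1, i0 + 1]
                    c00 = c000 * (1 - fx) + c001 * fx
                    c01 = c010 * (1 - fx) + c011 * fx
                    c10 = c100 * (1 - fx) + c101 * fx
                    c11 = c110 * (1 - fx) + c111 * fx
                    c0 = c00 * (1 - fy) + c01 * fy
                    c1 = c10 * (1 - fy) + c11 * fy
                    out[c, k, j, i] = c0 * (1 - fz) + c1 * fz


# ---------------------------------------------------------------------------
# Bilateral-filtering DVF regularizer (value and analytic gradient)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _spatial_weight_sum(hz, hy, hx, hw, sx2, nz, ny, nx, out):
    """Per-voxel sum of the spatial kernel over the (2hw+1)^3-1 neighbourhood
    (used by the normalized-kernel variant)."""
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                acc = 0.0
                for dk in range(-hw, hw + 1):
                    k2 = k + dk
                    if k2 < 0 or k2 >= nz:
                        continue
                    for dj in range(-hw, hw + 1):
                        j2 = j + dj
                        if j2 < 0 or j2 >= ny:
                            continue
                        for di in range(-hw, hw + 1):
                            if dk == 0 and dj == 0 and di == 0:
                                continue
                            i2 = i + di
                            if i2 < 0 or i2 >= nx:
                                continue
                            d2 = (dk * hz) ** 2 + (dj * hy) ** 2 + (di * hx) ** 2
                            acc += np.exp(-d2 / (2.0 * sx2))
                out[k, j, i] = acc


@njit(cache=True, fastmath=True)
def _bilateral_phi_kernel(v, mu, offs, d2s, gxs, smu2, sv2, wnorm):
    """phi = sum over voxels x, neighbours y, components c of
    Gx * Gmu * Gv * ((v_c(x)-v_c(y)) / |x-y|)^2.

    ``offs``/``d2s``/``gxs`` enumerate one half of the symmetric
    neighbourhood (each unordered pair once; the double count of the full
    sum is restored through the per-pair weight).  ``wnorm`` holds the
    per-voxel spatial normalizer (ones for the unnormalized form, where the
    pair weight is simply 2 Gx Gmu)."""
    nz, ny, nx = mu.shape
    n_off = offs.shape[0]
    phi = 0.0
    for q in range(n_off):
        dk, dj, di = offs[q, 0], offs[q, 1], offs[q, 2]
        inv_d2 = 1.0 / d2s[q]
        gx = gxs[q]
        for k in range(max(0, -dk), min(nz, nz - dk)):
            k2 = k + dk
            for j in range(max(0, -dj), min(ny, ny - dj)):
                j2 = j + dj
                for i in range(max(0, -di), min(nx, nx - di)):
                    i2 = i + di
                    dmu = mu[k, j, i] - mu[k2, j2, i2]
                    gmu = np.exp(-dmu * dmu / (2.0 * smu2))
                    w = gx * gmu * (1.0 / wnorm[k, j, i] + 1.0 / wnorm[k2, j2, i2])
                    acc = 0.0
                    for c in range(3):
                        dv = v[c, k, j, i] - v[c, k2, j2, i2]
                        acc += np.exp(-dv * dv / (2.0 * sv2)) * dv * dv
                    phi += w * acc * inv_d2
    return phi


@njit(cache=True, fastmath=True)
def _bilateral_grad_kernel(v, mu, offs, d2s, gxs, smu2, sv2, wnorm, out):
    """Analytic gradient of ``_bilateral_phi_kernel`` w.r.t. every v_c(x).

    Per unordered pair (x, y) the derivative has a weighted-difference term
    and a Gv kernel-derivative term,
    g = w * Gv * (2 dv - dv^3 / sv^2) / d^2, added at x and subtracted at y
    (both orderings of the pair contribute equally)."""
    nz, ny, nx = mu.shape
    n_off = offs.shape[0]
    out[...] = 0.0
    for q in range(n_off):
        dk, dj, di = offs[q, 0], offs[q, 1], offs[q, 2]
        inv_d2 = 1.0 / d2s[q]
        gx = gxs[q]
        for k in range(max(0, -dk), min(nz, nz - dk)):
            k2 = k + dk
            for j in range(max(0, -dj), min(ny, ny - dj)):
                j2 = j + dj
                for i in range(max(0, -di), min(nx, nx - di)):
                    i2 = i + di
                    dmu = mu[k, j, i] - mu[k2, j2, i2]
                    gmu = np.exp(-dmu * dmu / (2.0 * smu2))
                    w = gx * gmu * (1.0 / wnorm[k, j, i] + 1.0 / wnorm[k2, j2, i2])
                    for c in range(3):
                        dv = v[c, k, j, i] - v[c, k2, j2, i2]
                        gv = np.exp(-dv * dv / (2.0 * sv2))
                        g = w * gv * (2.0 * dv - dv * dv * dv / sv2) * inv_d2
                        out[c, k, j, i] += g
                        out[c, k2, j2, i2] -= g
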