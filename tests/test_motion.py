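"""DVF algebra: warping, inversion, regularizers and their gradients."""

import itertools

import numpy as np
import pytest

import recon4d as r4d
from recon4d.motion import (BilateralParams, bilateral_phi, bilateral_phi_grad,
                            consistency_residual, invert_dvf, isotropic_phi,
                            isotropic_phi_grad, warp_volume)


def _smooth_dvf(rng, shape, spacing, amp=1.5):
    from scipy import ndimage
    data = ndimage.gaussian_filter(rng.normal(0, amp, (3, *shape)),
                                   sigma=(0, 1.5, 1.5, 1.5))
    return r4d.DVF(data, spacing)


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------

def test_warp_zero_field_identity(rng):
    vol = r4d.Volume(rng.random((8, 9, 10)), (2.0, 1.5, 1.0))
    out = warp_volume(vol, r4d.DVF.zeros_like(vol))
    assert np.array_equal(out.data, vol.data)


def test_warp_integer_shift_exact(rng):
    """Constant one-voxel shift reproduces the shifted array exactly on the
    interior (interpolation is exact at lattice points)."""
    vol = r4d.Volume(rng.random((8, 8, 8)), (2.0, 2.0, 2.0))
    d = r4d.DVF.zeros_like(vol)
    d.data[0, ...] = 2.0  # one voxel along z
    out = warp_volume(vol, d)
    np.testing.assert_array_equal(out.data[:-1], vol.data[1:])


def test_warp_matches_bruteforce_loop(rng):
    """Trilinear pull-back agrees with a per-voxel scalar loop to 1e-12."""
    vol = r4d.Volume(rng.random((6, 6, 6)), (2.0, 2.0, 2.0))
    dvf = _smooth_dvf(rng, (6, 6, 6), vol.spacing)
    out = warp_volume(vol, dvf).data

    def sample(p):
        p = np.clip(p, 0, 5)
        i0 = np.minimum(np.floor(p).astype(int), 4)
        f = p - i0
        acc = 0.0
        for dz, dy, dx in itertools.product((0, 1), repeat=3):
            w = ((f[0] if dz else 1 - f[0]) * (f[1] if dy else 1 - f[1])
                 * (f[2] if dx else 1 - f[2]))
            acc += w * vol.data[i0[0] + dz, i0[1] + dy, i0[2] + dx]
        return acc

    for k, j, i in itertools.product(range(6), repeat=3):
        p = np.array([k, j, i]) + dvf.data[:, k, j, i] / vol.spacing
        assert out[k, j, i] == pytest.approx(sample(p), abs=1e-12)


def test_warp_grid_mismatch(rng):
    vol = r4d.Volume(rng.random((4, 4, 4)), (1.0, 1.0, 1.0))
    dvf = r4d.DVF.zeros((5, 4, 4), (1.0, 1.0, 1.0))
    with pytest.raises(ValueError):
        warp_volume(vol, dvf)


# ---------------------------------------------------------------------------
# inversion and consistency
# ---------------------------------------------------------------------------

def test_invert_zero_and_constant():
    z = r4d.DVF.zeros((6, 6, 6), (2.0, 2.0, 2.0))
    assert np.all(invert_dvf(z).data == 0.0)
    c = z.like(np.full((3, 6, 6, 6), 3.0))
    inv = invert_dvf(c)
    np.testing.assert_allclose(inv.data, -3.0, atol=1e-10)
    assert inv.converged


def test_invert_smooth_field_small_residual(rng):
    dvf = _smooth_dvf(rng, (10, 10, 10), (2.0, 2.0, 2.0), amp=3.0)
    inv = invert_dvf(dvf, tol=0.05, max_iter=40)
    _, res = consistency_residual(dvf, inv)
    assert res < 0.1


def test_invert_ground_truth_smooth_interior(small_spec, small_motion):
    """The analytic phantom field inverts to a small composition residual
    away from the sliding shell (no exact inverse exists on the shell)."""
    from scipy import ndimage
    dvf = small_motion.dvfs[5]
    inv = invert_dvf(dvf, tol=0.05, max_iter=40)
    mag, _ = consistency_residual(dvf, inv)
    # exclude a 2-voxel shell around the discontinuity surfaces
    moving = np.abs(dvf.data).sum(axis=0) > 1e-9
    shell = ndimage.binary_dilation(moving, iterations=2) & \
        ~ndimage.binary_erosion(moving, iterations=2)
    assert np.median(mag[~shell]) < 0.1
    assert np.percentile(mag[~shell], 95) < 0.5


def test_invert_involution(rng):
    """Double inversion restores a smooth field (interior voxels; the
    boundary-clamped samples are not invertible information)."""
    dvf = _smooth_dvf(rng, (10, 10, 10), (2.0, 2.0, 2.0), amp=2.0)
    back = invert_dvf(invert_dvf(dvf, tol=0.02, max_iter=50),
                      tol=0.02, max_iter=50)
    err = np.abs(back.data - dvf.data)[:, 2:-2, 2:-2, 2:-2]
    assert err.max() < 2 * 0.02 + 0.02


def test_consistency_residual_closed_forms(rng):
    shape = (6, 6, 6)
    c = r4d.DVF(np.full((3, *shape), 2.0), (2.0, 2.0, 2.0))
    mag, mx = consistency_residual(c, c)
    # v(x + c) + c = 2c in the interior
    np.testing.assert_allclose(mag[1:-1, 1:-1, 1:-1],
                               2 * np.sqrt(3 * 4.0), atol=1e-9)

    v = _smooth_dvf(rng, (5, 5, 5), (1.0, 1.0, 1.0), amp=0.4)
    u = _smooth_dvf(rng, (5, 5, 5), (1.0, 1.0, 1.0), amp=0.4)
    mag, _ = consistency_residual(v, u)
    # brute-force evaluation at one interior voxel
    k, j, i = 2, 3, 1
    p = np.array([k, j, i]) + u.data[:, k, j, i]
    i0 = np.floor(p).astype(int)
    f = p - i0
    acc = np.zeros(3)
    for dz, dy, dx in itertools.product((0, 1), repeat=3):
        w = ((f[0] if dz else 1 - f[0]) * (f[1] if dy else 1 - f[1])
             * (f[2] if dx else 1 - f[2]))
        acc += w * v.data[:, i0[0] + dz, i0[1] + dy, i0[2] + dx]
    expect = np.linalg.norm(acc + u.data[:, k, j, i])
    assert mag[k, j, i] == pytest.approx(expect, abs=1e-12)


# ---------------------------------------------------------------------------
# isotropic regularizer
# ---------------------------------------------------------------------------

def test_isotropic_constant_field_zero():
    c = r4d.DVF(np.full((3, 5, 5, 5), 1.7), (2.0, 2.0, 2.0))
    assert isotropic_phi(c) == 0.0
    assert np.all(isotropic_phi_grad(c) == 0.0)


def test_isotropic_ramp_closed_form():
    """Unit-slope ramp: each forward-difference site contributes 1."""
    n = 6
    d = r4d.DVF.zeros((n, n, n), (1.0, 1.0, 1.0))
    x = np.arange(n, dtype=float)
    d.data[2] = np.broadcast_to(x, (n, n, n))  # v_x = x, slope 1 per mm
    assert isotropic_phi(d) == pytest.approx((n - 1) * n * n)


def test_isotropic_grad_finite_difference(rng):
    d = r4d.DVF(rng.normal(0, 1, (3, 6, 6, 6)), (2.0, 1.0, 1.5))
    g = isotropic_phi_grad(d)
    h = 1e-5
    for _ in range(12):
        c = tuple(rng.integers(s) for s in (3, 6, 6, 6))
        dp, dm = d.copy(), d.copy()
        dp.data[c] += h
        dm.data[c] -= h
        fd = (isotropic_phi(dp) - isotropic_phi(dm)) / (2 * h)
        assert abs(fd - g[c]) <= 1e-5 * max(abs(fd), 1.0)


# ---------------------------------------------------------------------------
# bilateral regularizer
# ---------------------------------------------------------------------------

def test_spatial_kernel_closed_form():
    """G_x at |x - y| = 3 mm with sigma_x = 3 mm is exp(-1/2)."""
    par = BilateralParams(sigma_x=3.0)
    d = r4d.DVF.zeros((1, 1, 2), (1.0, 1.0, 3.0))
    d.data[2, 0, 0, 0] = 1.0  # single differing pair 3 mm apart
    mu = r4d.Volume(np.zeros((1, 1, 2)), d.spacing)
    big = BilateralParams(sigma_x=3.0, sigma_mu=1e9, sigma_v=1e9)
    # phi = 2 (both orderings) * Gx * (dv/d)^2
    assert bilateral_phi(d, mu, big) == pytest.approx(
        2 * np.exp(-0.5) * (1.0 / 3.0) ** 2, rel=1e-9)


def test_bilateral_constant_field_zero(rng):
    c = r4d.DVF(np.full((3, 5, 5, 5), 2.2), (2.0, 2.0, 2.0))
    mu = r4d.Volume(rng.random((5, 5, 5)), c.spacing)
    assert bilateral_phi(c, mu, BilateralParams()) == 0.0
    assert np.all(bilateral_phi_grad(c, mu, BilateralParams()) == 0.0)


def test_bilateral_wide_kernel_limit_matches_bruteforce(rng):
    """With all sigmas -> inf and uniform intensity, phi equals the
    neighbourhood-summed isotropic penalty; checked against a triple loop."""
    shape = (5, 5, 5)
    h = (2.0, 2.0, 2.0)
    v = r4d.DVF(rng.normal(0, 1.0, (3, *shape)), h)
    mu = r4d.Volume(np.full(shape, 0.02), h)
    par = BilateralParams(sigma_x=1e9, sigma_mu=1e9, sigma_v=1e9)

    phi = 0.0
    for k, j, i in itertools.product(range(5), repeat=3):
        for dk, dj, di in itertools.product((-1, 0, 1), repeat=3):
            if (dk, dj, di) == (0, 0, 0):
                continue
            k2, j2, i2 = k + dk, j + dj, i + di
            if not (0 <= k2 < 5 and 0 <= j2 < 5 and 0 <= i2 < 5):
                continue
            d2 = (dk * h[0]) ** 2 + (dj * h[1]) ** 2 + (di * h[2]) ** 2
            for c in range(3):
                dv = v.data[c, k, j, i] - v.data[c, k2, j2, i2]
                phi += dv * dv / d2
    assert bilateral_phi(v, mu, par) == pytest.approx(phi, rel=1e-9)


def test_bilateral_grad_finite_difference(rng):
    for par in (BilateralParams(),
                BilateralParams(sigma_x=2.0, sigma_mu=0.02, sigma_v=2.0,
                                normalized=True)):
        v = r4d.DVF(rng.normal(0, 2.0, (3, 5, 5, 5)), (2.0, 2.0, 2.0))
        mu = r4d.Volume(rng.random((5, 5, 5)) * 0.03, v.spacing)
        g = bilateral_phi_grad(v, mu, par)
        h = 1e-4
        for _ in range(12):
            c = tuple(rng.integers(s) for s in (3, 5, 5, 5))
            vp, vm = v.copy(), v.copy()
            vp.data[c] += h
            vm.data[c] -= h
            fd = (bilateral_phi(vp, mu, par) - bilateral_phi(vm, mu, par)) / (2 * h)
            assert abs(fd - g[c]) <= 1e-4 * max(abs(fd), 1e-6)


def test_bilateral_grad_wide_limit_equals_isotropic_neighbourhood(rng):
    """With G_mu and G_v frozen to 1 the gradient equals the spatially
    weighted neighbourhood isotropic gradient (finite-sigma_x weights)."""
    v = r4d.DVF(rng.normal(0, 1.0, (3, 5, 5, 5)), (2.0, 2.0, 2.0))
    mu = r4d.Volume(np.zeros((5, 5, 5)), v.spacing)
    par = BilateralParams(sigma_x=3.0, sigma_mu=1e9, sigma_v=1e9)
    g = bilateral_phi_grad(v, mu, par)

    expect = np.zeros_like(v.data)
    h = v.spacing
    for k, j, i in itertools.product(range(5), repeat=3):
        for dk, dj, di in itertools.product((-1, 0, 1), repeat=3):
            if (dk, dj, di) == (0, 0, 0):
                continue
            k2, j2, i2 = k + dk, j + dj, i + di
            if not (0 <= k2 < 5 and 0 <= j2 < 5 and 0 <= i2 < 5):
                continue
            d2 = (dk * h[0]) ** 2 + (dj * h[1]) ** 2 + (di * h[2]) ** 2
            gx = np.exp(-d2 / (2 * 9.0))
            for c in range(3):
                dv = v.data[c, k, j, i] - v.data[c, k2, j2, i2]
                expect[c, k, j, i] += 2 * gx * 2 * dv / d2
    np.testing.assert_allclose(g, expect, rtol=1e-9, atol=1e-12)


def test_bilateral_nonnegative_and_zero_iff_constant(rng):
    par = BilateralParams()
    for _ in range(3):
        v = r4d.DVF(rng.normal(0, 1, (3, 4, 4, 4)), (2.0, 2.0, 2.0))
        mu = r4d.Volume(rng.random((4, 4, 4)), v.spacing)
        assert bilateral_phi(v, mu, par) > 0.0


def test_sliding_preservation_two_block_field():
    """One smoothing step on a tangential jump aligned with an intensity
    edge: the bilateral gradient leaves the jump nearly intact while the
    isotropic gradient flattens it substantially at the same step size."""
    n = 16
    h = (1.0, 1.0, 1.0)
    jump = 10.0
    v0 = np.zeros((3, n, n, n))
    v0[0, :, :, : n // 2] = jump  # SI displacement jumps across x-plane
    mu = np.zeros((n, n, n))
    mu[:, :, : n // 2] = 0.09  # edge of 3 sigma_mu for sigma_mu = 0.03
    par = BilateralParams(sigma_x=3.0, sigma_mu=0.03, sigma_v=2.5)
    eta = 0.1

    def jump_after(grad_fn):
        v = r4d.DVF(v0.copy(), h)
        g = grad_fn(v)
        vn = v0 - eta * g
        left = vn[0, :, :, n // 2 - 1].mean()
        right = vn[0, :, :, n // 2].mean()
        return left - right

    jb = jump_after(lambda v: bilateral_phi_grad(v, r4d.Volume(mu, h), par))
    ji = jump_after(isotropic_phi_grad)
    red_b = (jump - jb) / jump
    red_i = (jump - ji) / jump
    assert abs(red_b) < 0.10
    assert red_i > 0.30
    assert red_i > 3 * abs(red_b)
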