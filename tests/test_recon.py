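"""SART family: closed forms, convergence, motion-compensated degeneracies."""

import numpy as np
import pytest

import recon4d as r4d
from recon4d.recon import (ReconConfig, msart_reconstruct, sart_pass,
                           sart_reconstruct, tv_reconstruct,
                           projection_residual_norm)


def _single_voxel_setup():
    """One voxel, one ray: the SART update has a scalar closed form."""
    geo = r4d.ConeBeamGeometry(sad=1000, sdd=1500, det_rows=1, det_cols=1,
                               det_pitch=2.0)
    vol = r4d.Volume(np.zeros((1, 1, 1)), (2.0, 2.0, 2.0))
    return geo, vol


def test_sart_single_voxel_closed_form():
    """a = 2 mm, p = 0.4, mu0 = 0, lambda = 1: one pass solves mu = p/a."""
    geo, vol = _single_voxel_setup()
    p = r4d.ProjectionSet(np.full((1, 1, 1), 0.4), [0.0])
    cfg = ReconConfig(relaxation=1.0, n_iterations=1)
    out = sart_pass(vol, p, geo, cfg)
    assert out.data[0, 0, 0] == pytest.approx(0.2, rel=1e-12)
    # and the update is a fixed point afterwards
    again = sart_pass(out, p, geo, cfg)
    assert again.data[0, 0, 0] == pytest.approx(0.2, rel=1e-12)


def test_sart_zero_projections_zero_volume_unchanged(tiny_geometry):
    vol = r4d.Volume(np.zeros((8, 8, 8)), (2.0, 2.0, 2.0))
    p = r4d.ProjectionSet(np.zeros((4, 24, 24)), [0.0, 1.0, 2.0, 3.0])
    out = sart_pass(vol, p, tiny_geometry, ReconConfig())
    assert np.all(out.data == 0.0)


def test_sart_residual_decreases(tiny_geometry, rng):
    """Consistent noise-free projections: residual norm strictly decreases
    over passes."""
    truth = r4d.Volume(np.zeros((16, 16, 16)), (2.0, 2.0, 2.0))
    truth.data[4:12, 4:12, 4:12] = 0.02
    truth.data[6:10, 6:10, 6:10] = 0.005
    angles = np.linspace(0, 2 * np.pi, 30, endpoint=False)
    p = r4d.forward_project(truth, tiny_geometry, angles)
    vol = truth.like(np.zeros(truth.shape))
    cfg = ReconConfig(relaxation=0.8)
    res = [projection_residual_norm(vol, p, tiny_geometry)]
    for _ in range(10):
        vol = sart_pass(vol, p, tiny_geometry, cfg)
        res.append(projection_residual_norm(vol, p, tiny_geometry))
    assert all(b < a for a, b in zip(res, res[1:]))


def test_sart_fixed_point(tiny_geometry, rng):
    """If A mu = p exactly, one pass leaves mu unchanged to 1e-10."""
    vol = r4d.Volume(rng.random((8, 8, 8)) * 0.02, (4.0, 4.0, 4.0))
    angles = [0.0, 1.3, 2.6]
    p = r4d.forward_project(vol, tiny_geometry, angles)
    out = sart_pass(vol, p, tiny_geometry, ReconConfig(relaxation=1.0))
    np.testing.assert_allclose(out.data, vol.data, atol=1e-10)


def test_nonnegativity_clamp(tiny_geometry):
    vol = r4d.Volume(np.zeros((8, 8, 8)), (2.0, 2.0, 2.0))
    p = r4d.ProjectionSet(np.full((2, 24, 24), -1.0), [0.0, 2.0])
    out = sart_pass(vol, p, tiny_geometry, ReconConfig(nonneg=True))
    assert out.data.min() >= 0.0


def test_msart_identity_dvfs_equals_pooled_sart(tiny_geometry, rng):
    """With identity DVFs the motion-compensated update degenerates to SART
    over the pooled views — exact array equality."""
    vol_t = r4d.Volume(rng.random((8, 8, 8)) * 0.02, (4.0, 4.0, 4.0))
    grid = vol_t.like(np.zeros(vol_t.shape))
    angle_sets = [np.array([0.0, 1.0]), np.array([2.0, 3.0]),
                  np.array([4.0, 5.0])]
    projs = [r4d.forward_project(vol_t, tiny_geometry, a, phase=t)
             for t, a in enumerate(angle_sets)]
    cfg = ReconConfig(n_iterations=2)
    m = msart_reconstruct(projs, [None] * 3, tiny_geometry, cfg, grid)

    pooled = r4d.ProjectionSet(
        np.concatenate([p.data for p in projs]),
        np.concatenate([p.angles for p in projs]))
    s = grid.like(np.zeros(grid.shape))
    lam = cfg.relaxation
    for _ in range(cfg.n_iterations):
        s = sart_pass(s, pooled, tiny_geometry, cfg, relaxation=lam)
        lam *= cfg.relaxation_decay
    assert np.array_equal(m.data, s.data)


def test_msart_single_phase_identity_equals_sart(tiny_geometry, rng):
    vol = r4d.Volume(rng.random((8, 8, 8)) * 0.02, (4.0, 4.0, 4.0))
    p = r4d.forward_project(vol, tiny_geometry, [0.5, 1.5, 2.5])
    grid = vol.like(np.zeros(vol.shape))
    cfg = ReconConfig(n_iterations=3)
    m = msart_reconstruct([p], [None], tiny_geometry, cfg, grid)
    s = sart_reconstruct(p, tiny_geometry, cfg, grid)
    assert np.array_equal(m.data, s.data)


def test_msart_requires_dvf_per_phase(tiny_geometry):
    p = r4d.ProjectionSet(np.zeros((1, 24, 24)), [0.0])
    grid = r4d.Volume(np.zeros((4, 4, 4)), (2.0, 2.0, 2.0))
    with pytest.raises(ValueError):
        msart_reconstruct([p, p], [None], tiny_geometry, ReconConfig(), grid)


def test_tv_weight_zero_identical_to_sart(tiny_geometry, rng):
    vol = r4d.Volume(rng.random((8, 8, 8)) * 0.02, (4.0, 4.0, 4.0))
    p = r4d.forward_project(vol, tiny_geometry, np.linspace(0, 3, 8))
    grid = vol.like(np.zeros(vol.shape))
    cfg0 = ReconConfig(n_iterations=3, tv_weight=0.0)
    a = tv_reconstruct(p, tiny_geometry, cfg0, grid)
    b = sart_reconstruct(p, tiny_geometry, cfg0, grid)
    assert np.array_equal(a.data, b.data)


def test_tv_lowers_total_variation_under_noise(tiny_geometry, rng):
    """Piecewise-constant phantom, few noisy views: the TV-regularized
    result has lower total variation than plain SART."""
    truth = r4d.Volume(np.zeros((16, 16, 16)), (2.0, 2.0, 2.0))
    truth.data[3:13, 3:13, 3:13] = 0.02
    truth.data[5:11, 5:11, 5:11] = 0.006
    angles = np.linspace(0, 2 * np.pi, 20, endpoint=False)
    p = r4d.forward_project(truth, tiny_geometry, angles)
    p = r4d.projector.add_projection_noise(p, 0.02, rng)
    grid = truth.like(np.zeros(truth.shape))

    def tv_of(vol):
        return sum(np.abs(np.diff(vol.data, axis=ax)).sum() for ax in range(3))

    s = sart_reconstruct(p, tiny_geometry, ReconConfig(n_iterations=5), grid)
    t = tv_reconstruct(p, tiny_geometry,
                       ReconConfig(n_iterations=5, tv_weight=0.3, tv_steps=10),
                       grid)
    assert tv_of(t) < tv_of(s)


def test_recon_config_validation():
    with pytest.raises(ValueError):
        ReconConfig(relaxation=0.0)
    with pytest.raises(ValueError):
        ReconConfig(n_iterations=0)
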