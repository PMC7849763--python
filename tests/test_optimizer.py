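"""Projection-matching energy: values, gradients, NCG behaviour."""

import numpy as np
import pytest

import recon4d as r4d
from recon4d.motion import BilateralParams
from recon4d.optimizer import (EnergyConfig, data_fidelity, fidelity_gradient,
                               ncg_optimize)


@pytest.fixture
def fid_setup(rng, tiny_geometry):
    mu0 = r4d.Volume(np.clip(rng.normal(0.02, 0.008, (8, 8, 8)), 0, None),
                     (4.0, 4.0, 4.0))
    v = r4d.DVF(rng.normal(0, 1.2, (3, 8, 8, 8)), (4.0, 4.0, 4.0))
    angles = [0.3, 1.9]
    return mu0, v, angles


def test_fidelity_zero_at_exact_match(fid_setup, tiny_geometry):
    mu0, v, angles = fid_setup
    p = r4d.forward_project(r4d.warp_volume(mu0, v), tiny_geometry, angles)
    assert data_fidelity(v, mu0, p, tiny_geometry) == pytest.approx(0.0, abs=1e-20)
    g = fidelity_gradient(v, mu0, p, tiny_geometry)
    np.testing.assert_allclose(g, 0.0, atol=1e-15)


def test_fidelity_independent_of_regularizer(fid_setup, tiny_geometry, rng):
    """The data term ignores beta and the kernel parameters entirely."""
    mu0, v, angles = fid_setup
    p = r4d.forward_project(mu0, tiny_geometry, angles)
    a = data_fidelity(v, mu0, p, tiny_geometry)
    b = data_fidelity(v, mu0, p, tiny_geometry)  # no params enter the call
    assert a == b


def test_fidelity_gradient_matches_directional_fd(fid_setup, tiny_geometry, rng):
    """Directional finite differences on random perturbations agree with the
    analytic chain-rule gradient to better than 1e-3 relative."""
    mu0, v, angles = fid_setup
    target = r4d.Volume(rng.random((8, 8, 8)) * 0.03, mu0.spacing)
    p = r4d.forward_project(target, tiny_geometry, angles)
    g = fidelity_gradient(v, mu0, p, tiny_geometry)
    h = 1e-5
    for _ in range(10):
        d = rng.normal(size=g.shape)
        d /= np.linalg.norm(d)
        fp = data_fidelity(v.like(v.data + h * d), mu0, p, tiny_geometry)
        fm = data_fidelity(v.like(v.data - h * d), mu0, p, tiny_geometry)
        fd = (fp - fm) / (2 * h)
        an = float((g * d).sum())
        assert abs(fd - an) <= 1e-3 * max(abs(fd), 1e-9)


def test_fidelity_gradient_zero_outside_ray_support(tiny_geometry, rng):
    """Voxels never traversed by any measured ray receive zero gradient."""
    mu0 = r4d.Volume(rng.random((8, 8, 8)) * 0.02, (4.0, 4.0, 4.0))
    v = r4d.DVF.zeros_like(mu0)
    angles = [0.0]
    p = r4d.forward_project(mu0, tiny_geometry, angles)
    p = r4d.ProjectionSet(p.data + 0.1, p.angles)  # nonzero residual
    g = fidelity_gradient(v, mu0, p, tiny_geometry)
    bp = r4d.back_project(r4d.ProjectionSet(np.ones_like(p.data), p.angles),
                          tiny_geometry, mu0)
    outside = bp.data == 0.0
    assert np.all(g[:, outside] == 0.0)


def _blob_volume(n=24, h=4.0):
    z, y, x = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    c = (n - 1) / 2
    blob = 0.02 * np.exp(-(((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2)
                           / (2 * 25.0)))
    return r4d.Volume(blob, (h, h, h))


def test_ncg_recovers_small_translation(tiny_geometry):
    """beta = 0, projections of a translated blob, zero init.

    Without regularization only the gradient-normal motion component is
    identifiable (aperture problem), so the checks are: the projection
    residual collapses, the re-warped image matches the translated blob,
    and the normal-flow component of the recovered field matches the
    translation's normal component to within half a voxel (median over the
    gradient shell)."""
    mu0 = _blob_volume()
    shift = np.zeros((3, *mu0.shape))
    shift[0] = 6.0  # 1.5 voxels SI
    v_true = r4d.DVF(shift, mu0.spacing)
    angles = np.linspace(0, np.pi, 6, endpoint=False)
    p_t = r4d.forward_project(r4d.warp_volume(mu0, v_true), tiny_geometry, angles)
    p_0 = r4d.forward_project(mu0, tiny_geometry, angles)

    cfg = EnergyConfig(beta=0.0, regularizer="none", max_iterations=40,
                       consistency_interval=10)
    st = ncg_optimize(r4d.DVF.zeros_like(mu0), r4d.DVF.zeros_like(mu0),
                      mu0, p_t, p_0, tiny_geometry, config=cfg)

    fid0 = data_fidelity(r4d.DVF.zeros_like(mu0), mu0, p_t, tiny_geometry)
    fid1 = data_fidelity(st.v_fwd, mu0, p_t, tiny_geometry)
    assert fid1 < 0.05 * fid0

    w_true = r4d.warp_volume(mu0, v_true)
    w_rec = r4d.warp_volume(mu0, st.v_fwd)
    rmse = np.sqrt(((w_rec.data - w_true.data) ** 2).mean())
    assert rmse < 0.03 * w_true.data.max()

    grad = np.stack([np.gradient(mu0.data, mu0.spacing[a], axis=a)
                     for a in range(3)])
    gmag = np.sqrt((grad**2).sum(axis=0))
    shell = gmag > 0.5 * gmag.max()
    n_hat = grad[:, shell] / gmag[shell]
    flow_rec = (st.v_fwd.data[:, shell] * n_hat).sum(axis=0)
    flow_true = (v_true.data[:, shell] * n_hat).sum(axis=0)
    assert np.median(np.abs(flow_rec - flow_true)) < 2.0  # half a voxel


def test_ncg_stationary_at_exact_solution(tiny_geometry):
    """Starting from the exact field the optimizer accepts (at most) steps
    that do not move the field appreciably."""
    mu0 = _blob_volume()
    shift = np.zeros((3, *mu0.shape))
    shift[0] = 4.0
    v_true = r4d.DVF(shift, mu0.spacing)
    angles = np.linspace(0, np.pi, 4, endpoint=False)
    p_t = r4d.forward_project(r4d.warp_volume(mu0, v_true), tiny_geometry, angles)
    p_0 = r4d.forward_project(mu0, tiny_geometry, angles)
    cfg = EnergyConfig(beta=0.0, regularizer="none", max_iterations=5,
                       consistency_interval=100)
    st = ncg_optimize(v_true, v_true.like(-v_true.data), mu0, p_t, p_0,
                      tiny_geometry, config=cfg)
    # interior of the blob; the boundary-clamped voxels carry no signal
    core = mu0.data > 0.1 * mu0.data.max()
    assert np.abs(st.v_fwd.data[:, core] - v_true.data[:, core]).max() < 0.5


def test_energy_monotone_over_accepted_steps(small_spec, small_projections,
                                             small_motion, geometry):
    """f1 and f2 never increase over the accepted line-search steps within a
    consistency block."""
    mu0 = r4d.build_phantom_phase(small_spec, 0)
    t = 3
    fwd0 = small_motion.dvfs[t].like(small_motion.dvfs[t].data * 0.7)
    inv0 = r4d.invert_dvf(fwd0)
    cfg = EnergyConfig(max_iterations=8, consistency_interval=8)
    st = ncg_optimize(fwd0, inv0, mu0, small_projections[t],
                      small_projections[0], geometry,
                      params=BilateralParams(), config=cfg)
    f1 = [h["f1"] for h in st.history]
    f2 = [h["f2"] for h in st.history]
    assert all(b <= a + 1e-9 for a, b in zip(f1, f1[1:]))
    assert all(b <= a + 1e-9 for a, b in zip(f2, f2[1:]))
    assert st.beta > 0  # auto-balanced weight was set


def test_energy_config_validation():
    with pytest.raises(ValueError):
        EnergyConfig(beta=-1.0)
    with pytest.raises(ValueError):
        EnergyConfig(regularizer="banana")
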