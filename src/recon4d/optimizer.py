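"""Projection-matching DVF estimation by nonlinear conjugate gradient.

Per non-reference phase t a symmetric energy pair is minimized:

    f1(v_fwd) = || p_t - A warp(mu0, v_fwd) ||^2 + beta * phi(v_fwd)
    f2(v_inv) = || p_0 - A warp(mu_t, v_inv) ||^2 + beta * phi(v_inv)

subject to the inverse-consistency constraint that the forward (0->t) and
inverse (t->0) fields compose to the identity.  ``phi`` is either the
isotropic or the bilateral regularizer.  ``mu_t`` in f2 is the current
forward-warped estimate of the phase-t image (a single-image unknown keeps
f2 well defined at every iterate).

The two fields are updated alternately with Polak-Ribiere(+) conjugate
gradient and Armijo backtracking; every ``consistency_interval`` iterations
the pair is re-symmetrized by averaging each field with the inversion of
its partner, enforcing the constraint without a third hyperparameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .geometry import ConeBeamGeometry, ProjectionSet
from .grids import DVF, Volume
from .motion import (BilateralParams, bilateral_phi, bilateral_phi_grad,
                     consistency_residual, invert_dvf, isotropic_phi,
                     isotropic_phi_grad, warp_image_gradient, warp_volume)
from .projector import back_project, forward_project

__all__ = ["EnergyConfig", "OptState", "data_fidelity", "fidelity_gradient",
           "ncg_optimize", "auto_beta"]


@dataclass
class EnergyConfig:
    """Controls of the symmetric DVF energy and its optimizer."""

    beta: float | None = None           # None -> auto-balanced at iteration 0
    regularizer: str = "bilateral"      # "bilateral" | "isotropic" | "none"
    max_iterations: int = 200
    consistency_interval: int = 10
    tolerance: float = 1e-4             # relative energy decrease
    tolerance_window: int = 10
    armijo_c1: float = 1e-4
    armijo_shrink: float = 0.5
    max_linesearch: int = 8
    initial_step_mm: float = 1.0        # first trial step (max displacement)

    def __post_init__(self):
        if self.beta is not None and self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.regularizer not in ("bilateral", "isotropic", "none"):
            raise ValueError(f"unknown regularizer {self.regularizer!r}")


@dataclass
class OptState:
    """Optimizer trace for one phase."""

    v_fwd: DVF = None
    v_inv: DVF = None
    history: list = dc_field(default_factory=list)  # dicts per iteration
    iterations: int = 0
    converged: bool = False
    beta: float = 0.0

    def energy_curve(self):
        return np.array([h["f1"] + h["f2"] for h in self.history])


def data_fidelity(v: DVF, mu0: Volume, p_t: ProjectionSet,
                  geometry: ConeBeamGeometry) -> float:
    """Squared l2 projection residual of the warped reference volume."""
    warped = warp_volume(mu0, v)
    sim = forward_project(warped, geometry, p_t.angles)
    return float(((p_t.data - sim.data) ** 2).sum())


def fidelity_gradient(v: DVF, mu0: Volume, p_t: ProjectionSet,
                      geometry: ConeBeamGeometry) -> np.ndarray:
    """Analytic gradient of :func:`data_fidelity` w.r.t. the displacement.

    Chain rule: -2 * [A^T (p_t - A mu_w)] (x) * d mu0(x + v(x)) / d v(x),
    the latter being the exact gradient of the trilinear interpolant.
    Returns shape (3, Z, Y, X).
    """
    warped = warp_volume(mu0, v)
    sim = forward_project(warped, geometry, p_t.angles)
    resid = ProjectionSet(p_t.data - sim.data, p_t.angles, p_t.phase)
    bp = back_project(resid, geometry, mu0)
    gvol = warp_image_gradient(mu0, v)
    return -2.0 * bp.data[None, ...] * gvol


def _reg_value_grad(v: DVF, intensity: Volume, config: EnergyConfig,
                    params: BilateralParams):
    if config.regularizer == "bilateral":
        return (bilateral_phi(v, intensity, params),
                lambda: bilateral_phi_grad(v, intensity, params))
    if config.regularizer == "isotropic":
        return isotropic_phi(v), lambda: isotropic_phi_grad(v)
    return 0.0, lambda: np.zeros_like(v.data)


def auto_beta(v: DVF, mu0: Volume, p_t: ProjectionSet,
              geometry: ConeBeamGeometry, intensity: Volume,
              config: EnergyConfig, params: BilateralParams,
              fraction: float = 0.1) -> float:
    """Scale-free default: beta such that the regularizer term is
    ``fraction`` of the initial fidelity term (0 when the initial field is
    flat and the regularizer vanishes)."""
    fid = data_fidelity(v, mu0, p_t, geometry)
    reg, _ = _reg_value_grad(v, intensity, config, params)
    if reg <= 1e-12:
        return 0.0
    return fraction * fid / reg


class _PhaseEnergy:
    """f(v) = fidelity + beta * phi(v) for one direction of one phase.

    The warped volume and its simulated projections are cached per iterate
    so an accepted line-search value is not recomputed by the following
    gradient call.
    """

    def __init__(self, mu_ref, p_meas, geometry, intensity, beta, config, params):
        self.mu_ref = mu_ref
        self.p_meas = p_meas
        self.geometry = geometry
        self.intensity = intensity
        self.beta = beta
        self.config = config
        self.params = params
        self._cache_key = None
        self._cache = None

    def _warp_and_project(self, v: DVF):
        # identity key with a strong reference: a live object cannot share
        # its id with a new one, and v.data is never mutated in place here
        if self._cache_key is not v:
            warped = warp_volume(self.mu_ref, v)
            sim = forward_project(warped, self.geometry, self.p_meas.angles)
            self._cache_key = v
            self._cache = (warped, sim)
        return self._cache

    def invalidate(self):
        self._cache_key = None

    def value(self, v: DVF):
        _, sim = self._warp_and_project(v)
        fid = float(((self.p_meas.data - sim.data) ** 2).sum())
        reg, _ = _reg_value_grad(v, self.intensity, self.config, self.params)
        return fid + self.beta * reg, fid, reg

    def grad(self, v: DVF):
        _, sim = self._warp_and_project(v)
        resid = ProjectionSet(self.p_meas.data - sim.data, self.p_meas.angles,
                              self.p_meas.phase)
        bp = back_project(resid, self.geometry, self.mu_ref)
        gvol = warp_image_gradient(self.mu_ref, v)
        g = -2.0 * bp.data[None, ...] * gvol
        if self.beta > 0 and self.config.regularizer != "none":
            _, gfun = _reg_value_grad(v, self.intensity, self.config, self.params)
            g = g + self.beta * gfun()
        return g


def _ncg_steps(energy: _PhaseEnergy, v: DVF, n_steps: int, config: EnergyConfig,
               state_tag: str, history: list, start_iter: int):
    """Run ``n_steps`` PR+ CG steps on one field; returns updated field and
    the last accepted energy value."""
    f_cur, fid_cur, reg_cur = energy.value(v)
    g = energy.grad(v)
    d = -g
    step = config.initial_step_mm
    for it in range(n_steps):
        gmax = float(np.abs(d).max())
        if gmax <= 1e-30:
            break
        # trial step expressed as max displacement change in mm
        alpha = step / gmax
        accepted = False
        gd = float((g * d).sum())
        if gd >= 0:  # not a descent direction: steepest-descent restart
            d = -g
            gd = float((g * d).sum())
            gmax = float(np.abs(d).max())
            alpha = step / gmax if gmax > 0 else 0.0
        for _ls in range(config.max_linesearch):
            v_try = v.like(v.data + alpha * d)
            f_try, fid_try, reg_try = energy.value(v_try)
            if f_try <= f_cur + config.armijo_c1 * alpha * gd:
                accepted = True
                break
            alpha *= config.armijo_shrink
        if not accepted:
            break
        v = v_try
        g_new = energy.grad(v)
        beta_pr = float(((g_new - g) * g_new).sum()) / max(float((g * g).sum()), 1e-30)
        beta_pr = max(0.0, beta_pr)
        d = -g_new + beta_pr * d
        g = g_new
        f_cur, fid_cur, reg_cur = f_try, fid_try, reg_try
        step = max(alpha * float(np.abs(d).max()) * 2.0, 1e-3)
        history.append({
            "iteration": start_iter + it,
            "field": state_tag,
            "energy": f_cur,
            "fidelity": fid_cur,
            "regularizer": reg_cur,
            "step_mm": alpha * gmax,
        })
    return v, f_cur


def ncg_optimize(v_fwd: DVF, v_inv: DVF, mu0: Volume, p_t: ProjectionSet,
                 p_0: ProjectionSet, geometry: ConeBeamGeometry,
                 params: BilateralParams = None,
                 config: EnergyConfig = None) -> OptState:
    """Alternating NCG on the symmetric energy pair of one phase.

    ``v_fwd`` (0->t) is optimized against the phase-t projections, ``v_inv``
    (t->0) against the reference-phase projections; see the module
    docstring for the scheme.
    """
    params = params or BilateralParams()
    config = config or EnergyConfig()

    state = OptState(v_fwd=v_fwd.copy(), v_inv=v_inv.copy())
    mu_t = warp_volume(mu0, state.v_fwd)

    beta = config.beta
    if beta is None:
        beta = auto_beta(state.v_fwd, mu0, p_t, geometry, mu_t, config, params)
    state.beta = beta

    e_fwd = _PhaseEnergy(mu0, p_t, geometry, mu_t, beta, config, params)
    e_inv = _PhaseEnergy(mu_t, p_0, geometry, mu0, beta, config, params)

    block = max(1, config.consistency_interval)
    total_energy_log = []
    it = 0
    while it < config.max_iterations:
        n = min(block, config.max_iterations - it)
        hist_f1 = []
        state.v_fwd, f1 = _ncg_steps(e_fwd, state.v_fwd, n, config, "fwd",
                                     hist_f1, it)
        # refresh the phase-t estimate used by f2 and the intensity kernels
        mu_t = warp_volume(mu0, state.v_fwd)
        e_fwd.intensity = mu_t
        e_inv.mu_ref = mu_t
        e_inv.invalidate()
        hist_f2 = []
        state.v_inv, f2 = _ncg_steps(e_inv, state.v_inv, n, config, "inv",
                                     hist_f2, it)

        for a, b in zip(hist_f1, hist_f2):
            state.history.append({
                "iteration": a["iteration"], "f1": a["energy"], "f2": b["energy"],
                "fidelity": a["fidelity"] + b["fidelity"],
                "regularizer": a["regularizer"] + b["regularizer"],
                "step_mm": max(a["step_mm"], b["step_mm"]),
            })
        it += n

        # inverse-consistency projection: average each field with the
        # inversion of its partner
        inv_of_fwd = invert_dvf(state.v_fwd)
        inv_of_inv = invert_dvf(state.v_inv)
        state.v_inv = state.v_inv.like(0.5 * (state.v_inv.data + inv_of_fwd.data))
        state.v_fwd = state.v_fwd.like(0.5 * (state.v_fwd.data + inv_of_inv.data))
        mu_t = warp_volume(mu0, state.v_fwd)
        e_fwd.intensity = mu_t
        e_inv.mu_ref = mu_t
        e_fwd.invalidate()
        e_inv.invalidate()

        total = f1 + f2
        total_energy_log.append(total)
        if len(total_energy_log) >= 2:
            prev = total_energy_log[-2]
            if prev > 0 and (prev - total) / prev < config.tolerance:
                state.converged = True
                break
        if not hist_f1 and not hist_f2:
            # no step accepted in either field: stationary
            state.converged = True
            break

    state.iterations = it
    _, state.consistency_max_mm = consistency_residual(state.v_fwd, state.v_inv)
    return state
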