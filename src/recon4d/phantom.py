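"""Synthetic 4-D digital thorax phantom with analytic sliding motion.

A geometric-primitive stand-in for a licensed anthropomorphic breathing
phantom: elliptic-cylinder torso, two ellipsoidal lungs truncated below by a
spherical diaphragm dome, an ellipsoidal heart, rib arcs embedded in the
chest wall, one intra-lung vessel and one spherical tumor.

Motion model
------------
A cosine breathing waveform ``w(t) = (1 - cos(2 pi t / T)) / 2`` over the
respiratory period scales all displacements; phase 0 (peak exhale) is the
static reference and the phase at half period is peak inhale (w = 1).

The displacement field (pull-back convention, phase 0 -> phase t) has two
parts with deliberately different support:

* superior-inferior (SI): confined to the visceral compartment — the lung
  interiors (with a one-voxel transition band just inside the pleural
  surface) and the heart.  The amplitude ramps from the full diaphragm
  excursion at the lung base to zero near the apex; around the heart it is
  held at the heart amplitude so the tracked heart edge translates rigidly.
* anterior-posterior (AP): a smooth anterior-weighted expansion shared by
  the whole thorax (ribs, chest wall and, attenuated, the viscera), so the
  AP component is continuous everywhere.

Because the SI field stops dead at the pleural surface while the chest wall
carries no SI motion at all, the tangential component of the motion is
discontinuous across the lung/chest-wall interface — the sliding phenomenon
the bilateral regularizer is designed to preserve.

All volumes are produced by evaluating the *analytic* reference phantom at
the displaced coordinates, so phantom phases and ground-truth DVFs are
consistent by construction (up to interpolation when warping voxelized
images).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import DVF, Volume

__all__ = [
    "PhantomSpec",
    "GroundTruthMotion",
    "build_phantom_phase",
    "ground_truth_motion",
    "heart_edge_truth",
    "breathing_weight",
    "heart_edge_roi",
]


@dataclass
class PhantomSpec:
    """Parameters of the 4-D thorax phantom.

    The default grid is the desk-scale 64x64x48 at 2 mm; the study-scale
    256x256x150 at 1 mm grid is selected by configuration.  Motion defaults
    are a 4 s breathing period, 20 mm peak diaphragm SI excursion and 12 mm
    peak anterior chest AP excursion, with a 10 mm SI heart excursion.
    """

    grid_shape: tuple = (48, 64, 64)  # (Z, Y, X)
    voxel_mm: tuple = (2.0, 2.0, 2.0)  # (sz, sy, sx)
    n_phases: int = 10
    period_s: float = 4.0
    diaphragm_si_mm: float = 20.0
    chest_ap_mm: float = 12.0
    heart_si_mm: float = 10.0
    # attenuation values, mm^-1 (roughly water / inflated lung / blood-like)
    intensities: dict = field(default_factory=lambda: {
        "body": 0.020,
        "lung": 0.005,
        "heart": 0.022,
        "rib": 0.032,
        "vessel": 0.018,
        "tumor": 0.024,
    })
    tumor_center_frac: tuple = (-0.05, -0.05, -0.22)  # (z, y, x) of extent
    tumor_radius_mm: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if self.diaphragm_si_mm < 0 or self.chest_ap_mm < 0 or self.heart_si_mm < 0:
            raise ValueError("motion amplitudes must be >= 0")
        if any(v < 0 for v in self.intensities.values()):
            raise ValueError("attenuation values must be >= 0")
        if self.intensities["lung"] >= self.intensities["body"]:
            raise ValueError("lung attenuation must be below body attenuation")
        if self.heart_si_mm > self.diaphragm_si_mm:
            raise ValueError("heart SI amplitude cannot exceed the diaphragm excursion")

    # --- derived geometry (mm, world coordinates, grid centred on axis) ---

    @property
    def extent(self):
        return tuple(n * h for n, h in zip(self.grid_shape, self.voxel_mm))  # (Lz, Ly, Lx)

    def _geom(self):
        Lz, Ly, Lx = self.extent
        g = {}
        g["body_ax"] = 0.45 * Lx
        g["body_ay"] = 0.42 * Ly
        g["lung_centers"] = [(-0.21 * Lx, -0.03 * Ly, 0.08 * Lz),
                             (+0.21 * Lx, -0.03 * Ly, 0.08 * Lz)]  # (x, y, z)
        g["lung_axes"] = (0.16 * Lx, 0.26 * Ly, 0.34 * Lz)
        g["dome_radius"] = 0.28 * min(Lx, Ly)
        g["dome_apex_z"] = 0.08 * Lz - 0.18 * Lz
        g["heart_center"] = (-0.06 * Lx, -0.02 * Ly, 0.10 * Lz)
        g["heart_axes"] = (0.14 * Lx, 0.15 * Ly, 0.22 * Lz)
        g["vessel_xy"] = (+0.24 * Lx, -0.06 * Ly)
        g["vessel_radius"] = max(3.0, 1.2 * self.voxel_mm[2])
        g["vessel_z"] = (0.08 * Lz - 0.20 * Lz, 0.08 * Lz + 0.25 * Lz)
        g["rib_z_step"] = 0.16 * Lz
        g["rib_half_thickness"] = max(1.5, 0.8 * self.voxel_mm[0])
        g["tumor_center"] = (self.tumor_center_frac[2] * Lx,
                             self.tumor_center_frac[1] * Ly,
                             self.tumor_center_frac[0] * Lz)
        # SI amplitude ramp: full at/below z1, zero just below the lung apex
        # (the apex itself stays attached to the static chest wall)
        g["ramp_z1"] = g["dome_apex_z"] + 3.0 * self.voxel_mm[0]
        g["ramp_z2"] = g["lung_centers"][0][2] + 0.8 * g["lung_axes"][2]
        return g

    def reference_volume_template(self) -> Volume:
        return Volume(np.zeros(self.grid_shape), np.asarray(self.voxel_mm))


@dataclass
class GroundTruthMotion:
    """Analytic motion of the phantom: per-phase forward DVFs (0->t,
    pull-back convention), binary lung masks, heart-edge z positions (mm)
    and the pleural (sliding) interface voxel mask."""

    dvfs: list            # DVF per phase, direction "0->t"
    lung_masks: list      # bool ndarray (Z, Y, X) per phase
    heart_edge_z: list    # float mm per phase
    pleural_surface: np.ndarray  # bool ndarray (Z, Y, X), reference phase


def breathing_weight(spec: PhantomSpec, phase: int) -> float:
    """Cosine displacement weight for ``phase``; 0 at phase 0, 1 at half
    period."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * phase / spec.n_phases))


def _voxel_center_mesh(spec: PhantomSpec):
    nz, ny, nx = spec.grid_shape
    hz, hy, hx = spec.voxel_mm
    Lz, Ly, Lx = spec.extent
    z = -Lz / 2 + (np.arange(nz) + 0.5) * hz
    y = -Ly / 2 + (np.arange(ny) + 0.5) * hy
    x = -Lx / 2 + (np.arange(nx) + 0.5) * hx
    return np.meshgrid(z, y, x, indexing="ij")


def _lung_implicit(spec, g, x, y, z, which):
    cx, cy, cz = g["lung_centers"][which]
    ax, ay, az = g["lung_axes"]
    return np.sqrt(((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2)


def _heart_implicit(spec, g, x, y, z):
    cx, cy, cz = g["heart_center"]
    ax, ay, az = g["heart_axes"]
    return np.sqrt(((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2)


def _band_mask(s, r_min, band_mm):
    """Smooth interior mask of an implicit surface s=1: 1 at depth >= band,
    linear transition inside the surface, exactly 0 outside."""
    depth = (1.0 - s) * r_min
    return np.clip(depth / band_mm, 0.0, 1.0)


def _si_ramp(spec, g, z):
    z1, z2 = g["ramp_z1"], g["ramp_z2"]
    return np.clip((z2 - z) / (z2 - z1), 0.0, 1.0)


def _displacement(spec: PhantomSpec, x, y, z, weight: float):
    """Analytic pull-back displacement (phase-t voxel -> phase-0 source), mm.

    Returns (uz, uy, ux) arrays.  ``uz`` points superiorly (+z) inside the
    visceral compartment so inhale structures shift inferiorly; ``uy``
    displaces the chest wall; ``ux`` is identically zero.
    """
    g = spec._geom()
    Lz, Ly, Lx = spec.extent
    band = min(spec.voxel_mm)
    r_min_lung = min(g["lung_axes"])
    r_min_heart = min(g["heart_axes"])

    m_lung = np.maximum(
        _band_mask(_lung_implicit(spec, g, x, y, z, 0), r_min_lung, band),
        _band_mask(_lung_implicit(spec, g, x, y, z, 1), r_min_lung, band),
    )
    m_heart = _band_mask(_heart_implicit(spec, g, x, y, z), r_min_heart, band)
    # dilated heart neighbourhood: holds the SI amplitude at the heart value
    # around the heart so its inferior edge translates rigidly
    s_hd = _heart_implicit(spec, g, x, y, z) / 1.35
    m_heart_nbhd = _band_mask(s_hd, 1.35 * r_min_heart, 3.0 * band)

    amp = (m_heart_nbhd * spec.heart_si_mm
           + (1.0 - m_heart_nbhd) * spec.diaphragm_si_mm * _si_ramp(spec, g, z))
    m_visceral = np.maximum(m_lung, m_heart)
    uz = weight * m_visceral * amp

    # AP expansion is shared smoothly by the whole thorax (anterior-weighted)
    # so the only motion discontinuity is the tangential SI jump at the
    # pleural surface; +uy samples posteriorly, advancing the anterior wall
    ant = np.clip((0.10 * Ly - y) / (0.45 * Ly), 0.0, 1.0)
    uy = weight * spec.chest_ap_mm * ant
    ux = np.zeros_like(uz)
    return uz, uy, ux


def _reference_mu(spec: PhantomSpec, x, y, z) -> np.ndarray:
    """Analytic reference-phase attenuation at arbitrary world points."""
    g = spec._geom()
    I = spec.intensities
    mu = np.zeros_like(x)

    body = ((x / g["body_ax"]) ** 2 + (y / g["body_ay"]) ** 2) <= 1.0
    mu[body] = I["body"]

    # rib arcs: thin shell between two scaled body ellipses at periodic z
    # levels, anterior-lateral sector only
    e_body = (x / g["body_ax"]) ** 2 + (y / g["body_ay"]) ** 2
    shell = (e_body >= 0.80) & (e_body <= 0.97)
    zr = np.mod(z + spec.extent[0] / 2, g["rib_z_step"])
    near_plane = np.minimum(zr, g["rib_z_step"] - zr) <= g["rib_half_thickness"]
    anterior = y <= 0.25 * spec.extent[1]
    mu[shell & near_plane & anterior] = I["rib"]

    dome_cz = g["dome_apex_z"] - g["dome_radius"]
    for which in (0, 1):
        cx, cy, _ = g["lung_centers"][which]
        s = _lung_implicit(spec, g, x, y, z, which)
        lung = s <= 1.0
        dome = ((x - cx) ** 2 + (y - cy) ** 2 + (z - dome_cz) ** 2
                <= g["dome_radius"] ** 2)
        mu[lung & ~dome] = I["lung"]
        mu[lung & dome] = I["body"]

    vx, vy = g["vessel_xy"]
    z0, z1 = g["vessel_z"]
    vessel = (((x - vx) ** 2 + (y - vy) ** 2) <= g["vessel_radius"] ** 2) \
        & (z >= z0) & (z <= z1)
    in_lung_air = (_lung_implicit(spec, g, x, y, z, 1) <= 1.0)
    mu[vessel & in_lung_air] = I["vessel"]

    heart = _heart_implicit(spec, g, x, y, z) <= 1.0
    mu[heart] = I["heart"]

    tx, ty, tz = g["tumor_center"]
    tumor = ((x - tx) ** 2 + (y - ty) ** 2 + (z - tz) ** 2) <= spec.tumor_radius_mm ** 2
    mu[tumor] = I["tumor"]
    return mu


def _reference_lung_mask(spec: PhantomSpec, x, y, z) -> np.ndarray:
    """Lung compartment (air-like lung plus embedded vessel/tumor, minus the
    diaphragm dome and the heart) — the ground truth for Dice scoring."""
    g = spec._geom()
    dome_cz = g["dome_apex_z"] - g["dome_radius"]
    mask = np.zeros(x.shape, dtype=bool)
    for which in (0, 1):
        cx, cy, _ = g["lung_centers"][which]
        s = _lung_implicit(spec, g, x, y, z, which)
        dome = ((x - cx) ** 2 + (y - cy) ** 2 + (z - dome_cz) ** 2
                <= g["dome_radius"] ** 2)
        mask |= (s <= 1.0) & ~dome
    mask &= ~(_heart_implicit(spec, g, x, y, z) <= 1.0)
    return mask


def build_phantom_phase(spec: PhantomSpec, phase: int) -> Volume:
    """Analytic phantom volume at breathing ``phase`` (0-based index)."""
    if not (0 <= phase < spec.n_phases):
        raise ValueError(f"phase {phase} out of range [0, {spec.n_phases})")
    z, y, x = _voxel_center_mesh(spec)
    w = breathing_weight(spec, phase)
    if w == 0.0:
        mu = _reference_mu(spec, x, y, z)
    else:
        uz, uy, ux = _displacement(spec, x, y, z, w)
        mu = _reference_mu(spec, x + ux, y + uy, z + uz)
    return Volume(mu, np.asarray(spec.voxel_mm))


def ground_truth_motion(spec: PhantomSpec) -> GroundTruthMotion:
    """Per-phase analytic DVFs (0->t), lung masks, heart-edge positions and
    the pleural interface mask, all consistent with
    :func:`build_phantom_phase` by construction."""
    z, y, x = _voxel_center_mesh(spec)
    spacing = np.asarray(spec.voxel_mm)
    dvfs, masks = [], []
    for phase in range(spec.n_phases):
        w = breathing_weight(spec, phase)
        uz, uy, ux = _displacement(spec, x, y, z, w)
        dvfs.append(DVF(np.stack([uz, uy, ux]), spacing,
                        direction="0->t", phase=phase))
        masks.append(_reference_lung_mask(spec, x + ux, y + uy, z + uz))
    edges = heart_edge_truth(spec)

    # pleural surface: one-voxel shell of the reference lung compartment
    ref_mask = masks[0]
    shell = ref_mask & ~ndimage.binary_erosion(ref_mask)
    return GroundTruthMotion(dvfs, masks, edges, shell)


def _heart_edge_probe(spec: PhantomSpec):
    """World-coordinate footprint of the heart-edge probe.

    The tracked feature is the *superior* heart edge where the heart bulges
    into the left lung: there the bright heart is roofed by dark lung for the
    whole breathing cycle, so a uniform threshold yields a clean edge (the
    inferior edge is shadowed by the moving diaphragm dome).  Returns
    (x_lo, x_hi, y_lo, y_hi) in mm.
    """
    g = spec._geom()
    cx, cy, _ = g["heart_center"]
    ax = g["heart_axes"][0]
    xp = cx - 0.75 * ax
    return (xp - 2.0, xp + 2.0, cy - 3.0, cy + 3.0)


def _heart_edge_ref_z(spec: PhantomSpec) -> float:
    """Reference-phase z (mm) of the superior heart edge inside the probe
    footprint (the highest heart surface point over the footprint)."""
    g = spec._geom()
    cx, cy, cz = g["heart_center"]
    ax, ay, az = g["heart_axes"]
    x_lo, x_hi, y_lo, y_hi = _heart_edge_probe(spec)
    # the surface maximum over the box sits at the corner closest to centre
    ex = min(((x_lo - cx) / ax) ** 2, ((x_hi - cx) / ax) ** 2)
    ey = min(((y_lo - cy) / ay) ** 2, ((y_hi - cy) / ay) ** 2)
    return cz + az * np.sqrt(max(1.0 - ex - ey, 0.0))


def heart_edge_truth(spec: PhantomSpec) -> list:
    """Analytic z position (mm) of the tracked heart edge per phase.

    The heart translates rigidly in SI by ``heart_si_mm * w(t)``, so the
    edge is the reference edge shifted inferiorly by that amount.
    """
    z_ref = _heart_edge_ref_z(spec)
    return [z_ref - breathing_weight(spec, p) * spec.heart_si_mm
            for p in range(spec.n_phases)]


def heart_edge_roi(spec: PhantomSpec):
    """Voxel-index ROI ``((z0, z1), (y0, y1), (x0, x1))`` (half-open)
    bracketing the tracked heart edge over the whole breathing cycle."""
    hz, hy, hx = spec.voxel_mm
    Lz, Ly, Lx = spec.extent
    nz, ny, nx = spec.grid_shape
    x_lo, x_hi, y_lo, y_hi = _heart_edge_probe(spec)
    z_ref = _heart_edge_ref_z(spec)

    def to_idx(v, L, h, n):
        return int(np.clip(np.floor((v + L / 2) / h), 0, n - 1))

    z0 = to_idx(z_ref - spec.heart_si_mm - 4 * hz, Lz, hz, nz)
    # keep the superior margin tight: one voxel above the reference edge,
    # below the lung-apex transition band
    z1 = to_idx(z_ref + 1.2 * hz, Lz, hz, nz) + 1
    y0 = to_idx(y_lo, Ly, hy, ny)
    y1 = to_idx(y_hi, Ly, hy, ny) + 1
    x0 = to_idx(x_lo, Lx, hx, nx)
    x1 = to_idx(x_hi, Lx, hx, nx) + 1
    return ((z0, z1), (y0, y1), (x0, x1))
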