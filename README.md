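# recon4d

Sliding-motion-compensated simultaneous 4D cone-beam CT reconstruction.

In image-guided radiotherapy of lung cancer, a one-minute gantry rotation
yields only ~20 usable projections per breathing phase, far too few to
reconstruct each phase independently.  `recon4d` implements a
motion-compensated approach for physicists and algorithm researchers
working on respiratory-correlated CBCT: a **motion-compensated SART**
(mSART) reconstructs a single high-quality reference phase `mu^0` from
*all* phases' projections, while per-phase deformation vector fields (DVFs)
are refined by **projection matching** — the forward projection of the
deformed reference is driven toward each phase's measured projections by a
nonlinear conjugate gradient on the symmetric, inverse-consistent energy

    f1(v_0->t) = || p^t - A mu^0(x + v_0->t) ||_2^2 + beta * phi(v_0->t)
    f2(v_t->0) = || p^0 - A mu^t(x + v_t->0) ||_2^2 + beta * phi(v_t->0)

At the lung/chest-wall interface the true motion field is discontinuous:
the lung slides along the pleura while the ribs stay still in the
superior-inferior direction.  An isotropic smoothness penalty
`phi(v) = sum_{i,j} (dv_i/dx_j)^2` smears this jump.  The package's central
piece is a **bilateral-filtering regularizer** whose pair weights combine a
spatial Gaussian (`sigma_x`), an image-intensity Gaussian (`sigma_mu`) and
a displacement-similarity Gaussian (`sigma_v`): where a large DVF jump
coincides with an intensity edge, the weights collapse and the penalty
stops smoothing across the interface — sliding is preserved with no lung
segmentation step.

The package ships a fully synthetic 4-D digital thorax phantom with
analytic ground-truth motion (20 mm diaphragm SI excursion, 12 mm AP chest
expansion, 4 s period, 10 phases) and an exact Siddon cone-beam
projector, so the complete study — simulation, reconstruction, evaluation —
runs from nothing but this repository.

## Worked example

```python
import recon4d as r4d
from recon4d.pipeline import PipelineConfig, simulate_projections

cfg = PipelineConfig()                      # desk-scale: 64x64x48 @ 2 mm
projs, truth = simulate_projections(cfg.phantom, cfg.geometry,
                                    views_per_phase=20)

model = r4d.SlidingRecon4D(projs, cfg.geometry, cfg)
results = model.fit()
print(results.summary())
```

prints (abridged):

```
SlidingRecon4D results
======================
phases:            10
grid:              (48, 64, 64) @ (2.0, 2.0, 2.0) mm
regularizer:       bilateral
beta (per phase):  min 0.000118, max 0.00169
phase 1:  20 accepted steps, energy 37.93 -> 31.54, consistency 0.299 mm
phase 5:  17 accepted steps, energy 461 -> 392.4, consistency 28.022 mm
...
```

Each phase line shows the symmetric energy `f1 + f2` falling over the
accepted conjugate-gradient steps (the optimizer's convergence curve) and
the final inverse-consistency residual, whose maximum sits on the sliding
interface where no exact inverse exists (hence the large value at peak
inhale).  `results.phases` holds the ten reconstructed volumes,
`results.dvfs_fwd` the estimated motion fields.  Scoring against the
phantom truth:

```python
from recon4d.metrics import extract_trajectory, trajectory_rmse_maxe
from recon4d.phantom import heart_edge_roi

roi = heart_edge_roi(cfg.phantom)
thr = 0.5 * (cfg.phantom.intensities["heart"] + cfg.phantom.intensities["lung"])
traj_r = extract_trajectory(results.phases, roi, thr, subvoxel=True)
traj_t = extract_trajectory(truth, roi, thr, subvoxel=True)
rmse, maxe = trajectory_rmse_maxe(traj_r[1:], traj_t[1:])
print("trajectory RMSE %.3f mm, MaxE %.3f mm" % (rmse, maxe))
```

```
trajectory RMSE 0.460 mm, MaxE 0.738 mm
```

`rmse`/`maxe` are the heart-edge trajectory errors in mm over the nine
non-reference phases — the motion-tracking accuracy of the reconstruction,
well under half a voxel here.  Swapping `cfg.dvf.regularizer =
"isotropic"` reruns the study without sliding modelling; its trajectory
error is larger because the smoothed DVF drags the moving heart edge
toward the static chest wall, and the Demons initialization alone is
larger still.

A command-line surface mirrors the library:

```bash
recon4d phantom  --out truth/  --seed 1        # phantom + ground truth
recon4d project  --out proj.h5 --seed 1        # simulate projections
recon4d run      --projections proj.h5 --out run/ --seed 1
recon4d metrics  --truth-dir truth/ --recon-dir run/ --out metrics.json --seed 1
recon4d sweep-sigma-v --out sweep.json --seed 1
```

## Layout

| module | contents |
|---|---|
| `recon4d.phantom` | 4-D digital thorax phantom with analytic sliding motion |
| `recon4d.projector` | Siddon ray tracing, forward/back projection |
| `recon4d.recon` | SART, motion-compensated SART, TV initializer |
| `recon4d.demons` | additive Demons registration (DVF initialization) |
| `recon4d.motion` | warping, field inversion, isotropic + bilateral regularizers |
| `recon4d.optimizer` | symmetric projection-matching energy, NCG |
| `recon4d.pipeline` | `SlidingRecon4D` model / `Recon4DResults`, sigma_v sweep |
| `recon4d.metrics` | trajectory RMSE/MaxE, Dice, relative error |
| `recon4d.io`, `recon4d.cli` | MetaImage/NIfTI/HDF5 IO, YAML config, CLI |

See `docs/methods.md` for the model, parameter defaults and limitations.
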