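"""Readers/writers and configuration: volumes, DVFs, projections, YAML.

Array layout on disk matches the in-memory convention: volumes ``[Z, Y, X]``
and DVFs ``[3, Z, Y, X]`` (components dz, dy, dx, mm, pull-back convention —
stamped into the file metadata so misuse is detectable).  Projection stacks
live in one HDF5 file::

    /phase_{t}/data      (views, rows, cols) float64
    /phase_{t}/angles    (views,) radians
    /geometry            attrs: sad, sdd, pitch, rows, cols

Supported volume formats: .mha / .mhd, .nii / .nii.gz (via SimpleITK) and
.npz with a JSON-compatible sidecar of spacing/origin.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import SimpleITK as sitk
import yaml

from .demons import DemonsConfig
from .geometry import ConeBeamGeometry, ProjectionSet
from .grids import DVF, Volume
from .motion import BilateralParams
from .optimizer import EnergyConfig
from .phantom import PhantomSpec
from .pipeline import PipelineConfig, desk_geometry
from .recon import ReconConfig

__all__ = ["read_volume", "write_volume", "read_dvf", "write_dvf",
           "read_projections", "write_projections", "parse_config",
           "write_manifest"]

_SITK_EXT = (".mha", ".mhd", ".nii", ".nii.gz")


def _sitk_ext(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(e) for e in _SITK_EXT)


def write_volume(volume: Volume, path) -> None:
    path = Path(path)
    if _sitk_ext(path):
        img = sitk.GetImageFromArray(volume.data)  # sitk: index (x,y,z)
        img.SetSpacing(tuple(volume.spacing[::-1]))
        img.SetOrigin(tuple((volume.origin + volume.spacing / 2)[::-1]))
        sitk.WriteImage(img, str(path))
    elif path.suffix == ".npz":
        np.savez(path, data=volume.data, spacing=volume.spacing,
                 origin=volume.origin)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def read_volume(path) -> Volume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _sitk_ext(path):
        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as e:
            raise ValueError(f"unreadable/truncated volume file {path}: {e}") from e
        data = sitk.GetArrayFromImage(img)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3-D volume, got {data.shape}")
        spacing = np.asarray(img.GetSpacing())[::-1]
        origin = np.asarray(img.GetOrigin())[::-1] - spacing / 2
        return Volume(data, spacing, origin)
    if path.suffix == ".npz":
        try:
            with np.load(path) as z:
                return Volume(z["data"], z["spacing"], z["origin"])
        except Exception as e:
            raise ValueError(f"unreadable/truncated volume file {path}: {e}") from e
    raise ValueError(f"unsupported volume format: {path.name}")


def write_dvf(dvf: DVF, path) -> None:
    path = Path(path)
    if _sitk_ext(path):
        # 3-component vector image; sitk component order is (x, y, z)
        arr = np.ascontiguousarray(np.moveaxis(dvf.data[::-1], 0, -1))
        img = sitk.GetImageFromArray(arr, isVector=True)
        img.SetSpacing(tuple(dvf.spacing[::-1]))
        img.SetOrigin(tuple((dvf.origin + dvf.spacing / 2)[::-1]))
        sitk.WriteImage(img, str(path))
        return
    if path.suffix not in (".h5", ".hdf5", ".npz"):
        raise ValueError("DVFs are stored as .mha/.h5/.npz ([3, Z, Y, X], mm)")
    if path.suffix == ".npz":
        np.savez(path, data=dvf.data, spacing=dvf.spacing, origin=dvf.origin,
                 direction=np.bytes_(dvf.direction), phase=dvf.phase)
        return
    with h5py.File(path, "w") as f:
        d = f.create_dataset("dvf", data=dvf.data)
        d.attrs["layout"] = "[3,Z,Y,X] (dz,dy,dx)"
        d.attrs["units"] = "mm"
        d.attrs["convention"] = "pull-back: out(x) = in(x + v(x))"
        d.attrs["direction"] = dvf.direction
        d.attrs["phase"] = dvf.phase
        f.create_dataset("spacing", data=dvf.spacing)
        f.create_dataset("origin", data=dvf.origin)


def read_dvf(path) -> DVF:
    path = Path(path)
    if _sitk_ext(path):
        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise ValueError(f"{path}: expected a 3-component vector image")
        data = np.moveaxis(arr, -1, 0)[::-1]  # (x,y,z) comps -> (dz,dy,dx)
        spacing = np.asarray(img.GetSpacing())[::-1]
        origin = np.asarray(img.GetOrigin())[::-1] - spacing / 2
        return DVF(np.ascontiguousarray(data), spacing, origin)
    if path.suffix == ".npz":
        with np.load(path) as z:
            return DVF(z["data"], z["spacing"], z["origin"],
                       direction=str(z["direction"].item().decode()),
                       phase=int(z["phase"]))
    with h5py.File(path, "r") as f:
        d = f["dvf"]
        return DVF(d[...], f["spacing"][...], f["origin"][...],
                   direction=d.attrs.get("direction", "0->t"),
                   phase=int(d.attrs.get("phase", 0)))


def write_projections(projections, geometry: ConeBeamGeometry, path) -> None:
    """All phases' projection stacks plus geometry attributes, one HDF5."""
    with h5py.File(path, "w") as f:
        g = f.create_group("geometry")
        g.attrs["sad"] = geometry.sad
        g.attrs["sdd"] = geometry.sdd
        g.attrs["rows"] = geometry.det_rows
        g.attrs["cols"] = geometry.det_cols
        g.attrs["pitch"] = geometry.det_pitch
        for p in projections:
            grp = f.create_group(f"phase_{p.phase}")
            grp.create_dataset("data", data=p.data)
            grp.create_dataset("angles", data=p.angles)


def read_projections(path, expected_phases: int | None = None):
    """Returns (list of ProjectionSet ordered by phase, ConeBeamGeometry)."""
    with h5py.File(path, "r") as f:
        if "geometry" not in f:
            raise ValueError(f"{path}: missing /geometry group")
        g = f["geometry"].attrs
        for key in ("sad", "sdd", "rows", "cols", "pitch"):
            if key not in g:
                raise ValueError(f"{path}: /geometry missing attribute {key!r}")
        geometry = ConeBeamGeometry(sad=float(g["sad"]), sdd=float(g["sdd"]),
                                    det_rows=int(g["rows"]), det_cols=int(g["cols"]),
                                    det_pitch=tuple(np.atleast_1d(g["pitch"])[:2]))
        phases = sorted(int(k.split("_")[1]) for k in f if k.startswith("phase_"))
        out = []
        for t in phases:
            grp = f[f"phase_{t}"]
            data, angles = grp["data"][...], grp["angles"][...]
            if data.shape[0] != angles.shape[0]:
                raise ValueError(
                    f"{path} phase {t}: {data.shape[0]} views but "
                    f"{angles.shape[0]} angles")
            out.append(ProjectionSet(data, angles, phase=t))
    if expected_phases is not None and len(out) != expected_phases:
        raise ValueError(f"{path}: expected {expected_phases} phases, "
                         f"found {len(out)}")
    return out, geometry


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def _build_dataclass(cls, block: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(block) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) {path}.{sorted(unknown)}")
    kwargs = {}
    for k, v in block.items():
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def parse_config(path) -> PipelineConfig:
    """Build a validated :class:`PipelineConfig` from a YAML file.

    Recognized top-level blocks: ``phantom``, ``geometry``, ``recon``
    (sub-blocks ``tv`` and ``msart``), ``demons``, ``dvf``, ``bilateral``,
    ``pipeline``.  An empty file yields the full-default desk-scale config;
    unknown keys raise with the offending key path.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    known = {"phantom", "geometry", "recon", "demons", "dvf", "bilateral",
             "pipeline"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config block(s): {sorted(unknown)}")

    cfg = PipelineConfig()
    if "phantom" in raw:
        cfg.phantom = _build_dataclass(PhantomSpec, raw["phantom"] or {}, "phantom")
    if "geometry" in raw:
        cfg.geometry = _build_dataclass(ConeBeamGeometry, raw["geometry"] or {},
                                        "geometry")
    recon = raw.get("recon") or {}
    bad = set(recon) - {"tv", "msart"}
    if bad:
        raise ValueError(f"unknown config key(s) recon.{sorted(bad)}")
    if "tv" in recon:
        cfg.tv = _build_dataclass(ReconConfig, recon["tv"] or {}, "recon.tv")
    if "msart" in recon:
        cfg.msart = _build_dataclass(ReconConfig, recon["msart"] or {},
                                     "recon.msart")
    if "demons" in raw:
        cfg.demons = _build_dataclass(DemonsConfig, raw["demons"] or {}, "demons")
    if "dvf" in raw:
        cfg.dvf = _build_dataclass(EnergyConfig, raw["dvf"] or {}, "dvf")
    if "bilateral" in raw:
        cfg.bilateral = _build_dataclass(BilateralParams, raw["bilateral"] or {},
                                         "bilateral")
    pipe = raw.get("pipeline") or {}
    allowed = {"views_per_phase", "outer_loops", "skip_dvf_opt", "noise_sigma",
               "seed"}
    bad = set(pipe) - allowed
    if bad:
        raise ValueError(f"unknown config key(s) pipeline.{sorted(bad)}")
    for k, v in pipe.items():
        setattr(cfg, k, v)
    cfg.__post_init__()
    return cfg


def _config_dict(cfg: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (tuple, list)):
            return [enc(x) for x in obj]
        return obj
    return {
        "phantom": enc(cfg.phantom), "geometry": enc(cfg.geometry),
        "recon": {"tv": enc(cfg.tv), "msart": enc(cfg.msart)},
        "demons": enc(cfg.demons), "dvf": enc(cfg.dvf),
        "bilateral": enc(cfg.bilateral),
        "pipeline": {"views_per_phase": cfg.views_per_phase,
                     "outer_loops": cfg.outer_loops,
                     "skip_dvf_opt": cfg.skip_dvf_opt,
                     "noise_sigma": cfg.noise_sigma, "seed": cfg.seed},
    }


def write_manifest(cfg: PipelineConfig, out_dir, seed: int,
                   stage_timings: dict = None, file_hashes: dict = None) -> Path:
    """Reproducibility manifest: config snapshot + hash, seed, timings."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    snap = _config_dict(cfg)
    blob = json.dumps(snap, sort_keys=True).encode()
    manifest = {
        "tool": "recon4d", "version": __version__, "seed": seed,
        "config": snap,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "stage_timings_s": stage_timings or {},
        "file_sha256": file_hashes or {},
    }
    path = out_dir / "manifest.json"
    tmp = path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=2))
    tmp.replace(path)  # atomic publish
    return path
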