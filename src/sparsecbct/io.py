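"""File formats, run configuration and the end-to-end pipeline runner.

Volumes are exchanged as NIfTI (spacing and origin in the affine),
projection stacks as HDF5 (datasets ``/frames`` and ``/angles_deg`` plus
geometry attributes and a geometry hash), transforms and configurations
as JSON. CSV output uses 6-significant-digit formatting so repeated runs
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .geometry import ScanGeometry
from .phantoms import Volume
from .projector import ProjectionStack

__all__ = [
    "read_volume",
    "write_volume",
    "read_stack",
    "write_stack",
    "RunConfig",
    "run_pipeline",
    "CSV_FLOAT_FORMAT",
]

CSV_FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def write_volume(volume: Volume, path) -> None:
    """Write a volume as NIfTI; spacing/origin live in the affine."""
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = volume.spacing_mm
    affine[:3, 3] = volume.origin_mm
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32), affine)
    img.header.set_zooms(tuple(float(s) for s in volume.spacing_mm))
    nib.save(img, str(path))


def read_volume(path) -> Volume:
    """Read a NIfTI volume written by :func:`write_volume`.

    Requires an axis-aligned affine (no rotation/shear); raises naming the
    offending header field otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    aff = img.affine
    rot = aff[:3, :3].copy()
    spacing = np.abs(np.diag(rot))
    if np.any(spacing <= 0) or np.abs(rot - np.diag(np.diag(rot))).max() > 1e-6:
        raise ValueError(
            "malformed NIfTI header: affine srow matrix must be diagonal "
            "(axis-aligned) with positive spacing"
        )
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError("malformed NIfTI: dim field is not 3-D")
    return Volume(data, spacing, aff[:3, 3].copy())


# ---------------------------------------------------------------------------
# HDF5 projection stacks
# ---------------------------------------------------------------------------

def _geometry_hash(geom: ScanGeometry) -> str:
    payload = json.dumps(geom.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_stack(stack: ProjectionStack, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=stack.frames, compression="gzip",
                         compression_opts=1)
        f.create_dataset("angles_deg", data=stack.angles_deg)
        f.attrs["geometry"] = json.dumps(stack.geometry.to_dict(), sort_keys=True)
        f.attrs["geometry_hash"] = _geometry_hash(stack.geometry)
        if stack.i0_photons is not None:
            f.attrs["i0_photons"] = float(stack.i0_photons)
        if stack.seed is not None:
            f.attrs["seed"] = int(stack.seed)
        f.attrs["meta"] = json.dumps(stack.meta, sort_keys=True)


def read_stack(path) -> ProjectionStack:
    """Read a stack; warns (via meta) when the geometry hash mismatches."""
    import warnings

    with h5py.File(path, "r") as f:
        for ds in ("frames", "angles_deg"):
            if ds not in f:
                raise ValueError(f"stack file missing dataset /{ds}")
        frames = f["frames"][...]
        angles = f["angles_deg"][...]
        geom = ScanGeometry.from_dict(json.loads(f.attrs["geometry"]))
        stored = f.attrs.get("geometry_hash", "")
        meta = json.loads(f.attrs.get("meta", "{}"))
        i0 = float(f.attrs["i0_photons"]) if "i0_photons" in f.attrs else None
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
    if stored and stored != _geometry_hash(geom):
        warnings.warn("stack geometry hash mismatch: attributes were edited",
                      stacklevel=2)
        meta["geometry_hash_mismatch"] = True
    return ProjectionStack(frames, angles, geom, i0, seed, meta)


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    kind: str = "qa"                 # 'qa' | 'protocol' | 'thorax' | 'nonrigid'
    seed: int = 7
    n_views: int = 240
    schemes: tuple = (1, 2, 3, 4, 5, 6)
    phantom: str = "head"            # protocol runs: 'head' | 'pelvis'
    preset_site: str = "R-H&N"
    conditions: tuple = ("T=2mm", "T=5mm", "R=3deg", "T=2mm,R=3deg")
    mode: str = "bone"
    repeats: int = 3
    out_dir: str = "runs"

    _KINDS = ("qa", "protocol", "thorax", "nonrigid")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: (tuple(v) if isinstance(v, list) else v)
                     for k, v in d.items()})
        if cfg.kind not in cls._KINDS:
            raise ValueError(f"kind must be one of {cls._KINDS}")
        if cfg.repeats < 1 or cfg.n_views < 1:
            raise ValueError("repeats and n_views must be >= 1")
        return cfg

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schemes"] = list(self.schemes)
        d["conditions"] = list(self.conditions)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured study end to end into an artifact directory.

    Writes the result CSV(s), the resolved config with its hash, and a log
    of the seeds used. Re-running the same config reproduces all CSV
    numbers exactly.
    """
    from . import protocol as proto
    from .phantoms import build_rigid_anatomy

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps({**config.to_dict(), "config_hash": config.config_hash},
                   indent=2, sort_keys=True)
    )
    if config.kind == "qa":
        reports, curves = proto.run_qa_study(
            master_seed=config.seed, n_views=config.n_views,
            schemes=config.schemes,
        )
        curves.to_csv(out / "qa_report.csv", index=False,
                      float_format=CSV_FLOAT_FORMAT)
    elif config.kind == "protocol":
        reference = build_rigid_anatomy(config.phantom, seed=config.seed)
        records = proto.run_protocol(
            reference, preset_site=config.preset_site,
            schemes=config.schemes, conditions=config.conditions,
            modes=(config.mode,), repeats=config.repeats,
            master_seed=config.seed, n_views=config.n_views,
        )
        records.to_csv(out / "records.csv", index=False,
                       float_format=CSV_FLOAT_FORMAT)
    elif config.kind == "thorax":
        records = proto.run_thorax_study(
            master_seed=config.seed, schemes=config.schemes,
            repeats=config.repeats, n_views=config.n_views,
        )
        records.to_csv(out / "records.csv", index=False,
                       float_format=CSV_FLOAT_FORMAT)
    else:  # nonrigid
        records = proto.run_nonrigid_study(
            master_seed=config.seed, schemes=config.schemes,
            repeats=config.repeats, n_views=config.n_views,
        )
        records.to_csv(out / "records.csv", index=False,
                       float_format=CSV_FLOAT_FORMAT)
    return out
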