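"""6-DOF rigid transforms with a fixed convention.

Convention used throughout the package:

* parameters ``(tx, ty, tz)`` in mm and ``(rx, ry, rz)`` in degrees;
* the rotation matrix is the fixed-frame (extrinsic) composition
  ``R = Rz(rz) @ Ry(ry) @ Rx(rx)``;
* a transform maps a point ``p`` (mm, in the patient frame whose origin is
  the isocenter) to ``R @ p + t`` — rotation about the isocenter first,
  translation second;
* transforms map *moving* coordinates to *fixed* coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform", "transform_delta"]

_CONVENTION = "fixed-frame Euler ZYX, rotate-then-translate, moving->fixed"


@dataclass(frozen=True)
class RigidTransform:
    """Rigid transform: rotation about the isocenter followed by translation."""

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz], dtype=float)

    @property
    def rotation_deg(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz], dtype=float)

    def rotation_matrix(self) -> np.ndarray:
        # scipy extrinsic 'xyz' composes Rz @ Ry @ Rx, matching the fixed-frame
        # Z.Y.X convention.
        return Rotation.from_euler(
            "xyz", [self.rx, self.ry, self.rz], degrees=True
        ).as_matrix()

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix mapping moving -> fixed coordinates (mm)."""
        m = np.eye(4)
        m[:3, :3] = self.rotation_matrix()
        m[:3, 3] = self.translation
        return m

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array of points (mm)."""
        p = np.asarray(points_mm, dtype=float)
        return p @ self.rotation_matrix().T + self.translation

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        rx, ry, rz = Rotation.from_matrix(m[:3, :3]).as_euler("xyz", degrees=True)
        tx, ty, tz = m[:3, 3]
        return cls(tx, ty, tz, rx, ry, rz)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first, then ``self``)."""
        return RigidTransform.from_matrix(self.matrix() @ other.matrix())

    def inverse(self) -> "RigidTransform":
        r = self.rotation_matrix().T
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = -r @ self.translation
        return RigidTransform.from_matrix(m)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz, self.rx, self.ry, self.rz])

    @classmethod
    def from_params(cls, params) -> "RigidTransform":
        tx, ty, tz, rx, ry, rz = (float(v) for v in params)
        return cls(tx, ty, tz, rx, ry, rz)

    def is_identity(self, atol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.params) <= atol))

    # JSON round trip -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["convention"] = _CONVENTION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        conv = d.get("convention", _CONVENTION)
        if conv != _CONVENTION:
            raise ValueError(f"unsupported transform convention: {conv!r}")
        return cls(*(float(d[k]) for k in ("tx", "ty", "tz", "rx", "ry", "rz")))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def transform_delta(a: RigidTransform, b: RigidTransform):
    """Componentwise parameter difference ``a - b``.

    Mirrors the protocol's baseline-subtraction bookkeeping: registration
    results are compared parameter by parameter, not by transform
    composition (second-order equivalent for small offsets).

    Returns ``(d_translation_mm, d_rotation_deg, translation_norm_mm,
    max_abs_rotation_deg)``.
    """
    dt = a.translation - b.translation
    dr = a.rotation_deg - b.rotation_deg
    return dt, dr, float(np.linalg.norm(dt)), float(np.max(np.abs(dr)))
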