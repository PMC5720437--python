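"""Scanner geometry, site acquisition presets and projection subsampling.

The geometry models an Elekta XVI-class onboard imager: a kV source and a
flat-panel detector rotating about the isocenter, source-to-isocenter
distance 1000 mm, source-to-detector distance 1536 mm, 512x512 panel with
0.8 mm pixels, full 360-degree (full-fan) or 200-degree (half-fan) arcs.

Desk-scale runs keep the physical geometry (distances, field of view,
object sizes in mm) and coarsen only the *sampling*: ``scale_factor`` s < 1
multiplies the detector pixel counts by s and the pixel pitch by 1/s, so
the panel's physical span — hence the fan angle and the SID/SDD ratio — is
unchanged while the number of samples shrinks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

__all__ = [
    "ScanGeometry",
    "AcquisitionPreset",
    "SubsampleScheme",
    "SITES",
    "make_preset",
    "generate_view_angles",
    "subsample_indices",
    "scheme_label",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Flat-panel cone-beam acquisition geometry (lengths in mm)."""

    source_to_isocenter_mm: float = 1000.0
    source_to_detector_mm: float = 1536.0
    detector_cols: int = 512
    detector_rows: int = 512
    pixel_pitch_mm: float = 0.8
    arc_start_deg: float = 0.0
    arc_span_deg: float = 360.0
    rotation_direction: str = "ccw"
    scale_factor: float = 1.0

    def __post_init__(self):
        if not (self.source_to_detector_mm > self.source_to_isocenter_mm > 0):
            raise ValueError("require source_to_detector > source_to_isocenter > 0")
        if not (0 < self.arc_span_deg <= 360):
            raise ValueError("arc_span_deg must lie in (0, 360]")
        if self.detector_cols < 1 or self.detector_rows < 1:
            raise ValueError("detector dimensions must be positive")
        if self.rotation_direction not in ("cw", "ccw"):
            raise ValueError("rotation_direction must be 'cw' or 'ccw'")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")

    @property
    def arc_end_deg(self) -> float:
        sign = 1.0 if self.rotation_direction == "ccw" else -1.0
        return (self.arc_start_deg + sign * self.arc_span_deg) % 360.0

    @property
    def magnification(self) -> float:
        return self.source_to_detector_mm / self.source_to_isocenter_mm

    @property
    def fan_angle_deg(self) -> float:
        """Full in-plane fan opening angle of the panel."""
        half_width = 0.5 * self.detector_cols * self.pixel_pitch_mm
        return 2.0 * math.degrees(math.atan2(half_width, self.source_to_detector_mm))

    @property
    def fov_radius_mm(self) -> float:
        """Radius of the cylinder fully seen by every view (at isocenter)."""
        half_width = 0.5 * self.detector_cols * self.pixel_pitch_mm
        return half_width / self.magnification

    def scaled(self, scale_factor: float) -> "ScanGeometry":
        """Coarsen detector sampling by ``scale_factor`` (see module docs)."""
        if not (0 < scale_factor <= 1):
            raise ValueError("scale_factor must lie in (0, 1]")
        return replace(
            self,
            detector_cols=max(1, round(self.detector_cols * scale_factor)),
            detector_rows=max(1, round(self.detector_rows * scale_factor)),
            pixel_pitch_mm=self.pixel_pitch_mm / scale_factor,
            scale_factor=self.scale_factor * scale_factor,
        )

    def with_detector(self, cols: int, rows: int, pitch_mm: float) -> "ScanGeometry":
        return replace(
            self, detector_cols=cols, detector_rows=rows, pixel_pitch_mm=pitch_mm
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(**d)


@dataclass(frozen=True)
class AcquisitionPreset:
    """One site's scan technique (tube settings, arc, projection count)."""

    site_label: str
    kvp: float
    tube_current_ma: float
    pulse_ms: float
    n_projections: int
    n_projections_registered: int
    arc_start_deg: float
    arc_end_deg: float
    arc_span_deg: float
    collimator: str

    def __post_init__(self):
        if self.n_projections < 1:
            raise ValueError("n_projections must be >= 1")

    @property
    def mas_per_frame(self) -> float:
        """Tube charge per pulse in mAs (current x pulse length)."""
        return self.tube_current_ma * self.pulse_ms / 1000.0

    def geometry(self, scale_factor: float = 1.0) -> ScanGeometry:
        g = ScanGeometry(
            arc_start_deg=self.arc_start_deg, arc_span_deg=self.arc_span_deg
        )
        return g.scaled(scale_factor) if scale_factor != 1.0 else g

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionPreset":
        return cls(**d)


# Site technique table. Arc "183-180" is a full-fan 360-degree rotation and
# "260-100" a half-fan 200-degree short scan; the start angle only sets the
# phase of the view-angle list. The Catphan acquisition registered 668
# frames although its technique row lists 652; both counts are kept and the
# registered count is what QA runs subsample.
_PRESET_ROWS = {
    "Catphan":    dict(kvp=120, ma=30, ms=40, n=652, n_reg=668, arc=(183, 180, 360), coll="S20"),
    "R-H&N":      dict(kvp=100, ma=10, ms=10, n=362, n_reg=362, arc=(260, 100, 200), coll="S20"),
    "R-Thoracic": dict(kvp=120, ma=40, ms=25, n=652, n_reg=652, arc=(183, 180, 360), coll="M20"),
    "R-Pelvis":   dict(kvp=120, ma=40, ms=25, n=652, n_reg=652, arc=(183, 180, 360), coll="M20"),
    "P-Brain":    dict(kvp=100, ma=10, ms=10, n=362, n_reg=362, arc=(260, 100, 200), coll="S20"),
    "P-Lung":     dict(kvp=120, ma=40, ms=25, n=652, n_reg=652, arc=(183, 180, 360), coll="M20"),
    "P-Prostate": dict(kvp=120, ma=40, ms=40, n=652, n_reg=652, arc=(183, 180, 360), coll="M10"),
}

SITES = tuple(_PRESET_ROWS)


def make_preset(site_label: str) -> AcquisitionPreset:
    """Look up the acquisition technique for one of the seven study sites."""
    try:
        row = _PRESET_ROWS[site_label]
    except KeyError:
        raise ValueError(
            f"unknown site {site_label!r}; valid sites: {', '.join(SITES)}"
        ) from None
    start, end, span = row["arc"]
    return AcquisitionPreset(
        site_label=site_label,
        kvp=row["kvp"],
        tube_current_ma=row["ma"],
        pulse_ms=row["ms"],
        n_projections=row["n"],
        n_projections_registered=row["n_reg"],
        arc_start_deg=start,
        arc_end_deg=end,
        arc_span_deg=span,
        collimator=row["coll"],
    )


def generate_view_angles(geometry: ScanGeometry, n_projections: int) -> np.ndarray:
    """Uniformly spaced gantry angles (deg) over the geometry's arc.

    The first angle is the arc start; spacing is ``arc_span / n``; angles are
    reduced modulo 360 so a short scan starting at 260 wraps past 0.
    """
    if n_projections < 1:
        raise ValueError("n_projections must be >= 1")
    sign = 1.0 if geometry.rotation_direction == "ccw" else -1.0
    spacing = geometry.arc_span_deg / n_projections
    return (geometry.arc_start_deg + sign * spacing * np.arange(n_projections)) % 360.0


@dataclass(frozen=True)
class SubsampleScheme:
    """Every-nth-frame retention scheme ("XVI-1/n")."""

    divisor_n: int
    label: str
    retained_indices: tuple  # 1-based frame indices, strictly increasing

    @property
    def n_retained(self) -> int:
        return len(self.retained_indices)

    def select(self, arr: np.ndarray) -> np.ndarray:
        """Subset the leading axis of a per-frame array (0-based internally)."""
        idx = np.asarray(self.retained_indices) - 1
        return arr[idx]


def scheme_label(divisor_n: int) -> str:
    return "XVI-full" if divisor_n == 1 else f"XVI-1/{divisor_n}"


def subsample_indices(n_total: int, divisor_n: int) -> SubsampleScheme:
    """Retain the 1-based frame indices divisible by ``divisor_n``.

    Retains ``{n, 2n, ...} <= n_total``, i.e. ``floor(n_total / n)`` frames;
    divisor 1 keeps every frame.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if divisor_n < 1:
        raise ValueError("divisor_n must be >= 1")
    retained = tuple(range(divisor_n, n_total + 1, divisor_n))
    return SubsampleScheme(
        divisor_n=divisor_n, label=scheme_label(divisor_n), retained_indices=retained
    )
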