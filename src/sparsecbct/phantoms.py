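"""Analytic digital phantoms and their voxelization.

Phantoms are ordered lists of geometric primitives (ellipsoids, cylinders,
boxes) carrying linear attenuation values mu (per mm). Voxelization samples
the primitive list at voxel centers in painter's order: the last primitive
containing a center wins. Because the description is analytic, exact line
integrals through the same primitives are available as an independent
forward-projection route (see :mod:`sparsecbct.projector`).

The generators emulate the study's imaging subjects:

* a cylindrical QA phantom with a line-pair resolution module, a pair of
  low-contrast inserts (polystyrene / LDPE analogues) and a uniform module;
* rigid anatomies (skull-like head, pelvis) — soft-tissue body, bone
  shells/cores, internal air cavities;
* a thoracic anatomy whose spine is a deliberately near-periodic chain of
  vertebrae, so edge-based registration has secondary cost minima one
  vertebra away;
* a smooth free-form deformation to build nonrigid "patient" pairs.

All attenuation values are mu per mm at a nominal ~60 keV effective energy
(water 0.020 /mm, bone 0.048 /mm, lung 0.004 /mm).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .transforms import RigidTransform

__all__ = [
    "MU_AIR",
    "MU_WATER",
    "MU_SOFT",
    "MU_BONE",
    "MU_LUNG",
    "GridSpec",
    "Volume",
    "Primitive",
    "PhantomSpec",
    "DeformationParams",
    "build_qa_phantom",
    "build_rigid_anatomy",
    "build_thoracic_anatomy",
    "build_deformable_pair",
    "apply_rigid",
    "apply_deformation",
]

MU_AIR = 0.0
MU_WATER = 0.020
MU_SOFT = 0.019
MU_BONE = 0.048
MU_LUNG = 0.004

# Low-contrast insert attenuation at ~60 keV, matching the real sensitometry
# materials (polystyrene ~ -35 HU, LDPE ~ -100 HU): each within a few percent
# of the water background, ~6.5% apart from each other.
MU_POLYSTYRENE = 0.0193
MU_LDPE = 0.0180


@dataclass(frozen=True)
class GridSpec:
    """Reconstruction/voxelization grid: shape in voxels, spacing in mm.

    The grid is centered on the isocenter unless an explicit origin (world
    position of the center of voxel (0, 0, 0)) is given. Axis order of the
    voxel array is (x, y, z).
    """

    shape: tuple
    spacing_mm: tuple
    origin_mm: tuple | None = None

    def __post_init__(self):
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be three positive integers")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be three positive lengths")

    @property
    def origin(self) -> np.ndarray:
        if self.origin_mm is not None:
            return np.asarray(self.origin_mm, dtype=float)
        sh = np.asarray(self.shape, dtype=float)
        sp = np.asarray(self.spacing_mm, dtype=float)
        return -0.5 * (sh - 1) * sp

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing_mm[axis]

    @classmethod
    def cube(cls, n: int, spacing: float) -> "GridSpec":
        return cls((n, n, n), (spacing, spacing, spacing))


DEFAULT_GRID = GridSpec.cube(160, 1.25)


@dataclass
class Volume:
    """Scalar attenuation volume on a regular grid (axis order x, y, z)."""

    voxels: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.shape, tuple(self.spacing_mm), tuple(self.origin_mm))

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        return (np.asarray(points_mm, dtype=float) - self.origin_mm) / self.spacing_mm

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin_mm + np.asarray(idx, dtype=float) * self.spacing_mm

    def sample(self, points_mm: np.ndarray, order: int = 1, cval: float = MU_AIR):
        """Interpolate voxel values at world points (trilinear by default)."""
        idx = self.world_to_index(np.atleast_2d(points_mm))
        return ndimage.map_coordinates(
            self.voxels.astype(float, copy=False), idx.T, order=order,
            mode="constant", cval=cval,
        )

    def copy(self) -> "Volume":
        return Volume(self.voxels.copy(), self.spacing_mm.copy(), self.origin_mm.copy())

    def downsample(self, factor: int) -> "Volume":
        """Block-mean downsampling (used by the multiresolution registration)."""
        if factor == 1:
            return self
        f = int(factor)
        sh = [s // f for s in self.shape]
        if min(sh) < 1:
            raise ValueError("downsample factor larger than volume")
        v = self.voxels[: sh[0] * f, : sh[1] * f, : sh[2] * f]
        v = v.reshape(sh[0], f, sh[1], f, sh[2], f).mean(axis=(1, 3, 5))
        origin = self.origin_mm + 0.5 * (f - 1) * self.spacing_mm
        return Volume(v, self.spacing_mm * f, origin)


@dataclass(frozen=True)
class Primitive:
    """One analytic solid: 'ellipsoid', 'cylinder' (axis z) or 'box'.

    ``rotation_deg`` rotates the solid about the world z axis about its own
    center; ``semi_axes_mm`` are the half-extents along the solid's local
    axes (for a cylinder: radius_x, radius_y, half_length_z).
    """

    shape: str
    center_mm: tuple
    semi_axes_mm: tuple
    mu: float
    rotation_deg: float = 0.0

    def __post_init__(self):
        if self.shape not in ("ellipsoid", "cylinder", "box"):
            raise ValueError(f"unknown primitive shape {self.shape!r}")
        if self.mu < 0:
            raise ValueError("attenuation must be non-negative")

    def _local(self, pts: np.ndarray) -> np.ndarray:
        """World points -> local frame (center subtracted, z-rotation undone)."""
        q = pts - np.asarray(self.center_mm)
        if self.rotation_deg:
            a = np.deg2rad(self.rotation_deg)
            c, s = np.cos(a), np.sin(a)
            x = c * q[..., 0] + s * q[..., 1]
            y = -s * q[..., 0] + c * q[..., 1]
            q = np.stack([x, y, q[..., 2]], axis=-1)
        return q

    def contains(self, pts: np.ndarray) -> np.ndarray:
        q = self._local(np.asarray(pts, dtype=float))
        a = np.asarray(self.semi_axes_mm, dtype=float)
        if self.shape == "ellipsoid":
            return (q / a).__pow__(2).sum(axis=-1) <= 1.0
        if self.shape == "cylinder":
            r2 = (q[..., 0] / a[0]) ** 2 + (q[..., 1] / a[1]) ** 2
            return (r2 <= 1.0) & (np.abs(q[..., 2]) <= a[2])
        return np.all(np.abs(q) <= a, axis=-1)

    def bounding_box(self) -> tuple:
        """Conservative world-axis-aligned bounds (lo, hi), mm."""
        a = np.asarray(self.semi_axes_mm, dtype=float)
        r_xy = float(np.hypot(a[0], a[1])) if self.shape == "box" else float(max(a[0], a[1]))
        if self.rotation_deg == 0.0 and self.shape == "box":
            half = a
        else:
            half = np.array([r_xy, r_xy, a[2]])
        c = np.asarray(self.center_mm, dtype=float)
        return c - half, c + half

    @property
    def bounding_radius(self) -> float:
        a = np.asarray(self.semi_axes_mm, dtype=float)
        return float(np.linalg.norm(a))


@dataclass
class PhantomSpec:
    """Ordered primitive list plus named ROI annotations.

    Later primitives overwrite earlier ones where they overlap (painter's
    order). ``annotations`` is a JSON-serializable dict of named regions of
    interest and measurement points used by the QA analyses.
    """

    name: str
    primitives: list
    grid: GridSpec
    annotations: dict = field(default_factory=dict)

    def voxelize(self, grid: GridSpec | None = None, supersample: int = 1) -> Volume:
        """Sample mu at voxel centers (optionally 2x supersampled then averaged)."""
        grid = grid or self.grid
        if supersample < 1:
            raise ValueError("supersample must be >= 1")
        ss = int(supersample)
        shape = tuple(int(s) * ss for s in grid.shape)
        spacing = np.asarray(grid.spacing_mm) / ss
        origin = grid.origin - (ss - 1) / 2.0 * spacing
        vox = np.zeros(shape, dtype=np.float32)
        xs = origin[0] + np.arange(shape[0]) * spacing[0]
        ys = origin[1] + np.arange(shape[1]) * spacing[1]
        zs = origin[2] + np.arange(shape[2]) * spacing[2]
        for prim in self.primitives:
            lo, hi = prim.bounding_box()
            i0 = np.searchsorted(xs, lo[0] - spacing[0])
            i1 = np.searchsorted(xs, hi[0] + spacing[0])
            j0 = np.searchsorted(ys, lo[1] - spacing[1])
            j1 = np.searchsorted(ys, hi[1] + spacing[1])
            k0 = np.searchsorted(zs, lo[2] - spacing[2])
            k1 = np.searchsorted(zs, hi[2] + spacing[2])
            if i0 >= i1 or j0 >= j1 or k0 >= k1:
                continue
            gx, gy, gz = np.meshgrid(
                xs[i0:i1], ys[j0:j1], zs[k0:k1], indexing="ij", sparse=False
            )
            pts = np.stack([gx, gy, gz], axis=-1)
            mask = prim.contains(pts)
            sub = vox[i0:i1, j0:j1, k0:k1]
            sub[mask] = prim.mu
        if ss > 1:
            vol = Volume(vox, spacing, origin)
            return vol.downsample(ss)
        return Volume(vox, spacing, origin)

    def roi_mask(self, volume: Volume, roi_name: str) -> np.ndarray:
        roi = self.annotations["rois"][roi_name]
        prim = Primitive(
            shape=roi["shape"], center_mm=tuple(roi["center_mm"]),
            semi_axes_mm=tuple(roi["semi_axes_mm"]), mu=0.0,
            rotation_deg=roi.get("rotation_deg", 0.0),
        )
        g = volume.grid
        gx, gy, gz = np.meshgrid(
            g.axis_coords(0), g.axis_coords(1), g.axis_coords(2),
            indexing="ij", sparse=False,
        )
        return prim.contains(np.stack([gx, gy, gz], axis=-1))


# ---------------------------------------------------------------------------
# QA phantom
# ---------------------------------------------------------------------------

QA_BODY_RADIUS_MM = 100.0
QA_MODULE_HALF_LENGTH_MM = 15.0
# module axial centers: resolution / low contrast / uniformity
QA_MODULE_Z_MM = {"resolution": -50.0, "low_contrast": 0.0, "uniform": 50.0}
LP_FREQS_PER_CM = tuple(range(1, 10))
LP_GROUP_RADIUS_MM = 45.0
MU_LP_BAR = MU_BONE  # aluminium-like high-contrast gauge bars


def _lp_bars_per_group(freq: int) -> int:
    # wide low-frequency groups carry fewer bars so neighbours don't collide
    return 3 if freq == 1 else (4 if freq == 2 else 5)


def build_qa_phantom(grid: GridSpec = DEFAULT_GRID) -> tuple:
    """Cylindrical QA phantom with resolution, low-contrast, uniform modules.

    Returns ``(volume, spec)``. The resolution module holds radial bar
    groups at 1..9 line pairs per cm (bar width = 1/(2f) cm); the
    low-contrast module holds polystyrene / LDPE-like inserts at the 7 and
    9 o'clock positions; the third module is uniform water-equivalent.

    Raises if the grid cannot contain the 20 cm-diameter body.
    """
    half_extent = (np.asarray(grid.shape) - 1) / 2.0 * np.asarray(grid.spacing_mm)
    if half_extent[0] < QA_BODY_RADIUS_MM - 1 or half_extent[1] < QA_BODY_RADIUS_MM - 1:
        raise ValueError(
            f"grid half-extent {tuple(np.round(half_extent, 1))} mm too small "
            f"for a {QA_BODY_RADIUS_MM:.0f} mm-radius phantom"
        )

    prims = [
        Primitive("cylinder", (0, 0, 0),
                  (QA_BODY_RADIUS_MM, QA_BODY_RADIUS_MM, 90.0), MU_WATER)
    ]
    ann: dict = {"rois": {}, "lp_groups": {}, "module_z_mm": dict(QA_MODULE_Z_MM)}

    # --- resolution module: radial bar groups --------------------------
    z_res = QA_MODULE_Z_MM["resolution"]
    for gi, f in enumerate(LP_FREQS_PER_CM):
        w = 10.0 / (2.0 * f)  # bar width in mm (= gap width)
        theta = np.deg2rad(gi * (360.0 / len(LP_FREQS_PER_CM)))
        cx = LP_GROUP_RADIUS_MM * np.cos(theta)
        cy = LP_GROUP_RADIUS_MM * np.sin(theta)
        rot = np.rad2deg(theta)  # bars run radially; pattern repeats tangentially
        bar_len = 8.0
        n_bars = _lp_bars_per_group(f)
        bar_centers, gap_centers = [], []
        for b in range(n_bars):
            off = (b - (n_bars - 1) / 2.0) * 2.0 * w
            # local offset along the tangential direction, rotated to world
            dx = -off * np.sin(theta)
            dy = off * np.cos(theta)
            prims.append(
                Primitive("box", (cx + dx, cy + dy, z_res),
                          (bar_len / 2.0, w / 2.0, 10.0), MU_LP_BAR,
                          rotation_deg=rot)
            )
            bar_centers.append([cx + dx, cy + dy, z_res])
            if b < n_bars - 1:
                goff = off + w
                gap_centers.append(
                    [cx - goff * np.sin(theta), cy + goff * np.cos(theta), z_res]
                )
        ann["lp_groups"][str(f)] = {
            "freq_lp_per_cm": f,
            "bar_width_mm": w,
            "bar_centers_mm": bar_centers,
            "gap_centers_mm": gap_centers,
        }

    # --- low-contrast module: polystyrene (7 o'clock) / LDPE (9 o'clock)
    z_lc = QA_MODULE_Z_MM["low_contrast"]
    r_ins, rad_ins = 50.0, 8.0
    for name, mu, clock in (("polystyrene", MU_POLYSTYRENE, 7),
                            ("LDPE", MU_LDPE, 9)):
        a = np.deg2rad(90.0 - clock * 30.0)  # 12 o'clock = +y
        c = (r_ins * np.cos(a), r_ins * np.sin(a), z_lc)
        prims.append(
            Primitive("cylinder", c, (rad_ins, rad_ins, QA_MODULE_HALF_LENGTH_MM), mu)
        )
        ann["rois"][name] = {
            "shape": "cylinder", "center_mm": list(c),
            "semi_axes_mm": [5.5, 5.5, 12.0],
        }
    ann["rois"]["lc_background"] = {
        "shape": "cylinder", "center_mm": [0.0, 0.0, z_lc],
        "semi_axes_mm": [15.0, 15.0, 8.0],
    }

    # --- uniformity module: four 1x1 cm probe windows at 70% radius -----
    z_u = QA_MODULE_Z_MM["uniform"]
    r_probe = 0.7 * QA_BODY_RADIUS_MM
    for name, ang in (("u12", 90), ("u3", 0), ("u6", -90), ("u9", 180)):
        a = np.deg2rad(ang)
        ann["rois"][name] = {
            "shape": "box",
            "center_mm": [r_probe * np.cos(a), r_probe * np.sin(a), z_u],
            "semi_axes_mm": [5.0, 5.0, 5.0],
        }
    ann["rois"]["uniform_center"] = {
        "shape": "box", "center_mm": [0.0, 0.0, z_u], "semi_axes_mm": [5.0, 5.0, 5.0],
    }

    spec = PhantomSpec("qa_phantom", prims, grid, ann)
    return spec.voxelize(), spec


# ---------------------------------------------------------------------------
# Rigid anatomies
# ---------------------------------------------------------------------------

def _jitter(rng: np.random.Generator, scale: float) -> float:
    return float(rng.uniform(-scale, scale))


def build_rigid_anatomy(site: str, seed: int = 0,
                        grid: GridSpec = DEFAULT_GRID,
                        gas_seed: int | None = None) -> Volume:
    """Skull-like head or pelvis: soft tissue + bone + internal air.

    Deterministic for a given seed; the seed drives small jitters in
    feature positions/sizes so different seeds give distinct but
    comparable anatomies. Asymmetric bone features (orbital ridges, jaw /
    sacrum, femoral heads) make all six rigid degrees of freedom
    observable from edges.

    ``gas_seed`` (pelvis only) controls bowel-gas pocket placement
    independently of the rest of the anatomy: two volumes built with the
    same ``seed`` but different ``gas_seed`` are the same patient with
    different bowel contents — the day-to-day change that gives pelvic
    registration non-corresponding structures.
    """
    rng = np.random.default_rng(seed)
    gas_rng = np.random.default_rng(seed + 77 if gas_seed is None else gas_seed)
    prims: list = []
    if site == "head":
        j = _jitter
        # soft tissue scalp/face
        prims.append(Primitive("ellipsoid", (0, j(rng, 2), -5),
                               (78 + j(rng, 2), 92 + j(rng, 2), 85), MU_SOFT))
        # skull: outer bone shell, then brain-like interior
        prims.append(Primitive("ellipsoid", (0, 2, 0), (70, 84, 76), MU_BONE))
        # natural-skeleton surface irregularity: small bony bumps scattered
        # over the cranium (decorrelates edge-localization bias that a
        # perfectly smooth parametric shell would make orientation-coherent)
        for _ in range(30):
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            c = np.array([0, 2, 0]) + d * np.array([70, 84, 76])
            prims.append(Primitive(
                "ellipsoid", tuple(c),
                (rng.uniform(3, 7), rng.uniform(3, 7), rng.uniform(3, 7)),
                MU_BONE, rotation_deg=_jitter(rng, 45),
            ))
        prims.append(Primitive("ellipsoid", (0, 2, 0), (63, 77, 69), MU_SOFT * 1.05))
        # air cavities: frontal sinus, nasal airway, ear canals
        prims.append(Primitive("ellipsoid", (0, 62 + j(rng, 2), -18),
                               (12, 9, 8), MU_AIR))
        prims.append(Primitive("ellipsoid", (0, 74, -42), (9, 14, 16), MU_AIR))
        prims.append(Primitive("ellipsoid", (58, 0, -30), (7, 7, 5), MU_AIR))
        prims.append(Primitive("ellipsoid", (-58, 0, -30), (7, 7, 5), MU_AIR))
        # orbital ridges / jaw: break left-right vs up-down symmetry
        prims.append(Primitive("box", (26, 64, -28), (12, 8, 6), MU_BONE,
                               rotation_deg=12))
        prims.append(Primitive("box", (-26, 64, -28), (12, 8, 6), MU_BONE,
                               rotation_deg=-12))
        prims.append(Primitive("ellipsoid", (0, 58 + j(rng, 2), -62),
                               (34, 22, 12), MU_BONE))
        prims.append(Primitive("ellipsoid", (0, 56, -62), (28, 16, 8), MU_SOFT))
        # teeth row along the jaw arc: strong, peripheral rotation landmarks
        for ang in range(-60, 61, 20):
            a = np.deg2rad(90 - ang)
            prims.append(Primitive("box",
                                   (30 * np.cos(a), 42 + 26 * np.sin(a), -70),
                                   (3.5, 3.5, 6), MU_BONE * 1.15,
                                   rotation_deg=-ang))
        # mastoid processes (left/right, different heights) and occipital bump
        prims.append(Primitive("ellipsoid", (52, -28, -52), (9, 9, 13), MU_BONE))
        prims.append(Primitive("ellipsoid", (-52, -28, -46), (9, 9, 13), MU_BONE))
        prims.append(Primitive("ellipsoid", (0, -80, -18 + j(rng, 2)),
                               (16, 10, 20), MU_BONE))
        # nasal septum
        prims.append(Primitive("box", (0, 70, -40), (2, 10, 14), MU_BONE))
        # cervical vertebrae stub
        for k in range(3):
            prims.append(Primitive("cylinder", (0, -38, -62 - 14 * k),
                                   (11, 11, 5), MU_BONE))
    elif site == "pelvis":
        prims.append(Primitive("ellipsoid", (0, 0, 0),
                               (96 + _jitter(rng, 2), 74 + _jitter(rng, 2), 92),
                               MU_SOFT))
        # iliac wings: two tilted bone slabs
        prims.append(Primitive("box", (52, 18, 25), (26, 7, 38), MU_BONE,
                               rotation_deg=35 + _jitter(rng, 3)))
        prims.append(Primitive("box", (-52, 18, 25), (26, 7, 38), MU_BONE,
                               rotation_deg=-35 - _jitter(rng, 3)))
        # sacrum + lumbar stub
        prims.append(Primitive("box", (0, -40, 30), (16, 12, 30), MU_BONE))
        prims.append(Primitive("cylinder", (0, -36, 72), (12, 12, 14), MU_BONE))
        # femoral heads and necks
        prims.append(Primitive("ellipsoid", (44, -6, -40), (16, 16, 16), MU_BONE))
        prims.append(Primitive("ellipsoid", (-44, -6, -40), (16, 16, 16), MU_BONE))
        prims.append(Primitive("cylinder", (58, -6, -70), (10, 10, 22), MU_BONE))
        prims.append(Primitive("cylinder", (-58, -6, -70), (10, 10, 22), MU_BONE))
        # bladder (water-like) and rectal gas: internal soft contrast + air
        prims.append(Primitive("ellipsoid", (0, 22, -18), (22, 18, 18),
                               MU_WATER * 1.02))
        prims.append(Primitive("ellipsoid", (0, -28 + _jitter(rng, 3), -16),
                               (10, 12, 20), MU_AIR))
        # prostate-like gland between bladder and rectum
        prims.append(Primitive("ellipsoid", (0, -2, -28), (13, 11, 11),
                               MU_WATER * 1.04))
        # soft-tissue texture: low-contrast blobs throughout the body (fat
        # planes, muscle bundles, bowel). Real anatomy is textured at every
        # scale; an untextured body gives intensity registration an
        # unrealistically smooth, convex cost landscape.
        for _ in range(60):
            c = rng.uniform(-1, 1, 3) * np.array([80, 60, 75])
            if (c[0] / 96) ** 2 + (c[1] / 74) ** 2 + (c[2] / 92) ** 2 > 0.8:
                continue
            prims.append(Primitive(
                "ellipsoid", tuple(c),
                tuple(rng.uniform(5, 18, 3)),
                MU_SOFT * rng.uniform(0.96, 1.05),
                rotation_deg=_jitter(rng, 60),
            ))
        # bowel-gas pockets (tissue-air edges whose presence and position
        # change between scan days; drawn from the dedicated gas generator)
        for _ in range(3):
            c = (gas_rng.uniform(-45, 45), gas_rng.uniform(-10, 35),
                 gas_rng.uniform(10, 60))
            prims.append(Primitive("ellipsoid", c,
                                   tuple(gas_rng.uniform(6, 12, 3)),
                                   MU_AIR, rotation_deg=_jitter(gas_rng, 60)))
    else:
        raise ValueError(f"unknown rigid anatomy site {site!r}; use 'head' or 'pelvis'")
    spec = PhantomSpec(f"rigid_{site}", prims, grid)
    return spec.voxelize()


def build_thoracic_anatomy(n_vertebrae: int = 6, pitch_mm: float = 25.0,
                           seed: int = 0, grid: GridSpec = DEFAULT_GRID) -> Volume:
    """Thorax with a near-periodic spine (secondary minima at +-pitch).

    The vertebral chain repeats at ``pitch_mm`` (matching 2.5 cm slab
    spacing); ribs attach at every level. The deliberate periodicity gives
    the chamfer cost secondary minima one vertebra superior/inferior.
    """
    if n_vertebrae < 1:
        raise ValueError("n_vertebrae must be >= 1")
    rng = np.random.default_rng(seed)
    prims = [Primitive("ellipsoid", (0, 0, 0), (92, 70, 95), MU_SOFT)]
    # lungs
    prims.append(Primitive("ellipsoid", (40, 8, 5), (34, 44, 78), MU_LUNG))
    prims.append(Primitive("ellipsoid", (-40, 8, 5), (34, 44, 78), MU_LUNG))
    z0 = -0.5 * (n_vertebrae - 1) * pitch_mm
    for k in range(n_vertebrae):
        z = z0 + k * pitch_mm
        # vertebral body + spinous process (identical at every level)
        prims.append(Primitive("cylinder", (0, -48, z), (13, 13, 7), MU_BONE))
        prims.append(Primitive("box", (0, -64, z), (4, 10, 5), MU_BONE))
        # rib pair: thin tilted slabs hugging the lungs
        for sgn in (1, -1):
            prims.append(Primitive("box", (sgn * 55, -10, z + 4),
                                   (6, 42, 3), MU_BONE,
                                   rotation_deg=sgn * 70))
    # one weak unique landmark (heart-like) so the global minimum exists
    prims.append(Primitive("ellipsoid", (-12 + _jitter(rng, 2), 26, -8),
                           (26, 24, 30), MU_WATER * 1.03))
    spec = PhantomSpec("thorax", prims, grid)
    return spec.voxelize()


# ---------------------------------------------------------------------------
# Volume transformation: rigid resampling and smooth deformation
# ---------------------------------------------------------------------------

def apply_rigid(volume: Volume, transform: RigidTransform,
                interpolation: str = "trilinear") -> Volume:
    """Resample ``volume`` under a rigid transform, on the same grid.

    The transform maps input-volume coordinates to output coordinates
    (moving -> fixed), so the resampler pulls back through its inverse.
    Out-of-field voxels are set to air.
    """
    orders = {"trilinear": 1, "nearest": 0, "cubic": 3}
    if interpolation not in orders:
        raise ValueError("interpolation must be 'trilinear', 'nearest' or 'cubic'")
    if transform.is_identity():
        return volume.copy()
    r_inv = transform.rotation_matrix().T
    sp = volume.spacing_mm
    # input_index = D^-1 (R^T (origin + D i - t) - origin)
    a = (r_inv * sp[None, :]) / sp[:, None]
    off = (r_inv @ (volume.origin_mm - transform.translation) - volume.origin_mm) / sp
    out = ndimage.affine_transform(
        volume.voxels.astype(np.float32, copy=False), a, offset=off,
        order=orders[interpolation], mode="constant", cval=MU_AIR,
        output=np.float32,
    )
    if interpolation == "cubic":
        np.clip(out, 0.0, None, out=out)  # suppress spline undershoot
    return Volume(out, sp.copy(), volume.origin_mm.copy())


@dataclass
class DeformationParams:
    """Smooth random free-form deformation confined to an ellipsoidal mask.

    * ``amplitude_mm`` — scale of control-point displacements;
    * ``smoothness_mm`` — correlation length of the displacement field;
    * ``mask_center_mm`` / ``mask_semi_axes_mm`` — region that deforms
      (displacement tapers smoothly to zero at the mask boundary);
    * ``max_displacement_mm`` — hard bound; exceeding it is an error.
    """

    amplitude_mm: float = 4.0
    smoothness_mm: float = 30.0
    mask_center_mm: tuple = (0.0, 0.0, 0.0)
    mask_semi_axes_mm: tuple = (70.0, 70.0, 70.0)
    max_displacement_mm: float = 15.0
    seed: int = 0


def _displacement_field(volume: Volume, params: DeformationParams) -> np.ndarray:
    """(3, nx, ny, nz) smooth displacement in mm, zero outside the mask."""
    rng = np.random.default_rng(params.seed)
    sigma_vox = params.smoothness_mm / volume.spacing_mm
    field_ = rng.standard_normal((3,) + volume.shape)
    for c in range(3):
        field_[c] = ndimage.gaussian_filter(field_[c], sigma=sigma_vox)
        s = field_[c].std()
        if s > 0:
            field_[c] *= params.amplitude_mm / (3.0 * s)  # ~3 sigma = amplitude
    g = volume.grid
    gx, gy, gz = np.meshgrid(g.axis_coords(0), g.axis_coords(1), g.axis_coords(2),
                             indexing="ij", sparse=False)
    q = np.stack([gx, gy, gz], axis=0)
    c = np.asarray(params.mask_center_mm)[:, None, None, None]
    a = np.asarray(params.mask_semi_axes_mm)[:, None, None, None]
    r2 = (((q - c) / a) ** 2).sum(axis=0)
    taper = np.clip(1.0 - r2, 0.0, None) ** 2  # C1, zero outside the ellipsoid
    return field_ * taper[None]


def apply_deformation(volume: Volume, params: DeformationParams) -> tuple:
    """Warp a volume with a smooth masked displacement field.

    Returns ``(warped_volume, displacement_field_mm)`` where the field is
    the backward map: ``warped(x) = volume(x + u(x))``. Raises if the
    field exceeds ``params.max_displacement_mm``.
    """
    u = _displacement_field(volume, params)
    maxd = float(np.abs(u).max())
    if maxd > params.max_displacement_mm:
        raise ValueError(
            f"max displacement {maxd:.2f} mm exceeds bound "
            f"{params.max_displacement_mm:.2f} mm"
        )
    if params.amplitude_mm == 0:
        return volume.copy(), u
    g = volume.grid
    idx = np.indices(volume.shape, dtype=np.float32)
    coords = idx + (u / volume.spacing_mm[:, None, None, None]).astype(np.float32)
    warped = ndimage.map_coordinates(
        volume.voxels.astype(np.float32, copy=False), coords, order=1,
        mode="constant", cval=MU_AIR,
    )
    return Volume(warped, volume.spacing_mm.copy(), volume.origin_mm.copy()), u


def build_deformable_pair(seed: int = 0, grid: GridSpec = DEFAULT_GRID,
                          params: DeformationParams | None = None) -> tuple:
    """Nonrigid 'patient' pair: (reference, deformed) pelvis-like volumes.

    The treatment-day volume differs from the reference by (a) a smooth
    deformation (bladder/rectum filling squeezing the gland and nearby
    tissue) and (b) independently placed bowel-gas pockets — structures
    with no counterpart in the reference, as between a planning CT and a
    treatment-day scan. The rigid component of the ground truth is the
    identity, so registration error remains well defined as deviation
    from it.
    """
    ref = build_rigid_anatomy("pelvis", seed=seed, grid=grid)
    day2 = build_rigid_anatomy("pelvis", seed=seed, grid=grid,
                               gas_seed=seed + 1009)
    if params is None:
        params = DeformationParams(
            amplitude_mm=12.0, smoothness_mm=25.0,
            mask_center_mm=(0.0, -10.0, -25.0),
            mask_semi_axes_mm=(85.0, 70.0, 75.0),
            max_displacement_mm=15.0, seed=seed + 1,
        )
    warped, u = apply_deformation(day2, params)
    return ref, warped, u
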