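"""QA-phantom image-quality analyses.

Three analyses mirror a kV-CBCT acceptance test on a Catphan-class
phantom:

* **spatial resolution** — the highest line-pair frequency (lp/cm) whose
  bar pattern retains a minimum modulation in the reconstruction;
* **low-contrast visibility (LCV)** — ``5.5 * mean(SD) / |dMean|`` over
  the polystyrene and LDPE insert ROIs: large when ROI noise overwhelms
  the true insert contrast;
* **uniformity** — ``(max(mean) - min(mean)) / max(mean)`` over four
  1 x 1 cm probe windows in the uniform module.

All metrics are plain fractions of the attenuation scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantoms import PhantomSpec, Volume

__all__ = [
    "RoiStats",
    "QaReport",
    "roi_stats",
    "low_contrast_visibility",
    "uniformity",
    "resolvable_line_pairs",
    "qa_curves",
]

LCV_FACTOR = 5.5
LCV_SPEC = 0.02
UNIFORMITY_SPEC = 0.02
RESOLUTION_SPEC_LP_PER_CM = 7
DEFAULT_MODULATION_THRESHOLD = 0.1
UNIFORMITY_ROI_NAMES = ("u12", "u3", "u6", "u9")


@dataclass(frozen=True)
class RoiStats:
    roi_name: str
    mean: float
    sd: float
    n_voxels: int


def roi_stats(volume: Volume, spec: PhantomSpec, roi_name: str) -> RoiStats:
    """Sample mean and SD (ddof=1) over an annotated ROI's voxels."""
    mask = spec.roi_mask(volume, roi_name)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"ROI {roi_name!r} covers no voxels of this grid")
    vals = volume.voxels[mask].astype(np.float64)
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return RoiStats(roi_name, float(vals.mean()), sd, n)


def low_contrast_visibility(stats_a: RoiStats, stats_b: RoiStats) -> float:
    """LCV = 5.5 * mean(SD) / |mean_a - mean_b| (dimensionless fraction).

    Large values mean ROI noise swamps the true material contrast, i.e.
    poor low-contrast visibility. Raises when the two means coincide
    (contrast undefined).
    """
    dmean = abs(stats_a.mean - stats_b.mean)
    if dmean == 0:
        raise ValueError("insert means are equal: contrast undefined")
    return LCV_FACTOR * 0.5 * (stats_a.sd + stats_b.sd) / dmean


def uniformity(four_stats) -> float:
    """Largest relative difference between any two of four ROI means."""
    four_stats = list(four_stats)
    if len(four_stats) != 4:
        raise ValueError("uniformity requires exactly four ROI stats")
    means = np.array([s.mean for s in four_stats], dtype=float)
    if means.max() <= 0:
        raise ValueError("nonpositive ROI means: uniformity undefined")
    return float((means.max() - means.min()) / means.max())


def _group_modulation(volume: Volume, group: dict) -> float:
    bars = volume.sample(np.asarray(group["bar_centers_mm"], dtype=float))
    gaps = volume.sample(np.asarray(group["gap_centers_mm"], dtype=float))
    hi, lo = float(bars.mean()), float(gaps.mean())
    if hi + lo == 0:
        return 0.0
    return (hi - lo) / (hi + lo)


def resolvable_line_pairs(volume: Volume, spec: PhantomSpec,
                          modulation_threshold: float = DEFAULT_MODULATION_THRESHOLD):
    """Highest bar-group frequency still resolved in a reconstruction.

    For each annotated group the Michelson-style modulation between bar
    centers and gap centers is computed by trilinear sampling; a group is
    visible when its modulation reaches the threshold. Returns
    ``(resolved_lp_per_cm, per_group_table)`` where the score is the
    largest frequency such that it and every lower frequency are visible.
    """
    if not (0 < modulation_threshold):
        raise ValueError("modulation_threshold must be positive")
    groups = spec.annotations["lp_groups"]
    rows = []
    for key in sorted(groups, key=lambda k: groups[k]["freq_lp_per_cm"]):
        g = groups[key]
        rows.append((g["freq_lp_per_cm"], _group_modulation(volume, g)))
    table = pd.DataFrame(rows, columns=["freq_lp_per_cm", "modulation"])
    resolved = 0
    for _, row in table.iterrows():
        if row["modulation"] >= modulation_threshold:
            resolved = int(row["freq_lp_per_cm"])
        else:
            break
    return resolved, table


@dataclass
class QaReport:
    """One scheme's QA summary with pass flags against the XVI-style specs."""

    scheme: str
    mean_polystyrene: float
    sd_polystyrene: float
    mean_ldpe: float
    sd_ldpe: float
    lcv: float
    uniformity: float
    resolvable_lp_per_cm: int
    modulation_table: pd.DataFrame

    @property
    def lcv_pass(self) -> bool:
        return self.lcv < LCV_SPEC

    @property
    def uniformity_pass(self) -> bool:
        return self.uniformity <= UNIFORMITY_SPEC

    @property
    def resolution_pass(self) -> bool:
        return self.resolvable_lp_per_cm >= RESOLUTION_SPEC_LP_PER_CM

    def as_row(self) -> dict:
        return {
            "scheme": self.scheme,
            "mean_polystyrene": self.mean_polystyrene,
            "sd_polystyrene": self.sd_polystyrene,
            "mean_ldpe": self.mean_ldpe,
            "sd_ldpe": self.sd_ldpe,
            "lcv": self.lcv,
            "uniformity": self.uniformity,
            "resolvable_lp_per_cm": self.resolvable_lp_per_cm,
            "lcv_pass": self.lcv_pass,
            "uniformity_pass": self.uniformity_pass,
            "resolution_pass": self.resolution_pass,
        }


def qa_report(scheme_label: str, spec: PhantomSpec,
              module_volumes: dict,
              modulation_threshold: float = DEFAULT_MODULATION_THRESHOLD) -> QaReport:
    """Assemble one scheme's QA metrics from its reconstructed modules.

    ``module_volumes`` maps module name ('resolution', 'low_contrast',
    'uniform') to the reconstruction covering that module.
    """
    lc = module_volumes["low_contrast"]
    poly = roi_stats(lc, spec, "polystyrene")
    ldpe = roi_stats(lc, spec, "LDPE")
    uni = [roi_stats(module_volumes["uniform"], spec, n)
           for n in UNIFORMITY_ROI_NAMES]
    lp, table = resolvable_line_pairs(module_volumes["resolution"], spec,
                                      modulation_threshold)
    return QaReport(
        scheme=scheme_label,
        mean_polystyrene=poly.mean, sd_polystyrene=poly.sd,
        mean_ldpe=ldpe.mean, sd_ldpe=ldpe.sd,
        lcv=low_contrast_visibility(poly, ldpe),
        uniformity=uniformity(uni),
        resolvable_lp_per_cm=lp,
        modulation_table=table,
    )


def qa_curves(reports) -> pd.DataFrame:
    """Per-scheme metric table (the CSV behind the insert mean/SD, LCV and
    uniformity curves)."""
    reports = list(reports)
    if len(reports) < 2:
        raise ValueError("need at least two schemes to tabulate curves")
    return pd.DataFrame([r.as_row() for r in reports])
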