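"""Agatston scoring, calcium volume and CAD grading.

The clinical Agatston convention: reconstructions are resampled to 3.0-mm
scoring slices; in each slice, voxels at or above 130 HU inside the scoring
ROI form lesions (8-connected components); each lesion contributes its area
(mm^2) times a density factor set by the lesion's maximum HU (1/2/3/4 for
130-199 / 200-299 / 300-399 / >=400).  The total score over slices maps to a
CAD grade: 0 -> No CAD, <=10 Minimal, <=100 Mild, <=400 Moderate, else
Severe.  Calcium volume is the supra-threshold voxel volume on the same
scoring slices.  Lesions are attributed to the nearest ground-truth insert
center so that per-insert tables can be built.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

GRADES = ("No CAD", "Minimal", "Mild", "Moderate", "Severe")


@dataclass(frozen=True)
class ScoringConfig:
    threshold_hu: float = 130.0
    slice_thickness_mm: float = 3.0
    connectivity: int = 2  # 8-neighborhood in-slice (skimage connectivity=2)
    min_lesion_area_mm2: float = 0.0


def resample_to_scoring_slices(volume_hu: np.ndarray, z_spacing_mm: float, config: ScoringConfig = ScoringConfig()) -> np.ndarray:
    """Average consecutive voxel slabs into scoring-thickness slices."""
    ratio = config.slice_thickness_mm / z_spacing_mm
    n = int(round(ratio))
    if abs(ratio - n) > 1e-9 or n < 1:
        raise ValueError(f"z spacing {z_spacing_mm} does not divide slice thickness {config.slice_thickness_mm}")
    nz = volume_hu.shape[0]
    if nz % n:
        raise ValueError(f"number of slices {nz} not divisible by the slab factor {n}")
    return volume_hu.reshape(nz // n, n, *volume_hu.shape[1:]).mean(axis=1)


def density_factor(max_hu: float) -> int:
    """Agatston density factor from the lesion's maximum HU."""
    if not np.isfinite(max_hu):
        raise ValueError("max HU must be finite")
    if max_hu < 130:
        return 0
    if max_hu < 200:
        return 1
    if max_hu < 300:
        return 2
    if max_hu < 400:
        return 3
    return 4


def cad_grade(total_score: float) -> str:
    """CAD grade band of a total calcium score."""
    if total_score < 0:
        raise ValueError("score must be nonnegative")
    if total_score == 0:
        return "No CAD"
    if total_score <= 10:
        return "Minimal"
    if total_score <= 100:
        return "Mild"
    if total_score <= 400:
        return "Moderate"
    return "Severe"


@dataclass
class Lesion:
    slice_index: int
    area_mm2: float
    max_hu: float
    score: float
    centroid_xy_mm: tuple[float, float]


def find_lesions(
    scoring_volume_hu: np.ndarray,
    pixel_spacing: tuple[float, float],
    config: ScoringConfig = ScoringConfig(),
    roi_mask: np.ndarray | None = None,
) -> list[Lesion]:
    """Per-slice 8-connected supra-threshold lesions with Agatston scores."""
    dy, dx = pixel_spacing
    pixel_area = dx * dy
    nz, ny, nx = scoring_volume_hu.shape
    lesions: list[Lesion] = []
    for k in range(nz):
        sl = scoring_volume_hu[k]
        mask = sl >= config.threshold_hu
        if roi_mask is not None:
            mask &= roi_mask[k] if roi_mask.ndim == 3 else roi_mask
        if not mask.any():
            continue
        labels = measure.label(mask, connectivity=config.connectivity)
        for region in measure.regionprops(labels, intensity_image=sl):
            area = region.area * pixel_area
            if area < config.min_lesion_area_mm2:
                continue
            max_hu = float(region.intensity_max)
            cy, cx = region.centroid
            x_mm = (cx - (nx - 1) / 2.0) * dx
            y_mm = (cy - (ny - 1) / 2.0) * dy
            lesions.append(
                Lesion(
                    slice_index=k,
                    area_mm2=float(area),
                    max_hu=max_hu,
                    score=float(area) * density_factor(max_hu),
                    centroid_xy_mm=(x_mm, y_mm),
                )
            )
    return lesions


def agatston_score(
    scoring_volume_hu: np.ndarray,
    pixel_spacing: tuple[float, float],
    config: ScoringConfig = ScoringConfig(),
    roi_mask: np.ndarray | None = None,
) -> tuple[float, list[Lesion]]:
    """Total Agatston score and the contributing lesions."""
    lesions = find_lesions(scoring_volume_hu, pixel_spacing, config, roi_mask)
    return sum(l.score for l in lesions), lesions


def calcium_volume(
    scoring_volume_hu: np.ndarray,
    pixel_spacing: tuple[float, float],
    config: ScoringConfig = ScoringConfig(),
    roi_mask: np.ndarray | None = None,
) -> float:
    """Supra-threshold voxel volume (mm^3) on the scoring slices."""
    dy, dx = pixel_spacing
    mask = scoring_volume_hu >= config.threshold_hu
    if roi_mask is not None:
        mask &= roi_mask
    return float(mask.sum()) * dx * dy * config.slice_thickness_mm


def reclassification_rate(grades, reference_grades) -> float:
    """Percent of lesions whose CAD grade differs from the reference."""
    grades = list(grades)
    reference_grades = list(reference_grades)
    if len(grades) != len(reference_grades):
        raise ValueError("grade lists must have equal length")
    if not grades:
        raise ValueError("empty grade lists")
    mismatches = sum(a != b for a, b in zip(grades, reference_grades))
    return round(100.0 * mismatches / len(grades), 1)


def score_table(
    volume_hu: np.ndarray,
    z_spacing_mm: float,
    pixel_spacing: tuple[float, float],
    inserts,
    config: ScoringConfig = ScoringConfig(),
    roi_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-insert calcium volume, Agatston score and CAD grade.

    Each lesion is attributed to the nearest insert center in-plane.  The
    per-insert grade applies the CAD bands to that insert's own score, which
    makes the nine inserts usable as nine graded lesions.
    """
    from cacstudy.phantom_forge import nominal_insert_volume

    scoring = resample_to_scoring_slices(volume_hu, z_spacing_mm, config)
    if roi_mask is not None and roi_mask.ndim == 3 and roi_mask.shape[0] == volume_hu.shape[0]:
        # collapse the ROI to scoring slices (a voxel ROI covers a slab if any member does)
        n = int(round(config.slice_thickness_mm / z_spacing_mm))
        roi_mask = roi_mask.reshape(-1, n, *roi_mask.shape[1:]).any(axis=1)
    lesions = find_lesions(scoring, pixel_spacing, config, roi_mask)

    centers = np.array([[ins.center[0], ins.center[1]] for ins in inserts])
    dy, dx = pixel_spacing
    per_insert_score = np.zeros(len(inserts))
    per_insert_area = np.zeros(len(inserts))
    for lesion in lesions:
        d = np.hypot(centers[:, 0] - lesion.centroid_xy_mm[0], centers[:, 1] - lesion.centroid_xy_mm[1])
        i = int(np.argmin(d))
        per_insert_score[i] += lesion.score
        per_insert_area[i] += lesion.area_mm2

    rows = []
    for i, ins in enumerate(inserts):
        volume = per_insert_area[i] * config.slice_thickness_mm
        score = per_insert_score[i]
        rows.append(
            {
                "insert_id": i + 1,
                "density_mg_cm3": ins.density,
                "diameter_mm": ins.diameter,
                "nominal_volume_mm3": nominal_insert_volume(ins.diameter, ins.height),
                "volume_mm3": round(volume, 1),
                "score": round(score, 1),
                "grade": cad_grade(score),
            }
        )
    return pd.DataFrame(rows)
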