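"""Threshold-based inflammation segmentation within the disease region.

The label convention follows the two-threshold scheme: voxels inside the
disease region at or above the sensitive threshold ``L_lower`` are labelled
1; those also at or above the conservative threshold ``L_upper`` are
labelled 2 (so the conservative set is a subset of the sensitive set).
Voxels outside the disease region are always 0, however bright.

Equality at a threshold counts as meeting it: with ``>=`` the reference
region's own maximum is the lowest conservative intensity, and behaviour
does not depend on floating-point open-interval edge cases.

Connected components are computed per 2-D slice with 8-connectivity on the
sensitive (label >= 1) mask; the size filter and the cleaning step operate
on whole components — a lesion is left in place or removed altogether,
never edited at its boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from skimage import measure

from .core import (
    ImageVolume,
    RegionMask,
    ValidationError,
    ensure_aligned,
    voxel_volume_mm3,
)
from .thresholds import ThresholdEstimate, estimate_thresholds, extract_region_intensities

__all__ = [
    "InflammationLabelMap",
    "VhiResult",
    "apply_thresholds",
    "remove_small_regions",
    "clean",
    "compute_vhi",
    "run_pipeline",
    "PipelineResult",
    "MIN_REGION_PIXELS",
]

logger = logging.getLogger(__name__)

MIN_REGION_PIXELS = 4  # components with fewer in-plane pixels are noise/vessels


@dataclass
class InflammationLabelMap:
    """Tri-level inflammation map: 0 background, 1 sensitive-only, 2 conservative."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    thresholds: ThresholdEstimate

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValidationError("label map must be 3-D")
        if not np.isin(np.unique(labels), (0, 1, 2)).all():
            raise ValidationError("labels must be in {0, 1, 2}")
        self.labels = labels.astype(np.uint8)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def sensitive(self) -> np.ndarray:
        """Binary mask of voxels meeting at least the sensitive threshold."""
        return self.labels >= 1

    @property
    def conservative(self) -> np.ndarray:
        return self.labels == 2

    def copy(self) -> "InflammationLabelMap":
        return InflammationLabelMap(self.labels.copy(), self.spacing_mm, self.thresholds)


@dataclass(frozen=True)
class VhiResult:
    """Volume of hyperintense inflammation.

    ``voxel_count`` counts the sensitive set (labels 1 and 2), which defines
    V_HI for primary analyses; the conservative count is reported alongside.
    ``volume_mm3`` is the voxel count times the volume of one voxel.
    """

    voxel_count: int
    conservative_voxel_count: int
    volume_mm3: float


def apply_thresholds(
    stir: ImageVolume, disease_region: RegionMask, thresholds: ThresholdEstimate
) -> InflammationLabelMap:
    """Label voxels inside the disease region by the two intensity thresholds."""
    ensure_aligned(stir, disease_region, context="apply_thresholds")
    if thresholds.degenerate:
        logger.warning(
            "degenerate thresholds: sensitive and conservative labels coincide"
        )
    labels = np.zeros(stir.shape, dtype=np.uint8)
    inside = disease_region.data
    labels[inside & (stir.data >= thresholds.l_lower)] = 1
    labels[inside & (stir.data >= thresholds.l_upper)] = 2
    return InflammationLabelMap(labels, stir.spacing_mm, thresholds)


def _slice_components(binary_slice: np.ndarray) -> np.ndarray:
    """8-connected component labels of one 2-D slice."""
    return measure.label(binary_slice, connectivity=2)


def remove_small_regions(
    label_map: InflammationLabelMap, min_pixels: int = MIN_REGION_PIXELS
) -> InflammationLabelMap:
    """Remove per-slice components with fewer than ``min_pixels`` pixels.

    Components are found on the sensitive mask; a removed component has all
    its labels (1 and 2) zeroed. At 0.59 x 0.59 mm pixels the default of
    4 pixels corresponds to an in-plane area of 1.39 mm^2.
    """
    if min_pixels < 1:
        raise ValidationError("min_pixels must be >= 1")
    out = label_map.copy()
    removed = 0
    for k in range(out.labels.shape[2]):
        binary = out.labels[:, :, k] >= 1
        if not binary.any():
            continue
        comp = _slice_components(binary)
        sizes = np.bincount(comp.ravel())
        small = np.flatnonzero(sizes < min_pixels)
        small = small[small != 0]  # 0 is background
        if small.size:
            kill = np.isin(comp, small)
            out.labels[:, :, k][kill] = 0
            removed += int(small.size)
    logger.info("remove_small_regions: removed %d components (< %d px)", removed, min_pixels)
    return out


def clean(
    label_map: InflammationLabelMap, removal_marks: RegionMask
) -> InflammationLabelMap:
    """Remove, in full, every component that intersects a removal mark.

    Mirrors the reader's correction step: candidate lesions are either left
    in place or removed altogether; boundaries are never edited. Components
    use the same per-slice 8-connectivity as the size filter.
    """
    if removal_marks.shape != label_map.labels.shape:
        raise ValidationError(
            f"clean: marks shape {removal_marks.shape} != map shape {label_map.labels.shape}"
        )
    out = label_map.copy()
    removed = 0
    for k in range(out.labels.shape[2]):
        marks = removal_marks.data[:, :, k]
        if not marks.any():
            continue
        binary = out.labels[:, :, k] >= 1
        if not binary.any():
            continue
        comp = _slice_components(binary)
        touched = np.unique(comp[marks])
        touched = touched[touched != 0]
        if touched.size:
            kill = np.isin(comp, touched)
            out.labels[:, :, k][kill] = 0
            removed += int(touched.size)
    logger.info("clean: removed %d marked components", removed)
    return out


def compute_vhi(label_map: InflammationLabelMap) -> VhiResult:
    """Count inflamed voxels and convert to a physical volume (mm^3)."""
    voxel_count = int(np.count_nonzero(label_map.labels))
    conservative = int(np.count_nonzero(label_map.labels == 2))
    return VhiResult(
        voxel_count=voxel_count,
        conservative_voxel_count=conservative,
        volume_mm3=voxel_count * voxel_volume_mm3(label_map.spacing_mm),
    )


class PipelineResult(NamedTuple):
    label_map: InflammationLabelMap
    vhi: VhiResult
    thresholds: ThresholdEstimate
    log: dict


def run_pipeline(
    stir: ImageVolume,
    t1w: ImageVolume | None,
    normal_bone: RegionMask,
    disease_region: RegionMask,
    removal_marks: RegionMask | None = None,
    min_pixels: int = MIN_REGION_PIXELS,
    min_reference_samples: int = 8,
) -> PipelineResult:
    """Threshold estimation -> thresholding -> size filter -> cleaning -> V_HI.

    ``t1w`` is accepted for interface completeness (it drives disease-region
    learning upstream and reader orientation downstream) but is not used by
    the thresholding stages themselves. When ``removal_marks`` is None the
    cleaning step is skipped.
    """
    ensure_aligned(stir, normal_bone, disease_region, context="run_pipeline")
    intensities = extract_region_intensities(stir, normal_bone)
    thresholds = estimate_thresholds(intensities, min_samples=min_reference_samples)
    label_map = apply_thresholds(stir, disease_region, thresholds)
    raw_count = int(np.count_nonzero(label_map.labels))
    filtered = remove_small_regions(label_map, min_pixels=min_pixels)
    filtered_count = int(np.count_nonzero(filtered.labels))
    if removal_marks is not None:
        cleaned = clean(filtered, removal_marks)
    else:
        cleaned = filtered
    vhi = compute_vhi(cleaned)
    log = {
        "n_reference_voxels": int(intensities.size),
        "thresholds": {
            "q_upper": thresholds.q_upper,
            "iqr": thresholds.iqr,
            "n_multiple": thresholds.n_multiple,
            "l_lower": thresholds.l_lower,
            "l_upper": thresholds.l_upper,
            "degenerate": thresholds.degenerate,
        },
        "voxels_after_thresholding": raw_count,
        "voxels_removed_by_size_filter": raw_count - filtered_count,
        "voxels_removed_by_cleaning": filtered_count - vhi.voxel_count,
        "vhi_voxel_count": vhi.voxel_count,
        "vhi_conservative_voxel_count": vhi.conservative_voxel_count,
        "vhi_volume_mm3": vhi.volume_mm3,
    }
    logger.info("pipeline: %s", log)
    return PipelineResult(cleaned, vhi, thresholds, log)
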