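"""SPARCC-style bone-marrow-oedema scoring from quadrant annotations.

Oedema presence is scored over six consecutive slices with the sacroiliac
joints divided into eight quadrants per slice (four per joint). Each
quadrant scores 1 when it contains any lesion voxel. Per joint and slice, a
bonus point is added when the oedema extends more than 10 mm deep from the
joint line, and another when any oedema voxel is at least as intense as
cerebrospinal fluid. The maximum total is therefore
6 x 8 presence + 6 x 2 depth + 6 x 2 intensity = 72.

Depth is operationalised as the maximum perpendicular distance (in mm,
through the in-plane voxel spacing) from the supplied joint-line segment to
any lesion voxel centre within the joint's quadrants; the visual scoring
scheme itself does not define a computable depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageVolume, RegionMask, ValidationError

__all__ = [
    "QuadrantScheme",
    "SparccResult",
    "score_bme",
    "csf_reference_from_roi",
    "scheme_from_label_volume",
    "DEPTH_THRESHOLD_MM",
    "N_SCORED_SLICES",
    "N_QUADRANTS_PER_SLICE",
    "MAX_TOTAL",
]

N_SCORED_SLICES = 6
N_JOINTS = 2  # left / right sacroiliac joint
N_QUADRANTS_PER_JOINT = 4
N_QUADRANTS_PER_SLICE = N_JOINTS * N_QUADRANTS_PER_JOINT
DEPTH_THRESHOLD_MM = 10.0
MAX_TOTAL = N_SCORED_SLICES * N_QUADRANTS_PER_SLICE + 2 * N_SCORED_SLICES * N_JOINTS


@dataclass
class QuadrantScheme:
    """Quadrant masks and joint lines for the six scored slices.

    Attributes
    ----------
    slice_indices : 6 consecutive slice indices into the volume.
    quadrant_masks : bool array (6, 2, 4, H, W) — slice, joint (0 left /
        1 right), quadrant; pairwise disjoint within a slice.
    joint_lines_mm : float array (6, 2, 2, 2) — per slice and joint, two
        in-plane endpoints in mm coordinates (index * spacing).
    """

    slice_indices: tuple[int, ...]
    quadrant_masks: np.ndarray
    joint_lines_mm: np.ndarray

    def __post_init__(self) -> None:
        self.slice_indices = tuple(int(s) for s in self.slice_indices)
        if len(self.slice_indices) != N_SCORED_SLICES:
            raise ValidationError(f"exactly {N_SCORED_SLICES} scored slices required")
        if list(self.slice_indices) != list(
            range(self.slice_indices[0], self.slice_indices[0] + N_SCORED_SLICES)
        ):
            raise ValidationError("scored slices must be consecutive")
        self.quadrant_masks = np.asarray(self.quadrant_masks, dtype=bool)
        if self.quadrant_masks.shape[:3] != (N_SCORED_SLICES, N_JOINTS, N_QUADRANTS_PER_JOINT):
            raise ValidationError(
                f"quadrant_masks must be (6, 2, 4, H, W), got {self.quadrant_masks.shape}"
            )
        flat = self.quadrant_masks.reshape(N_SCORED_SLICES, -1, *self.quadrant_masks.shape[3:])
        if np.any(flat.sum(axis=1) > 1):
            raise ValidationError("quadrant masks within a slice must be pairwise disjoint")
        self.joint_lines_mm = np.asarray(self.joint_lines_mm, dtype=np.float64)
        if self.joint_lines_mm.shape != (N_SCORED_SLICES, N_JOINTS, 2, 2):
            raise ValidationError(
                f"joint_lines_mm must be (6, 2, 2, 2), got {self.joint_lines_mm.shape}"
            )


@dataclass(frozen=True)
class SparccResult:
    presence: np.ndarray  # (6, 8) binary
    depth_bonus: np.ndarray  # (6, 2) binary
    intensity_bonus: np.ndarray  # (6, 2) binary

    @property
    def total(self) -> int:
        return int(
            self.presence.sum() + self.depth_bonus.sum() + self.intensity_bonus.sum()
        )


def _perpendicular_distances_mm(points_mm: np.ndarray, line_mm: np.ndarray) -> np.ndarray:
    """Perpendicular distance of points to the infinite line through a segment."""
    p0, p1 = line_mm
    direction = p1 - p0
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValidationError("joint line endpoints must be distinct")
    rel = points_mm - p0
    # 2-D cross product magnitude / |direction|
    return np.abs(rel[:, 0] * direction[1] - rel[:, 1] * direction[0]) / norm


def score_bme(
    stir: ImageVolume,
    lesions: RegionMask,
    scheme: QuadrantScheme,
    csf_reference: float,
) -> SparccResult:
    """Score oedema presence, depth and intensity over the six scored slices.

    ``csf_reference`` is the cerebrospinal-fluid reference intensity; the
    intensity bonus requires a lesion voxel at least as intense (>=), and
    the depth bonus requires oedema strictly more than 10 mm from the joint
    line.
    """
    if stir.shape != lesions.shape:
        raise ValidationError("stir and lesions must share shape")
    if scheme.quadrant_masks.shape[3:] != stir.shape[:2]:
        raise ValidationError(
            f"scheme in-plane shape {scheme.quadrant_masks.shape[3:]} != volume {stir.shape[:2]}"
        )
    if csf_reference <= 0:
        raise ValidationError("csf_reference must be positive")
    for s in scheme.slice_indices:
        if not 0 <= s < stir.n_slices:
            raise ValidationError(f"scored slice {s} outside volume (n={stir.n_slices})")

    sx, sy = stir.spacing_mm[:2]
    presence = np.zeros((N_SCORED_SLICES, N_QUADRANTS_PER_SLICE), dtype=np.int8)
    depth_bonus = np.zeros((N_SCORED_SLICES, N_JOINTS), dtype=np.int8)
    intensity_bonus = np.zeros((N_SCORED_SLICES, N_JOINTS), dtype=np.int8)

    for si, slice_idx in enumerate(scheme.slice_indices):
        lesion_slice = lesions.data[:, :, slice_idx]
        stir_slice = stir.data[:, :, slice_idx]
        for joint in range(N_JOINTS):
            joint_points = []
            joint_has_csf = False
            for quad in range(N_QUADRANTS_PER_JOINT):
                hits = lesion_slice & scheme.quadrant_masks[si, joint, quad]
                if hits.any():
                    presence[si, joint * N_QUADRANTS_PER_JOINT + quad] = 1
                    ij = np.argwhere(hits)
                    joint_points.append(ij * np.array([sx, sy]))
                    if np.any(stir_slice[hits] >= csf_reference):
                        joint_has_csf = True
            if joint_points:
                pts = np.concatenate(joint_points, axis=0)
                dists = _perpendicular_distances_mm(
                    pts, scheme.joint_lines_mm[si, joint]
                )
                if dists.max() > DEPTH_THRESHOLD_MM:
                    depth_bonus[si, joint] = 1
                if joint_has_csf:
                    intensity_bonus[si, joint] = 1
    return SparccResult(presence, depth_bonus, intensity_bonus)


def csf_reference_from_roi(stir: ImageVolume, csf_roi: RegionMask) -> float:
    """Median STIR intensity within a cerebrospinal-fluid ROI."""
    if stir.shape != csf_roi.shape:
        raise ValidationError("stir and csf_roi must share shape")
    if csf_roi.is_empty():
        raise ValidationError("CSF ROI is empty")
    return float(np.median(stir.data[csf_roi.data]))


def scheme_from_label_volume(
    labels: np.ndarray,
    slice_indices,
    joint_lines_mm,
) -> QuadrantScheme:
    """Build a scheme from a per-slice quadrant label image.

    ``labels`` is (H, W, n_slices) with values 0 (unscored) and 1-8: labels
    1-4 are the left joint's quadrants, 5-8 the right joint's.
    """
    labels = np.asarray(labels)
    values = np.unique(labels)
    bad = values[~np.isin(values, range(9))]
    if bad.size:
        raise ValidationError(f"quadrant labels must be 0-8; found {bad[:10].tolist()}")
    slice_indices = [int(s) for s in slice_indices]
    h, w = labels.shape[:2]
    masks = np.zeros((N_SCORED_SLICES, N_JOINTS, N_QUADRANTS_PER_JOINT, h, w), dtype=bool)
    for si, slice_idx in enumerate(slice_indices):
        plane = labels[:, :, slice_idx]
        for joint in range(N_JOINTS):
            for quad in range(N_QUADRANTS_PER_JOINT):
                masks[si, joint, quad] = plane == (joint * N_QUADRANTS_PER_JOINT + quad + 1)
    return QuadrantScheme(tuple(slice_indices), masks, np.asarray(joint_lines_mm))
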