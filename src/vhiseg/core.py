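"""Core data carriers and error types.

The workflow operates on 3-D scalar grids with physical voxel spacing taken
from the image header. Two carriers cover every stage: :class:`ImageVolume`
for STIR / T1-weighted intensities and :class:`RegionMask` for binary regions
(normal-bone reference, disease region, cleaning marks, CSF ROI, truths).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationError",
    "ConfigurationError",
    "ImageVolume",
    "RegionMask",
    "voxel_volume_mm3",
]


class ValidationError(ValueError):
    """Invalid input data (shape mismatch, empty mask, non-finite values...)."""


class ConfigurationError(ValueError):
    """Invalid configuration (non-positive spacing, degenerate geometry...)."""


def _as_spacing(spacing_mm) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3:
        raise ConfigurationError(f"spacing must have 3 components, got {len(spacing)}")
    if any(s <= 0 for s in spacing):
        raise ConfigurationError(f"spacing components must be positive, got {spacing}")
    return spacing


def voxel_volume_mm3(spacing_mm) -> float:
    """Volume of a single voxel in mm^3 from per-axis spacing in mm."""
    sx, sy, sz = _as_spacing(spacing_mm)
    return sx * sy * sz


@dataclass
class ImageVolume:
    """A 3-D scalar grid with per-axis voxel spacing in millimetres.

    The first two axes are in-plane, the last axis indexes slices.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    identifier: str = "volume"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(f"volume must be 3-D, got ndim={self.data.ndim}")
        self.spacing_mm = _as_spacing(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def voxel_volume_mm3(self) -> float:
        return voxel_volume_mm3(self.spacing_mm)


@dataclass
class RegionMask:
    """A binary 3-D grid aligned voxel-for-voxel to an :class:`ImageVolume`."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    identifier: str = "mask"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValidationError(f"mask must be 3-D, got ndim={arr.ndim}")
        if arr.dtype != bool:
            values = np.unique(arr)
            bad = values[~np.isin(values, (0, 1))]
            if bad.size:
                raise ValidationError(
                    f"mask must be binary; found values {bad[:10].tolist()}"
                )
            arr = arr.astype(bool)
        self.data = arr
        self.spacing_mm = _as_spacing(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return not bool(self.data.any())


def ensure_aligned(*grids, context: str = "input") -> None:
    """Raise :class:`ValidationError` unless all grids share shape and spacing."""
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape:
            raise ValidationError(
                f"{context}: shape mismatch {g.shape} vs {ref.shape} "
                f"({getattr(g, 'identifier', '?')} vs {getattr(ref, 'identifier', '?')})"
            )
        if tuple(g.spacing_mm) != tuple(ref.spacing_mm):
            raise ValidationError(
                f"{context}: spacing mismatch {g.spacing_mm} vs {ref.spacing_mm}"
            )
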