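"""NIfTI / CSV / JSON / YAML input-output.

Volumes and masks travel as NIfTI-1 files; voxel spacing is taken from the
header zooms and written back through the affine, so every physical
measurement (mm^2 filter areas, mm^3 volumes, mm depths) honours the
header. Orientation is taken as stored — no resampling. Voxel indexing is
0-based throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import ImageVolume, RegionMask, ValidationError

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_label_volume",
    "write_label_volume",
    "read_yaml_config",
    "write_manifest",
]


def _load(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3-D image, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def _save(data: np.ndarray, spacing, path) -> None:
    affine = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_volume(path, identifier: str | None = None) -> ImageVolume:
    data, spacing = _load(path)
    return ImageVolume(data.astype(np.float64), spacing, identifier or Path(path).stem)


def write_volume(volume: ImageVolume, path) -> None:
    _save(volume.data.astype(np.float32), volume.spacing_mm, path)


def read_mask(path, identifier: str | None = None) -> RegionMask:
    data, spacing = _load(path)
    values = np.unique(data)
    bad = values[~np.isin(values, (0, 1))]
    if bad.size:
        raise ValidationError(
            f"{path}: binary mask expected; offending values {bad[:10].tolist()}"
        )
    return RegionMask(data.astype(bool), spacing, identifier or Path(path).stem)


def write_mask(mask: RegionMask, path) -> None:
    _save(mask.data.astype(np.uint8), mask.spacing_mm, path)


def read_label_volume(path, allowed=range(9)):
    """Integer label volume (e.g. quadrant labels 1-8); returns (array, spacing)."""
    data, spacing = _load(path)
    values = np.unique(data)
    bad = values[~np.isin(values, list(allowed))]
    if bad.size:
        raise ValidationError(
            f"{path}: labels outside {list(allowed)}: {bad[:10].tolist()}"
        )
    return data.astype(np.int16), spacing


def write_label_volume(labels: np.ndarray, spacing, path) -> None:
    _save(np.asarray(labels).astype(np.int16), spacing, path)


def read_yaml_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValidationError(f"{path}: YAML config must be a mapping")
    return config


def write_manifest(path, *, command: str, inputs: dict, config: dict, seed, outputs: dict) -> dict:
    """Write the JSON run manifest that makes a run reproducible."""
    from . import __version__

    manifest = {
        "command": command,
        "version": __version__,
        "seed": seed,
        "inputs": inputs,
        "config": config,
        "outputs": outputs,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
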