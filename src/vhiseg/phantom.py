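"""Synthetic pelvis-like STIR / T1-weighted phantom volumes with ground truth.

Real oblique-coronal pelvis scans (matrix ~336x336, 23-25 slices, voxel
0.59 x 0.59 x 3 mm) contain normal marrow with a right-skewed intensity
distribution, hyperintense subchondral lesions, thin bright vessels and the
occasional reconstruction artefact. The generator emulates exactly those
features on a simplified geometry — a central sacral block flanked by two
iliac plates — so that every downstream stage (reference-region thresholds,
disease-region learning, small-region filtering, cleaning, V_HI, SPARCC)
can be exercised and validated without patient data.

Intensity model (STIR, before noise):

* normal marrow: Gaussian ``N(marrow_mean, marrow_sd)`` truncated to
  ``[0, marrow_mean + 3 * marrow_sd]``, plus a small right tail — a random
  ``tail_fraction`` of marrow voxels multiplied by a factor drawn from
  ``tail_multiplier_range`` — emulating partial-volume and intra-marrow
  vessels. The tail pushes the reference maximum well above
  ``Q_U + 1.5 * IQR`` so the threshold-adaptation loop runs non-trivially.
* lesions: exactly ``intensity_multiplier * marrow_mean``.
* vessels / artefacts: fixed bright multiples of ``marrow_mean``.

Noise is additive Gaussian by default; a Rician option is available. The
default test geometry is 96 x 96 x 12; the full acquisition matrix
(336 x 336, 23-25 slices) is available through the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import ConfigurationError, ImageVolume, RegionMask

__all__ = ["LesionSpec", "PhantomConfig", "PhantomCase", "generate_phantom", "write_case"]

DEFAULT_SPACING = (0.59, 0.59, 3.0)


@dataclass(frozen=True)
class LesionSpec:
    """A spherical subchondral lesion.

    ``center_voxel`` is a 0-based (i, j, k) grid index; ``radius_mm`` is a
    physical radius applied through the voxel spacing (anisotropic in index
    space); ``intensity_multiplier`` scales the mean marrow intensity and
    must exceed 1 (lesions are hyperintense on STIR).
    """

    center_voxel: tuple[int, int, int]
    radius_mm: float
    intensity_multiplier: float


@dataclass
class PhantomConfig:
    matrix_size: tuple[int, int] = (96, 96)
    n_slices: int = 12
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING
    marrow_mean: float = 100.0
    marrow_sd: float = 10.0
    lesion_specs: list[LesionSpec] = field(default_factory=list)
    n_vessels: int = 2
    n_artefacts: int = 0
    noise_sd: float = 0.0
    seed: int = 0
    # secondary knobs
    tail_fraction: float = 0.01
    tail_multiplier_range: tuple[float, float] = (1.15, 1.4)
    vessel_multiplier: float = 1.8
    artefact_multiplier: float = 1.7
    background_level: float = 0.3  # x marrow_mean, soft tissue on STIR
    rician_noise: bool = False

    def validate(self) -> None:
        if min(self.matrix_size) < 8 or self.n_slices < 8:
            raise ConfigurationError(
                f"matrix {self.matrix_size} x {self.n_slices}: all dims must be >= 8"
            )
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError(f"spacing must be 3 positive reals: {self.spacing_mm}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for spec in self.lesion_specs:
            if spec.intensity_multiplier <= 1:
                raise ConfigurationError(
                    f"lesion intensity_multiplier must be > 1, got {spec.intensity_multiplier}"
                )
            if spec.radius_mm <= 0:
                raise ConfigurationError("lesion radius_mm must be > 0")


@dataclass
class PhantomCase:
    stir: ImageVolume
    t1w: ImageVolume
    truth_disease_region: RegionMask
    truth_normal_bone: RegionMask
    truth_lesions: RegionMask
    truth_vessels: RegionMask
    truth_lesion_voxel_count: int
    config: PhantomConfig | None = None

    def validate(self) -> None:
        grids = [
            self.stir,
            self.t1w,
            self.truth_disease_region,
            self.truth_normal_bone,
            self.truth_lesions,
            self.truth_vessels,
        ]
        shapes = {g.shape for g in grids}
        spacings = {tuple(g.spacing_mm) for g in grids}
        assert len(shapes) == 1 and len(spacings) == 1, "grids must be aligned"
        lesions = self.truth_lesions.data
        assert not np.any(lesions & ~self.truth_disease_region.data), (
            "lesions must lie inside the disease region"
        )
        assert not np.any(lesions & self.truth_normal_bone.data), (
            "normal bone must not overlap lesions"
        )
        assert self.truth_lesion_voxel_count == int(lesions.sum())


def _ellipse_mask(shape2d, center, semi_axes) -> np.ndarray:
    ii, jj = np.ogrid[: shape2d[0], : shape2d[1]]
    return ((ii - center[0]) / semi_axes[0]) ** 2 + (
        (jj - center[1]) / semi_axes[1]
    ) ** 2 <= 1.0


def _bone_masks(config: PhantomConfig):
    """Sacrum + two iliac plates, with a mild slice-dependent taper."""
    h, w = config.matrix_size
    s = config.n_slices
    cx, cy = h / 2.0, w / 2.0
    bone = np.zeros((h, w, s), dtype=bool)
    normal = np.zeros((h, w, s), dtype=bool)
    for k in range(s):
        # taper: outer slices slightly smaller, as when a curved bone exits the slab
        taper = 1.0 - 0.25 * abs(k - (s - 1) / 2.0) / max(s / 2.0, 1.0)
        sacrum = _ellipse_mask((h, w), (cx, cy), (0.30 * h * taper, 0.18 * w * taper))
        ilium_l = _ellipse_mask((h, w), (cx, cy - 0.32 * w), (0.36 * h * taper, 0.11 * w))
        ilium_r = _ellipse_mask((h, w), (cx, cy + 0.32 * w), (0.36 * h * taper, 0.11 * w))
        bone[:, :, k] = sacrum | ilium_l | ilium_r
        # interforaminal reference: central sacral core on the middle slices
        if s // 4 <= k <= 3 * s // 4:
            normal[:, :, k] = _ellipse_mask((h, w), (cx, cy), (0.12 * h, 0.07 * w))
    normal &= bone
    return bone, normal


def _lesion_mask(config: PhantomConfig) -> np.ndarray:
    h, w = config.matrix_size
    shape = (h, w, config.n_slices)
    lesions = np.zeros(shape, dtype=bool)
    if not config.lesion_specs:
        return lesions
    sx, sy, sz = config.spacing_mm
    ii, jj, kk = np.ogrid[: shape[0], : shape[1], : shape[2]]
    for spec in config.lesion_specs:
        ci, cj, ck = spec.center_voxel
        d2 = ((ii - ci) * sx) ** 2 + ((jj - cj) * sy) ** 2 + ((kk - ck) * sz) ** 2
        lesions |= d2 <= spec.radius_mm**2
    return lesions


def _vessel_mask(config: PhantomConfig, bone: np.ndarray, rng: np.random.Generator):
    """Thin bright curvilinear tracks, each starting inside bone and walking
    outward so it crosses the bone boundary (partly inside, partly outside)."""
    h, w = config.matrix_size
    s = config.n_slices
    vessels = np.zeros((h, w, s), dtype=bool)
    if config.n_vessels <= 0 or not bone.any():
        return vessels
    idx = np.argwhere(bone)
    centroid = idx.mean(axis=0)
    for _ in range(config.n_vessels):
        start = idx[rng.integers(len(idx))]
        direction = start[:2] - centroid[:2]
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 1e-6 else np.array([1.0, 0.0])
        pos = start.astype(float)
        n_steps = int(0.5 * max(h, w))
        for _ in range(n_steps):
            i, j, k = np.round(pos).astype(int)
            if 0 <= i < h and 0 <= j < w and 0 <= k < s:
                vessels[i, j, k] = True
            pos[:2] += direction + rng.normal(0.0, 0.4, size=2)
            pos[2] += rng.normal(0.0, 0.15)
            pos[2] = np.clip(pos[2], 0, s - 1)
    return vessels


def _artefact_mask(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = config.matrix_size
    s = config.n_slices
    art = np.zeros((h, w, s), dtype=bool)
    sx, sy, sz = config.spacing_mm
    ii, jj, kk = np.ogrid[:h, :w, :s]
    for _ in range(config.n_artefacts):
        ci = rng.integers(2, h - 2)
        cj = rng.integers(2, w - 2)
        ck = rng.integers(0, s)
        r = rng.uniform(1.5, 3.0)
        d2 = ((ii - ci) * sx) ** 2 + ((jj - cj) * sy) ** 2 + ((kk - ck) * sz) ** 2
        art |= d2 <= r**2
    return art


def generate_phantom(config: PhantomConfig | None = None) -> PhantomCase:
    """Generate one synthetic STIR / T1w case with ground-truth masks.

    Deterministic for a fixed config (the seed lives in the config): calling
    twice yields bit-identical volumes.
    """
    config = config if config is not None else PhantomConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.matrix_size
    shape = (h, w, config.n_slices)
    spacing = tuple(config.spacing_mm)

    bone, normal = _bone_masks(config)
    lesions = _lesion_mask(config)
    disease = bone & ~normal
    lesions &= disease  # lesions live in potentially-diseased bone only
    vessels = _vessel_mask(config, bone, rng)
    artefacts = _artefact_mask(config, rng)
    normal &= ~lesions & ~vessels

    # --- STIR ---
    mean, sd = config.marrow_mean, config.marrow_sd
    stir = np.full(shape, config.background_level * mean, dtype=np.float64)
    marrow = bone & ~lesions & ~vessels
    base = np.clip(rng.normal(mean, sd, size=shape), 0.0, mean + 3.0 * sd)
    tail = rng.random(shape) < config.tail_fraction
    lo, hi = config.tail_multiplier_range
    base = np.where(tail, base * rng.uniform(lo, hi, size=shape), base)
    stir[marrow] = base[marrow]
    for spec in config.lesion_specs:
        this = _lesion_mask(
            PhantomConfig(
                matrix_size=config.matrix_size,
                n_slices=config.n_slices,
                spacing_mm=config.spacing_mm,
                lesion_specs=[spec],
            )
        )
        stir[this & lesions] = spec.intensity_multiplier * mean
    stir[vessels] = config.vessel_multiplier * mean
    stir[artefacts & ~lesions] = config.artefact_multiplier * mean

    # --- T1w: bone is a distinct bright band; oedema and vessels are dark ---
    t1 = np.full(shape, 0.25, dtype=np.float64)
    t1[bone] = 0.75
    t1[lesions] = 0.60
    t1[vessels] = 0.20
    t1 += rng.normal(0.0, 0.02, size=shape)

    if config.noise_sd > 0:
        if config.rician_noise:
            n1 = rng.normal(0.0, config.noise_sd, size=shape)
            n2 = rng.normal(0.0, config.noise_sd, size=shape)
            stir = np.sqrt((stir + n1) ** 2 + n2**2)
        else:
            stir = stir + rng.normal(0.0, config.noise_sd, size=shape)

    case = PhantomCase(
        stir=ImageVolume(stir, spacing, "stir"),
        t1w=ImageVolume(t1, spacing, "t1w"),
        truth_disease_region=RegionMask(disease, spacing, "disease_region"),
        truth_normal_bone=RegionMask(normal, spacing, "normal_bone"),
        truth_lesions=RegionMask(lesions, spacing, "lesions"),
        truth_vessels=RegionMask(vessels, spacing, "vessels"),
        truth_lesion_voxel_count=int(lesions.sum()),
        config=config,
    )
    case.validate()
    return case


def write_case(case: PhantomCase, directory) -> dict:
    """Write a phantom case as NIfTI files plus a JSON manifest.

    Returns the manifest dict (roles -> filenames, seed, lesion voxel count).
    """
    from . import io as _io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    roles = {
        "stir": case.stir,
        "t1w": case.t1w,
        "disease_region": case.truth_disease_region,
        "normal_bone": case.truth_normal_bone,
        "lesions": case.truth_lesions,
        "vessels": case.truth_vessels,
    }
    files = {}
    for role, grid in roles.items():
        path = directory / f"{role}.nii"
        if isinstance(grid, ImageVolume):
            _io.write_volume(grid, path)
        else:
            _io.write_mask(grid, path)
        files[role] = path.name
    manifest = {
        "roles": files,
        "seed": case.config.seed if case.config is not None else None,
        "truth_lesion_voxel_count": case.truth_lesion_voxel_count,
        "spacing_mm": list(case.stir.spacing_mm),
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
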