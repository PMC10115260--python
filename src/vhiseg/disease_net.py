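"""Trainable 2-D U-net disease-region segmenter.

The network learns to recognise potentially-inflamed bone ("disease
region") on T1-weighted slices — a deliberately simple task compared with
direct lesion recognition, achievable with a small training set. Volumes
are normalised by three standard deviations of the whole-volume intensity
distribution (no mean subtraction). Training runs a fixed number of
augmentation steps per epoch: at each step a random mini-batch is drawn
from the slice pool, augmented on the fly (elastic deformation, affine
rotation/scale/shear, random horizontal flip with probability 0.5, and a
random intensity power applied to the image only) and used for one Adam
update of the binary-cross-entropy loss.

Two named profiles exist: ``reference`` carries the full-scale protocol
(epoch grid {60, 100}, resolution levels {2, 4, 6}, kernels {3, 5}, batch
size 4, learning rate 1e-3, 350 augmentation steps per epoch); ``test`` is
a desk-scale configuration for phantoms. Off-grid values require
``allow_nonstandard=True``.

Data are partitioned at subject level — no subject contributes slices to
two sets — and the final segmenter averages the per-voxel probabilities of
three independently seeded training runs before rounding (half up) at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import ImageVolume, RegionMask, ValidationError, ConfigurationError
from .nn import Adam, UNet2d, bce_with_logits
from . import evaluation

__all__ = [
    "AugmentRanges",
    "AugmentParams",
    "NetConfig",
    "SubjectSplit",
    "TrainingCase",
    "TrainedModel",
    "normalize_volume",
    "sample_augment_params",
    "apply_spatial",
    "augment_slice",
    "make_splits",
    "hyperparameter_grid",
    "train",
    "train_ensemble",
    "ensemble_predict",
    "evaluate_model",
]

EPOCH_GRID = (60, 100)
LEVEL_GRID = (2, 4, 6)
KERNEL_GRID = (3, 5)
ENSEMBLE_SIZE = 3


@dataclass(frozen=True)
class AugmentRanges:
    """Uniform sampling ranges for the on-the-fly augmentation."""

    rotation_deg: float = 15.0
    scale: tuple[float, float] = (0.9, 1.1)
    shear: float = 0.1
    power: tuple[float, float] = (0.7, 1.4)
    flip_prob: float = 0.5
    elastic_grid: int = 3
    elastic_sigma_px: float = 2.0
    elastic_enabled: bool = True


@dataclass(frozen=True)
class AugmentParams:
    rotation_deg: float
    scale: float
    shear: float
    flip: bool
    power: float
    elastic_disp: np.ndarray | None  # (2, g, g) coarse displacement grid, px


@dataclass(frozen=True)
class NetConfig:
    epochs: int = 60
    resolution_levels: int = 2
    kernel_size: int = 3
    batch_size: int = 4
    learning_rate: float = 1e-3
    augmentation_steps_per_epoch: int = 350
    base_channels: int = 16
    seed: int = 0
    augmentation: AugmentRanges = field(default_factory=AugmentRanges)
    allow_nonstandard: bool = False

    def validate(self) -> None:
        if self.allow_nonstandard:
            if self.epochs < 1 or self.resolution_levels < 1:
                raise ConfigurationError("epochs and resolution_levels must be >= 1")
            if self.kernel_size % 2 != 1:
                raise ConfigurationError("kernel_size must be odd")
            return
        if self.epochs not in EPOCH_GRID:
            raise ConfigurationError(
                f"epochs {self.epochs} outside grid {EPOCH_GRID}; set allow_nonstandard"
            )
        if self.resolution_levels not in LEVEL_GRID:
            raise ConfigurationError(
                f"resolution_levels {self.resolution_levels} outside grid {LEVEL_GRID}"
            )
        if self.kernel_size not in KERNEL_GRID:
            raise ConfigurationError(f"kernel_size {self.kernel_size} outside grid {KERNEL_GRID}")
        if self.batch_size != 4 or self.learning_rate != 1e-3:
            raise ConfigurationError("batch_size 4 and learning_rate 1e-3 are fixed")
        if self.augmentation_steps_per_epoch != 350:
            raise ConfigurationError("350 augmentation steps per epoch are fixed")

    @classmethod
    def reference_profile(cls, epochs: int = 60, resolution_levels: int = 4,
                          kernel_size: int = 3, seed: int = 0) -> "NetConfig":
        """Full-scale protocol configuration (on-grid values only)."""
        cfg = cls(epochs=epochs, resolution_levels=resolution_levels,
                  kernel_size=kernel_size, seed=seed)
        cfg.validate()
        return cfg

    @classmethod
    def test_profile(cls, seed: int = 0, epochs: int = 6,
                     steps_per_epoch: int = 30) -> "NetConfig":
        """Desk-scale configuration for phantom experiments."""
        return cls(
            epochs=epochs,
            resolution_levels=2,
            kernel_size=3,
            augmentation_steps_per_epoch=steps_per_epoch,
            base_channels=8,
            seed=seed,
            allow_nonstandard=True,
        )


def hyperparameter_grid() -> list[NetConfig]:
    """The 2 x 3 x 2 = 12 candidate configurations of the search grid."""
    return [
        NetConfig(epochs=e, resolution_levels=l, kernel_size=k)
        for e in EPOCH_GRID
        for l in LEVEL_GRID
        for k in KERNEL_GRID
    ]


@dataclass(frozen=True)
class SubjectSplit:
    train_subjects: frozenset
    val_subjects: frozenset
    test_subjects: frozenset = frozenset()

    def __post_init__(self) -> None:
        pairs = [
            (self.train_subjects, self.val_subjects),
            (self.train_subjects, self.test_subjects),
            (self.val_subjects, self.test_subjects),
        ]
        for a, b in pairs:
            if a & b:
                raise ValidationError(f"subject sets must be disjoint; overlap {a & b}")


@dataclass
class TrainingCase:
    """One subject's normalisable T1w volume with its disease-region truth."""

    subject_id: str
    t1w: ImageVolume
    disease_region: RegionMask


def normalize_volume(volume: ImageVolume) -> ImageVolume:
    """Divide intensities by 3x the population SD of the whole volume."""
    sd = float(volume.data.std())
    if sd == 0:
        raise ValidationError(f"{volume.identifier}: zero intensity spread")
    return ImageVolume(volume.data / (3.0 * sd), volume.spacing_mm, volume.identifier)


def sample_augment_params(rng: np.random.Generator, ranges: AugmentRanges) -> AugmentParams:
    disp = None
    if ranges.elastic_enabled:
        g = ranges.elastic_grid
        disp = rng.normal(0.0, ranges.elastic_sigma_px, size=(2, g, g))
    return AugmentParams(
        rotation_deg=rng.uniform(-ranges.rotation_deg, ranges.rotation_deg),
        scale=rng.uniform(*ranges.scale),
        shear=rng.uniform(-ranges.shear, ranges.shear),
        flip=bool(rng.random() < ranges.flip_prob),
        power=rng.uniform(*ranges.power),
        elastic_disp=disp,
    )


def apply_spatial(arr: np.ndarray, params: AugmentParams, order: int) -> np.ndarray:
    """Apply the spatial part of an augmentation (elastic + affine + flip)."""
    h, w = arr.shape
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([ii, jj]).astype(np.float64)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])

    theta = np.deg2rad(params.rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shear = np.array([[1.0, params.shear], [0.0, 1.0]])
    affine = params.scale * (rot @ shear)
    inv = np.linalg.inv(affine)  # map output pixels back to input coords

    rel = coords - center[:, None, None]
    src = np.einsum("ab,bhw->ahw", inv, rel) + center[:, None, None]

    if params.elastic_disp is not None:
        for axis in range(2):
            zoom = (h / params.elastic_disp.shape[1], w / params.elastic_disp.shape[2])
            src[axis] += ndimage.zoom(params.elastic_disp[axis], zoom, order=3)

    out = ndimage.map_coordinates(arr, src, order=order, mode="constant", cval=0.0)
    if params.flip:
        out = out[:, ::-1]
    return out


def augment_slice(image: np.ndarray, mask: np.ndarray, seed,
                  ranges: AugmentRanges | None = None):
    """Jointly augment one slice and its binary mask.

    The same spatial transform is applied to both (mask with
    nearest-neighbour interpolation, then re-binarised); the intensity
    power is applied to the image only. ``seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    if image.shape != mask.shape:
        raise ValidationError(f"image {image.shape} and mask {mask.shape} differ")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ranges = ranges if ranges is not None else AugmentRanges()
    params = sample_augment_params(rng, ranges)
    img_out = apply_spatial(image, params, order=1)
    img_out = np.clip(img_out, 0.0, None) ** params.power
    mask_out = apply_spatial(mask.astype(np.float64), params, order=0) > 0.5
    return img_out, mask_out


def make_splits(subject_ids, scheme: str, seed: int) -> list[SubjectSplit]:
    """Subject-level data splits.

    ``cv4`` partitions the subjects into four validation folds (each
    subject validates exactly once; with 8 subjects this is the 6-train /
    2-validation layout). ``train_test`` holds out ~20% of subjects
    (at least one) as a test set.
    """
    subjects = sorted(str(s) for s in subject_ids)
    if len(subjects) != len(set(subjects)):
        raise ValidationError("duplicate subject ids")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    if scheme == "cv4":
        if len(subjects) < 4:
            raise ValidationError("cv4 needs at least 4 subjects")
        folds = np.array_split(order, 4)
        return [
            SubjectSplit(
                train_subjects=frozenset(order) - frozenset(fold),
                val_subjects=frozenset(fold),
            )
            for fold in folds
        ]
    if scheme == "train_test":
        if len(subjects) < 2:
            raise ValidationError("train_test needs at least 2 subjects")
        n_test = max(1, round(0.2 * len(subjects)))
        return [
            SubjectSplit(
                train_subjects=frozenset(order[n_test:]),
                val_subjects=frozenset(),
                test_subjects=frozenset(order[:n_test]),
            )
        ]
    raise ValidationError(f"unknown split scheme {scheme!r}")


def _pad_to_multiple(arr: np.ndarray, multiple: int):
    h, w = arr.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph or pw:
        arr = np.pad(arr, ((0, ph), (0, pw)))
    return arr, (h, w)


@dataclass
class TrainedModel:
    """A trained U-net with its configuration and seed."""

    net: UNet2d
    config: NetConfig

    def predict_proba(self, t1w: ImageVolume, normalized: bool = False) -> np.ndarray:
        """Per-voxel disease-region probabilities for a whole volume."""
        vol = t1w if normalized else normalize_volume(t1w)
        multiple = 2 ** (self.config.resolution_levels - 1)
        probs = np.empty(vol.shape, dtype=np.float64)
        for k in range(vol.n_slices):
            padded, (h, w) = _pad_to_multiple(vol.data[:, :, k], multiple)
            p = self.net.predict_proba(padded[None, None])[0, 0]
            probs[:, :, k] = p[:h, :w]
        return probs


def _collect_slices(cases: list[TrainingCase], subjects: frozenset, multiple: int):
    images, masks, owners = [], [], []
    for case in cases:
        if case.subject_id not in subjects:
            continue
        vol = normalize_volume(case.t1w)
        for k in range(vol.n_slices):
            img, _ = _pad_to_multiple(vol.data[:, :, k], multiple)
            msk, _ = _pad_to_multiple(case.disease_region.data[:, :, k].astype(np.float64), multiple)
            images.append(img)
            masks.append(msk)
            owners.append(case.subject_id)
    return images, masks, owners


def train(cases: list[TrainingCase], config: NetConfig, split: SubjectSplit):
    """Train one U-net on the split's training subjects.

    Returns ``(model, loss_trace)`` where the trace holds one BCE value per
    augmentation step. Fully deterministic for a fixed config seed.
    """
    config.validate()
    if not split.train_subjects:
        raise ValidationError("empty training subject set")
    case_subjects = {c.subject_id for c in cases}
    missing = split.train_subjects - case_subjects
    if missing:
        raise ValidationError(f"training subjects without data: {sorted(missing)}")

    multiple = 2 ** (config.resolution_levels - 1)
    images, masks, owners = _collect_slices(cases, split.train_subjects, multiple)
    # subject-level leakage guard: the pool must contain no held-out subject
    held_out = split.val_subjects | split.test_subjects
    assert not (set(owners) & held_out), "validation/test slices leaked into training"
    if not images:
        raise ValidationError("no training slices collected")

    net = UNet2d(config.resolution_levels, config.kernel_size, config.base_channels,
                 seed=config.seed)
    optimizer = Adam(net.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    n = len(images)
    trace: list[float] = []
    for _ in range(config.epochs):
        for _ in range(config.augmentation_steps_per_epoch):
            batch_idx = rng.choice(n, size=min(config.batch_size, n), replace=False)
            xb, yb = [], []
            for i in batch_idx:
                img, msk = augment_slice(images[i], masks[i], rng, config.augmentation)
                xb.append(img)
                yb.append(msk.astype(np.float64))
            x = np.stack(xb)[:, None]
            y = np.stack(yb)[:, None]
            logits = net.forward(x, train=True)
            loss, dlogits = bce_with_logits(logits, y)
            net.backward(dlogits)
            optimizer.step()
            trace.append(loss)
    return TrainedModel(net, config), trace


def train_ensemble(cases: list[TrainingCase], config: NetConfig, split: SubjectSplit,
                   n_models: int = ENSEMBLE_SIZE):
    """Train ``n_models`` networks with distinct seeds derived from the master seed."""
    models = []
    traces = []
    for i in range(n_models):
        member = replace(config, seed=(config.seed * 1000 + i) % (2**31))
        model, trace = train(cases, member, split)
        models.append(model)
        traces.append(trace)
    return models, traces


def ensemble_predict(models: list[TrainedModel], t1w: ImageVolume,
                     normalized: bool = False,
                     allow_nonstandard: bool = False) -> RegionMask:
    """Average the members' probability maps and round half-up at 0.5."""
    if len(models) != ENSEMBLE_SIZE and not allow_nonstandard:
        raise ValidationError(
            f"ensemble uses exactly {ENSEMBLE_SIZE} models (got {len(models)}); "
            "pass allow_nonstandard=True to override"
        )
    if not models:
        raise ValidationError("no models")
    mean = np.mean([m.predict_proba(t1w, normalized=normalized) for m in models], axis=0)
    return RegionMask(mean >= 0.5, t1w.spacing_mm, "disease_region_pred")


def evaluate_model(pred: RegionMask, truth: RegionMask) -> float:
    """Dice overlap of a predicted disease region against its reference."""
    return evaluation.dice(pred, truth)


def save_model(model: TrainedModel, path) -> None:
    """Checkpoint a trained model (weights + config + seed) as .npz."""
    import json
    from dataclasses import asdict

    cfg = asdict(model.config)
    cfg["augmentation"]["elastic_enabled"] = bool(cfg["augmentation"]["elastic_enabled"])
    state = model.net.get_state()
    np.savez(
        path,
        config_json=np.array(json.dumps(cfg)),
        **{f"arr_{i:03d}": a for i, a in enumerate(state)},
    )


def load_model(path) -> TrainedModel:
    import json

    with np.load(path, allow_pickle=False) as data:
        cfg = json.loads(str(data["config_json"]))
        aug = AugmentRanges(
            rotation_deg=cfg["augmentation"]["rotation_deg"],
            scale=tuple(cfg["augmentation"]["scale"]),
            shear=cfg["augmentation"]["shear"],
            power=tuple(cfg["augmentation"]["power"]),
            flip_prob=cfg["augmentation"]["flip_prob"],
            elastic_grid=cfg["augmentation"]["elastic_grid"],
            elastic_sigma_px=cfg["augmentation"]["elastic_sigma_px"],
            elastic_enabled=cfg["augmentation"]["elastic_enabled"],
        )
        config = NetConfig(
            epochs=cfg["epochs"],
            resolution_levels=cfg["resolution_levels"],
            kernel_size=cfg["kernel_size"],
            batch_size=cfg["batch_size"],
            learning_rate=cfg["learning_rate"],
            augmentation_steps_per_epoch=cfg["augmentation_steps_per_epoch"],
            base_channels=cfg["base_channels"],
            seed=cfg["seed"],
            augmentation=aug,
            allow_nonstandard=cfg["allow_nonstandard"],
        )
        keys = sorted(k for k in data.files if k.startswith("arr_"))
        state = [data[k] for k in keys]
    net = UNet2d(config.resolution_levels, config.kernel_size, config.base_channels,
                 seed=config.seed)
    net.set_state(state)
    return TrainedModel(net, config)
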