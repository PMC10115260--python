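"""Disease-region U-net: normalisation, augmentation, splits, training, ensemble."""

import numpy as np
import pytest

from vhiseg.core import ImageVolume, ValidationError, ConfigurationError
from vhiseg import disease_net as dn
from vhiseg.nn import UNet2d, bce_with_logits
from vhiseg.phantom import PhantomConfig, generate_phantom


SPACING = (1.0, 1.0, 3.0)


def small_cases(n, matrix=32, n_slices=8, noise_sd=2.0, seed0=500):
    cases = []
    for i in range(n):
        c = generate_phantom(PhantomConfig(matrix_size=(matrix, matrix),
                                           n_slices=n_slices, noise_sd=noise_sd,
                                           n_vessels=0, seed=seed0 + i))
        cases.append(dn.TrainingCase(f"s{i:02d}", c.t1w, c.truth_disease_region))
    return cases


class TestNormalizeVolume:
    def test_divides_by_three_population_sd(self):
        rng = np.random.default_rng(0)
        data = rng.normal(10, 2, (8, 8, 8))
        vol = ImageVolume(data, SPACING)
        out = dn.normalize_volume(vol)
        np.testing.assert_allclose(out.data, data / (3 * data.std()))
        # no mean subtraction
        assert out.data.mean() == pytest.approx(data.mean() / (3 * data.std()))

    def test_constant_volume_rejected(self):
        with pytest.raises(ValidationError):
            dn.normalize_volume(ImageVolume(np.full((8, 8, 8), 5.0), SPACING))

    def test_each_pass_leaves_population_sd_one_third(self):
        rng = np.random.default_rng(1)
        vol = ImageVolume(rng.normal(0, 7, (8, 8, 8)), SPACING)
        once = dn.normalize_volume(vol)
        twice = dn.normalize_volume(once)
        assert once.data.std() == pytest.approx(1 / 3)
        assert twice.data.std() == pytest.approx(1 / 3)


class TestAugmentation:
    def test_identity_parameters_reproduce_input(self):
        rng = np.random.default_rng(2)
        img = rng.random((16, 16))
        mask = rng.random((16, 16)) < 0.4
        params = dn.AugmentParams(rotation_deg=0.0, scale=1.0, shear=0.0,
                                  flip=False, power=1.0, elastic_disp=None)
        out_img = dn.apply_spatial(img, params, order=1) ** params.power
        out_mask = dn.apply_spatial(mask.astype(float), params, order=0) > 0.5
        np.testing.assert_allclose(out_img, img, atol=1e-12)
        np.testing.assert_array_equal(out_mask, mask)

    def test_flip_frequency_close_to_half(self):
        rng = np.random.default_rng(3)
        ranges = dn.AugmentRanges()
        flips = sum(dn.sample_augment_params(rng, ranges).flip for _ in range(10_000))
        assert abs(flips / 10_000 - 0.5) <= 0.02

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_shapes_preserved_and_mask_binary(self, seed):
        rng = np.random.default_rng(4)
        img = rng.random((20, 24))
        mask = rng.random((20, 24)) < 0.3
        out_img, out_mask = dn.augment_slice(img, mask, seed)
        assert out_img.shape == img.shape
        assert out_mask.shape == mask.shape
        assert out_mask.dtype == bool

    def test_mask_transform_consistent_with_image_transform(self):
        # the augmented mask equals the spatial transform applied to the mask alone
        rng = np.random.default_rng(5)
        img = rng.random((24, 24))
        mask = np.zeros((24, 24), dtype=bool)
        mask[6:18, 8:16] = True
        _, mask_joint = dn.augment_slice(img, mask, 17)
        params = dn.sample_augment_params(np.random.default_rng(17), dn.AugmentRanges())
        mask_alone = dn.apply_spatial(mask.astype(float), params, order=0) > 0.5
        np.testing.assert_array_equal(mask_joint, mask_alone)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            dn.augment_slice(np.zeros((8, 8)), np.zeros((9, 8), bool), 0)


class TestSplits:
    def test_cv4_with_eight_subjects_is_six_two(self):
        subjects = [f"s{i}" for i in range(8)]
        splits = dn.make_splits(subjects, "cv4", seed=0)
        assert len(splits) == 4
        for split in splits:
            assert len(split.train_subjects) == 6
            assert len(split.val_subjects) == 2

    def test_each_subject_validates_exactly_once(self):
        subjects = [f"s{i}" for i in range(9)]
        splits = dn.make_splits(subjects, "cv4", seed=1)
        seen = [s for split in splits for s in split.val_subjects]
        assert sorted(seen) == sorted(subjects)
        for split in splits:
            assert not (split.train_subjects & split.val_subjects)

    def test_seeded_twice_identical(self):
        subjects = [f"s{i}" for i in range(8)]
        assert dn.make_splits(subjects, "cv4", 42) == dn.make_splits(subjects, "cv4", 42)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError):
            dn.make_splits(["a", "b", "c"], "cv4", 0)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValidationError):
            dn.SubjectSplit(frozenset("ab"), frozenset("bc"))


class TestNetConfig:
    def test_hyperparameter_grid_enumerates_12_configurations(self):
        grid = dn.hyperparameter_grid()
        assert len(grid) == 12
        assert {(c.epochs, c.resolution_levels, c.kernel_size) for c in grid} == {
            (e, l, k) for e in (60, 100) for l in (2, 4, 6) for k in (3, 5)
        }

    def test_off_grid_values_require_override(self):
        with pytest.raises(ConfigurationError):
            dn.NetConfig(epochs=7).validate()
        dn.NetConfig(epochs=7, allow_nonstandard=True).validate()


class TestBackpropagation:
    def test_gradients_match_finite_differences(self):
        """Analytic gradients of the full tiny U-net vs central differences."""
        rng = np.random.default_rng(6)
        net = UNet2d(levels=2, kernel=3, base_channels=2, seed=0)
        x = rng.random((2, 1, 8, 8))
        y = (rng.random((2, 1, 8, 8)) < 0.5).astype(float)

        def loss_fn():
            return bce_with_logits(net.forward(x, train=True), y)[0]

        loss, grad = bce_with_logits(net.forward(x, train=True), y)
        net.backward(grad)
        params = net.params()
        eps = 1e-6
        checked = 0
        for p, g in params[::3]:  # sample every third parameter tensor
            flat_p, flat_g = p.ravel(), g.ravel()
            for idx in (0, flat_p.size // 2):
                orig = flat_p[idx]
                flat_p[idx] = orig + eps
                up = loss_fn()
                flat_p[idx] = orig - eps
                down = loss_fn()
                flat_p[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert numeric == pytest.approx(flat_g[idx], rel=1e-4, abs=1e-8)
                checked += 1
        assert checked >= 8


class TestTraining:
    def test_seeded_run_repeats_identical_loss_trace(self):
        cases = small_cases(3)
        split = dn.SubjectSplit(frozenset(["s00", "s01", "s02"]), frozenset())
        config = dn.NetConfig.test_profile(seed=9, epochs=1, steps_per_epoch=5)
        config = dn.NetConfig(**{**config.__dict__, "base_channels": 4})
        _, trace_a = dn.train(cases, config, split)
        _, trace_b = dn.train(cases, config, split)
        assert trace_a == trace_b

    def test_loss_decreases_on_separable_phantoms(self):
        cases = small_cases(4)
        split = dn.SubjectSplit(frozenset(f"s{i:02d}" for i in range(4)), frozenset())
        config = dn.NetConfig.test_profile(seed=2, epochs=2, steps_per_epoch=20)
        _, trace = dn.train(cases, config, split)
        assert np.mean(trace[-5:]) < np.mean(trace[:5])

    def test_validation_subjects_never_contribute_slices(self):
        cases = small_cases(4)
        split = dn.SubjectSplit(frozenset(["s00", "s03"]), frozenset(["s01"]),
                                frozenset(["s02"]))
        config = dn.NetConfig.test_profile(seed=0, epochs=1, steps_per_epoch=2)
        model, _ = dn.train(cases, config, split)  # internal leakage assert passes
        assert model.config.seed == 0

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValidationError):
            dn.train(small_cases(2), dn.NetConfig.test_profile(),
                     dn.SubjectSplit(frozenset(), frozenset(["s00"])))


class TestEnsemble:
    class _Stub:
        def __init__(self, value):
            self.value = value

        def predict_proba(self, t1w, normalized=False):
            return np.full(t1w.shape, self.value)

    def _t1w(self):
        return ImageVolume(np.zeros((4, 4, 2)), SPACING, "t1w")

    def test_half_rounds_up(self):
        models = [self._Stub(v) for v in (0.2, 0.6, 0.7)]  # mean exactly 0.5
        mask = dn.ensemble_predict(models, self._t1w())
        assert mask.data.all()

    def test_identical_models_equal_single_rounding(self):
        models = [self._Stub(0.51)] * 3
        mask = dn.ensemble_predict(models, self._t1w())
        assert mask.data.all()
        low = [self._Stub(0.1)] * 3
        assert not dn.ensemble_predict(low, self._t1w()).data.any()

    def test_requires_exactly_three_models_unless_overridden(self):
        with pytest.raises(ValidationError):
            dn.ensemble_predict([self._Stub(0.9)] * 2, self._t1w())
        mask = dn.ensemble_predict([self._Stub(0.9)] * 2, self._t1w(),
                                   allow_nonstandard=True)
        assert mask.data.all()

    def test_ensemble_members_get_distinct_seeds(self):
        cases = small_cases(3)
        split = dn.SubjectSplit(frozenset(["s00", "s01", "s02"]), frozenset())
        config = dn.NetConfig.test_profile(seed=1, epochs=1, steps_per_epoch=2)
        models, traces = dn.train_ensemble(cases, config, split, n_models=2)
        assert models[0].config.seed != models[1].config.seed
        assert traces[0] != traces[1]


class TestCheckpoint:
    def test_save_load_round_trip_preserves_predictions(self, tmp_path):
        cases = small_cases(2)
        split = dn.SubjectSplit(frozenset(["s00", "s01"]), frozenset())
        config = dn.NetConfig.test_profile(seed=3, epochs=1, steps_per_epoch=5)
        model, _ = dn.train(cases, config, split)
        path = tmp_path / "model.npz"
        dn.save_model(model, path)
        loaded = dn.load_model(path)
        vol = cases[0].t1w
        np.testing.assert_allclose(
            model.predict_proba(vol), loaded.predict_proba(vol), atol=1e-12
        )
        assert loaded.config == model.config
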