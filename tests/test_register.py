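"""Similarity measures, resampling and rigid registration recovery."""

import numpy as np
import pytest

import warpgauge as wg
from warpgauge.errors import DegenerateInputError, OverlapError
from warpgauge.register import (
    RegistrationConfig,
    marginal_entropy,
    mi_from_joint_histogram,
)
from warpgauge.volume import ImageVolume
from warpgauge.xform import AffineTransform, compose, decompose_affine


def noise_volume(shape, seed):
    rng = np.random.default_rng(seed)
    return ImageVolume(rng.uniform(0, 100, shape))


class TestMutualInformation:
    def test_self_mi_equals_marginal_entropy(self, reference):
        mi = wg.mutual_information(reference, reference, bins=64)
        h = marginal_entropy(reference, bins=64)
        assert mi == pytest.approx(h, abs=1e-12)

    def test_hand_built_joint_histogram(self):
        """[[2, 0], [0, 2]] has uniform marginals and a diagonal joint:
        MI = 1 bit exactly."""
        assert mi_from_joint_histogram(np.array([[2, 0], [0, 2]])) == pytest.approx(
            1.0, abs=1e-15
        )

    def test_independent_noise_near_zero(self):
        a = noise_volume((100, 100, 100), seed=1)
        b = noise_volume((100, 100, 100), seed=2)
        assert wg.mutual_information(a, b, bins=64) < 0.05

    def test_nonnegative(self, reference):
        shifted = AffineTransform.from_translation((2.5, 1.0, -0.5))
        assert wg.mutual_information(reference, reference, shifted) >= -1e-12

    def test_diverged_transform_raises(self, reference):
        far = AffineTransform.from_translation((500.0, 0, 0))
        with pytest.raises(OverlapError):
            wg.mutual_information(reference, reference, far)


class TestCorrelationRatio:
    def test_functional_dependence_approaches_one(self, reference):
        scaled = reference.like(3.0 * reference.data + 7.0)
        cr = wg.correlation_ratio(reference, scaled, bins=128)
        assert cr > 0.99

    def test_independent_noise_small(self):
        a = noise_volume((100, 100, 100), seed=3)
        b = noise_volume((100, 100, 100), seed=4)
        assert wg.correlation_ratio(a, b, bins=32) < 0.05

    def test_constant_moving_raises(self, reference):
        flat = reference.like(np.full(reference.shape, 5.0))
        with pytest.raises(DegenerateInputError):
            wg.correlation_ratio(reference, flat)


class TestResample:
    def test_identity_exact(self, reference):
        out = wg.resample(reference, AffineTransform.identity(), reference)
        assert np.array_equal(out.data, reference.data)

    def test_one_voxel_shift(self, reference):
        """Translation by exactly one voxel spacing shifts the array by one
        index in the interior."""
        a = AffineTransform.from_translation((1.0, 0.0, 0.0))  # 1 mm = 1 voxel
        out = wg.resample(reference, a, reference)
        assert np.allclose(out.data[1:, :, :], reference.data[:-1, :, :], atol=1e-9)

    def test_round_trip_error_small(self, reference):
        a = AffineTransform.from_params(
            translation_mm=(1.7, -0.9, 0.4),
            rotation_deg=(2.0, 1.0, -3.0),
            center_mm=reference.center_world,
        )
        fwd = wg.resample(reference, a, reference)
        back = wg.resample(fwd, wg.invert(a), reference)
        interior = reference.data > 0
        rms = np.sqrt(np.mean((back.data[interior] - reference.data[interior]) ** 2))
        assert rms < 0.02 * reference.data.max()

    def test_singular_transform_rejected(self, reference):
        from warpgauge.errors import SingularTransformError

        with pytest.raises(SingularTransformError):
            AffineTransform(np.diag([1.0, 1.0, 0.0, 1.0]))


class TestRegister:
    def test_self_registration_recovers_identity(self, reference):
        cfg = RegistrationConfig(dof=6, coarse_search_range_deg=6.0, seed=0)
        xfm, cost, diag = wg.register(reference, reference, cfg)
        rep = decompose_affine(xfm)
        c = reference.center_world
        assert np.linalg.norm(xfm.apply(c) - c) < 0.1
        assert np.abs(rep.rotation_deg).max() < 0.1

    def test_rigid_recovery(self, reference, landmarks, head_spec):
        """Known rigid truth at SNR ~20 recovered within 0.3 mm / 0.3 deg."""
        d = wg.DistortionSpec(
            translation_mm=(3.0, -2.0, 1.5), rotation_deg=(0, 0, 4.0),
            noise_sigma=3.0,
        )
        test, truth = wg.apply_ground_truth_distortion(
            reference, d, seed=2, landmarks=landmarks,
            cavity_center_mm=head_spec.cavity_center_mm,
        )
        cfg = RegistrationConfig(dof=6, coarse_search_range_deg=9.0, seed=0)
        xfm, cost, diag = wg.register(reference, test, cfg)
        err = compose(xfm, truth.true_affine)  # should be identity
        rep = decompose_affine(err)
        c = reference.center_world
        assert np.linalg.norm(err.apply(c) - c) < 0.3
        assert np.abs(rep.rotation_deg).max() < 0.3

    def test_cost_not_below_init(self, reference, head_spec):
        """Monotonicity: the returned transform never scores below init."""
        d = wg.DistortionSpec(translation_mm=(1.0, 0.5, -0.5), noise_sigma=3.0)
        test, truth = wg.apply_ground_truth_distortion(
            reference, d, seed=4, cavity_center_mm=head_spec.cavity_center_mm
        )
        init = truth.registration_affine
        cfg = RegistrationConfig(dof=6, seed=0, max_iterations=40)
        xfm, final_cost, diag = wg.register(reference, test, cfg, init=init)
        from warpgauge.register import _CostEngine

        engine = _CostEngine(
            reference, test, reference.data > 0, cfg.histogram_bins,
            max_samples=cfg.max_samples, seed=cfg.seed, jitter=True,
        )
        assert engine.evaluate(xfm) >= engine.evaluate(init) - 1e-6
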