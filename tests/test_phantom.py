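"""Phantom generation, distortion chain and ground-truth bookkeeping."""

import numpy as np
import pytest
from scipy import stats

import warpgauge as wg
from warpgauge.errors import InvalidSpecError, OutOfBoundsError
from warpgauge.phantom import Ellipsoid, PhantomSpec, _warp_displacement


def single_ellipsoid_spec(**kwargs):
    defaults = dict(
        grid_shape=(32, 32, 32),
        voxel_size_mm=(1.0, 1.0, 1.0),
        ellipsoids=[Ellipsoid((0, 0, 0), (10, 12, 8), (0, 0, 0), 1.0)],
        seed=0,
    )
    defaults.update(kwargs)
    return PhantomSpec(**defaults)


class TestGenerate:
    def test_center_inside_corner_outside(self):
        vol, _ = wg.generate_phantom(single_ellipsoid_spec())
        center = tuple(s // 2 for s in vol.shape)
        assert vol.data[center] == 1.0
        assert vol.data[0, 0, 0] == 0.0

    def test_determinism(self):
        spec = wg.default_head_spec(seed=42)
        v1, l1 = wg.generate_phantom(spec)
        v2, l2 = wg.generate_phantom(wg.default_head_spec(seed=42))
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(l1.positions, l2.positions)

    def test_bright_count_matches_bruteforce_membership(self):
        """Voxel count equals a direct quadratic-form membership sweep."""
        spec = single_ellipsoid_spec()
        vol, _ = wg.generate_phantom(spec)
        e = spec.ellipsoids[0]
        count = 0
        semi = np.asarray(e.semiaxes_mm)
        for i in range(vol.shape[0]):
            for j in range(vol.shape[1]):
                for k in range(vol.shape[2]):
                    p = vol.voxel_to_world(np.array([i, j, k], float))
                    q = (p - np.asarray(e.center_mm)) / semi
                    count += np.dot(q, q) <= 1.0
        assert int((vol.data > 0).sum()) == count

    def test_landmarks_inside_brain(self, head_spec, phantom_pair):
        vol, lm = phantom_pair
        assert len(lm) >= 7
        brain = head_spec.ellipsoids[0]
        assert bool(np.all(brain.contains(lm.positions)))

    def test_degenerate_grid_rejected(self):
        with pytest.raises(InvalidSpecError):
            single_ellipsoid_spec(grid_shape=(7, 32, 32))

    def test_negative_spacing_rejected(self):
        with pytest.raises(InvalidSpecError):
            single_ellipsoid_spec(voxel_size_mm=(1.0, -1.0, 1.0))


class TestDistortionChain:
    def test_identity_noop(self, reference):
        out, truth = wg.apply_ground_truth_distortion(
            reference, wg.DistortionSpec(), seed=0
        )
        assert np.abs(out.data - reference.data).max() < 1e-9
        assert truth.true_affine.almost_equal(wg.AffineTransform.identity())

    def test_translation_center_of_mass_oracle(self, reference):
        """COM of a smooth phantom shifts by exactly the applied translation."""
        d = wg.DistortionSpec(translation_mm=(3.0, -2.0, 1.5))
        out, _ = wg.apply_ground_truth_distortion(reference, d, seed=0)

        def com(vol):
            from scipy import ndimage

            return vol.voxel_to_world(np.array(ndimage.center_of_mass(vol.data)))

        shift = com(out) - com(reference)
        assert np.abs(shift - np.array([3.0, -2.0, 1.5])).max() < 0.1

    def test_full_dropout_kills_cavity_signal(self, reference, head_spec):
        cavity = head_spec.cavity_center_mm
        # relocate the cavity inside tissue so the ratio is meaningful
        inside = (0.0, -8.0, -7.0)
        d = wg.DistortionSpec(dropout_strength=1.0, dropout_sigma_mm=6.0)
        out, _ = wg.apply_ground_truth_distortion(
            reference, d, seed=0, cavity_center_mm=inside
        )
        ijk = tuple(np.round(reference.world_to_voxel(np.array(inside))).astype(int))
        assert out.data[ijk] < 0.05 * reference.data[ijk]
        del cavity

    def test_truth_landmark_mapping_exact(self, reference, landmarks):
        d = wg.DistortionSpec(
            translation_mm=(1, 2, -1),
            rotation_deg=(2, -3, 1),
            scales=(1.01, 0.99, 1.0),
            shears=(0.01, 0, -0.005),
            warp_amplitude_mm=1.5,
            warp_sigma_mm=5.0,
        )
        _, truth = wg.apply_ground_truth_distortion(
            reference, d, seed=0, landmarks=landmarks
        )
        mapped = truth.forward(truth.landmarks_ref.positions)
        assert np.abs(mapped - truth.landmarks_test.positions).max() < 1e-9

    def test_rician_background_is_rayleigh(self):
        """Zero signal + Rician noise: background follows Rayleigh(sigma)."""
        zero = wg.ImageVolume(np.zeros((48, 48, 48)))
        sigma = 2.5
        out, _ = wg.apply_ground_truth_distortion(
            zero, wg.DistortionSpec(noise_sigma=sigma), seed=1
        )
        sample = out.data.ravel()[:100000]
        _, p = stats.kstest(sample, stats.rayleigh(scale=sigma).cdf)
        assert p > 0.01

    def test_warp_locality(self):
        d = wg.DistortionSpec(warp_amplitude_mm=2.0, warp_sigma_mm=4.0)
        center = np.zeros(3)
        far = np.array([[4 * 4.0 + 0.5, 0, 0], [0, 20, 0], [0, 0, -30]])
        disp = _warp_displacement(far, d, center)
        assert np.linalg.norm(disp, axis=1).max() < 0.02 * 2.0

    def test_noninvertible_warp_rejected(self):
        with pytest.raises(InvalidSpecError):
            wg.DistortionSpec(warp_amplitude_mm=10.0, warp_sigma_mm=2.0)

    def test_scale_bounds_enforced(self):
        with pytest.raises(InvalidSpecError):
            wg.DistortionSpec(scales=(2.5, 1.0, 1.0))

    def test_presets_ordered(self):
        ps = wg.preset_distortion("PS")
        as_ = wg.preset_distortion("AS")
        assert max(abs(h) for h in as_.shears) > max(abs(h) for h in ps.shears)


class TestSlab:
    def test_slice_count(self, reference):
        slab = wg.make_slab(reference, (0, 0, 0), 40.0, 0.4, 2.0)
        assert slab.shape[2] == 20
        assert np.allclose(slab.voxel_size, (0.4, 0.4, 2.0))

    def test_world_bookkeeping(self, reference):
        """Slab voxel (i, j, 0) maps to the same world point as its parent."""
        slab = wg.make_slab(reference, (0, 0, 0), 40.0, 1.0, 2.0)
        w_slab = slab.voxel_to_world(np.array([3.0, 5.0, 0.0]))
        ijk_parent = reference.world_to_voxel(w_slab)
        w_parent = reference.voxel_to_world(ijk_parent)
        assert np.allclose(w_slab, w_parent, atol=1e-9)

    def test_mean_matches_parent_region(self, reference):
        """Slab mean equals the parent volume's mean over the same z-band."""
        slab = wg.make_slab(reference, (0, 0, 0), 20.0, 1.0, 1.0)
        zs = reference.grid_world_coordinates()[..., 2]
        band = (zs >= -10.5) & (zs <= 10.5)
        parent_mean = reference.data[band].mean()
        assert slab.data.mean() == pytest.approx(parent_mean, rel=0.05)

    def test_out_of_bounds_rejected(self, reference):
        with pytest.raises(OutOfBoundsError):
            wg.make_slab(reference, (0, 0, 30.0), 40.0, 1.0, 2.0)


class TestJitter:
    def test_zero_sigma_identity(self, landmarks):
        out = wg.jitter_landmarks(landmarks, 0.0, seed=3)
        assert np.array_equal(out.positions, landmarks.positions)

    def test_seeds_differ(self, landmarks):
        a = wg.jitter_landmarks(landmarks, 0.5, seed=1)
        b = wg.jitter_landmarks(landmarks, 0.5, seed=2)
        assert not np.array_equal(a.positions, b.positions)

    def test_mean_displacement_matches_sampling_oracle(self):
        """Observed mean 3D displacement matches a Monte-Carlo estimate.

        |N(0, sigma^2 I_3)| follows a chi_3 distribution scaled by sigma;
        the oracle is an independent large-sample simulation.
        """
        sigma = 0.5
        n = 1000
        lm = wg.LandmarkSet(
            [f"r{i}" for i in range(n)], np.zeros((n, 3))
        )
        out = wg.jitter_landmarks(lm, sigma, seed=11)
        observed = np.linalg.norm(out.positions, axis=1).mean()
        oracle_rng = np.random.default_rng(99)
        oracle = np.linalg.norm(
            oracle_rng.normal(0, sigma, (200000, 3)), axis=1
        ).mean()
        assert observed == pytest.approx(oracle, rel=0.05)
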