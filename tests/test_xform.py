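"""Affine algebra and decomposition metrics."""

import numpy as np
import pytest

from warpgauge.errors import ReflectionError, SingularTransformError
from warpgauge.xform import (
    AffineTransform,
    compose,
    decompose_affine,
    invert,
    rotation_matrix,
)


def random_proper_affine(rng, scale_spread=0.3, shear_spread=0.3):
    """Random rotation * positive scales * unit-upper-triangular shear."""
    return AffineTransform.from_params(
        translation_mm=rng.uniform(-20, 20, 3),
        rotation_deg=rng.uniform(-80, 80, 3),
        scales=np.exp(rng.uniform(-scale_spread, scale_spread, 3)),
        shears=rng.uniform(-shear_spread, shear_spread, 3),
    )


class TestDecompose:
    def test_identity(self):
        rep = decompose_affine(AffineTransform.identity())
        assert np.allclose(rep.scales, 1)
        assert np.allclose(rep.shear_tangents, 0)
        assert rep.determinant == pytest.approx(1.0)
        assert rep.max_scale_dev == 0
        assert rep.max_skew == 0
        assert rep.volume_dev == 0

    def test_diagonal_scaling(self):
        a = AffineTransform(np.diag([1.01, 0.99, 1.0, 1.0]))
        rep = decompose_affine(a)
        assert rep.max_scale_dev == pytest.approx(0.01)
        assert rep.determinant == pytest.approx(0.9999)
        assert rep.volume_dev == pytest.approx(0.0001, abs=1e-12)

    def test_pure_shear(self):
        m = np.eye(4)
        m[0, 1] = 0.01  # (x, y) entry of the unit-upper-triangular factor
        rep = decompose_affine(AffineTransform(m))
        assert rep.max_skew == pytest.approx(0.01)
        assert np.allclose(rep.scales, 1)
        assert rep.determinant == pytest.approx(1.0)

    def test_recomposition_and_determinant_oracle(self, rng):
        """1000 random proper affines: R*S*H round trip and det identity."""
        worst = 0.0
        for _ in range(1000):
            a = random_proper_affine(rng)
            rep = decompose_affine(a)
            back = rep.recompose()
            worst = max(worst, np.abs(back.matrix - a.matrix).max())
            # brute-force oracle for the volume-change metric
            assert rep.volume_dev == pytest.approx(
                abs(np.linalg.det(a.matrix[:3, :3]) - 1.0), abs=1e-12
            )
            assert rep.determinant == pytest.approx(np.prod(rep.scales))
        assert worst < 1e-10

    def test_left_rotation_leaves_scales_and_shears(self, rng):
        a = random_proper_affine(rng)
        rep = decompose_affine(a)
        r = np.eye(4)
        r[:3, :3] = rotation_matrix((17.0, -33.0, 55.0))
        rotated = AffineTransform(r.copy() @ a.matrix)
        rep2 = decompose_affine(rotated)
        assert np.allclose(rep2.scales, rep.scales, atol=1e-12)
        assert np.allclose(rep2.shear_tangents, rep.shear_tangents, atol=1e-12)

    def test_reflection_rejected(self):
        with pytest.raises(ReflectionError):
            decompose_affine(AffineTransform(np.diag([-1.0, 1, 1, 1])))

    def test_params_round_trip(self, rng):
        """from_params -> decompose recovers the construction parameters."""
        t = rng.uniform(-5, 5, 3)
        r = rng.uniform(-40, 40, 3)
        s = np.exp(rng.uniform(-0.1, 0.1, 3))
        h = rng.uniform(-0.05, 0.05, 3)
        a = AffineTransform.from_params(t, r, s, h)
        rep = decompose_affine(a)
        assert np.allclose(rep.translation_mm, t, atol=1e-10)
        assert np.allclose(rep.rotation_deg, r, atol=1e-9)
        assert np.allclose(rep.scales, s, atol=1e-12)
        assert np.allclose(rep.shear_tangents, h, atol=1e-12)


class TestComposeInvert:
    def test_compose_identity(self, rng):
        a = random_proper_affine(rng)
        assert compose(AffineTransform.identity(), a).almost_equal(a)
        assert compose(a, AffineTransform.identity()).almost_equal(a)

    def test_compose_translations(self):
        t1 = AffineTransform.from_translation((1, 2, 3))
        t2 = AffineTransform.from_translation((-4, 0.5, 2))
        out = compose(t1, t2)
        assert np.allclose(out.translation, (-3, 2.5, 5))

    def test_compose_applies_inner_first(self, rng):
        a = random_proper_affine(rng)
        b = random_proper_affine(rng)
        pts = rng.uniform(-10, 10, (20, 3))
        assert np.allclose(compose(b, a).apply(pts), b.apply(a.apply(pts)))

    def test_invert_translation(self):
        inv = invert(AffineTransform.from_translation((1, 2, 3)))
        assert np.allclose(inv.translation, (-1, -2, -3))

    def test_invert_round_trip(self, rng):
        for _ in range(50):
            a = random_proper_affine(rng)
            eye = compose(a, invert(a)).matrix
            assert np.abs(eye - np.eye(4)).max() < 1e-10

    def test_singular_rejected(self):
        m = np.eye(4)
        m[0, 0] = 0.0
        with pytest.raises(SingularTransformError):
            AffineTransform(m)


def test_rotation_convention_is_zyx_extrinsic():
    """R(rx, ry, rz) must equal Rz @ Ry @ Rx of the individual angles."""
    rx, ry, rz = 10.0, -20.0, 30.0
    full = rotation_matrix((rx, ry, rz))
    rxm = rotation_matrix((rx, 0, 0))
    rym = rotation_matrix((0, ry, 0))
    rzm = rotation_matrix((0, 0, rz))
    assert np.allclose(full, rzm @ rym @ rxm, atol=1e-12)
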