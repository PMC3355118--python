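"""Landmark transformation and distance statistics."""

import numpy as np
import pytest

from warpgauge.errors import EmptyMatchError
from warpgauge.landmarks import (
    LandmarkSet,
    landmark_distances,
    read_landmarks_tsv,
    transform_points,
    write_landmarks_tsv,
)
from warpgauge.xform import AffineTransform


def make_set(points, prefix="p"):
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return LandmarkSet([f"{prefix}{i}" for i in range(len(pts))], pts)


class TestTransformPoints:
    def test_identity(self):
        lm = make_set([[1, 2, 3], [4, 5, 6]])
        out = transform_points(AffineTransform.identity(), lm)
        assert out.names == lm.names
        assert np.allclose(out.positions, lm.positions)

    def test_translation(self):
        lm = make_set([[0, 0, 0]])
        out = transform_points(AffineTransform.from_translation((1, 0, 0)), lm)
        assert np.allclose(out.positions, [[1, 0, 0]])

    def test_matches_homogeneous_product(self, rng):
        a = AffineTransform.from_params(
            translation_mm=rng.uniform(-5, 5, 3),
            rotation_deg=rng.uniform(-30, 30, 3),
            scales=np.exp(rng.uniform(-0.1, 0.1, 3)),
            shears=rng.uniform(-0.05, 0.05, 3),
        )
        lm = make_set(rng.uniform(-20, 20, (12, 3)))
        out = transform_points(a, lm)
        homo = np.hstack([lm.positions, np.ones((12, 1))])
        expected = (a.matrix @ homo.T).T[:, :3]
        assert np.allclose(out.positions, expected, atol=1e-12)


class TestDistances:
    def test_identical_sets(self):
        lm = make_set([[1, 1, 1], [2, 2, 2], [3, 3, 3]])
        stats = landmark_distances(lm, lm)
        assert np.allclose(stats.distances_mm, 0)
        assert stats.mean == 0

    def test_three_four_five(self):
        ref = make_set([[0, 0, 0], [0, 0, 0]])
        test = make_set([[0, 0, 0], [3, 4, 0]])
        stats = landmark_distances(ref, test)
        assert sorted(stats.distances_mm) == [0.0, 5.0]

    def test_boxplot_convention_hand_oracle(self):
        """distances [1,2,3,4,100]: hand-computed quartiles and outlier.

        Linear-interpolation quartiles: Q1 = 2, Q3 = 4; IQR = 2; fences at
        -1 and 7; whiskers are the extreme data within the fences (1 and
        4); 100 is flagged as an outlier.
        """
        names = [f"p{i}" for i in range(5)]
        d = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        ref = LandmarkSet(names, np.zeros((5, 3)))
        test = LandmarkSet(names, np.column_stack([d, np.zeros((5, 2))]))
        stats = landmark_distances(ref, test)
        assert stats.median == 3.0
        assert stats.q1 == 2.0
        assert stats.q3 == 4.0
        assert stats.whisker_low == 1.0
        assert stats.whisker_high == 4.0
        assert stats.outliers == {"p4": 100.0}

    def test_missing_names_dropped_pairwise(self):
        ref = LandmarkSet(["a", "b", "c"], np.zeros((3, 3)))
        test = LandmarkSet(["b", "c", "d"], np.ones((3, 3)))
        stats = landmark_distances(ref, test)
        assert sorted(stats.names) == ["b", "c"]

    def test_no_match_raises(self):
        ref = LandmarkSet(["a"], np.zeros((1, 3)))
        test = LandmarkSet(["z"], np.zeros((1, 3)))
        with pytest.raises(EmptyMatchError):
            landmark_distances(ref, test)

    def test_rigid_invariance(self, rng):
        """Distances unchanged when both sets move through the same rigid."""
        ref = make_set(rng.uniform(-20, 20, (9, 3)))
        test = make_set(ref.positions + rng.normal(0, 1, (9, 3)))
        base = landmark_distances(ref, test).distances_mm
        rigid = AffineTransform.from_params(
            translation_mm=(5, -3, 2), rotation_deg=(10, 20, -15)
        )
        moved = landmark_distances(
            transform_points(rigid, ref), transform_points(rigid, test)
        ).distances_mm
        assert np.allclose(moved, base, atol=1e-10)

    def test_voxel_equivalent_uses_reference_voxel(self):
        ref = make_set([[0, 0, 0]])
        test = make_set([[3.0, 0, 0]])
        stats = landmark_distances(ref, test, voxel_size_mm=(1.0, 1.0, 2.0))
        diag = np.sqrt(1 + 1 + 4)
        assert stats.voxel_equivalent[0] == pytest.approx(3.0 / diag)


def test_tsv_round_trip(tmp_path, rng):
    lm = make_set(rng.uniform(-50, 50, (7, 3)), prefix="mark_")
    path = tmp_path / "lm.tsv"
    write_landmarks_tsv(lm, path)
    back = read_landmarks_tsv(path)
    assert back.names == lm.names
    assert np.allclose(back.positions, lm.positions, atol=1e-9)
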