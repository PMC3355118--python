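"""Parcellation, signal-loss exclusion and regional summaries."""

import numpy as np
import pandas as pd
import pytest

import warpgauge as wg
from warpgauge.errors import EmptySummaryError, ParcellationError
from warpgauge.preprocess import BrainMask
from warpgauge.regional import (
    Region,
    RegionalResult,
    detect_signal_loss,
    parcel,
    regional_summary,
)
from warpgauge.volume import ImageVolume
from warpgauge.xform import AffineTransform, decompose_affine


def full_mask(shape):
    return BrainMask(np.ones(shape, dtype=bool), np.eye(4))


class TestParcel:
    def test_thirds_arithmetic(self):
        """An AP span of 0..89 splits into [0,30), [30,60), [60,90)."""
        mask = full_mask((10, 90, 10))
        grid = parcel(mask, "3slab")
        ap_ranges = sorted(r.box[1] for r in grid)
        assert ap_ranges == [(0, 30), (30, 60), (60, 90)]

    def test_remainder_goes_to_last_third(self):
        mask = full_mask((10, 92, 10))
        grid = parcel(mask, "3slab")
        ap_ranges = sorted(r.box[1] for r in grid)
        assert ap_ranges == [(0, 30), (30, 60), (60, 92)]

    def test_region_counts(self, brain_mask):
        assert len(parcel(brain_mask, "3x3")) == 9
        assert len(parcel(brain_mask, "3slab")) == 3

    def test_labels_unique_and_descriptive(self, brain_mask):
        labels = [r.label for r in parcel(brain_mask, "3x3")]
        assert len(set(labels)) == 9
        assert "mid-middle" in labels
        assert "antero-superior" in labels

    def test_union_tiles_bounding_box_exactly(self, brain_mask):
        grid = parcel(brain_mask, "3x3")
        bbox = grid.bounding_box
        shape = brain_mask.shape
        covered = np.zeros(shape, dtype=int)
        for region in grid:
            covered[region.slices()] += 1
        box_mask = np.zeros(shape, dtype=bool)
        box_mask[tuple(slice(lo, hi) for lo, hi in bbox)] = True
        assert np.all(covered[box_mask] == 1)
        assert np.all(covered[~box_mask] == 0)

    def test_tiling_property_random_masks(self, rng):
        """Tiling holds for arbitrary mask shapes and offsets."""
        for _ in range(20):
            shape = tuple(rng.integers(12, 40, 3))
            mask = np.zeros(shape, dtype=bool)
            lo = [int(rng.integers(0, s - 8)) for s in shape]
            hi = [int(rng.integers(l + 6, s)) + 1 for l, s in zip(lo, shape)]
            mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
            bm = BrainMask(mask, np.eye(4))
            grid = parcel(bm, "3x3")
            covered = np.zeros(shape, dtype=int)
            for region in grid:
                covered[region.slices()] += 1
            box = tuple(slice(a, b) for a, b in bm.bounding_box)
            inside = np.zeros(shape, dtype=bool)
            inside[box] = True
            assert np.all(covered[inside] == 1)
            assert np.all(covered[~inside] == 0)

    def test_thin_mask_rejected(self):
        mask = full_mask((10, 2, 10))
        with pytest.raises(ParcellationError):
            parcel(mask, "3slab")

    def test_ap_names_follow_world_direction(self, brain_mask):
        """+y (anterior) thirds must be labelled antero."""
        grid = parcel(brain_mask, "3slab")
        centers = {}
        for region in grid:
            mids = [(lo + hi) / 2 for lo, hi in region.box]
            world = brain_mask.affine[:3, :3] @ mids + brain_mask.affine[:3, 3]
            centers[region.label] = world[1]
        assert centers["antero"] > centers["mid"] > centers["posterior"]


class TestSignalLoss:
    def test_intact_region_not_excluded(self, reference, brain_mask):
        grid = parcel(brain_mask, "3x3")
        for region in grid:
            excluded, _ = detect_signal_loss(reference, region, brain_mask)
            assert not excluded

    def test_dropout_region_excluded(self, reference, brain_mask, head_spec):
        """A full-strength dropout cavity at the frontal-inferior sinus
        position knocks out the antero-inferior region and only it."""
        grid = parcel(brain_mask, "3x3")
        d = wg.DistortionSpec(dropout_strength=1.0, dropout_sigma_mm=18.0)
        degraded, _ = wg.apply_ground_truth_distortion(
            reference, d, seed=0, cavity_center_mm=head_spec.cavity_center_mm
        )
        flags = {
            r.label: detect_signal_loss(degraded, r, brain_mask)[0] for r in grid
        }
        assert flags["antero-inferior"]
        # regions away from the cavity keep their signal
        assert not flags["posterior-superior"]
        assert not flags["mid-middle"]

    def test_flag_matches_direct_fraction(self, reference, brain_mask, rng):
        """Exclusion decision equals the counting definition for any
        threshold."""
        grid = parcel(brain_mask, "3x3")
        region = grid.regions[4]
        robust_max = np.percentile(reference.data[brain_mask.mask], 98)
        sl = region.slices()
        vals = reference.data[sl][brain_mask.mask[sl]]
        for frac in [0.05, 0.1, 0.3, 0.9]:
            for min_bright in [0.1, 0.5, 0.95]:
                expected = np.mean(vals > frac * robust_max) < min_bright
                got, _ = detect_signal_loss(
                    reference, region, brain_mask,
                    intensity_fraction=frac, min_bright_fraction=min_bright,
                )
                assert got == expected

    def test_empty_region_raises(self, reference):
        mask = BrainMask(
            np.pad(np.ones((10, 10, 10), dtype=bool), ((0, 54),) * 3),
            reference.affine,
        )
        empty = Region("far-corner", ((50, 60), (50, 60), (50, 60)))
        with pytest.raises(ParcellationError):
            detect_signal_loss(reference, empty, mask)


def _result(label, skew, scale_dev=0.0):
    a = AffineTransform.from_params(scales=(1 + scale_dev, 1, 1),
                                    shears=(skew, 0, 0))
    return RegionalResult(
        label=label, local=AffineTransform.identity(), total=a,
        report=decompose_affine(a), improved=True,
        cost_global_in_region=1.0, cost_total_in_region=1.1,
    )


class TestSummary:
    def test_single_result(self):
        table = regional_summary([_result("mid-middle", 0.01, 0.002)])
        row = table.loc["mid-middle"]
        assert row["mean_max_skew"] == pytest.approx(0.01)
        assert row["mean_max_scale_dev"] == pytest.approx(0.002)

    def test_two_runs_mean(self):
        runs = [[_result("antero-middle", 0.00)], [_result("antero-middle", 0.02)]]
        table = regional_summary(runs)
        assert table.loc["antero-middle", "mean_max_skew"] == pytest.approx(0.01)
        assert table.loc["antero-middle", "max_max_skew"] == pytest.approx(0.02)

    def test_matches_bruteforce_aggregation(self, rng):
        labels = ["a", "b", "c"]
        runs = []
        for _ in range(5):
            runs.append([_result(l, float(rng.uniform(0, 0.05))) for l in labels])
        table = regional_summary(runs)
        for label in labels:
            vals = [
                res.report.max_skew
                for run in runs for res in run if res.label == label
            ]
            assert table.loc[label, "mean_max_skew"] == pytest.approx(np.mean(vals))
            assert table.loc[label, "max_max_skew"] == pytest.approx(np.max(vals))
            assert table.loc[label, "n"] == 5

    def test_excluded_absent(self):
        results = [
            _result("mid-middle", 0.01),
            RegionalResult("antero-inferior", excluded=True, reason="signal loss"),
        ]
        table = regional_summary(results)
        assert "antero-inferior" not in table.index

    def test_all_excluded_raises(self):
        with pytest.raises(EmptySummaryError):
            regional_summary(
                [RegionalResult("x", excluded=True, reason="signal loss")]
            )

    def test_returns_dataframe(self):
        assert isinstance(regional_summary([_result("m", 0.0)]), pd.DataFrame)
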