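"""Piecewise regional registration: a spatial map of residual distortion.

After the global affine registration, the brain-mask bounding box is
parceled into sub-regions (a 3x3 grid of anterior–posterior x
superior–inferior thirds spanning the full left–right extent, or three
anterior–posterior slabs for thin axial acquisitions). Each region of the
globally registered test volume is then re-registered independently to the
corresponding reference region with a tightly bounded 12-DOF transform.
The scales/shears/determinant of the composed (local ∘ global) transform
approximate, to first order, the residual geometric distortion in that
region; regions whose test-image signal has been lost to susceptibility
effects are excluded before registration, since no meaningful estimate is
possible there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import EmptySummaryError, OverlapError, ParcellationError, WarpgaugeError
from .preprocess import BrainMask
from .register import RegistrationConfig, _CostEngine, register, resample
from .volume import ImageVolume
from .xform import AffineTransform, DecompositionReport, compose, decompose_affine

__all__ = [
    "Region",
    "RegionGrid",
    "RegionalResult",
    "parcel",
    "detect_signal_loss",
    "register_regions",
    "regional_summary",
]

log = logging.getLogger(__name__)


@dataclass
class Region:
    """One parcel: a label and half-open voxel index ranges per axis."""

    label: str
    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in self.box)  # type: ignore[return-value]

    def volume_voxels(self) -> int:
        return int(np.prod([hi - lo for lo, hi in self.box]))


@dataclass
class RegionGrid:
    """Parcellation of a brain-mask bounding box into labelled boxes."""

    scheme: str
    regions: list[Region]
    bounding_box: tuple[tuple[int, int], ...]

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class RegionalResult:
    """Outcome of one region's local registration.

    ``total = local ∘ global`` (global applied first); ``report`` is its
    decomposition. ``improved`` records whether the in-region cost of the
    total transform at least matches that of the global transform alone —
    the success criterion for a regional registration. Excluded regions
    (signal loss, or registration failure after all fallbacks) carry no
    report.
    """

    label: str
    excluded: bool = False
    reason: str = ""
    local: AffineTransform | None = None
    total: AffineTransform | None = None
    report: DecompositionReport | None = None
    improved: bool = False
    cost_global_in_region: float = float("nan")
    cost_total_in_region: float = float("nan")
    fallback_used: str = ""


# ---------------------------------------------------------------------
# parcellation

def _thirds(lo: int, hi: int) -> list[tuple[int, int]]:
    """Split [lo, hi) into three near-equal parts; remainder to the last."""
    width = (hi - lo) // 3
    return [
        (lo, lo + width),
        (lo + width, lo + 2 * width),
        (lo + 2 * width, hi),
    ]


def _world_axis_to_voxel_axis(affine: np.ndarray, world_axis: int) -> tuple[int, float]:
    """Voxel axis most aligned with a world axis, and its direction sign."""
    col = np.argmax(np.abs(affine[world_axis, :3]))
    return int(col), float(np.sign(affine[world_axis, col]))


def parcel(mask: BrainMask, scheme: str = "3x3") -> RegionGrid:
    """Split the mask bounding box into labelled thirds.

    ``"3x3"``: {posterior, mid, antero} x {superior, middle, inferior}
    over the anterior–posterior and superior–inferior world axes, full
    left–right extent (9 regions). ``"3slab"``: anterior–posterior thirds
    only (3 regions). The boxes tile the bounding box exactly.
    """
    if scheme not in ("3x3", "3slab"):
        raise ValueError("scheme must be '3x3' or '3slab'")
    bbox = mask.bounding_box
    ap_axis, ap_sign = _world_axis_to_voxel_axis(mask.affine, 1)
    si_axis, si_sign = _world_axis_to_voxel_axis(mask.affine, 2)
    if ap_axis == si_axis:
        raise ParcellationError("degenerate affine: AP and SI map to one voxel axis")
    for axis in {ap_axis} | ({si_axis} if scheme == "3x3" else set()):
        if bbox[axis][1] - bbox[axis][0] < 3:
            raise ParcellationError(
                f"mask thinner than 3 voxels along split axis {axis}"
            )

    ap_names = ["posterior", "mid", "antero"]
    if ap_sign < 0:  # increasing index runs anterior -> posterior
        ap_names = ap_names[::-1]
    ap_parts = _thirds(*bbox[ap_axis])

    regions: list[Region] = []
    if scheme == "3slab":
        for name, rng in zip(ap_names, ap_parts):
            box = list(bbox)
            box[ap_axis] = rng
            regions.append(Region(label=name, box=tuple(box)))  # type: ignore[arg-type]
    else:
        si_names = ["inferior", "middle", "superior"]
        if si_sign < 0:
            si_names = si_names[::-1]
        si_parts = _thirds(*bbox[si_axis])
        for si_name, si_rng in zip(si_names, si_parts):
            for ap_name, ap_rng in zip(ap_names, ap_parts):
                box = list(bbox)
                box[ap_axis] = ap_rng
                box[si_axis] = si_rng
                regions.append(
                    Region(label=f"{ap_name}-{si_name}", box=tuple(box))  # type: ignore[arg-type]
                )
    return RegionGrid(scheme=scheme, regions=regions, bounding_box=bbox)


# ---------------------------------------------------------------------
# signal-loss exclusion

def detect_signal_loss(
    vol: ImageVolume,
    region: Region,
    mask: BrainMask,
    intensity_fraction: float = 0.1,
    min_bright_fraction: float = 0.5,
) -> tuple[bool, str]:
    """Flag a region whose test-image signal is too depleted to register.

    A region is excluded when fewer than ``min_bright_fraction`` of its
    in-mask voxels exceed ``intensity_fraction`` of the volume's robust
    maximum (98th percentile inside the mask) — the situation near air
    cavities at high field, where susceptibility-induced dropout leaves no
    meaningful structure to drive a cost function.
    """
    sl = region.slices()
    m = mask.mask[sl]
    if not np.any(m):
        raise ParcellationError(f"region {region.label!r} contains no mask voxels")
    robust_max = float(np.percentile(vol.data[mask.mask], 98))
    if robust_max <= 0:
        return True, "no signal anywhere in the mask"
    vals = vol.data[sl][m]
    bright = float(np.mean(vals > intensity_fraction * robust_max))
    if bright < min_bright_fraction:
        return True, (
            f"signal loss: only {bright:.0%} of in-mask voxels above "
            f"{intensity_fraction:.0%} of robust max"
        )
    return False, ""


# ---------------------------------------------------------------------
# per-region registration

def _crop(vol: ImageVolume, region: Region) -> ImageVolume:
    sl = region.slices()
    sub = vol.data[sl]
    affine = vol.affine.copy()
    start = np.array([s.start for s in sl], dtype=float)
    affine[:3, 3] = vol.affine[:3, :3] @ start + vol.affine[:3, 3]
    return ImageVolume(sub.copy(), affine)


def _local_config(config: RegistrationConfig | None) -> RegistrationConfig:
    base = config or RegistrationConfig()
    # a single-level fit: the global transform already aligns the crops to
    # within ~1 mm, and coarse pyramid levels of a small crop carry too few
    # samples for a stable histogram cost
    return replace(
        base,
        dof=12,
        coarse_search_range_deg=0.0,
        pyramid_levels=1,
        max_samples=min(base.max_samples, 20000),
        max_iterations=max(base.max_iterations, 500),
        convergence_tol=min(base.convergence_tol, 1e-6),
        jitter_replicates=max(base.jitter_replicates, 2),
        scale_bound=base.scale_bound if base.scale_bound is not None else 0.1,
        shear_bound=base.shear_bound if base.shear_bound is not None else 0.1,
    )


def register_regions(
    fixed: ImageVolume,
    moving: ImageVolume,
    global_xfm: AffineTransform,
    grid: RegionGrid,
    config: RegistrationConfig | None = None,
    fixed_mask: BrainMask | None = None,
) -> list[RegionalResult]:
    """Independently re-register every region of the globally aligned pair.

    The moving volume is first resampled through the global transform onto
    the fixed grid, so each local registration starts at identity in fixed
    space and ``total = local ∘ global``. Failed local registrations fall
    back, in order, to a restricted ±5° rotation search, the correlation
    ratio cost, and perturbed initializations before the region is marked
    excluded. Per-region errors are recorded, never fatal.
    """
    if fixed_mask is None:
        fixed_mask = BrainMask(fixed.data > 0, fixed.affine)
    cfg = _local_config(config)
    moving_g = resample(moving, global_xfm, fixed)

    results: list[RegionalResult] = []
    for region in grid:
        try:
            excluded, reason = detect_signal_loss(moving_g, region, fixed_mask)
        except ParcellationError as exc:
            results.append(RegionalResult(region.label, excluded=True, reason=str(exc)))
            continue
        if excluded:
            log.info("region %s excluded: %s", region.label, reason)
            results.append(RegionalResult(region.label, excluded=True, reason=reason))
            continue

        f_crop = _crop(fixed, region)
        m_crop = _crop(moving_g, region)
        mask_crop = fixed_mask.mask[region.slices()]
        results.append(
            _register_one_region(region, f_crop, m_crop, mask_crop, global_xfm, cfg)
        )
    return results


def _region_engine(f_crop, m_crop, mask_crop, cfg) -> _CostEngine:
    return _CostEngine(
        f_crop, m_crop, mask_crop, cfg.histogram_bins, metric="mi",
        max_samples=cfg.max_samples, percentiles=cfg.intensity_percentiles,
        seed=cfg.seed, min_overlap=min(500, max(50, int(mask_crop.sum()) // 4)),
        jitter=True, jitter_replicates=cfg.jitter_replicates,
    )


def _register_one_region(
    region: Region,
    f_crop: ImageVolume,
    m_crop: ImageVolume,
    mask_crop: np.ndarray,
    global_xfm: AffineTransform,
    cfg: RegistrationConfig,
) -> RegionalResult:
    identity = AffineTransform.identity()
    engine = _region_engine(f_crop, m_crop, mask_crop, cfg)
    try:
        cost_global = engine.evaluate(identity)
    except (OverlapError, WarpgaugeError) as exc:
        return RegionalResult(region.label, excluded=True,
                              reason=f"no in-region overlap: {exc}")

    # fallback schedule: default run, restricted search angle, correlation
    # ratio cost, perturbed initializations
    attempts: list[tuple[str, RegistrationConfig, AffineTransform]] = [
        ("", cfg, identity),
        ("restricted search angle",
         replace(cfg, coarse_search_range_deg=5.0, coarse_search_step_deg=2.5),
         identity),
        ("correlation ratio cost", replace(cfg, cost="cr"), identity),
    ]
    rng = np.random.default_rng(cfg.seed)
    for k in range(2):
        jitter = AffineTransform.from_params(
            translation_mm=rng.normal(0, 1.0, 3),
            rotation_deg=rng.normal(0, 1.0, 3),
            center_mm=f_crop.center_world,
        )
        attempts.append((f"perturbed initialization {k + 1}", cfg, jitter))

    n_failures = 0
    best_local, best_cost, used = identity, cost_global, "none"
    for name, attempt_cfg, init in attempts:
        try:
            local, _, _ = register(
                f_crop, m_crop, attempt_cfg,
                init=init if attempt_cfg.coarse_search_range_deg == 0 else None,
                fixed_mask=mask_crop,
            )
            cost_total = engine.evaluate(local)
        except (OverlapError, WarpgaugeError) as exc:
            log.info("region %s attempt %r failed: %s", region.label, name, exc)
            n_failures += 1
            continue
        if cost_total > best_cost:
            best_local, best_cost, used = local, cost_total, name or "default"
        if cost_total >= cost_global:
            break  # attempt succeeded (matching the global is not a failure)
    if n_failures == len(attempts):
        return RegionalResult(
            region.label, excluded=True,
            reason="registration failed after all fallbacks",
        )
    total = compose(best_local, global_xfm)
    return RegionalResult(
        label=region.label,
        local=best_local,
        total=total,
        report=decompose_affine(total),
        improved=bool(best_cost > cost_global),
        cost_global_in_region=float(cost_global),
        cost_total_in_region=float(best_cost),
        fallback_used=used,
    )


# ---------------------------------------------------------------------
# summary

def regional_summary(results: list[list[RegionalResult]] | list[RegionalResult]) -> pd.DataFrame:
    """Per-label mean/max of the distortion metrics across runs.

    Accepts results from one run or a list of runs (e.g. several subjects
    or replicates); excluded regions are absent from the table. Aggregation
    is max-over-shear-components first (within each run's report), then
    mean/max across runs.
    """
    if results and isinstance(results[0], RegionalResult):
        runs = [results]  # type: ignore[list-item]
    else:
        runs = list(results)  # type: ignore[arg-type]
    rows: dict[str, dict[str, list[float]]] = {}
    for run in runs:
        for res in run:
            if res.excluded or res.report is None:
                continue
            acc = rows.setdefault(
                res.label,
                {"max_scale_dev": [], "max_skew": [], "volume_dev": []},
            )
            acc["max_scale_dev"].append(res.report.max_scale_dev)
            acc["max_skew"].append(res.report.max_skew)
            acc["volume_dev"].append(res.report.volume_dev)
    if not rows:
        raise EmptySummaryError("every region was excluded")
    records = []
    for label, acc in rows.items():
        rec = {"label": label, "n": len(acc["max_skew"])}
        for metric, vals in acc.items():
            rec[f"mean_{metric}"] = float(np.mean(vals))
            rec[f"max_{metric}"] = float(np.max(vals))
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("label")
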