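"""Staged affine registration maximizing mutual information.

The schedule mirrors the clinical workflow for co-registering two
acquisitions of the same head: a coarse rigid (6-DOF) search over rotation
space at a fixed angular step, local 6-DOF refinement through a Gaussian
multi-resolution pyramid, then — if requested — release of scales and
shears for a full 12-DOF affine polish at the finest levels. The cost is
mutual information of the joint intensity histogram (robust across
contrasts), with correlation ratio available as a fallback.

Conventions (load-bearing, because the decomposition must invert them):

* the returned transform maps moving-space world mm to fixed-space world mm;
* rotations are extrinsic about fixed axes, composed z·y·x, about the
  fixed volume's centre;
* resampling is inverse mapping with trilinear interpolation, zero outside
  the field of view;
* the cost samples only voxels inside the (dilated) fixed brain mask, so
  non-brain structure cannot drive the fit; intensities themselves are
  left intact — hard-zeroing the background would create an artificial
  edge at the mask cut that the cost would align instead of anatomy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .errors import DegenerateInputError, OverlapError
from .preprocess import BrainMask
from .volume import ImageVolume
from .xform import AffineTransform, decompose_affine, invert

__all__ = [
    "RegistrationConfig",
    "mutual_information",
    "correlation_ratio",
    "mi_from_joint_histogram",
    "marginal_entropy",
    "resample",
    "register",
]

_IDENTITY_PARAMS = np.array(
    [0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0], dtype=float
)
# characteristic parameter magnitudes: mm, deg, unitless scale/shear
_PARAM_SCALES = np.array([1, 1, 1, 1, 1, 1, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01])


@dataclass
class RegistrationConfig:
    """Knobs of the staged registration.

    ``coarse_search_range_deg``/``coarse_search_step_deg`` define the
    rotation grid searched at the coarsest pyramid level (default ±30° at
    3° steps). ``histogram_bins`` is the per-axis joint histogram size.
    ``scale_bound``/``shear_bound``, when set, clamp the affine parameters
    during optimization (used by regional registration to curb robustness
    loss in small fields of view).
    """

    dof: int = 12
    pyramid_levels: int = 3
    coarse_search_range_deg: float = 30.0
    coarse_search_step_deg: float = 3.0
    histogram_bins: int = 32
    cost: str = "mi"  # "mi" or "cr"
    convergence_tol: float = 1e-5
    max_iterations: int = 300
    max_samples: int = 60000
    intensity_percentiles: tuple[float, float] = (2.0, 98.0)
    # light symmetric pre-smoothing of both images (voxels) during cost
    # evaluation; counteracts the scale-shrinkage bias of histogram MI on
    # noisy data (interpolating noise rewards contraction)
    presmooth_vox: float = 0.5
    # sampling replicates per mask voxel for the jittered cost engines
    jitter_replicates: int = 1
    # the brain mask is dilated by this many voxels before sampling, so the
    # true brain boundary (and a thin background ring that anchors it)
    # stays inside the cost; sampling exactly at a thresholded cut would
    # align the artificial cut surface instead of anatomy
    mask_dilation_vox: int = 4
    scale_bound: float | None = None
    shear_bound: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dof not in (6, 12):
            raise ValueError("dof must be 6 or 12")
        if self.histogram_bins < 8:
            raise ValueError("histogram_bins must be >= 8")
        if self.coarse_search_step_deg <= 0:
            raise ValueError("coarse_search_step_deg must be positive")
        if self.cost not in ("mi", "cr"):
            raise ValueError("cost must be 'mi' or 'cr'")


# ---------------------------------------------------------------------
# similarity measures

def mi_from_joint_histogram(counts: np.ndarray) -> float:
    """Mutual information (bits) of a 2D joint count histogram.

    ``MI = H(f) + H(m) − H(f, m)`` evaluated by direct summation over the
    nonzero joint cells; always >= 0 up to floating error.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise DegenerateInputError("empty joint histogram")
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))


def _entropy_bits(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def _robust_range(values: np.ndarray, percentiles) -> tuple[float, float]:
    lo, hi = np.percentile(values, percentiles)
    if hi <= lo:
        lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        hi = lo + 1.0
    return float(lo), float(hi)


def _bin_indices(values: np.ndarray, lo: float, hi: float, bins: int) -> np.ndarray:
    idx = np.floor((values - lo) / (hi - lo) * bins).astype(np.intp)
    return np.clip(idx, 0, bins - 1)


class _CostEngine:
    """Evaluates the similarity of (fixed samples, transformed moving) pairs.

    Fixed-grid sample points inside the mask are cached with their
    pre-binned intensities; each evaluation maps them through the candidate
    transform into moving voxel space, interpolates, and accumulates the
    joint histogram.
    """

    def __init__(
        self,
        fixed: ImageVolume,
        moving: ImageVolume,
        mask: np.ndarray | None,
        bins: int,
        metric: str = "mi",
        max_samples: int | None = None,
        percentiles=(2.0, 98.0),
        seed: int = 0,
        min_overlap: int = 1000,
        jitter: bool = False,
        jitter_replicates: int = 1,
    ):
        self.bins = bins
        self.metric = metric
        self.min_overlap = min_overlap
        self.moving = moving
        if mask is None:
            sel = np.ones(fixed.shape, dtype=bool)
        else:
            sel = np.asarray(mask, dtype=bool)
        ijk = np.argwhere(sel)
        rng = np.random.default_rng(seed)
        if max_samples is not None and len(ijk) > max_samples:
            ijk = ijk[rng.choice(len(ijk), size=max_samples, replace=False)]
        if jitter:
            # off-grid sampling: breaks the grid-commensurability bias of
            # histogram MI, which otherwise displaces the optimum by ~1%
            # in scale for nearly commensurate voxel spacings; replicates
            # average out residual interpolation-phase structure (used for
            # small-crop regional fits)
            if jitter_replicates > 1:
                ijk = np.repeat(ijk, jitter_replicates, axis=0)
            ijk = ijk + rng.uniform(-0.5, 0.5, size=ijk.shape)
            ijk = np.clip(ijk, 0.0, np.asarray(fixed.shape, dtype=float) - 1.0)
            fvals = ndimage.map_coordinates(fixed.data, ijk.T, order=1)
        else:
            ijk = ijk.astype(float)
            fvals = fixed.data[tuple(ijk.astype(np.intp).T)]
        self.points_world = fixed.voxel_to_world(ijk)
        flo, fhi = _robust_range(fvals, percentiles)
        self.fixed_bins = _bin_indices(np.clip(fvals, flo, fhi), flo, fhi, bins)
        # the same robust-range rule as the fixed side, so MI(X, X) with an
        # identity transform reproduces the marginal entropy exactly
        self.mrange = _robust_range(moving.data.ravel(), percentiles)
        self.minv_affine = np.linalg.inv(moving.affine)
        self.mshape = np.asarray(moving.shape, dtype=float)
        self.n_evaluations = 0

    def _sample_moving(self, a: AffineTransform) -> tuple[np.ndarray, np.ndarray]:
        """Interpolated moving intensities at mapped sample points + validity."""
        b = self.minv_affine @ np.linalg.inv(a.matrix)
        coords = self.points_world @ b[:3, :3].T + b[:3, 3]
        valid = np.all((coords >= 0.0) & (coords <= self.mshape - 1.0), axis=1)
        vals = ndimage.map_coordinates(
            self.moving.data, coords[valid].T, order=1, mode="constant", cval=0.0
        )
        return vals, valid

    def joint_histogram(self, a: AffineTransform) -> np.ndarray:
        vals, valid = self._sample_moving(a)
        if valid.sum() < self.min_overlap:
            raise OverlapError(
                f"only {int(valid.sum())} overlapping samples "
                f"(< {self.min_overlap}); transform likely diverged"
            )
        lo, hi = self.mrange
        mb = _bin_indices(np.clip(vals, lo, hi), lo, hi, self.bins)
        fb = self.fixed_bins[valid]
        joint = np.bincount(fb * self.bins + mb, minlength=self.bins * self.bins)
        return joint.reshape(self.bins, self.bins)

    def evaluate(self, a: AffineTransform) -> float:
        self.n_evaluations += 1
        if self.metric == "mi":
            return mi_from_joint_histogram(self.joint_histogram(a))
        return self._correlation_ratio(a)

    def _correlation_ratio(self, a: AffineTransform) -> float:
        vals, valid = self._sample_moving(a)
        if valid.sum() < self.min_overlap:
            raise OverlapError("insufficient overlap for correlation ratio")
        total_var = float(np.var(vals))
        if total_var <= 0:
            raise DegenerateInputError("moving image constant over the overlap")
        fb = self.fixed_bins[valid]
        n_k = np.bincount(fb, minlength=self.bins).astype(float)
        s_k = np.bincount(fb, weights=vals, minlength=self.bins)
        s2_k = np.bincount(fb, weights=vals * vals, minlength=self.bins)
        nz = n_k > 0
        within = s2_k[nz] - s_k[nz] ** 2 / n_k[nz]
        return float(1.0 - within.sum() / (valid.sum() * total_var))

    def evaluate_safe(self, a: AffineTransform) -> float:
        """Evaluation that maps failures to -inf for use inside optimizers."""
        try:
            return self.evaluate(a)
        except (OverlapError, DegenerateInputError):
            return -np.inf


def mutual_information(
    fixed: ImageVolume,
    moving: ImageVolume,
    a: AffineTransform | None = None,
    bins: int = 64,
    mask: np.ndarray | None = None,
) -> float:
    """MI (bits) between fixed intensities and transform-mapped moving ones."""
    a = a if a is not None else AffineTransform.identity()
    eng = _CostEngine(fixed, moving, mask, bins, metric="mi")
    return eng.evaluate(a)


def correlation_ratio(
    fixed: ImageVolume,
    moving: ImageVolume,
    a: AffineTransform | None = None,
    bins: int = 64,
    mask: np.ndarray | None = None,
) -> float:
    """Correlation ratio in [0, 1]; 1 means moving is a function of fixed."""
    a = a if a is not None else AffineTransform.identity()
    eng = _CostEngine(fixed, moving, mask, bins, metric="cr")
    return eng.evaluate(a)


def marginal_entropy(vol: ImageVolume, bins: int = 64,
                     percentiles=(2.0, 98.0)) -> float:
    """Entropy (bits) of the volume's binned intensity histogram.

    Uses the same robust-range binning as :func:`mutual_information`, so
    ``mutual_information(x, x)`` equals ``marginal_entropy(x)`` exactly.
    """
    vals = vol.data.ravel()
    lo, hi = _robust_range(vals, percentiles)
    idx = _bin_indices(np.clip(vals, lo, hi), lo, hi, bins)
    return _entropy_bits(np.bincount(idx, minlength=bins))


# ---------------------------------------------------------------------
# resampling

def resample(moving: ImageVolume, a: AffineTransform, fixed_grid) -> ImageVolume:
    """Pull the moving volume onto the fixed grid through ``a``.

    Each fixed-grid voxel's world point is mapped through ``a``'s inverse
    into moving space and trilinearly interpolated; points outside the
    moving field of view become 0.
    """
    if isinstance(fixed_grid, ImageVolume):
        shape, affine = fixed_grid.shape, fixed_grid.affine
    else:
        shape, affine = fixed_grid
        affine = np.asarray(affine, dtype=float)
    out = ImageVolume(np.zeros(tuple(int(s) for s in shape)), affine)
    b = np.linalg.inv(moving.affine) @ invert(a).matrix @ out.affine
    idx = np.indices(out.shape, dtype=float).reshape(3, -1)
    coords = b[:3, :3] @ idx + b[:3, 3:4]
    out.data.ravel()[:] = ndimage.map_coordinates(
        moving.data, coords, order=1, mode="constant", cval=0.0
    )
    return out


# ---------------------------------------------------------------------
# parameterization and pyramid

def params_to_affine(params: np.ndarray, center: np.ndarray) -> AffineTransform:
    """12-vector (t mm, r deg, scales, shears) -> world affine about center."""
    p = np.asarray(params, dtype=float)
    return AffineTransform.from_params(
        translation_mm=p[0:3], rotation_deg=p[3:6],
        scales=p[6:9], shears=p[9:12], center_mm=center,
    )


def affine_to_params(a: AffineTransform, center: np.ndarray) -> np.ndarray:
    """Inverse of :func:`params_to_affine` (exact round trip)."""
    rep = decompose_affine(a)
    c = np.asarray(center, dtype=float)
    t = a.matrix[:3, 3] - c + a.matrix[:3, :3] @ c
    return np.concatenate([t, rep.rotation_deg, rep.scales, rep.shear_tangents])


def _downsample(vol: ImageVolume, mask: np.ndarray) -> tuple[ImageVolume, np.ndarray]:
    """Dyadic pyramid step with Gaussian pre-smoothing.

    Axes shorter than 16 voxels are kept at full resolution (thin-slab
    volumes should not collapse through the plane).
    """
    factors = np.array([2 if s >= 16 else 1 for s in vol.shape])
    sigma = np.where(factors == 2, 0.85, 0.0)
    data = ndimage.gaussian_filter(vol.data, sigma)
    sl = tuple(slice(None, None, int(f)) for f in factors)
    data = data[sl]
    scale = np.eye(4)
    scale[:3, :3] = np.diag(factors.astype(float))
    new_affine = vol.affine @ scale
    new_mask = mask[sl]
    return ImageVolume(data, new_affine), new_mask


def _build_pyramid(vol: ImageVolume, mask: np.ndarray, levels: int):
    """Finest-to-coarsest list of (volume, mask)."""
    out = [(vol, mask)]
    for _ in range(levels - 1):
        v, m = _downsample(*out[-1])
        if min(v.shape) < 8 and v.shape == out[-1][0].shape:
            break
        out.append((v, m))
    return out


def _center_of_mass_world(vol: ImageVolume, mask: np.ndarray) -> np.ndarray:
    w = np.where(mask, vol.data, 0.0)
    total = w.sum()
    if total <= 0:
        return vol.center_world
    idx = np.indices(vol.shape, dtype=float)
    com_ijk = np.array([(idx[i] * w).sum() / total for i in range(3)])
    return vol.voxel_to_world(com_ijk)


# ---------------------------------------------------------------------
# staged registration

def _clip_params(p: np.ndarray, config: RegistrationConfig) -> np.ndarray:
    p = p.copy()
    if config.scale_bound is not None:
        p[6:9] = np.clip(p[6:9], 1 - config.scale_bound, 1 + config.scale_bound)
    if config.shear_bound is not None:
        p[9:12] = np.clip(p[9:12], -config.shear_bound, config.shear_bound)
    return p


def _local_optimize(
    engine: _CostEngine,
    params0: np.ndarray,
    active: np.ndarray,
    center: np.ndarray,
    config: RegistrationConfig,
    step: float,
    max_iterations: int | None = None,
) -> tuple[np.ndarray, float, bool]:
    """Derivative-free (Nelder–Mead) ascent over the active parameters.

    Parameters are optimized in scaled units (mm, deg, 0.01 for
    scale/shear) so one simplex step is comparable across kinds; terminates
    when the cost change falls below ``convergence_tol``.
    """
    p0 = params0.copy()

    def neg_cost(y: np.ndarray) -> float:
        p = p0.copy()
        p[active] = p0[active] + y * _PARAM_SCALES[active]
        p = _clip_params(p, config)
        return -engine.evaluate_safe(params_to_affine(p, center))

    n = int(active.sum())
    y0 = np.zeros(n)
    simplex = np.vstack([y0] + [y0 + step * np.eye(n)[i] for i in range(n)])
    res = minimize(
        neg_cost,
        y0,
        method="Nelder-Mead",
        options={
            "initial_simplex": simplex,
            "fatol": config.convergence_tol,
            "xatol": 1e-4,
            "maxiter": max_iterations or config.max_iterations,
            "adaptive": True,
        },
    )
    best = p0.copy()
    best[active] = p0[active] + res.x * _PARAM_SCALES[active]
    best = _clip_params(best, config)
    return best, -res.fun, bool(res.success)


def _coarse_rotation_search(
    engine: _CostEngine,
    t0: np.ndarray,
    center: np.ndarray,
    config: RegistrationConfig,
    keep: int = 3,
) -> list[np.ndarray]:
    """Exhaustive rotation grid at the coarsest level; returns best starts."""
    r = config.coarse_search_range_deg
    step = config.coarse_search_step_deg
    angles = np.arange(-r, r + step / 2, step)
    scored: list[tuple[float, np.ndarray]] = []
    for rx, ry, rz in itertools.product(angles, angles, angles):
        p = _IDENTITY_PARAMS.copy()
        p[0:3] = t0
        p[3:6] = (rx, ry, rz)
        c = engine.evaluate_safe(params_to_affine(p, center))
        scored.append((c, p))
    scored.sort(key=lambda sc: -sc[0])
    return [p for _, p in scored[:keep]]


def register(
    fixed: ImageVolume,
    moving: ImageVolume,
    config: RegistrationConfig | None = None,
    init: AffineTransform | None = None,
    fixed_mask: BrainMask | np.ndarray | None = None,
) -> tuple[AffineTransform, float, dict]:
    """Staged 6-DOF → 12-DOF affine registration of moving onto fixed.

    Returns the world-to-world transform maximizing the cost, the final
    cost at full resolution, and a diagnostics dict (per-level costs,
    evaluation counts, coarse-search winner, convergence flags). When
    ``init`` is given the coarse rotation search is skipped and refinement
    starts from it. Non-convergence within the iteration budget is reported
    in the diagnostics; the best transform found so far is still returned.
    """
    config = config or RegistrationConfig()
    if fixed_mask is None:
        mask = fixed.data > 0
    elif isinstance(fixed_mask, BrainMask):
        mask = fixed_mask.mask
    else:
        mask = np.asarray(fixed_mask, dtype=bool)
    if config.mask_dilation_vox > 0 and not mask.all():
        mask = ndimage.binary_dilation(
            mask, iterations=config.mask_dilation_vox
        )

    if config.presmooth_vox > 0:
        fixed = ImageVolume(
            ndimage.gaussian_filter(fixed.data, config.presmooth_vox), fixed.affine
        )
    pyramid = _build_pyramid(fixed, mask, config.pyramid_levels)
    center = fixed.center_world
    diagnostics: dict = {"levels": [], "warnings": []}

    if config.presmooth_vox > 0:
        moving_eval = ImageVolume(
            ndimage.gaussian_filter(moving.data, config.presmooth_vox),
            moving.affine,
        )
    else:
        moving_eval = moving
    engines = []
    for lvl, (fvol, fmask) in enumerate(pyramid):
        engines.append(
            _CostEngine(
                fvol, moving_eval, fmask, config.histogram_bins,
                metric=config.cost, max_samples=config.max_samples,
                percentiles=config.intensity_percentiles,
                seed=config.seed + lvl,
                min_overlap=min(1000, max(100, fmask.sum() // 4)),
                jitter=True,
                jitter_replicates=config.jitter_replicates,
            )
        )

    coarse = engines[-1]  # coarsest level
    if init is not None:
        params = affine_to_params(init, center)
        starts = [params]
    else:
        com_f = _center_of_mass_world(*pyramid[-1])
        com_m_vox = ndimage.center_of_mass(np.maximum(moving.data, 0.0))
        com_m = moving.voxel_to_world(np.asarray(com_m_vox))
        t0 = com_f - com_m
        if config.coarse_search_range_deg > 0:
            starts = _coarse_rotation_search(coarse, t0, center, config)
            diagnostics["coarse_search_best_rotation"] = list(starts[0][3:6])
        else:
            p = _IDENTITY_PARAMS.copy()
            p[0:3] = t0
            starts = [p]

    rigid = np.zeros(12, dtype=bool)
    rigid[:6] = True
    full = np.ones(12, dtype=bool)

    if len(starts) == 1:
        # nothing to choose between; the pyramid loop refines from here
        params = starts[0]
    else:
        # short 6-DOF polish of each coarse candidate, keep the best
        best_params, best_cost = None, -np.inf
        for p in starts:
            cand, cost, _ = _local_optimize(
                coarse, p, rigid, center, config, step=1.5, max_iterations=80,
            )
            if cost > best_cost:
                best_params, best_cost = cand, cost
        params = best_params

    # refine through the pyramid, coarsest to finest
    n_levels = len(pyramid)
    for lvl in range(n_levels - 1, -1, -1):
        engine = engines[lvl]
        step = 1.0 if lvl > 0 else 0.5
        params, cost, ok = _local_optimize(
            engine, params, rigid, center, config, step=step
        )
        level_info = {"level": lvl, "dof6_cost": cost, "converged_6dof": ok}
        if config.dof == 12 and lvl <= 1:
            params, cost, ok12 = _local_optimize(
                engine, params, full, center, config, step=step
            )
            level_info.update({"dof12_cost": cost, "converged_12dof": ok12})
            if not ok12:
                diagnostics["warnings"].append(
                    f"12-DOF stage at level {lvl} hit the iteration budget"
                )
        if not ok:
            diagnostics["warnings"].append(
                f"6-DOF stage at level {lvl} hit the iteration budget"
            )
        level_info["n_evaluations"] = engine.n_evaluations
        diagnostics["levels"].append(level_info)

    final_engine = engines[0]
    result = params_to_affine(params, center)
    final_cost = final_engine.evaluate(result)
    if init is not None:
        # monotonicity guard: never return something worse than the init
        init_cost = final_engine.evaluate_safe(init)
        if init_cost > final_cost:
            diagnostics["warnings"].append("optimization did not beat init")
            return init, init_cost, diagnostics
    diagnostics["final_cost"] = final_cost
    diagnostics["final_params"] = params.tolist()
    return result, final_cost, diagnostics
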