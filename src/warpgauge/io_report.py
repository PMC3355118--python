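"""File formats, QC overlays and end-to-end pipeline orchestration.

Formats: NIfTI-1 volumes (via nibabel), 4x4 whitespace text transform
files in world-mm convention (with a converter to/from the scaled-voxel
convention used by FLIRT-style tools), landmark TSV, JSON reports, CSV
regional tables and PNG edge overlays.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .errors import GridError, UnsupportedFormatError
from .landmarks import (
    DistanceStats,
    LandmarkSet,
    landmark_distances,
    read_landmarks_tsv,
    transform_points,
)
from .preprocess import correct_bias, extract_brain
from .register import RegistrationConfig, register, resample
from .regional import RegionalResult, parcel, register_regions, regional_summary
from .volume import ImageVolume
from .xform import AffineTransform, decompose_affine

__all__ = [
    "read_volume",
    "write_volume",
    "read_transform",
    "write_transform",
    "world_matrix_from_flirt",
    "flirt_matrix_from_world",
    "edge_overlay",
    "PipelineConfig",
    "RunReport",
    "run_pipeline",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# volumes

def read_volume(path: str | Path) -> ImageVolume:
    """Load a single 3D scalar NIfTI volume."""
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise UnsupportedFormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise UnsupportedFormatError(
            f"{path}: expected a 3D scalar volume, got shape {data.shape}"
        )
    return ImageVolume(data.astype(np.float64), np.asarray(img.affine))


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write float32 NIfTI-1; intensities and affine round-trip losslessly."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


# ---------------------------------------------------------------------
# transforms

_MAT_HEADER = "# warpgauge affine: world-mm (RAS) moving -> fixed, row-major 4x4"


def write_transform(a: AffineTransform, path: str | Path) -> None:
    """4-line whitespace 4x4 text matrix with a convention header comment."""
    with open(path, "w") as fh:
        fh.write(_MAT_HEADER + "\n")
        for row in a.matrix:
            fh.write("  ".join(f"{v: .12g}" for v in row) + "\n")


def read_transform(path: str | Path) -> AffineTransform:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([float(v) for v in line.split()])
    m = np.asarray(rows, dtype=float)
    if m.shape != (4, 4):
        raise UnsupportedFormatError(f"{path}: expected a 4x4 matrix, got {m.shape}")
    return AffineTransform(m)


def _flirt_sampling_matrix(vol: ImageVolume) -> np.ndarray:
    """World <- scaled-voxel map used by the FLIRT matrix convention.

    Scaled-voxel coordinates are voxel indices times voxel size, with the
    first axis flipped when the voxel-to-world affine has positive
    determinant (neurological-order storage).
    """
    spacing = vol.voxel_size
    sv = np.eye(4)
    sv[:3, :3] = np.diag(spacing)
    if np.linalg.det(vol.affine[:3, :3]) > 0:
        flip = np.eye(4)
        flip[0, 0] = -1.0
        flip[0, 3] = (vol.shape[0] - 1) * spacing[0]
        sv = flip @ sv
    # voxel -> scaled-voxel is sv; world <- voxel is vol.affine
    return vol.affine @ np.linalg.inv(sv)


def world_matrix_from_flirt(
    flirt: np.ndarray, fixed: ImageVolume, moving: ImageVolume
) -> AffineTransform:
    """Convert a FLIRT-convention matrix (moving -> fixed) to world mm."""
    sf = _flirt_sampling_matrix(fixed)
    sm = _flirt_sampling_matrix(moving)
    return AffineTransform(sf @ np.asarray(flirt, float) @ np.linalg.inv(sm))


def flirt_matrix_from_world(
    a: AffineTransform, fixed: ImageVolume, moving: ImageVolume
) -> np.ndarray:
    """Inverse of :func:`world_matrix_from_flirt`."""
    sf = _flirt_sampling_matrix(fixed)
    sm = _flirt_sampling_matrix(moving)
    return np.linalg.inv(sf) @ a.matrix @ sm


# ---------------------------------------------------------------------
# edge overlay QC

def _edge_mask(data2d: np.ndarray, percentile: float) -> np.ndarray:
    from skimage.filters import sobel

    grad = sobel(data2d)
    nz = grad[grad > 0]
    if nz.size == 0:
        return np.zeros_like(data2d, dtype=bool)
    thr = np.percentile(nz, percentile)
    return grad >= thr


def edge_overlay(
    reference: ImageVolume,
    registered: ImageVolume,
    out_dir: str | Path,
    slice_spec: dict[str, int] | None = None,
    percentile: float = 90.0,
    prefix: str = "overlay",
) -> list[Path]:
    """Draw registered-volume edges over the grayscale reference.

    The standard operating-room sanity check: if the registration is good,
    the test image's structural edges trace the same anatomy on the
    reference. Gradient-magnitude edges of the registered volume
    (thresholded at ``percentile`` of nonzero gradients) are overlaid in
    red on axial/coronal/sagittal slices (grid mid-slices by default) and
    written as PNGs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not reference.same_grid(registered):
        raise GridError("edge overlay requires both volumes on the same grid")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mids = {axis: reference.shape[i] // 2 for i, axis in enumerate("xyz")}
    if slice_spec:
        mids.update(slice_spec)
    planes = {
        "sagittal": (0, mids["x"]),
        "coronal": (1, mids["y"]),
        "axial": (2, mids["z"]),
    }
    paths = []
    for name, (axis, idx) in planes.items():
        ref2d = np.take(reference.data, idx, axis=axis)
        reg2d = np.take(registered.data, idx, axis=axis)
        edges = _edge_mask(reg2d, percentile)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(ref2d.T, cmap="gray", origin="lower")
        overlay = np.zeros((*edges.T.shape, 4))
        overlay[edges.T] = (1.0, 0.1, 0.1, 1.0)
        ax.imshow(overlay, origin="lower")
        ax.set_axis_off()
        ax.set_title(f"{name} (idx {idx})", fontsize=8)
        path = out_dir / f"{prefix}_{name}.png"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------
# pipeline configuration and report

_ALLOWED_KEYS = {
    "fixed", "moving", "landmarks_fixed", "landmarks_moving", "output_dir",
    "registration", "scheme", "bias_correction", "brain_extraction",
    "write_overlays", "transform", "seed",
}
_ALLOWED_REG_KEYS = {f.name for f in RegistrationConfig.__dataclass_fields__.values()} \
    if hasattr(RegistrationConfig, "__dataclass_fields__") else set()


@dataclass
class PipelineConfig:
    """Schema-validated configuration of a full distortion analysis run."""

    fixed: str
    moving: str
    output_dir: str
    landmarks_fixed: str | None = None
    landmarks_moving: str | None = None
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    scheme: str = "3x3"
    bias_correction: bool = True
    brain_extraction: bool = True
    write_overlays: bool = True
    transform: str | None = None  # pre-computed .mat bypassing registration
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        reg_raw = dict(raw.pop("registration", {}) or {})
        unknown_reg = set(reg_raw) - _ALLOWED_REG_KEYS
        if unknown_reg:
            raise ValueError(f"unknown registration keys: {sorted(unknown_reg)}")
        reg = RegistrationConfig(**reg_raw)
        return cls(registration=reg, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class RunReport:
    """Self-contained record of one subject pair's distortion analysis."""

    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)
    global_transform: list | None = None
    global_cost: float | None = None
    decomposition: dict | None = None
    distance_stats: dict | None = None
    regional: list | None = None
    regional_table: str | None = None
    overlays: list | None = None
    errors: dict = field(default_factory=dict)
    input_hashes: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _hash_volume(vol: ImageVolume) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(vol.data).tobytes())
    h.update(np.ascontiguousarray(vol.affine).tobytes())
    return h.hexdigest()[:16]


def _regional_result_to_dict(res: RegionalResult) -> dict:
    d = {
        "label": res.label,
        "excluded": res.excluded,
        "reason": res.reason,
        "improved": res.improved,
        "cost_global_in_region": res.cost_global_in_region,
        "cost_total_in_region": res.cost_total_in_region,
        "fallback_used": res.fallback_used,
    }
    if not res.excluded and res.total is not None:
        d["local_matrix"] = res.local.matrix.tolist()
        d["total_matrix"] = res.total.matrix.tolist()
        d["report"] = res.report.to_dict()
    return d


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full workflow for one reference/test volume pair.

    Stage order: bias correction → brain extraction → global registration
    (6-DOF then 12-DOF staged internally) → landmark assessment → affine
    decomposition → regional piecewise registration → QC edge overlays.
    Each stage is logged with START/END and input hashes; a stage error is
    recorded and its dependents skipped, but the partial report is still
    written.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict())

    def _stage(name: str):
        log.info("START %s", name)
        report.stages[name] = "started"

    def _done(name: str):
        log.info("END %s", name)
        report.stages[name] = "done"

    fixed = read_volume(config.fixed)
    moving = read_volume(config.moving)
    report.input_hashes = {
        "fixed": _hash_volume(fixed), "moving": _hash_volume(moving)
    }

    fixed_mask = None
    try:
        if config.bias_correction:
            _stage("bias_correction")
            moving = correct_bias(moving)
            _done("bias_correction")
        if config.brain_extraction:
            _stage("brain_extraction")
            # the mask restricts the registration cost; intensities stay
            # intact (zeroed backgrounds would add artificial edges)
            fixed_mask, _ = extract_brain(fixed)
            _done("brain_extraction")
    except Exception as exc:
        report.errors["preprocess"] = str(exc)

    xfm = None
    try:
        _stage("global_registration")
        if config.transform:
            xfm = read_transform(config.transform)
            cost = None
        else:
            xfm, cost, diagnostics = register(
                fixed, moving, config.registration, fixed_mask=fixed_mask
            )
            report.stages["global_registration_diagnostics"] = diagnostics
        report.global_transform = xfm.matrix.tolist()
        report.global_cost = cost
        write_transform(xfm, out_dir / "global.mat")
        _done("global_registration")
    except Exception as exc:
        report.errors["global_registration"] = str(exc)

    if xfm is not None and config.landmarks_fixed and config.landmarks_moving:
        try:
            _stage("landmark_assessment")
            lm_fixed = read_landmarks_tsv(config.landmarks_fixed)
            lm_moving = read_landmarks_tsv(config.landmarks_moving)
            mapped = transform_points(xfm, lm_moving)
            stats = landmark_distances(lm_fixed, mapped,
                                       voxel_size_mm=fixed.voxel_size)
            report.distance_stats = stats.to_dict()
            _done("landmark_assessment")
        except Exception as exc:
            report.errors["landmark_assessment"] = str(exc)

    if xfm is not None:
        try:
            _stage("decomposition")
            report.decomposition = decompose_affine(xfm).to_dict()
            _done("decomposition")
        except Exception as exc:
            report.errors["decomposition"] = str(exc)

        try:
            _stage("regional_analysis")
            if fixed_mask is None:
                fixed_mask, _ = extract_brain(fixed)
            grid = parcel(fixed_mask, config.scheme)
            results = register_regions(
                fixed, moving, xfm, grid, config.registration, fixed_mask
            )
            report.regional = [_regional_result_to_dict(r) for r in results]
            try:
                table = regional_summary(results)
                table_path = out_dir / "regional_summary.csv"
                table.to_csv(table_path)
                report.regional_table = str(table_path)
            except Exception as exc:
                report.errors["regional_summary"] = str(exc)
            _done("regional_analysis")
        except Exception as exc:
            report.errors["regional_analysis"] = str(exc)

        if config.write_overlays:
            try:
                _stage("qc_overlays")
                registered = resample(moving, xfm, fixed)
                paths = edge_overlay(fixed, registered, out_dir / "qc")
                report.overlays = [str(p) for p in paths]
                _done("qc_overlays")
            except Exception as exc:
                report.errors["qc_overlays"] = str(exc)

    report.to_json(out_dir / "report.json")
    return report
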