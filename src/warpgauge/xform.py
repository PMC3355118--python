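"""Affine transform algebra and distortion metrics.

A registration between two acquisitions of the same brain produces a 4x4
homogeneous affine mapping moving-space world mm to fixed-space world mm.
The non-rigid content of that matrix is what quantifies geometric
distortion: the deviation of the scale factors from 1, the shear tangents,
and the deviation of the determinant from 1 (volume change).

The 3x3 block is factored uniquely as ``A3 = R @ S @ H`` where ``R`` is a
proper rotation, ``S = diag(scales)`` with positive scales, and ``H`` is
unit-upper-triangular whose off-diagonal entries are the shear tangents
(the tangent of the skew angle). Shear values are order-dependent, so the
R·S·H order (rotation after scale after shear, reading right to left as
applied to points) is fixed and documented here; it matches the common
avscale-style convention. Metrics are always computed from the world-mm
matrix, so anisotropic voxels cannot masquerade as scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ReflectionError, SingularTransformError

__all__ = [
    "AffineTransform",
    "DecompositionReport",
    "decompose_affine",
    "compose",
    "invert",
    "rotation_matrix",
]

_SHEAR_LABELS = ("xy", "xz", "yz")


def rotation_matrix(rotation_deg) -> np.ndarray:
    """3x3 rotation from extrinsic angles about fixed axes, composed z·y·x.

    ``R = Rz(rz) @ Ry(ry) @ Rx(rx)`` for ``rotation_deg = (rx, ry, rz)``.
    """
    rx, ry, rz = np.asarray(rotation_deg, dtype=float)
    return Rotation.from_euler("xyz", [rx, ry, rz], degrees=True).as_matrix()


class AffineTransform:
    """4x4 homogeneous world-to-world affine (mm to mm).

    Acts on points as a matrix-vector product in homogeneous coordinates;
    the last row is always (0, 0, 0, 1) and the 3x3 block is non-singular.
    """

    __slots__ = ("matrix",)

    def __init__(self, matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(matrix[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise ValueError("last row of an affine must be (0, 0, 0, 1)")
        if abs(np.linalg.det(matrix[:3, :3])) < 1e-15:
            raise SingularTransformError("3x3 block of affine is singular")
        m = matrix.copy()
        m[3] = (0.0, 0.0, 0.0, 1.0)
        self.matrix = m

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_translation(cls, t) -> "AffineTransform":
        m = np.eye(4)
        m[:3, 3] = np.asarray(t, dtype=float)
        return cls(m)

    @classmethod
    def from_params(
        cls,
        translation_mm=(0.0, 0.0, 0.0),
        rotation_deg=(0.0, 0.0, 0.0),
        scales=(1.0, 1.0, 1.0),
        shears=(0.0, 0.0, 0.0),
        center_mm=(0.0, 0.0, 0.0),
    ) -> "AffineTransform":
        """Build ``T(c) T(t) R S H T(-c)``: rotate/scale/shear about a centre.

        ``shears`` are the (xy, xz, yz) tangents of the skew angles; the
        resulting matrix decomposes back to exactly these parameters (for
        ``center_mm = 0`` also the same translation).
        """
        c = np.asarray(center_mm, dtype=float)
        t = np.asarray(translation_mm, dtype=float)
        sh = np.asarray(shears, dtype=float)
        h = np.eye(3)
        h[0, 1], h[0, 2], h[1, 2] = sh
        a3 = rotation_matrix(rotation_deg) @ np.diag(np.asarray(scales, float)) @ h
        m = np.eye(4)
        m[:3, :3] = a3
        m[:3, 3] = t + c - a3 @ c
        return cls(m)

    # -- behaviour ----------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (..., 3) world points through the transform."""
        points = np.asarray(points, dtype=float)
        return points @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3].copy()

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:3, :3].copy()

    def __matmul__(self, other: "AffineTransform") -> "AffineTransform":
        return AffineTransform(self.matrix @ other.matrix)

    def __repr__(self) -> str:
        return f"AffineTransform(\n{np.array_str(self.matrix, precision=6)})"

    def almost_equal(self, other: "AffineTransform", atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=atol))


@dataclass
class DecompositionReport:
    """Parameters and distortion metrics of a decomposed affine.

    ``max_scale_dev`` is the maximum absolute deviation of any scale factor
    from 1, ``max_skew`` the maximum absolute shear tangent, and
    ``volume_dev`` the absolute deviation of the 3x3 determinant from 1 —
    the three headline distortion metrics of the analysis.
    """

    translation_mm: np.ndarray
    rotation_deg: np.ndarray
    scales: np.ndarray
    shear_tangents: np.ndarray  # (xy, xz, yz)
    determinant: float
    max_scale_dev: float = field(init=False)
    max_skew: float = field(init=False)
    volume_dev: float = field(init=False)

    def __post_init__(self) -> None:
        self.translation_mm = np.asarray(self.translation_mm, dtype=float)
        self.rotation_deg = np.asarray(self.rotation_deg, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        self.shear_tangents = np.asarray(self.shear_tangents, dtype=float)
        self.max_scale_dev = float(np.max(np.abs(self.scales - 1.0)))
        self.max_skew = float(np.max(np.abs(self.shear_tangents)))
        self.volume_dev = float(abs(self.determinant - 1.0))

    def recompose(self) -> AffineTransform:
        """Rebuild the affine from the decomposed parameters."""
        return AffineTransform.from_params(
            translation_mm=self.translation_mm,
            rotation_deg=self.rotation_deg,
            scales=self.scales,
            shears=self.shear_tangents,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("translation_mm", "rotation_deg", "scales", "shear_tangents"):
            d[key] = [float(v) for v in d[key]]
        d["shear_labels"] = list(_SHEAR_LABELS)
        return d


def decompose_affine(a: AffineTransform) -> DecompositionReport:
    """Factor an affine into rotation, scales and shear tangents.

    Gram–Schmidt on the columns of the 3x3 block (a QR factorization with
    the diagonal forced positive) yields ``A3 = R @ (S @ H)`` with ``R`` a
    proper rotation, ``S`` positive diagonal and ``H`` unit-upper-triangular.
    A negative determinant means the registration produced a reflection,
    which is pathological for same-subject brain images and raises.
    """
    a3 = a.matrix[:3, :3]
    det = float(np.linalg.det(a3))
    if det <= 0:
        raise ReflectionError(
            f"affine has non-positive determinant {det:.6g}; "
            "a proper (orientation-preserving) transform is required"
        )
    q, r = np.linalg.qr(a3)
    # force positive diagonal so q is the unique proper rotation
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    q = q * signs
    r = signs[:, None] * r
    scales = np.diag(r).copy()
    h = r / scales[:, None]
    rotation = Rotation.from_matrix(q).as_euler("xyz", degrees=True)
    return DecompositionReport(
        translation_mm=a.matrix[:3, 3],
        rotation_deg=rotation,
        scales=scales,
        shear_tangents=np.array([h[0, 1], h[0, 2], h[1, 2]]),
        determinant=det,
    )


def compose(outer: AffineTransform, inner: AffineTransform) -> AffineTransform:
    """Transform applying ``inner`` first, then ``outer`` (matrix product)."""
    return AffineTransform(outer.matrix @ inner.matrix)


def invert(a: AffineTransform) -> AffineTransform:
    """Inverse transform; ``compose(a, invert(a))`` is identity to 1e-10."""
    try:
        return AffineTransform(np.linalg.inv(a.matrix))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded in ctor
        raise SingularTransformError(str(exc)) from exc
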