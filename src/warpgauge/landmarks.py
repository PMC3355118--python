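"""Named anatomical landmarks and registration-error distance statistics.

The registration itself is landmark-free; landmarks are held out and used
only to validate it. After the recovered transform is applied to the test
image's landmarks, the 3D Euclidean distance to the corresponding
reference landmarks is the per-landmark target registration error, and its
boxplot summary is the headline validation statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptyMatchError
from .xform import AffineTransform

__all__ = [
    "LandmarkSet",
    "DistanceStats",
    "transform_points",
    "landmark_distances",
    "read_landmarks_tsv",
    "write_landmarks_tsv",
]

log = logging.getLogger(__name__)


@dataclass
class LandmarkSet:
    """Ordered list of uniquely named world-mm points."""

    names: list[str]
    positions: np.ndarray  # (n, 3) world mm

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape != (len(self.names), 3):
            raise ValueError("positions must be (n, 3) matching names")
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("landmark positions must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.positions[self.names.index(name)]

    def subset(self, names: list[str]) -> "LandmarkSet":
        idx = [self.names.index(n) for n in names]
        return LandmarkSet([self.names[i] for i in idx], self.positions[idx])


@dataclass
class DistanceStats:
    """Boxplot summary of per-landmark Euclidean distances.

    Quartiles use linear interpolation of order statistics; whiskers extend
    to the most extreme datum within 1.5·IQR of the box, and anything
    beyond is an outlier. ``voxel_equivalent`` expresses each distance in
    units of the reference-image voxel size (the clinically meaningful
    scale: sub-voxel error means the registration is as good as the data
    allow).
    """

    names: list[str]
    distances_mm: np.ndarray
    mean: float = field(init=False)
    median: float = field(init=False)
    q1: float = field(init=False)
    q3: float = field(init=False)
    whisker_low: float = field(init=False)
    whisker_high: float = field(init=False)
    outliers: dict[str, float] = field(init=False)
    voxel_size_mm: np.ndarray | None = None
    voxel_equivalent: np.ndarray | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        d = np.asarray(self.distances_mm, dtype=float)
        self.distances_mm = d
        self.mean = float(np.mean(d))
        self.median = float(np.median(d))
        self.q1 = float(np.percentile(d, 25, method="linear"))
        self.q3 = float(np.percentile(d, 75, method="linear"))
        iqr = self.q3 - self.q1
        lo_fence, hi_fence = self.q1 - 1.5 * iqr, self.q3 + 1.5 * iqr
        inside = d[(d >= lo_fence) & (d <= hi_fence)]
        if inside.size:
            self.whisker_low = float(inside.min())
            self.whisker_high = float(inside.max())
        else:  # pathological: everything an outlier
            self.whisker_low = self.q1
            self.whisker_high = self.q3
        out = (d < self.whisker_low) | (d > self.whisker_high)
        self.outliers = {
            n: float(v) for n, v, o in zip(self.names, d, out) if o
        }
        if self.voxel_size_mm is not None:
            vs = np.asarray(self.voxel_size_mm, dtype=float)
            self.voxel_size_mm = vs
            # per-axis is meaningless for a scalar distance; use the voxel
            # diagonal as the conservative one-voxel yardstick
            self.voxel_equivalent = d / float(np.linalg.norm(vs))

    def to_dict(self) -> dict:
        d = {
            "names": list(self.names),
            "distances_mm": [float(v) for v in self.distances_mm],
            "mean": self.mean,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "whisker_low": self.whisker_low,
            "whisker_high": self.whisker_high,
            "outliers": dict(self.outliers),
        }
        if self.voxel_size_mm is not None:
            d["voxel_size_mm"] = [float(v) for v in self.voxel_size_mm]
            d["voxel_equivalent"] = [float(v) for v in self.voxel_equivalent]
        return d


def transform_points(a: AffineTransform, lm: LandmarkSet) -> LandmarkSet:
    """Map every landmark through an affine; names are preserved."""
    return LandmarkSet(list(lm.names), a.apply(lm.positions))


def landmark_distances(
    ref: LandmarkSet,
    test: LandmarkSet,
    voxel_size_mm=None,
) -> DistanceStats:
    """Per-landmark 3D Euclidean distances between two named point sets.

    Landmarks are matched by name; names present in only one set are
    dropped pairwise with a logged warning (a landmark can be unmarkable
    in one acquisition, e.g. lost to susceptibility signal dropout).
    """
    common = [n for n in ref.names if n in set(test.names)]
    missing = sorted(set(ref.names) ^ set(test.names))
    if missing:
        log.warning("dropping unmatched landmarks: %s", ", ".join(missing))
    if not common:
        raise EmptyMatchError("no landmark names shared between the two sets")
    r = ref.subset(common)
    t = test.subset(common)
    d = np.linalg.norm(r.positions - t.positions, axis=1)
    return DistanceStats(names=common, distances_mm=d, voxel_size_mm=voxel_size_mm)


# -- TSV interchange --------------------------------------------------

def write_landmarks_tsv(lm: LandmarkSet, path: str | Path) -> None:
    """Write ``name<TAB>x<TAB>y<TAB>z`` (world mm) rows."""
    with open(path, "w") as fh:
        for name, (x, y, z) in zip(lm.names, lm.positions):
            fh.write(f"{name}\t{x:.10g}\t{y:.10g}\t{z:.10g}\n")


def read_landmarks_tsv(path: str | Path) -> LandmarkSet:
    names: list[str] = []
    pos: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"malformed landmark row: {line!r}")
            names.append(parts[0])
            pos.append([float(v) for v in parts[1:]])
    return LandmarkSet(names, np.asarray(pos))
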