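"""Streamline geometry primitives: arc-length resampling, length,
ROI intersection at a millimetre criterion, exclusion-plane filtering and
mask dilation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import GeometryError, UsageError
from .formats_io import Streamline, Tractogram, VolumeGrid

__all__ = [
    "ExclusionPlane",
    "resample_streamline",
    "streamline_length",
    "intersects_roi",
    "min_distance_to_roi",
    "crosses_plane",
    "filter_by_planes",
    "dilate_mask",
    "load_planes",
    "save_planes",
]


@dataclasses.dataclass
class ExclusionPlane:
    """An infinite plane used to drop streamlines.

    ``mode``:
      - ``remove_crossing``: drop streamlines with consecutive points on
        opposite sides (a point exactly on the plane counts as crossing).
      - ``keep_side_positive`` / ``keep_side_negative``: drop streamlines
        with ANY point on the forbidden side.  Positive side = direction of
        the normal.
    """

    point: np.ndarray
    normal: np.ndarray
    mode: str = "remove_crossing"

    _MODES = ("remove_crossing", "keep_side_positive", "keep_side_negative")

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).ravel()
        self.normal = np.asarray(self.normal, dtype=float).ravel()
        if self.point.shape != (3,) or self.normal.shape != (3,):
            raise GeometryError("plane point and normal must be 3-vectors")
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-6:
            if n < 1e-12:
                raise GeometryError("plane normal has zero length")
            self.normal = self.normal / n
        if self.mode not in self._MODES:
            raise UsageError(f"unknown plane mode {self.mode!r}; expected one of {self._MODES}")

    def signed_distances(self, pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - self.point) @ self.normal


def streamline_length(s: Streamline) -> float:
    """Total polyline length in mm (sum of Euclidean segment lengths)."""
    return float(np.linalg.norm(np.diff(s.points, axis=0), axis=1).sum())


def resample_streamline(s: Streamline, n_nodes: int) -> Streamline:
    """Resample to ``n_nodes`` points at equal arc-length spacing.

    Endpoints are preserved exactly; interior nodes are linear
    interpolations along the original polyline.
    """
    if n_nodes < 2:
        raise UsageError(f"n_nodes must be >= 2, got {n_nodes}")

    def one_pass(pts: np.ndarray) -> np.ndarray:
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        total = seg.sum()
        if total <= 0:
            raise GeometryError("cannot resample a zero-length streamline")
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        targets = np.linspace(0.0, total, n_nodes)
        out = np.empty((n_nodes, 3))
        for k in range(3):
            out[:, k] = np.interp(targets, cum, pts[:, k])
        out[0] = pts[0]
        out[-1] = pts[-1]
        return out

    # iterate to the equal-chord fixed point so the operation is idempotent
    pts = one_pass(s.points)
    for _ in range(30):
        new = one_pass(pts)
        if np.max(np.abs(new - pts)) < 1e-13:
            pts = new
            break
        pts = new
    return Streamline(pts)


def _roi_tree(roi: VolumeGrid) -> cKDTree:
    mask = np.asarray(roi.data) > 0
    if not mask.any():
        raise UsageError("ROI mask is empty")
    return cKDTree(roi.voxel_centers_world(mask))


def min_distance_to_roi(points: np.ndarray, roi: VolumeGrid) -> float:
    """Smallest Euclidean distance from any point to any ROI voxel center."""
    d, _ = _roi_tree(roi).query(np.atleast_2d(points))
    return float(np.min(d))


def intersects_roi(s: Streamline, roi: VolumeGrid, max_dist: float = 2.0) -> bool:
    """True iff some streamline point lies within ``max_dist`` (inclusive)
    of an ROI voxel center."""
    return min_distance_to_roi(s.points, roi) <= max_dist


def crosses_plane(s: Streamline, plane: ExclusionPlane) -> bool:
    """True iff consecutive points land on opposite (or on-plane) sides."""
    d = plane.signed_distances(s.points)
    # a point exactly on the plane belongs to both sides
    return bool(np.any(d[:-1] * d[1:] <= 0))


def _plane_keeps(s: Streamline, plane: ExclusionPlane) -> bool:
    d = plane.signed_distances(s.points)
    if plane.mode == "remove_crossing":
        return not bool(np.any(d[:-1] * d[1:] <= 0))
    if plane.mode == "keep_side_positive":
        return bool(np.all(d >= 0))
    return bool(np.all(d <= 0))


def filter_by_planes(t: Tractogram, planes: list[ExclusionPlane]) -> Tractogram:
    """Apply exclusion planes conjunctively; empty result is allowed."""
    keep = [i for i, s in enumerate(t) if all(_plane_keeps(s, p) for p in planes)]
    return t.subset(keep)


def dilate_mask(roi: VolumeGrid, npass: int) -> VolumeGrid:
    """``npass`` iterations of 6-connectivity binary dilation (npass=0 is
    the identity)."""
    if npass < 0:
        raise UsageError(f"npass must be >= 0, got {npass}")
    mask = np.asarray(roi.data) > 0
    if npass > 0:
        struct = ndimage.generate_binary_structure(3, 1)
        mask = ndimage.binary_dilation(mask, structure=struct, iterations=npass)
    return roi.with_data(mask.astype(np.uint8))


# ---------------------------------------------------------------------------
# Plane (de)serialization: JSON [{"point": [...], "normal": [...], "mode": ...}]
# ---------------------------------------------------------------------------

def load_planes(path: str | Path) -> list[ExclusionPlane]:
    with open(path) as fh:
        raw = json.load(fh)
    return [ExclusionPlane(np.array(p["point"]), np.array(p["normal"]), p.get("mode", "remove_crossing")) for p in raw]


def save_planes(planes: list[ExclusionPlane], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(
            [
                {"point": p.point.tolist(), "normal": p.normal.tolist(), "mode": p.mode}
                for p in planes
            ],
            fh,
            indent=2,
        )
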