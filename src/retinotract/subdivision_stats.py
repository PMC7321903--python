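"""Endpoint-based tract subdivision and its signal-detection quantification.

The target ROI is split 50/50 along its major axis; streamlines are
labelled PRO1 / PRO2 / UNASSIGNED by the half their ROI-side endpoint
terminates in; a hits / false-alarms d' summarises how well an
independently extracted subcomponent respects the split; seed-side
endpoints are histogrammed along the medial->lateral axis.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import norm

from .errors import UsageError
from .formats_io import Tractogram, VolumeGrid

__all__ = [
    "RoiSplit",
    "ClassificationResult",
    "DetectionStats",
    "split_roi",
    "classify_by_endpoint",
    "detection_stats",
    "detection_stats_from_counts",
    "endpoint_histogram",
]

LABELS = ("PRO1", "PRO2", "UNASSIGNED")

_AXIS_VECTORS = {
    "x": np.array([1.0, 0.0, 0.0]),
    "y": np.array([0.0, 1.0, 0.0]),
    "z": np.array([0.0, 0.0, 1.0]),
}


@dataclasses.dataclass
class RoiSplit:
    anterior_mask: VolumeGrid
    posterior_mask: VolumeGrid
    axis: np.ndarray  # unit 3-vector, anterior-positive
    split_value: float  # median projection


@dataclasses.dataclass
class ClassificationResult:
    labels: list[str]  # per-streamline, from LABELS
    proportions: dict[str, float]

    @property
    def counts(self) -> dict[str, int]:
        return {l: self.labels.count(l) for l in LABELS}

    def to_frame(self, endpoints: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"streamline": np.arange(len(self.labels)), "label": self.labels})
        if endpoints is not None:
            df[["end_x_mm", "end_y_mm", "end_z_mm"]] = np.asarray(endpoints)
        return df


@dataclasses.dataclass
class DetectionStats:
    hits: float
    false_alarms: float
    d_prime: float
    n: int | None = None


def _hint_vector(orientation_hint: str) -> np.ndarray:
    hint = orientation_hint.lower().lstrip("+")
    sign = 1.0
    if hint.startswith("-"):
        sign, hint = -1.0, hint[1:]
    if hint not in _AXIS_VECTORS:
        raise UsageError(f"unknown orientation hint {orientation_hint!r}; use one of +/-x, y, z")
    return sign * _AXIS_VECTORS[hint]


def split_roi(roi: VolumeGrid, orientation_hint: str = "y") -> RoiSplit:
    """Split an ROI into two equal halves along its major axis.

    The axis is the first principal direction of the ROI voxel world
    coordinates, sign-aligned with ``orientation_hint`` (anterior
    positive); for degenerate ROIs the hint axis itself is used.  Voxels
    are rank-ordered by projection (stable on voxel index) and the upper
    half — ties going anterior — forms the anterior mask, so the two
    halves differ by at most one voxel.
    """
    mask = np.asarray(roi.data) > 0
    idx = np.argwhere(mask)
    if idx.shape[0] < 2:
        raise UsageError("ROI must contain at least 2 voxels to split")
    # canonical voxel order for deterministic ties
    order0 = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
    idx = idx[order0]
    coords = roi.voxel_centers_world(mask)[order0]
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    hint = _hint_vector(orientation_hint)
    if evals[-1] <= 1e-12 or (evals[-1] - evals[-2]) / evals[-1] < 1e-9:
        axis = hint  # degenerate: no unique major axis
    else:
        axis = evecs[:, -1]
        if axis @ hint < 0:
            axis = -axis
    proj = centered @ axis
    rank = np.argsort(proj, kind="stable")
    n = len(rank)
    n_anterior = (n + 1) // 2
    anterior_rows = rank[n - n_anterior :]
    ant = np.zeros(mask.shape, dtype=np.uint8)
    sel = idx[anterior_rows]
    ant[sel[:, 0], sel[:, 1], sel[:, 2]] = 1
    post = (mask & ~(ant > 0)).astype(np.uint8)
    split_value = float(np.median(proj))
    return RoiSplit(
        anterior_mask=roi.with_data(ant),
        posterior_mask=roi.with_data(post),
        axis=np.asarray(axis, dtype=float),
        split_value=split_value,
    )


def roi_endpoints(t: Tractogram, roi: VolumeGrid) -> np.ndarray:
    """For each streamline, the endpoint nearer the ROI (n x 3 world mm)."""
    mask = np.asarray(roi.data) > 0
    if not mask.any():
        raise UsageError("ROI mask is empty")
    tree = cKDTree(roi.voxel_centers_world(mask))
    ends = np.array([[s.points[0], s.points[-1]] for s in t])  # (n, 2, 3)
    d, _ = tree.query(ends.reshape(-1, 3))
    d = d.reshape(-1, 2)
    pick = np.argmin(d, axis=1)
    return ends[np.arange(len(t)), pick]


def classify_by_endpoint(t: Tractogram, split: RoiSplit, max_dist: float = 2.0) -> ClassificationResult:
    """Label each streamline by the split half its ROI-side endpoint
    terminates in (within ``max_dist`` of a voxel center; nearer half wins
    when both are in reach)."""
    if len(t) == 0:
        raise UsageError("cannot classify an empty tractogram")
    ant_mask = np.asarray(split.anterior_mask.data) > 0
    post_mask = np.asarray(split.posterior_mask.data) > 0
    roi_union = split.anterior_mask.with_data((ant_mask | post_mask).astype(np.uint8))
    ends = roi_endpoints(t, roi_union)
    ant_tree = cKDTree(split.anterior_mask.voxel_centers_world(ant_mask))
    post_tree = cKDTree(split.posterior_mask.voxel_centers_world(post_mask))
    d_ant, _ = ant_tree.query(ends)
    d_post, _ = post_tree.query(ends)
    labels = []
    for da, dp in zip(d_ant, d_post):
        in_a, in_p = da <= max_dist, dp <= max_dist
        if in_a and (not in_p or da <= dp):
            labels.append("PRO1")
        elif in_p:
            labels.append("PRO2")
        else:
            labels.append("UNASSIGNED")
    n = len(labels)
    proportions = {l: labels.count(l) / n for l in LABELS}
    return ClassificationResult(labels=labels, proportions=proportions)


def _clamp_rate(rate: float, n: int | None) -> float:
    """Standard signal-detection boundary correction for perfect rates."""
    if n is not None and n > 0:
        lo, hi = 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)
    else:
        lo, hi = 1e-12, 1.0 - 1e-12
    return float(np.clip(rate, lo, hi))


def detection_stats(hits: float, false_alarms: float, n: int | None = None) -> DetectionStats:
    """d' = z(hits) - z(false alarms), z the standard-normal quantile.

    Rates of exactly 0 or 1 are clamped to 1/(2N) and 1 - 1/(2N) when a
    sample size is given.
    """
    if not (0.0 <= hits <= 1.0 and 0.0 <= false_alarms <= 1.0):
        raise UsageError("rates must lie in [0, 1]")
    h = _clamp_rate(hits, n)
    f = _clamp_rate(false_alarms, n)
    return DetectionStats(hits=hits, false_alarms=false_alarms, d_prime=float(norm.ppf(h) - norm.ppf(f)), n=n)


def detection_stats_from_counts(n_reference: int, n_opposite: int) -> DetectionStats:
    """Detection stats for a subcomponent from its termination counts.

    ``n_reference``: subcomponent fibers ending in its reference half
    (hits numerator); ``n_opposite``: ending in the opposite half.
    """
    n = n_reference + n_opposite
    if n == 0:
        raise UsageError("subcomponent has zero fibers")
    return detection_stats(n_reference / n, n_opposite / n, n=n)


def endpoint_histogram(
    t: Tractogram, seed_roi: VolumeGrid, axis: str = "medial_lateral", max_dist: float = 2.0
) -> pd.DataFrame:
    """Per-voxel seed-side endpoint counts, sorted medial -> lateral.

    Voxels of the seed ROI are sorted by ascending world X; a streamline
    contributes to every voxel whose center lies within ``max_dist`` of its
    seed-side endpoint (multi-voxel contribution allowed).
    """
    if axis != "medial_lateral":
        raise UsageError(f"unsupported histogram axis {axis!r}")
    mask = np.asarray(seed_roi.data) > 0
    if not mask.any():
        raise UsageError("seed ROI is empty")
    centers = seed_roi.voxel_centers_world(mask)
    order = np.lexsort((centers[:, 2], centers[:, 1], centers[:, 0]))
    centers = centers[order]
    counts = np.zeros(len(centers), dtype=int)
    if len(t) > 0:
        ends = roi_endpoints(t, seed_roi)
        tree = cKDTree(centers)
        for e in ends:
            for vi in tree.query_ball_point(e, max_dist):
                counts[vi] += 1
    return pd.DataFrame({"x_mm": centers[:, 0], "y_mm": centers[:, 1], "z_mm": centers[:, 2], "count": counts})
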