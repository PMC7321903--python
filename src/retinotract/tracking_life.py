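"""Curvature-constrained ensemble tractography on a tensor field, and
non-negative least-squares streamline pruning against the measured
diffusion signal.

Tracking is deterministic: streamlines are seeded at uniform positions
inside the seed mask and propagated bidirectionally along the principal
tensor eigenvector with a fixed step, stopping on mask exit, low
anisotropy, a per-step bend cap derived from the curvature radius
(theta_max = 2 asin(step / 2r)), or length limits.  The ensemble merges
runs over several curvature radii without deduplication.

Pruning uses a stick-model signal prediction per traversed voxel,
demeaned over the directions of one shell, and solves for non-negative
per-streamline weights; zero-weight streamlines are discarded.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import optimize, sparse

from .errors import UsageError
from .formats_io import GradientTable, Streamline, Tractogram, VolumeGrid
from .tensor_model import TensorField, tensors_to_matrices

__all__ = [
    "TrackingConfig",
    "LifeResult",
    "track_single",
    "ensemble_track",
    "life_prune",
    "theta_max",
]

STICK_AXIAL_DIFFUSIVITY = 1.7e-3  # mm^2/s, pruning forward model


@dataclasses.dataclass
class TrackingConfig:
    curvature_radii: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
    step_mm: float | None = None  # default 0.5 * voxel size, resolved at run time
    max_fibers: int = 10_000
    max_trials: int = 1_000_000
    min_length_mm: float = 10.0
    max_length_mm: float = 250.0
    endpoint_dist_mm: float = 2.0
    stop_fa: float = 0.15
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.curvature_radii):
            raise UsageError("curvature radii must be > 0")
        if self.step_mm is not None and self.step_mm <= 0:
            raise UsageError("step_mm must be > 0")
        if self.max_fibers > self.max_trials:
            raise UsageError("max_fibers must be <= max_trials")


@dataclasses.dataclass
class LifeResult:
    weights: np.ndarray  # per-candidate, >= 0
    kept: Tractogram
    kept_indices: np.ndarray
    error_map: VolumeGrid  # per-voxel residual norm


def theta_max(step_mm: float, radius_mm: float) -> float:
    """Per-step bend cap (radians) for a curvature radius; capped at pi."""
    x = step_mm / (2.0 * radius_mm)
    return np.pi if x >= 1.0 else 2.0 * np.arcsin(x)


class _TensorSampler:
    """Tri-linear interpolation of the 6 tensor coefficient volumes plus a
    nearest-voxel mask lookup, in world coordinates."""

    def __init__(self, tensors: TensorField, wm_mask: VolumeGrid):
        self.coeffs = np.ascontiguousarray(tensors.coefficients)
        self.mask = np.asarray(wm_mask.data) > 0
        self.inv_affine = np.linalg.inv(wm_mask.affine)
        self.shape = np.array(self.mask.shape)

    def voxel_coords(self, pt: np.ndarray) -> np.ndarray:
        return self.inv_affine[:3, :3] @ pt + self.inv_affine[:3, 3]

    def in_mask(self, pt: np.ndarray) -> bool:
        v = np.round(self.voxel_coords(pt)).astype(int)
        if np.any(v < 0) or np.any(v >= self.shape):
            return False
        return bool(self.mask[v[0], v[1], v[2]])

    def tensor_at(self, pt: np.ndarray) -> np.ndarray:
        v = self.voxel_coords(pt)
        f = np.floor(v).astype(int)
        w = v - f
        c = np.zeros(6)
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    i, j, k = f[0] + dx, f[1] + dy, f[2] + dz
                    if np.any((i, j, k) < np.zeros(3)) or i >= self.shape[0] or j >= self.shape[1] or k >= self.shape[2]:
                        continue
                    wt = (
                        (w[0] if dx else 1 - w[0])
                        * (w[1] if dy else 1 - w[1])
                        * (w[2] if dz else 1 - w[2])
                    )
                    if wt > 0:
                        c += wt * self.coeffs[i, j, k]
        return c


def _principal_direction(coeffs6: np.ndarray) -> tuple[np.ndarray, float]:
    """Principal eigenvector and a linearity index (l1-l2)/l1-free FA-like
    stop criterion; returns (e1, fa)."""
    D = tensors_to_matrices(coeffs6)
    evals, evecs = np.linalg.eigh(D)
    l = evals[::-1]
    e1 = evecs[:, 2]
    md = l.mean()
    den = np.sqrt((l**2).sum())
    fa = 0.0 if den <= 0 else float(np.sqrt(1.5) * np.sqrt(((l - md) ** 2).sum()) / den)
    return e1, fa


def _propagate(
    sampler: _TensorSampler,
    start: np.ndarray,
    direction: np.ndarray,
    step: float,
    cos_min: float,
    stop_fa: float,
    max_steps: int,
) -> list[np.ndarray]:
    pts = []
    pos = start.copy()
    d = direction.copy()
    for _ in range(max_steps):
        nxt = pos + step * d
        if not sampler.in_mask(nxt):
            break
        e1, fa = _principal_direction(sampler.tensor_at(nxt))
        if fa < stop_fa:
            break
        if e1 @ d < 0:
            e1 = -e1
        if e1 @ d < cos_min:
            break
        pts.append(nxt)
        pos, d = nxt, e1
    return pts


def track_single(
    tensors: TensorField,
    wm_mask: VolumeGrid,
    seed_mask: VolumeGrid,
    cfg: TrackingConfig,
    radius: float,
    roi_a: VolumeGrid | None = None,
    roi_b: VolumeGrid | None = None,
) -> Tractogram:
    """Deterministic single-curvature tracking run.

    Streamlines are retained only if they intersect both ``roi_a`` and
    ``roi_b`` (within ``endpoint_dist_mm``) and both endpoints lie within
    ``endpoint_dist_mm`` of the seed-mask region; when the ROIs are not
    given only the length criterion applies.
    """
    from .streamline_ops import min_distance_to_roi  # local import avoids cycle

    seed_vox = np.argwhere(np.asarray(seed_mask.data) > 0)
    if seed_vox.size == 0:
        raise UsageError("seed mask is empty")
    vs = float(np.mean(wm_mask.voxel_sizes))
    step = cfg.step_mm if cfg.step_mm is not None else 0.5 * vs
    cos_min = np.cos(theta_max(step, radius))
    max_steps = int(np.ceil(cfg.max_length_mm / step)) + 1
    rng = np.random.default_rng([cfg.rng_seed, int(radius * 10_000)])
    sampler = _TensorSampler(tensors, wm_mask)
    affine = wm_mask.affine

    n_aniso = 0
    accepted: list[np.ndarray] = []
    for _ in range(cfg.max_trials):
        if len(accepted) >= cfg.max_fibers:
            break
        vox = seed_vox[rng.integers(len(seed_vox))]
        pos_vox = vox + rng.uniform(-0.5, 0.5, size=3)
        pos = affine[:3, :3] @ pos_vox + affine[:3, 3]
        if not sampler.in_mask(pos):
            continue
        e1, fa = _principal_direction(sampler.tensor_at(pos))
        if fa < cfg.stop_fa:
            continue
        n_aniso += 1
        fwd = _propagate(sampler, pos, e1, step, cos_min, cfg.stop_fa, max_steps)
        bwd = _propagate(sampler, pos, -e1, step, cos_min, cfg.stop_fa, max_steps)
        pts = np.array(bwd[::-1] + [pos] + fwd)
        if len(pts) < 2:
            continue
        length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        if not (cfg.min_length_mm <= length <= cfg.max_length_mm):
            continue
        if roi_a is not None and roi_b is not None:
            d = cfg.endpoint_dist_mm
            if min_distance_to_roi(pts, roi_a) > d or min_distance_to_roi(pts, roi_b) > d:
                continue
            ends = pts[[0, -1]]
            end_d = np.minimum(
                np.array([min_distance_to_roi(e[None], roi_a) for e in ends]),
                np.array([min_distance_to_roi(e[None], roi_b) for e in ends]),
            )
            if np.any(end_d > d):
                continue
        accepted.append(pts)

    if n_aniso == 0 and cfg.max_trials > 0:
        warnings.warn("tensor field is isotropic at every sampled seed; no streamlines generated")
    return Tractogram.from_arrays(accepted) if accepted else Tractogram([])


def ensemble_track(
    tensors: TensorField,
    wm_mask: VolumeGrid,
    seed_mask: VolumeGrid,
    cfg: TrackingConfig,
    roi_a: VolumeGrid | None = None,
    roi_b: VolumeGrid | None = None,
) -> tuple[Tractogram, dict[float, int]]:
    """Merge (without deduplication) single-radius runs over the whole
    curvature ensemble; returns the tractogram and per-radius counts."""
    merged: list[Streamline] = []
    provenance: dict[float, int] = {}
    for radius in cfg.curvature_radii:
        t = track_single(tensors, wm_mask, seed_mask, cfg, radius, roi_a, roi_b)
        provenance[radius] = len(t)
        merged.extend(t.streamlines)
    return Tractogram(merged), provenance


# ---------------------------------------------------------------------------
# LiFE-style pruning
# ---------------------------------------------------------------------------

def _traversal(sl: Streamline, inv_affine: np.ndarray, shape: tuple[int, ...], half_voxel: float):
    """(voxel flat-index, mean unit tangent) pairs for one streamline."""
    arr = sl.points
    seg = np.linalg.norm(np.diff(arr, axis=0), axis=1)
    n_dense = max(int(np.ceil(seg.sum() / half_voxel)) + 1, 2)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    tt = np.linspace(0.0, cum[-1], n_dense)
    dense = np.column_stack([np.interp(tt, cum, arr[:, k]) for k in range(3)])
    tang = np.gradient(dense, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    vox = np.round(dense @ inv_affine[:3, :3].T + inv_affine[:3, 3]).astype(int)
    ok = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
    vox, tang = vox[ok], tang[ok]
    flat = np.ravel_multi_index(vox.T, shape)
    out = {}
    for f, tg in zip(flat, tang):
        if f in out:
            out[f] += tg
        else:
            out[f] = tg.copy()
    return [(f, t / np.linalg.norm(t)) for f, t in out.items() if np.linalg.norm(t) > 1e-9]


def life_prune(
    candidates: Tractogram,
    dwi: VolumeGrid,
    gtab: GradientTable,
    mask: VolumeGrid,
    shell: float | None = None,
    d_axial: float = STICK_AXIAL_DIFFUSIVITY,
    zero_tol: float = 1e-8,
) -> LifeResult:
    """Assign each candidate a non-negative weight by fitting predicted to
    measured demeaned diffusion-weighted signal; discard zero weights.

    Per traversed voxel v and shell direction g the column for streamline f
    holds exp(-b (g . t_fv)^2 d_axial) minus its per-voxel mean over the
    shell's directions; the target vector is the measured shell signal
    demeaned the same way.  Solved with non-negative least squares.
    """
    if len(candidates) == 0:
        raise UsageError("no candidate streamlines to prune")
    data = np.asarray(dwi.data, dtype=float)
    maskarr = np.asarray(mask.data) > 0
    shape = maskarr.shape
    nz = np.unique(gtab.bvals[gtab.bvals > 0])
    if nz.size == 0:
        raise UsageError("gradient table has no diffusion-weighted volumes")
    b = float(shell) if shell is not None else float(nz.min())
    sel = np.isclose(gtab.bvals, b)
    if not sel.any():
        raise UsageError(f"no volumes at b = {b}")
    g = gtab.bvecs[sel]  # (n_dir, 3)
    n_dir = g.shape[0]

    inv_affine = np.linalg.inv(dwi.affine)
    half_voxel = 0.5 * float(np.mean(dwi.voxel_sizes))
    traversals = [_traversal(sl, inv_affine, shape, half_voxel) for sl in candidates]

    # voxels used by the model: traversed, inside the mask
    used = sorted({f for tr in traversals for f, _ in tr if maskarr.flat[f]})
    if not used:
        raise UsageError("no candidate traverses the mask")
    vox_row = {f: i for i, f in enumerate(used)}
    n_vox = len(used)

    rows, cols, vals = [], [], []
    for ci, tr in enumerate(traversals):
        for f, t in tr:
            ri = vox_row.get(f)
            if ri is None:
                continue
            pred = np.exp(-b * (g @ t) ** 2 * d_axial)
            pred -= pred.mean()
            rows.extend(range(ri * n_dir, (ri + 1) * n_dir))
            cols.extend([ci] * n_dir)
            vals.extend(pred)
    M = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_vox * n_dir, len(candidates))
    )

    vox_idx = np.array(np.unravel_index(used, shape)).T
    meas = data[vox_idx[:, 0], vox_idx[:, 1], vox_idx[:, 2]][:, sel]  # (n_vox, n_dir)
    y = (meas - meas.mean(axis=1, keepdims=True)).ravel()

    col_norm = np.sqrt(np.asarray(M.multiply(M).sum(axis=0)).ravel())
    dead = col_norm == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} candidate(s) contribute no signal; weight set to 0")

    if len(candidates) <= 64:
        w, _ = optimize.nnls(M.toarray(), y)
    else:
        res = optimize.lsq_linear(M, y, bounds=(0.0, np.inf), tol=1e-12, method="trf")
        w = np.maximum(res.x, 0.0)
        w[w < zero_tol * max(w.max(), 1e-300)] = 0.0
    w[dead] = 0.0

    wmax = w.max()
    kept_idx = np.flatnonzero(w > (zero_tol * wmax if wmax > 0 else np.inf))
    resid = (M @ w - y).reshape(n_vox, n_dir)
    err = np.zeros(shape)
    err[vox_idx[:, 0], vox_idx[:, 1], vox_idx[:, 2]] = np.linalg.norm(resid, axis=1)
    return LifeResult(
        weights=w,
        kept=candidates.subset(kept_idx),
        kept_indices=kept_idx,
        error_map=dwi.with_data(err),
    )


def predict_from_weights(
    result_weights: np.ndarray,
    candidates: Tractogram,
    dwi: VolumeGrid,
    gtab: GradientTable,
    mask: VolumeGrid,
    shell: float | None = None,
    d_axial: float = STICK_AXIAL_DIFFUSIVITY,
) -> np.ndarray:
    """Demeaned signal predicted by a weighted candidate set (for
    prediction-equivalence checks)."""
    data = np.asarray(dwi.data, dtype=float)
    maskarr = np.asarray(mask.data) > 0
    shape = maskarr.shape
    nz = np.unique(gtab.bvals[gtab.bvals > 0])
    b = float(shell) if shell is not None else float(nz.min())
    sel = np.isclose(gtab.bvals, b)
    g = gtab.bvecs[sel]
    inv_affine = np.linalg.inv(dwi.affine)
    half_voxel = 0.5 * float(np.mean(dwi.voxel_sizes))
    pred = {}
    for w, sl in zip(result_weights, candidates):
        if w == 0:
            continue
        for f, t in _traversal(sl, inv_affine, shape, half_voxel):
            if not maskarr.flat[f]:
                continue
            p = np.exp(-b * (g @ t) ** 2 * d_axial)
            p -= p.mean()
            pred[f] = pred.get(f, 0.0) + w * p
    out = np.zeros((maskarr.size, g.shape[0]))
    for f, p in pred.items():
        out[f] = p
    return out
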