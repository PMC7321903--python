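"""Synthetic study generator.

Builds a small 3-D grid carrying: a seed ROI (thalamic stand-in) and an
elongated target ROI (cortical stand-in) with an anterior-posterior scalar
gradient; two ground-truth-labelled streamline bundles — a dorsal one
(label PRO1) from the medial half of the seed to the anterior half of the
target, and a ventral one (label PRO2) from the lateral half to the
posterior half; a white-matter mask with a carved "ventricle" void the
dorsal bundle arcs over; a per-voxel tensor field aligned with the local
streamline tangent; and noisy multi-shell diffusion signals.

Axis semantics (RAS world mm, voxel center = affine @ (i, j, k, 1)):
axis 0 = medial -> lateral ("X"), axis 1 = posterior -> anterior ("Y"),
axis 2 = ventral -> dorsal ("Z").
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ModelError, SizingError, UsageError
from .formats_io import (
    GradientTable,
    Streamline,
    Tractogram,
    VolumeGrid,
    write_gradient_table,
    write_tractogram,
    write_volume,
)
from .streamline_ops import ExclusionPlane
from .tensor_model import TensorField, predict_signal, tensor_from_eigen

__all__ = [
    "PhantomSpec",
    "Phantom",
    "build_phantom",
    "simulate_dwi",
    "electrostatic_directions",
    "make_gradient_table",
    "write_phantom",
]

# typical deep-white-matter diffusivities, mm^2/s; the ventral corridor is
# made slightly less anisotropic so the two bundles carry distinct FA/MD
# profiles
STICK_EIGENVALUES = (1.7e-3, 0.3e-3, 0.3e-3)
STICK_EIGENVALUES_VENTRAL = (1.5e-3, 0.35e-3, 0.35e-3)
ISOTROPIC_DIFFUSIVITY = 0.8e-3


@dataclasses.dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (36, 48, 36)
    voxel_size: float = 1.0
    n_streamlines_per_bundle: int = 200
    points_per_streamline: int = 60
    bundle_separation: float = 10.0  # dorsal/ventral apex height vs mid-plane, mm
    roi_gradient_range: tuple[float, float] = (0.0, 1.0)
    snr: float = 20.0
    shells: tuple[float, ...] = (1000.0, 2000.0, 3000.0)
    dirs_per_shell: int = 30
    n_b0: int = 6
    rng_seed: int = 42

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        if len(self.grid_shape) != 3 or any(v < 8 for v in self.grid_shape):
            raise UsageError(f"grid_shape components must be >= 8, got {self.grid_shape}")
        if self.voxel_size <= 0:
            raise UsageError("voxel_size must be > 0")
        if self.snr <= 0:
            raise UsageError("snr must be > 0")
        if any(b < 0 for b in self.shells):
            raise UsageError("b-values must be >= 0")
        if self.n_streamlines_per_bundle < 1:
            raise UsageError("n_streamlines_per_bundle must be >= 1")


@dataclasses.dataclass
class Phantom:
    spec: PhantomSpec
    dwi: VolumeGrid
    gtab: GradientTable
    wm_mask: VolumeGrid
    seed_roi: VolumeGrid
    target_roi: VolumeGrid
    gradient_map: VolumeGrid
    bundles: Tractogram  # PRO1 streamlines first, then PRO2
    labels: list[str]  # per-streamline ground truth, "PRO1" / "PRO2"
    tensors: TensorField
    dorsal_plane_z: float  # planes the dorsal / ventral arcs (and only they) cross
    ventral_plane_z: float

    @property
    def pro1(self) -> Tractogram:
        return self.bundles.subset([i for i, l in enumerate(self.labels) if l == "PRO1"])

    @property
    def pro2(self) -> Tractogram:
        return self.bundles.subset([i for i, l in enumerate(self.labels) if l == "PRO2"])

    def crossing_planes(self) -> tuple[ExclusionPlane, ExclusionPlane]:
        """Planes crossed exclusively by the dorsal / ventral bundle."""
        dorsal = ExclusionPlane(point=[0, 0, self.dorsal_plane_z], normal=[0, 0, 1.0])
        ventral = ExclusionPlane(point=[0, 0, self.ventral_plane_z], normal=[0, 0, 1.0])
        return dorsal, ventral


# ---------------------------------------------------------------------------
# gradient scheme
# ---------------------------------------------------------------------------

def electrostatic_directions(n: int, iterations: int = 200) -> np.ndarray:
    """Deterministic well-spread unit directions on the hemisphere.

    Starts from a Fibonacci arrangement and polishes it by gradient descent
    on the Coulomb energy of the antipodally symmetrized point set.
    """
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = (i + 0.5) / n  # upper hemisphere
    r = np.sqrt(1.0 - z**2)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])

    def min_angle(p: np.ndarray) -> float:
        dots = np.abs(p @ p.T)
        np.fill_diagonal(dots, 0.0)
        return float(np.arccos(np.clip(dots.max(), -1, 1)))

    best, best_score = pts.copy(), min_angle(pts)
    step = 1e-3
    for _ in range(iterations):
        full = np.vstack([pts, -pts])
        diff = pts[:, None, :] - full[None, :, :]  # (n, 2n, 3)
        d2 = (diff**2).sum(-1)
        np.fill_diagonal(d2[:, :n], np.inf)
        force = (diff / (d2[..., None] ** 1.5 + 1e-12)).sum(axis=1)
        norms = np.linalg.norm(force, axis=1, keepdims=True)
        force = force / np.maximum(norms, 1.0)  # cap per-point displacement
        pts = pts + step * force
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        score = min_angle(pts)
        if score > best_score:
            best, best_score = pts.copy(), score
    return best


def make_gradient_table(spec: PhantomSpec) -> GradientTable:
    dirs = electrostatic_directions(spec.dirs_per_shell)
    bvals = [0.0] * spec.n_b0
    bvecs = [np.zeros(3)] * spec.n_b0
    for b in spec.shells:
        bvals.extend([float(b)] * spec.dirs_per_shell)
        bvecs.extend(dirs)
    return GradientTable(bvals=np.array(bvals), bvecs=np.vstack(bvecs))


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _bezier(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, t: np.ndarray) -> np.ndarray:
    t = t[:, None]
    return (
        (1 - t) ** 3 * p0
        + 3 * (1 - t) ** 2 * t * p1
        + 3 * (1 - t) * t**2 * p2
        + t**3 * p3
    )


def _box_mask(shape: tuple[int, int, int], lo: tuple[int, int, int], hi: tuple[int, int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=np.uint8)
    m[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = 1
    return m


def _layout(spec: PhantomSpec) -> dict:
    """Voxel-index boxes for ROIs and arc heights; raises SizingError if the
    grid cannot contain the geometry (2-voxel boundary margin)."""
    nx, ny, nz = spec.grid_shape
    zmid = nz // 2
    vs = spec.voxel_size
    apex_vox = spec.bundle_separation / vs / 0.75  # bezier apex = 0.75 * control height
    margin = 3  # room for jitter + mask dilation

    seed = dict(lo=(4, 6, zmid - 2), hi=(14, 10, zmid + 2))
    target = dict(lo=(22, 12, zmid - 2), hi=(26, 40, zmid + 2))

    need = {
        "grid_shape[0]": target["hi"][0] + margin,
        "grid_shape[1]": target["hi"][1] + margin,
        "grid_shape[2]": int(np.ceil(zmid + apex_vox)) + margin,
    }
    have = {"grid_shape[0]": nx, "grid_shape[1]": ny, "grid_shape[2]": nz}
    for dim, req in need.items():
        if have[dim] < req:
            raise SizingError(f"{dim} = {have[dim]} too small; need >= {req} voxels")
    if zmid - apex_vox < margin:
        raise SizingError(f"grid_shape[2] = {nz} too small for ventral arc; need >= {int(2 * (apex_vox + margin))}")
    return dict(seed=seed, target=target, zmid=zmid, apex_vox=apex_vox)


# ---------------------------------------------------------------------------
# bundle synthesis
# ---------------------------------------------------------------------------

def _make_bundle(
    rng: np.random.Generator,
    spec: PhantomSpec,
    lay: dict,
    dorsal: bool,
) -> list[np.ndarray]:
    """Cubic-Bezier centerline per streamline, jittered control points.

    Dorsal streamlines run medial-seed -> anterior-target over a high arc;
    ventral ones lateral-seed -> posterior-target under a low arc.
    """
    vs = spec.voxel_size
    seed, target = lay["seed"], lay["target"]
    zmid = lay["zmid"]
    sx0, sx1 = seed["lo"][0], seed["hi"][0]
    sxm = (sx0 + sx1) / 2.0
    ty0, ty1 = target["lo"][1], target["hi"][1]
    tym = (ty0 + ty1) / 2.0

    # start (seed) boxes: medial = low X; end (target) boxes: anterior = high Y.
    # keep a 1.5-voxel guard away from the half boundary so endpoint halves
    # are unambiguous even after downstream 2 mm tolerance tests.
    if dorsal:
        sx_lo, sx_hi = sx0 + 0.5, sxm - 1.5
        ty_lo, ty_hi = tym + 1.5, ty1 - 0.5
        dz = +lay["apex_vox"]
    else:
        sx_lo, sx_hi = sxm + 1.5, sx1 - 0.5
        ty_lo, ty_hi = ty0 + 0.5, tym - 1.5
        dz = -lay["apex_vox"]

    t = np.linspace(0.0, 1.0, spec.points_per_streamline)
    out = []
    for _ in range(spec.n_streamlines_per_bundle):
        p0 = np.array(
            [
                rng.uniform(sx_lo, sx_hi),
                rng.uniform(seed["lo"][1] + 0.5, seed["hi"][1] - 0.5),
                rng.uniform(seed["lo"][2] + 0.5, seed["hi"][2] - 0.5),
            ]
        )
        p3 = np.array(
            [
                rng.uniform(target["lo"][0] + 0.5, target["hi"][0] - 0.5),
                rng.uniform(ty_lo, ty_hi),
                rng.uniform(target["lo"][2] + 0.5, target["hi"][2] - 0.5),
            ]
        )
        jit = rng.normal(0.0, 0.6, size=(2, 2))  # x/y jitter of the two inner controls
        p1 = p0 + 0.33 * (p3 - p0)
        p2 = p0 + 0.67 * (p3 - p0)
        p1[:2] += jit[0]
        p2[:2] += jit[1]
        p1[2] = zmid + dz + rng.normal(0.0, 0.3)
        p2[2] = zmid + dz + rng.normal(0.0, 0.3)
        out.append(_bezier(p0, p1, p2, p3, t) * vs)
    return out


def build_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Generate the full synthetic study deterministically from the spec."""
    spec = spec or PhantomSpec()
    lay = _layout(spec)
    rng = np.random.default_rng(spec.rng_seed)
    vs = spec.voxel_size
    shape = spec.grid_shape
    affine = np.diag([vs, vs, vs, 1.0])

    seed_mask = _box_mask(shape, lay["seed"]["lo"], lay["seed"]["hi"])
    target_mask = _box_mask(shape, lay["target"]["lo"], lay["target"]["hi"])

    pro1 = _make_bundle(rng, spec, lay, dorsal=True)
    pro2 = _make_bundle(rng, spec, lay, dorsal=False)
    bundles = Tractogram.from_arrays(pro1 + pro2)
    labels = ["PRO1"] * len(pro1) + ["PRO2"] * len(pro2)

    # rasterize: visited voxels, per-voxel mean tangent, per-bundle counts
    tangent_sum = np.zeros(shape + (3,))
    visit_count = np.zeros((2,) + shape, dtype=np.int32)  # 0 = dorsal, 1 = ventral
    visited = np.zeros(shape, dtype=bool)
    inv_vs = 1.0 / vs
    for si, arr in enumerate(pro1 + pro2):
        bundle_id = 0 if si < len(pro1) else 1
        # dense resample (half-voxel steps) so no traversed voxel is skipped
        seg = np.linalg.norm(np.diff(arr, axis=0), axis=1)
        n_dense = max(int(np.ceil(seg.sum() / (0.5 * vs))) + 1, 2)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        tt = np.linspace(0.0, cum[-1], n_dense)
        dense = np.column_stack([np.interp(tt, cum, arr[:, k]) for k in range(3)])
        tang = np.gradient(dense, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        idx = np.round(dense * inv_vs).astype(int)
        np.clip(idx, 0, np.array(shape) - 1, out=idx)
        visited[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        np.add.at(tangent_sum, (idx[:, 0], idx[:, 1], idx[:, 2]), tang)
        np.add.at(visit_count, (bundle_id, idx[:, 0], idx[:, 1], idx[:, 2]), 1)

    wm = ndimage.binary_dilation(
        visited, structure=ndimage.generate_binary_structure(3, 1), iterations=2
    )
    wm |= seed_mask.astype(bool)
    wm |= target_mask.astype(bool)

    # carve a "ventricle" void between the arcs; the dorsal bundle goes over it
    cx = (lay["seed"]["hi"][0] + lay["target"]["lo"][0]) / 2.0
    cy = (lay["seed"]["hi"][1] + lay["target"]["hi"][1]) / 2.0
    ii, jj, kk = np.indices(shape)
    void = ((ii - cx) ** 2 + (jj - cy) ** 2 + (kk - lay["zmid"]) ** 2) <= 2.5**2
    wm &= ~void

    # tensor field: stick along local tangent in visited voxels, isotropic
    # elsewhere in the white matter, zero outside
    coeffs = np.zeros(shape + (6,))
    iso = tensor_from_eigen(
        (ISOTROPIC_DIFFUSIVITY, ISOTROPIC_DIFFUSIVITY, ISOTROPIC_DIFFUSIVITY), [1.0, 0, 0]
    )
    coeffs[wm] = iso
    vis_idx = np.argwhere(visited & wm)
    for i, j, k in vis_idx:
        tsum = tangent_sum[i, j, k]
        n = np.linalg.norm(tsum)
        if n < 1e-9:
            continue
        # majority bundle picks the corridor's eigenvalue recipe
        ev = (
            STICK_EIGENVALUES
            if visit_count[0, i, j, k] >= visit_count[1, i, j, k]
            else STICK_EIGENVALUES_VENTRAL
        )
        coeffs[i, j, k] = tensor_from_eigen(ev, tsum / n)

    grid = VolumeGrid(np.zeros(shape), affine)
    s0 = 100.0
    tensors = TensorField(coefficients=coeffs, s0_map=np.full(shape, s0), grid=grid)

    gtab = make_gradient_table(spec)
    dwi = simulate_dwi(tensors, gtab, s0=s0, snr=spec.snr, rng_seed=spec.rng_seed)

    # anterior-posterior gradient over the target ROI
    lo, hi = spec.roi_gradient_range
    gmap = np.zeros(shape)
    tidx = np.argwhere(target_mask > 0)
    y0, y1 = tidx[:, 1].min(), tidx[:, 1].max()
    frac = (tidx[:, 1] - y0) / max(y1 - y0, 1)
    gmap[tidx[:, 0], tidx[:, 1], tidx[:, 2]] = lo + frac * (hi - lo)

    apex = lay["apex_vox"] * 0.75  # actual arc apex height in voxels
    return Phantom(
        spec=spec,
        dwi=dwi,
        gtab=gtab,
        wm_mask=VolumeGrid(wm.astype(np.uint8), affine),
        seed_roi=VolumeGrid(seed_mask, affine),
        target_roi=VolumeGrid(target_mask, affine),
        gradient_map=VolumeGrid(gmap, affine),
        bundles=bundles,
        labels=labels,
        tensors=tensors,
        dorsal_plane_z=(lay["zmid"] + 0.55 * apex) * vs,
        ventral_plane_z=(lay["zmid"] - 0.55 * apex) * vs,
    )


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def simulate_dwi(
    tensors: TensorField,
    gtab: GradientTable,
    s0: float = 100.0,
    snr: float = np.inf,
    rng_seed: int = 0,
    noise_model: str = "rician",
) -> VolumeGrid:
    """Forward-simulate a 4-D diffusion series from a tensor field.

    ``snr = inf`` returns the exact forward model; otherwise magnitude
    (Rician) or additive Gaussian noise with sigma = s0 / snr is applied.
    """
    if s0 <= 0:
        raise UsageError("s0 must be > 0")
    if noise_model not in ("rician", "gaussian"):
        raise UsageError(f"unknown noise model {noise_model!r}")
    evals = tensors.eigenvalues()
    bad = np.argwhere(evals[..., -1] < -1e-12)
    if bad.size:
        raise ModelError(f"non-PSD tensor at voxel {tuple(bad[0])}")
    signal = predict_signal(tensors.coefficients, gtab, s0)
    if np.isfinite(snr):
        if snr <= 0:
            raise UsageError("snr must be > 0")
        sigma = s0 / snr
        rng = np.random.default_rng(rng_seed)
        if noise_model == "rician":
            n1 = rng.normal(0.0, sigma, signal.shape)
            n2 = rng.normal(0.0, sigma, signal.shape)
            signal = np.sqrt((signal + n1) ** 2 + n2**2)
        else:
            signal = signal + rng.normal(0.0, sigma, signal.shape)
    return tensors.grid.with_data(signal)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_phantom(phantom: Phantom, outdir: str | Path) -> dict[str, str]:
    """Write all phantom artifacts in their standard formats; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = phantom.wm_mask
    paths = {}

    def _vol(name: str, v: VolumeGrid) -> None:
        paths[name] = str(write_volume(v, outdir / f"{name}.nii.gz"))

    _vol("dwi", phantom.dwi)
    _vol("wm_mask", phantom.wm_mask)
    _vol("seed_roi", phantom.seed_roi)
    _vol("target_roi", phantom.target_roi)
    _vol("gradient_map", phantom.gradient_map)
    _vol("tensors", grid.with_data(phantom.tensors.coefficients))
    write_gradient_table(phantom.gtab, outdir / "dwi.bval", outdir / "dwi.bvec")
    paths["bval"], paths["bvec"] = str(outdir / "dwi.bval"), str(outdir / "dwi.bvec")
    for name, tr in (("bundle_pro1", phantom.pro1), ("bundle_pro2", phantom.pro2)):
        paths[name] = str(write_tractogram(tr, outdir / f"{name}.tck"))
    with open(outdir / "labels.json", "w") as fh:
        json.dump(phantom.labels, fh)
    paths["labels"] = str(outdir / "labels.json")
    return paths
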