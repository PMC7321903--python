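"""Diffusion-tensor model: per-voxel log-linear least-squares fit and the
rotation-invariant scalar maps (FA, MD, RD) derived from the eigenvalues.

The forward model is S(b, g) = S0 * exp(-b * g^T D g) with D a symmetric
positive semi-definite tensor in mm^2/s.  Coefficients are stored in
lower-triangular order (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import ModelError, UsageError
from .formats_io import GradientTable, VolumeGrid

__all__ = [
    "TensorField",
    "ScalarMaps",
    "fit_tensor",
    "tensor_scalars",
    "tensors_to_matrices",
    "matrices_to_coefficients",
    "tensor_from_eigen",
    "predict_signal",
]

LOWER_TRIANGULAR_ORDER = ("Dxx", "Dxy", "Dyy", "Dxz", "Dyz", "Dzz")

# index pairs matching LOWER_TRIANGULAR_ORDER
_IJ = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]


@dataclasses.dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor (6 coefficients, mm^2/s)."""

    coefficients: np.ndarray  # (..., 6), lower-triangular order
    s0_map: np.ndarray
    grid: VolumeGrid

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.s0_map = np.asarray(self.s0_map, dtype=float)
        if self.coefficients.shape[-1] != 6:
            raise ModelError("tensor coefficients must have a trailing axis of 6")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.coefficients.shape[:-1]

    def matrices(self) -> np.ndarray:
        return tensors_to_matrices(self.coefficients)

    def eigenvalues(self, clamp: bool = False) -> np.ndarray:
        """Eigenvalues sorted descending; optionally clamped at zero."""
        evals = np.linalg.eigvalsh(self.matrices())[..., ::-1]
        if clamp:
            evals = np.clip(evals, 0.0, None)
        return evals


@dataclasses.dataclass
class ScalarMaps:
    """FA (dimensionless in [0, 1]), MD and RD (mm^2/s) volumes."""

    fa: VolumeGrid
    md: VolumeGrid
    rd: VolumeGrid


def tensors_to_matrices(coeffs: np.ndarray) -> np.ndarray:
    """(..., 6) lower-triangular coefficients -> (..., 3, 3) symmetric matrices."""
    coeffs = np.asarray(coeffs, dtype=float)
    out = np.zeros(coeffs.shape[:-1] + (3, 3))
    for k, (i, j) in enumerate(_IJ):
        out[..., i, j] = coeffs[..., k]
        out[..., j, i] = coeffs[..., k]
    return out


def matrices_to_coefficients(mats: np.ndarray) -> np.ndarray:
    mats = np.asarray(mats, dtype=float)
    out = np.empty(mats.shape[:-2] + (6,))
    for k, (i, j) in enumerate(_IJ):
        out[..., k] = mats[..., i, j]
    return out


def tensor_from_eigen(evals: np.ndarray, e1: np.ndarray) -> np.ndarray:
    """Build a 6-coefficient tensor with principal axis ``e1`` and axially
    symmetric eigenvalues ``(l1, l2, l2)`` (l3 taken equal to l2 when only
    two radial values coincide)."""
    l1, l2, l3 = evals
    e1 = np.asarray(e1, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    D = l2 * np.eye(3) if l2 == l3 else None
    if D is None:
        # need an explicit orthonormal frame
        tmp = np.array([1.0, 0.0, 0.0])
        if abs(e1 @ tmp) > 0.9:
            tmp = np.array([0.0, 1.0, 0.0])
        e2 = np.cross(e1, tmp)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        D = l1 * np.outer(e1, e1) + l2 * np.outer(e2, e2) + l3 * np.outer(e3, e3)
    else:
        D = D + (l1 - l2) * np.outer(e1, e1)
    return matrices_to_coefficients(D)


def predict_signal(coeffs: np.ndarray, gtab: GradientTable, s0: float | np.ndarray) -> np.ndarray:
    """Noiseless forward model, one value per gradient-table row.

    ``coeffs`` has shape (..., 6); the result has shape (..., n_volumes).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    gx, gy, gz = gtab.bvecs.T
    # quadratic form g^T D g expressed on the 6 coefficients directly
    Q = np.stack([gx * gx, 2 * gx * gy, gy * gy, 2 * gx * gz, 2 * gy * gz, gz * gz])  # (6, n)
    quad = coeffs @ Q
    s0 = np.asarray(s0, dtype=float)
    return s0[..., None] * np.exp(-gtab.bvals * quad)


def _design_matrix(gtab: GradientTable) -> np.ndarray:
    """Rows map (log S0, Dxx, Dxy, Dyy, Dxz, Dyz, Dzz) to log-signal."""
    b = gtab.bvals
    gx, gy, gz = gtab.bvecs.T
    X = np.column_stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -2 * b * gx * gy,
            -b * gy * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
            -b * gz * gz,
        ]
    )
    return X


def fit_tensor(dwi: VolumeGrid, gtab: GradientTable, mask: VolumeGrid) -> TensorField:
    """Ordinary least squares on the log-signal, voxelwise within the mask.

    Signals <= 0 are floored at machine epsilon before the log.  Voxels
    outside the mask are zero-filled.  All-zero masked voxels are fit
    anyway (yielding a zero tensor) and recorded on the returned field as
    ``flagged_voxels``.
    """
    data = np.asarray(dwi.data, dtype=float)
    if data.ndim != 4:
        raise UsageError("dwi must be a 4-D series")
    if data.shape[3] != gtab.n_volumes:
        raise UsageError(
            f"dwi has {data.shape[3]} volumes but gradient table has {gtab.n_volumes}"
        )
    if gtab.n_volumes < 7 or not np.any(gtab.b0_mask):
        raise ModelError("tensor fit needs >= 7 volumes including >= 1 b=0")
    m = np.asarray(mask.data) > 0
    if m.shape != data.shape[:3]:
        raise UsageError("mask shape does not match dwi grid")

    signals = data[m]  # (n_vox, n_vols)
    flagged = np.argwhere(m)[np.all(signals == 0, axis=1)]
    floored = np.maximum(signals, np.finfo(float).eps)
    X = _design_matrix(gtab)
    beta, *_ = np.linalg.lstsq(X, np.log(floored).T, rcond=None)  # (7, n_vox)

    coeffs = np.zeros(data.shape[:3] + (6,))
    s0 = np.zeros(data.shape[:3])
    coeffs[m] = beta[1:].T
    s0[m] = np.exp(beta[0])
    field = TensorField(coefficients=coeffs, s0_map=s0, grid=dwi.with_data(np.zeros(data.shape[:3])))
    field.flagged_voxels = [tuple(v) for v in flagged]  # type: ignore[attr-defined]
    return field


def eigenvalue_scalars(evals: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """FA, MD, RD from descending-sorted, non-negative eigenvalues.

    FA of the all-zero tensor is defined as 0.
    """
    evals = np.asarray(evals, dtype=float)
    md = evals.mean(axis=-1)
    rd = evals[..., 1:].mean(axis=-1)
    num = np.sqrt(((evals - md[..., None]) ** 2).sum(axis=-1))
    den = np.sqrt((evals**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0), md, rd


def tensor_scalars(t: TensorField) -> ScalarMaps:
    """FA/MD/RD maps with negative eigenvalues clamped to zero first."""
    evals = t.eigenvalues(clamp=True)
    fa, md, rd = eigenvalue_scalars(evals)
    g = t.grid
    return ScalarMaps(fa=g.with_data(fa), md=g.with_data(md), rd=g.with_data(rd))
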