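"""Core containers and file I/O: NIfTI volumes, TCK/TRK tractograms, FSL
gradient tables.

All streamline coordinates held in memory are world-space millimetres
(RAS).  TRK files, which store voxel-mm corner-origin coordinates on disk,
are converted through their header affine on read and write, so the two
tractogram formats round-trip through the same in-memory representation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import nibabel as nib
import numpy as np
from nibabel.streamlines import Field
from nibabel.streamlines.tck import TckFile
from nibabel.streamlines.trk import TrkFile

from .errors import FormatError, GeometryError, UsageError

__all__ = [
    "VolumeGrid",
    "Streamline",
    "Tractogram",
    "GradientTable",
    "read_volume",
    "write_volume",
    "read_tractogram",
    "write_tractogram",
    "read_gradient_table",
    "write_gradient_table",
]


@dataclasses.dataclass
class VolumeGrid:
    """A 3-D or 4-D scalar lattice plus its voxel-index -> world-mm affine."""

    data: np.ndarray
    affine: np.ndarray
    space_tag: str = "phantom"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise GeometryError("affine is singular")
        if self.data.ndim not in (3, 4):
            raise GeometryError(f"volume must be 3-D or 4-D, got {self.data.ndim}-D")

    @property
    def shape3(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_centers_world(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates of voxel centers, optionally restricted to a mask."""
        if mask is None:
            idx = np.indices(self.shape3).reshape(3, -1).T
        else:
            idx = np.argwhere(np.asarray(mask))
        return apply_affine(self.affine, idx.astype(float))

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        return apply_affine(np.linalg.inv(self.affine), np.atleast_2d(pts))

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(data=data, affine=self.affine.copy(), space_tag=self.space_tag)


def apply_affine(affine: np.ndarray, pts: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    return pts @ affine[:3, :3].T + affine[:3, 3]


class Streamline:
    """An ordered 3-D polyline in world mm; consecutive points distinct."""

    __slots__ = ("points",)

    def __init__(self, points: np.ndarray):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise GeometryError(f"streamline points must be Nx3, got {pts.shape}")
        if pts.shape[0] < 2:
            raise GeometryError("streamline needs at least 2 points")
        if np.isnan(pts).any():
            raise GeometryError("streamline contains NaN coordinates")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Streamline) and np.array_equal(self.points, other.points)

    def __repr__(self) -> str:
        return f"Streamline(n={len(self)})"


@dataclasses.dataclass
class Tractogram:
    """An ordered collection of streamlines sharing one space."""

    streamlines: list[Streamline]
    space_tag: str = "phantom"
    affine_to_world: np.ndarray = dataclasses.field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.streamlines = list(self.streamlines)
        self.affine_to_world = np.asarray(self.affine_to_world, dtype=float)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self) -> Iterator[Streamline]:
        return iter(self.streamlines)

    def __getitem__(self, i) -> Streamline:
        return self.streamlines[i]

    def subset(self, indices: Iterable[int]) -> "Tractogram":
        return Tractogram(
            [self.streamlines[i] for i in indices],
            space_tag=self.space_tag,
            affine_to_world=self.affine_to_world.copy(),
        )

    @classmethod
    def from_arrays(cls, arrays: Sequence[np.ndarray], space_tag: str = "phantom") -> "Tractogram":
        return cls([Streamline(a) for a in arrays], space_tag=space_tag)


@dataclasses.dataclass
class GradientTable:
    """Per-volume b-values (s/mm^2) and unit gradient directions."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise FormatError(
                f"bvecs shape {self.bvecs.shape} inconsistent with {self.bvals.size} b-values"
            )
        norms = np.linalg.norm(self.bvecs, axis=1)
        dw = self.bvals > 0
        if np.any(np.abs(norms[dw] - 1.0) > 1e-6):
            raise FormatError("b>0 gradient directions must be unit vectors")
        if np.any(self.bvals < 0):
            raise FormatError("negative b-value")

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> VolumeGrid:
    """Load a NIfTI-1 volume into a :class:`VolumeGrid`."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    data = np.asarray(img.dataobj)
    return VolumeGrid(data=data, affine=np.asarray(img.affine))


def write_volume(vol: VolumeGrid, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(vol.data)
    if data.dtype in (np.int64, np.uint64, bool):
        data = data.astype(np.int32)
    img = nib.Nifti1Image(data, vol.affine)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Tractograms
# ---------------------------------------------------------------------------

_FORMATS = ("tck", "trk")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise UsageError(f"unknown tractogram format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def read_tractogram(path: str | Path, format: str | None = None) -> Tractogram:
    """Read a TCK or TRK file into world-mm coordinates.

    TRK voxel-space coordinates are converted through the header's
    voxel-to-RAS affine; TCK coordinates are already world mm.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    cls = TckFile if fmt == "tck" else TrkFile
    try:
        tf = cls.load(str(path), lazy_load=False)
    except Exception as exc:
        raise FormatError(f"{path}: malformed {fmt.upper()} file ({exc})") from exc
    sls = [np.asarray(s, dtype=float) for s in tf.tractogram.streamlines]
    return Tractogram.from_arrays(sls)


def write_tractogram(
    t: Tractogram,
    path: str | Path,
    format: str | None = None,
    reference: VolumeGrid | None = None,
) -> Path:
    """Write a tractogram as TCK or TRK.

    TRK headers need grid geometry; pass ``reference`` to embed its affine
    and shape, otherwise an identity 1 mm header is written.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = [s.points for s in t.streamlines]
    nt = nib.streamlines.Tractogram(arrays, affine_to_rasmm=np.eye(4))
    if fmt == "tck":
        TckFile(nt).save(str(path))
    else:
        header = {}
        if reference is not None:
            header[Field.VOXEL_TO_RASMM] = reference.affine.astype(np.float32)
            header[Field.VOXEL_SIZES] = reference.voxel_sizes.astype(np.float32)
            header[Field.DIMENSIONS] = np.array(reference.shape3, dtype=np.int16)
        TrkFile(nt, header=header).save(str(path))
    return path


# ---------------------------------------------------------------------------
# FSL bval / bvec
# ---------------------------------------------------------------------------

def read_gradient_table(bval_path: str | Path, bvec_path: str | Path) -> GradientTable:
    try:
        bvals = np.loadtxt(bval_path).ravel()
        bvecs = np.loadtxt(bvec_path)
    except Exception as exc:
        raise FormatError(f"cannot parse gradient table: {exc}") from exc
    if bvecs.ndim == 1:
        bvecs = bvecs.reshape(3, -1)
    # FSL layout: one row per axis (3 x N)
    if bvecs.shape == (3, bvals.size):
        bvecs = bvecs.T
    return GradientTable(bvals=bvals, bvecs=bvecs)


def write_gradient_table(gtab: GradientTable, bval_path: str | Path, bvec_path: str | Path) -> None:
    Path(bval_path).parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(bval_path, gtab.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, gtab.bvecs.T, fmt="%.9f")
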