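"""Shared in-memory containers for volumetric data and their NIfTI / text I/O.

All analysis modules exchange two lightweight containers: :class:`BoldRun`
(a 4D BOLD time series with its affine and repetition time) and
:class:`ScalarMap` (a 3D per-voxel map on the same grid).  Values outside a
map's domain are NaN.  NIfTI serialization goes through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = [
    "BoldRun",
    "ScalarMap",
    "MotionTrace",
    "voxel_sizes",
    "save_map",
    "load_map",
    "save_motion_trace",
    "load_motion_trace",
]


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge lengths in mm (norms of the affine's spatial columns)."""
    return np.sqrt((np.asarray(affine, dtype=float)[:3, :3] ** 2).sum(axis=0))


@dataclass
class BoldRun:
    """One subject's 4D BOLD run: ``data[x, y, z, t]`` plus grid geometry."""

    data: np.ndarray
    affine: np.ndarray
    tr: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("BoldRun.data must be 4D (x, y, z, t)")
        if self.data.shape[3] < 2:
            raise ValueError("BoldRun needs at least 2 volumes")
        if self.tr <= 0:
            raise ValueError("repetition time must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("BoldRun contains non-finite values")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return replace(self, data=data)

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*voxel_sizes(self.affine), float(self.tr)))
        nib.save(img, str(path))

    @classmethod
    def load(cls, path, subject_id: str = "", tr: float | None = None) -> "BoldRun":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        if tr is None:
            zooms = img.header.get_zooms()
            tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return cls(data=data, affine=np.asarray(img.affine), tr=tr, subject_id=subject_id)


@dataclass
class ScalarMap:
    """A 3D per-voxel map (wGBC value, t statistic, Fisher z ...) on a grid.

    Voxels where the map is undefined hold NaN.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("ScalarMap.data must be 3D")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.data)


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion parameters.

    ``params`` has one row per volume and six columns in the SPM ``rp_*.txt``
    order: three translations in mm, then three rotations in radians.
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=np.float64))
        if self.params.shape[1] != 6:
            raise ValueError("MotionTrace needs exactly 6 columns")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]

    def sliced(self, index) -> "MotionTrace":
        return MotionTrace(self.params[index])


def save_map(smap: ScalarMap, path) -> None:
    nib.save(nib.Nifti1Image(smap.data.astype(np.float32), smap.affine), str(path))


def load_map(path) -> ScalarMap:
    img = nib.load(str(path))
    return ScalarMap(np.asanyarray(img.dataobj, dtype=np.float64), np.asarray(img.affine))


def save_motion_trace(trace: MotionTrace, path) -> None:
    np.savetxt(str(path), trace.params, fmt="%.10e")


def load_motion_trace(path) -> MotionTrace:
    return MotionTrace(np.loadtxt(str(path)))
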