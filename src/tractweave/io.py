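"""Neuroimaging containers and file formats.

All internal coordinates are world millimetres in RAS+ orientation
(+x right, +y anterior, +z superior).  Volumes loaded from disk are
reoriented to the closest RAS+ axis ordering before use, because the
geometric ROI operators ("anterior part", "axial slab", "left/right")
need a fixed anatomical frame.

Voxel indexing is 0-based.  A world point belongs to the voxel whose
half-open cell [edge, edge) contains it, i.e. voxel ``i`` covers the
continuous voxel coordinate range ``[i - 0.5, i + 0.5)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates


class FormatError(ValueError):
    """Input file does not satisfy the format contract."""


class GeometryError(ValueError):
    """Grids/transforms are geometrically inconsistent."""


# --------------------------------------------------------------------------
# coordinate helpers
# --------------------------------------------------------------------------

def world_to_voxel(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Map world-mm points (N, 3) to continuous voxel coordinates."""
    inv = np.linalg.inv(affine)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return pts @ inv[:3, :3].T + inv[:3, 3]


def voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
    return ijk @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]


def world_to_index(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Voxel index of each world point under the half-open cell rule."""
    return np.floor(world_to_voxel(affine, points) + 0.5).astype(np.intp)


def voxel_volume_mm3(affine: np.ndarray) -> float:
    return float(abs(np.linalg.det(np.asarray(affine)[:3, :3])))


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise GeometryError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise GeometryError("affine is singular")
    return affine


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class LabelVolume:
    """Integer parcellation grid with a structure-name -> label map."""

    grid: np.ndarray
    affine: np.ndarray
    labels: dict[str, int]
    absent: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise FormatError(f"label grid must be 3D, got ndim={self.grid.ndim}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise FormatError("label grid must be integer-valued")
        if self.grid.min() < 0:
            raise FormatError("label grid must be non-negative")
        self.affine = _check_affine(self.affine)
        present = set(np.unique(self.grid).tolist())
        self.absent = tuple(sorted(n for n, v in self.labels.items() if v not in present))

    def mask(self, name: str) -> "ScalarMap":
        """Binary mask of a single named structure."""
        if name not in self.labels:
            raise KeyError(f"unknown structure name: {name!r}")
        return ScalarMap((self.grid == self.labels[name]).astype(np.uint8),
                         self.affine, role="binary")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]


@dataclass
class ScalarMap:
    """One 3D grid, parameterized by role: density counts, binary mask, or probability."""

    grid: np.ndarray
    affine: np.ndarray
    role: str = "density"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise FormatError(f"scalar grid must be 3D, got ndim={self.grid.ndim}")
        self.affine = _check_affine(self.affine)
        if self.role not in ("density", "binary", "probability"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "binary":
            vals = np.unique(self.grid)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("binary map must contain only 0/1")
            self.grid = self.grid.astype(np.uint8)
        elif self.role == "density":
            if self.grid.min() < 0:
                raise ValueError("density map must be non-negative")
        elif self.role == "probability":
            if self.grid.min() < -1e-12 or self.grid.max() > 1 + 1e-12:
                raise ValueError("probability map must lie in [0, 1]")
            self.grid = np.clip(self.grid.astype(float), 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.grid))

    def volume_mm3(self) -> float:
        return self.voxel_count() * voxel_volume_mm3(self.affine)

    def _inv_affine(self) -> np.ndarray:
        inv = getattr(self, "_inv_cache", None)
        if inv is None:
            inv = np.linalg.inv(self.affine)
            object.__setattr__(self, "_inv_cache", inv)
        return inv

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership of world points in the nonzero voxels."""
        inv = self._inv_affine()
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.floor(pts @ inv[:3, :3].T + inv[:3, 3] + 0.5).astype(np.intp)
        shape = np.asarray(self.shape)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        out = np.zeros(len(idx), dtype=bool)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.grid[ii[:, 0], ii[:, 1], ii[:, 2]] != 0
        return out


@dataclass
class StreamlineSet:
    """Ordered 3D polylines in world mm, with optional per-streamline scores."""

    streamlines: list[np.ndarray]
    scores: object | None = None          # FbcScores, attached by the filter
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = []
        for sl in self.streamlines:
            sl = np.asarray(sl, dtype=np.float64)
            if sl.ndim != 2 or sl.shape[1] != 3:
                raise FormatError("each streamline must be an (N, 3) array")
            if len(sl) < 2:
                raise FormatError("each streamline must have >= 2 points")
            cleaned.append(sl)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


@dataclass
class SpatialTransform:
    """A consumed spatial mapping (registration estimation is out of scope).

    ``kind`` is one of ``identity``, ``affine``, ``displacement``.
    The transform maps points forward from its source space to its target
    space.  Grids are resampled through the inverse mapping; for dense
    displacement fields (which are not invertible in closed form) the
    caller must supply the field for the direction the operation needs.
    """

    kind: str = "identity"
    matrix: np.ndarray | None = None
    field: np.ndarray | None = None          # (X, Y, Z, 3) world-mm displacements
    field_affine: np.ndarray | None = None
    direction: str = "source->target"

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "affine", "displacement"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "affine":
            self.matrix = _check_affine(self.matrix)
        if self.kind == "displacement":
            f = np.asarray(self.field, dtype=float)
            if f.ndim != 4 or f.shape[3] != 3:
                raise GeometryError("displacement field must have shape (X, Y, Z, 3)")
            self.field = f
            self.field_affine = _check_affine(self.field_affine)

    @classmethod
    def identity(cls) -> "SpatialTransform":
        return cls(kind="identity")

    @classmethod
    def from_affine(cls, matrix: np.ndarray) -> "SpatialTransform":
        return cls(kind="affine", matrix=np.asarray(matrix, dtype=float))

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind == "identity":
            return pts.copy()
        if self.kind == "affine":
            return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        # displacement: sample the field (trilinear) at each point
        vox = world_to_voxel(self.field_affine, pts).T
        disp = np.stack([
            map_coordinates(self.field[..., c], vox, order=1, mode="nearest")
            for c in range(3)
        ], axis=1)
        return pts + disp

    def inverse(self) -> "SpatialTransform":
        if self.kind == "identity":
            return SpatialTransform.identity()
        if self.kind == "affine":
            return SpatialTransform.from_affine(np.linalg.inv(self.matrix))
        raise GeometryError("dense displacement fields have no closed-form inverse; "
                            "supply the field estimated in the opposite direction")


# --------------------------------------------------------------------------
# NIfTI input/output
# --------------------------------------------------------------------------

def _load_canonical(path) -> nib.Nifti1Image:
    img = nib.load(str(path))
    return nib.as_closest_canonical(img)


def read_label_volume(path, label_table: Mapping[str, int]) -> LabelVolume:
    """Read an integer parcellation NIfTI and attach a name -> label table.

    Structure names in the table that do not occur in the grid are flagged
    on ``LabelVolume.absent`` and reported through the warning channel.
    """
    img = _load_canonical(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D parcellation, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise FormatError("parcellation voxels are not integer-valued")
        data = np.round(data).astype(np.int32)
    vol = LabelVolume(grid=data.astype(np.int32), affine=img.affine,
                      labels=dict(label_table))
    if vol.absent:
        warnings.warn(f"labels absent from {path}: {', '.join(vol.absent)}",
                      stacklevel=2)
    return vol


def write_label_volume(vol: LabelVolume, path) -> None:
    nib.save(nib.Nifti1Image(vol.grid.astype(np.int32), vol.affine), str(path))


def read_scalar_map(path, role: str = "density") -> ScalarMap:
    img = _load_canonical(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D map, got shape {data.shape}")
    return ScalarMap(grid=data, affine=img.affine, role=role)


def write_scalar_map(m: ScalarMap, path) -> None:
    dtype = np.uint8 if m.role == "binary" else (
        np.int32 if m.role == "density" else np.float32)
    nib.save(nib.Nifti1Image(np.asarray(m.grid, dtype=dtype), m.affine), str(path))


# --------------------------------------------------------------------------
# streamline input/output (TCK / TRK)
# --------------------------------------------------------------------------

def read_streamlines(path) -> StreamlineSet:
    """Read a TCK or TRK file; points come back in world mm (RAS+)."""
    try:
        f = nib.streamlines.load(str(path))
    except ValueError as exc:
        raise FormatError(f"unrecognized streamline file {path}: {exc}") from exc
    sls = [np.asarray(s, dtype=np.float64) for s in f.tractogram.streamlines]
    return StreamlineSet(streamlines=sls)


def write_streamlines(sset: StreamlineSet, path,
                      reference: ScalarMap | LabelVolume | None = None) -> None:
    """Write TCK (MRtrix) or TRK (TrackVis) by file extension.

    TRK headers need a reference grid geometry; pass any map on the
    acquisition grid, or an identity-like header is synthesized.
    """
    path = str(path)
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in sset.streamlines],
        affine_to_rasmm=np.eye(4))
    if path.endswith(".tck"):
        nib.streamlines.TckFile(tractogram).save(path)
    elif path.endswith(".trk"):
        header = {}
        if reference is not None:
            aff = np.asarray(reference.affine, dtype=float)
            header[nib.streamlines.trk.Field.VOXEL_TO_RASMM] = aff
            header[nib.streamlines.trk.Field.VOXEL_SIZES] = \
                np.sqrt((aff[:3, :3] ** 2).sum(axis=0)).astype(np.float32)
            header[nib.streamlines.trk.Field.DIMENSIONS] = \
                np.asarray(reference.shape, dtype=np.int16)
            header[nib.streamlines.trk.Field.VOXEL_ORDER] = b"RAS"
        nib.streamlines.TrkFile(tractogram, header=header).save(path)
    else:
        raise FormatError(f"unknown streamline extension on {path}; use .tck or .trk")


# --------------------------------------------------------------------------
# resampling under a spatial transform
# --------------------------------------------------------------------------

def apply_transform(obj, transform: SpatialTransform,
                    template: ScalarMap | LabelVolume | None = None):
    """Map a ScalarMap / LabelVolume / StreamlineSet through a transform.

    Streamline points are mapped forward.  Grids are resampled onto the
    template grid (default: the input's own grid) by pulling each output
    voxel centre back through the inverse transform; interpolation is
    nearest-neighbour for binary masks and label grids (so they stay
    binary/integral) and trilinear for density and probability maps.
    """
    if isinstance(obj, StreamlineSet):
        mapped = [transform.apply_points(s) for s in obj.streamlines]
        out = StreamlineSet(streamlines=mapped, meta=dict(obj.meta))
        out.scores = obj.scores
        return out

    if isinstance(obj, (ScalarMap, LabelVolume)):
        is_label = isinstance(obj, LabelVolume)
        role = "binary" if is_label else obj.role
        ref = obj if template is None else template
        out_shape = ref.shape
        out_affine = np.asarray(ref.affine, dtype=float)

        if transform.kind == "identity" and np.allclose(out_affine, obj.affine) \
                and out_shape == obj.shape:
            # exact identity: no resampling drift
            if is_label:
                return LabelVolume(obj.grid.copy(), obj.affine.copy(), dict(obj.labels))
            return ScalarMap(obj.grid.copy(), obj.affine.copy(), role=obj.role)

        if transform.kind == "displacement":
            # field supplied as the pull-back map for grid resampling
            pull = transform
        else:
            pull = transform.inverse()

        ii, jj, kk = np.meshgrid(*[np.arange(n) for n in out_shape], indexing="ij")
        centers = voxel_to_world(out_affine,
                                 np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1))
        src_world = pull.apply_points(centers)
        src_vox = world_to_voxel(obj.affine, src_world).T
        order = 0 if role in ("binary",) or is_label else 1
        data = map_coordinates(np.asarray(obj.grid, dtype=float), src_vox,
                               order=order, mode="constant", cval=0.0)
        data = data.reshape(out_shape)
        if is_label:
            return LabelVolume(np.round(data).astype(np.int32), out_affine,
                               dict(obj.labels))
        if role == "binary":
            data = (data > 0.5).astype(np.uint8)
        elif role == "probability":
            data = np.clip(data, 0.0, 1.0)
        return ScalarMap(data, out_affine, role=role)

    raise TypeError(f"cannot transform object of type {type(obj).__name__}")
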