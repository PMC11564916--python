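"""Core spatial data types and NIfTI I/O.

All volumes live on a :class:`GridSpec`: a regular 3-D voxel lattice with
physical spacing (mm), a world-space origin at the *center* of voxel
``(0, 0, 0)``, and an orthonormal direction matrix.  World coordinates are in
millimetres; indices are 0-based; interpolation is evaluated at voxel centers.

Displacement fields use the pull-back convention throughout the package: a
field ``u`` defined on grid ``G`` warps a volume ``v`` into the frame of ``G``
via ``out(x) = v(x + u(x))`` for every voxel-center world position ``x`` of
``G``.  The identity field is all zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "GridSpec",
    "ScalarVolume",
    "StructureMask",
    "VectorField",
    "VolumeIOError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_vector_field",
    "write_vector_field",
    "resample_to_grid",
    "resample_mask_to_grid",
    "sample_at_world",
    "warp_values",
    "signed_distance",
]

STRUCTURE_LABELS = ("CTV", "PTV", "bladder", "rectum", "urethra")


class VolumeIOError(IOError):
    """Raised for unreadable, missing, or non-3-D NIfTI inputs."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular 3-D voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along each axis, ``(nx, ny, nz)``.
    spacing
        Voxel size in mm along each axis; strictly positive.
    origin
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    direction
        3x3 orthonormal direction matrix mapping index axes to world axes.
        Identity for all synthetic data; honored if non-identity on input.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
    )

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        direction = tuple(tuple(float(d) for d in row) for row in np.asarray(self.direction))
        if len(shape) != 3 or any(n <= 0 for n in shape):
            raise ValueError(f"shape must be 3 positive integers, got {shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {spacing}")
        d = np.asarray(direction, dtype=float)
        if d.shape != (3, 3) or abs(abs(np.linalg.det(d)) - 1.0) > 1e-6:
            raise ValueError("direction matrix must be orthonormal (|det| = 1)")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", direction)

    # -- geometry helpers -------------------------------------------------
    @property
    def affine(self) -> np.ndarray:
        """4x4 index->world affine (voxel-center convention)."""
        a = np.eye(4)
        a[:3, :3] = np.asarray(self.direction) * np.asarray(self.spacing)[None, :]
        a[:3, 3] = self.origin
        return a

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx @ (np.asarray(self.direction) * np.asarray(self.spacing)[None, :]).T + np.asarray(
            self.origin
        )

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        m = np.linalg.inv(np.asarray(self.direction) * np.asarray(self.spacing)[None, :])
        return (pts - np.asarray(self.origin)) @ m.T

    def voxel_centers_world(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(*shape, 3)``.

        The array is cached (read-only) because every warp and resampling
        operation needs it.
        """
        return _voxel_centers_cached(self)

    def same_geometry(self, other: "GridSpec", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned world bounding box of all voxel centers."""
        corners = np.array(
            [[i, j, k] for i in (0, self.shape[0] - 1) for j in (0, self.shape[1] - 1) for k in (0, self.shape[2] - 1)],
            dtype=float,
        )
        w = self.index_to_world(corners)
        return w.min(axis=0), w.max(axis=0)


from functools import lru_cache


@lru_cache(maxsize=8)
def _voxel_centers_cached(grid: GridSpec) -> np.ndarray:
    idx = np.stack(
        np.meshgrid(*(np.arange(n, dtype=float) for n in grid.shape), indexing="ij"),
        axis=-1,
    )
    out = grid.index_to_world(idx)
    out.setflags(write=False)
    return out


@dataclass
class ScalarVolume:
    """A 3-D scalar field on a grid: image intensities (a.u.) or dose (Gy)."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid shape {self.grid.shape}"
            )

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.grid, self.values.copy())


@dataclass
class StructureMask:
    """Binary structure mask (CTV, PTV, bladder, rectum, urethra) on a grid."""

    grid: GridSpec
    values: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.values.shape} does not match grid shape {self.grid.shape}"
            )

    @property
    def volume_cm3(self) -> float:
        return float(self.values.sum()) * self.grid.voxel_volume_mm3 / 1000.0

    def copy(self) -> "StructureMask":
        return StructureMask(self.grid, self.values.copy(), self.label)


@dataclass
class VectorField:
    """Per-voxel 3-D displacement (mm, world axes), pull-back convention."""

    grid: GridSpec
    values: np.ndarray  # shape (*grid.shape, 3)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != (*self.grid.shape, 3):
            raise ValueError(
                f"field shape {self.values.shape} does not match grid shape {self.grid.shape} + (3,)"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("displacement field contains non-finite values")

    @classmethod
    def identity(cls, grid: GridSpec) -> "VectorField":
        return cls(grid, np.zeros((*grid.shape, 3), dtype=np.float32))

    def max_displacement(self) -> float:
        return float(np.sqrt((self.values.astype(np.float64) ** 2).sum(axis=-1)).max())


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _grid_from_nifti(img: nib.Nifti1Image, path: Path) -> tuple[GridSpec, np.ndarray]:
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected 3-D volume, got {data.ndim}-D")
    aff = img.affine
    scale_dir = aff[:3, :3]
    spacing = np.linalg.norm(scale_dir, axis=0)
    if np.any(spacing <= 0):
        raise VolumeIOError(f"{path}: degenerate affine (zero spacing)")
    direction = scale_dir / spacing[None, :]
    grid = GridSpec(
        shape=tuple(data.shape),
        spacing=tuple(spacing),
        origin=tuple(aff[:3, 3]),
        direction=tuple(map(tuple, direction)),
    )
    return grid, data


def read_volume(path: str | Path) -> ScalarVolume:
    """Read a 3-D NIfTI scalar volume.

    Raises :class:`VolumeIOError` for missing files, unreadable headers, or
    non-3-D data.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of header errors
        raise VolumeIOError(f"{path}: unreadable NIfTI ({exc})") from exc
    grid, data = _grid_from_nifti(img, path)
    return ScalarVolume(grid, np.asarray(data))


def write_volume(vol: ScalarVolume, path: str | Path) -> None:
    """Write a scalar volume as NIfTI-1; spacing/origin round-trip to 1e-6 mm."""
    path = Path(path)
    if not path.parent.exists():
        raise VolumeIOError(f"directory does not exist: {path.parent}")
    data = np.asarray(vol.values)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, vol.grid.affine)
    img.header.set_zooms(vol.grid.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path, label: str) -> StructureMask:
    vol = read_volume(path)
    return StructureMask(vol.grid, vol.values > 0.5, label)


def write_mask(mask: StructureMask, path: str | Path) -> None:
    write_volume(ScalarVolume(mask.grid, mask.values.astype(np.uint8)), path)


_FIELD_SUFFIXES = ("_dx", "_dy", "_dz")


def _field_component_paths(path: str | Path) -> list[Path]:
    """Expand a base path like ``field.nii.gz`` to ``field_dx.nii.gz`` etc."""
    path = Path(path)
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            stem = name[: -len(ext)]
            return [path.with_name(stem + suf + ext) for suf in _FIELD_SUFFIXES]
    raise VolumeIOError(f"vector field path must end in .nii or .nii.gz: {path}")


def write_vector_field(dvf: VectorField, path: str | Path) -> None:
    """Store a displacement field as three scalar NIfTIs (_dx/_dy/_dz, mm)."""
    for axis, comp_path in enumerate(_field_component_paths(path)):
        write_volume(ScalarVolume(dvf.grid, dvf.values[..., axis]), comp_path)


def read_vector_field(path: str | Path) -> VectorField:
    comps = []
    grid = None
    for comp_path in _field_component_paths(path):
        vol = read_volume(comp_path)
        if grid is not None and not vol.grid.same_geometry(grid):
            raise VolumeIOError(f"{comp_path}: component grids disagree")
        grid = vol.grid
        comps.append(vol.values)
    return VectorField(grid, np.stack(comps, axis=-1))


# ---------------------------------------------------------------------------
# Sampling and resampling
# ---------------------------------------------------------------------------

def sample_at_world(
    values: np.ndarray,
    grid: GridSpec,
    pts: np.ndarray,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Sample ``values`` (defined on ``grid``) at world points ``pts``.

    ``order=1`` is trilinear, ``order=0`` nearest neighbour.  Points outside
    the grid return ``cval``.
    """
    pts = np.asarray(pts, dtype=float)
    idx = grid.world_to_index(pts.reshape(-1, 3))
    coords = idx.T  # (3, n)
    arr = np.asarray(values)
    if order and arr.dtype not in (np.float32, np.float64):
        arr = arr.astype(np.float32)  # interpolation needs a float type
    out = ndimage.map_coordinates(
        arr,
        coords,
        order=order,
        mode="constant",
        cval=cval,
        prefilter=False,
    )
    return out.reshape(pts.shape[:-1])


def warp_values(
    values: np.ndarray,
    source_grid: GridSpec,
    dvf: VectorField,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Pull ``values`` into the frame of ``dvf.grid``: ``out(x) = v(x + u(x))``."""
    if not np.any(dvf.values):
        # identity field: plain resample (exact when geometries match)
        if dvf.grid.same_geometry(source_grid):
            return np.asarray(values).copy()
    pts = dvf.grid.voxel_centers_world() + dvf.values.astype(np.float64)
    return sample_at_world(values, source_grid, pts, order=order, cval=cval)


def resample_to_grid(
    vol: ScalarVolume,
    target: GridSpec,
    mode: str = "trilinear",
    fill: float = 0.0,
) -> ScalarVolume:
    """Resample a scalar volume onto ``target`` (trilinear or nearest).

    Out-of-field voxels are filled with ``fill`` (0 for dose).  Raises
    ``ValueError`` if the world extents of source and target are disjoint.
    """
    if mode not in ("trilinear", "nearest"):
        raise ValueError(f"unknown resampling mode: {mode!r}")
    lo_s, hi_s = vol.grid.world_bounds()
    lo_t, hi_t = target.world_bounds()
    if np.any(hi_s < lo_t) or np.any(hi_t < lo_s):
        raise ValueError("source and target grids are disjoint in world space")
    if target.same_geometry(vol.grid):
        return ScalarVolume(target, np.asarray(vol.values).copy())
    pts = target.voxel_centers_world()
    order = 1 if mode == "trilinear" else 0
    out = sample_at_world(vol.values, vol.grid, pts, order=order, cval=fill)
    return ScalarVolume(target, out)


def resample_mask_to_grid(mask: StructureMask, target: GridSpec) -> StructureMask:
    """Nearest-neighbour mask resampling; output strictly binary."""
    vol = resample_to_grid(ScalarVolume(mask.grid, mask.values.astype(np.uint8)), target, mode="nearest")
    return StructureMask(target, vol.values > 0.5, mask.label)


def signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Signed Euclidean distance (mm) to the mask boundary; negative inside."""
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    if not mask.any():
        return np.full(mask.shape, np.inf, dtype=np.float32)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    return (outside - inside).astype(np.float32)
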