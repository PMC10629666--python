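"""Grid-aware brain volumes, NIfTI I/O, resampling, masks and components.

All spatial quantities live in a RAS+ world frame measured in millimetres;
voxel indices are only ever an addressing detail.  Volumes carry a payload
tag (``EF_Vm``, ``beta``, ``delta_beta``, ``tstat``, ``r``, ``p``, ``q``,
``label``, ``bold``) so that downstream stages can validate what they are
handed.  Undefined voxels are represented as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

PAYLOADS = frozenset(
    {"EF_Vm", "beta", "delta_beta", "tstat", "r", "p", "q", "label", "bold"}
)

#: common analysis grid used by the full-scale pipeline: 96 x 114 x 96 voxels
#: at 2 mm isotropic (~1 050 624 voxels).  Never hard-coded elsewhere.
DEFAULT_ANALYSIS_DIMS = (96, 114, 96)
DEFAULT_ANALYSIS_VOXEL_MM = 2.0


class VolumeError(ValueError):
    """Raised for malformed volumes, grids or masks."""


@dataclass(frozen=True)
class GridSpec:
    """Voxel lattice geometry: dims plus a voxel-index -> world-mm affine."""

    dims: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        object.__setattr__(self, "dims", dims)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise VolumeError(f"dims must be a positive integer triple, got {dims}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise VolumeError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise VolumeError("affine is singular")
        aff = aff.copy()
        aff.flags.writeable = False
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(np.asarray(self.affine)[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @classmethod
    def isotropic(cls, dims, voxel_mm: float, centered: bool = True) -> "GridSpec":
        """Axis-aligned RAS+ grid; origin at the grid centre when ``centered``."""
        dims = tuple(int(d) for d in dims)
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = float(voxel_mm)
        if centered:
            aff[:3, 3] = -(np.array(dims) - 1) / 2.0 * voxel_mm
        return cls(dims, aff)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ np.asarray(self.affine)[:3, :3].T + np.asarray(self.affine)[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(np.asarray(self.affine))
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape dims + (3,)."""
        ii, jj, kk = np.meshgrid(*(np.arange(d) for d in self.dims), indexing="ij")
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.index_to_world(idx).reshape(self.dims + (3,))

    def world_bbox(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) world coordinates over the eight grid corners."""
        corners = np.array(
            [[i, j, k] for i in (0, self.dims[0] - 1)
             for j in (0, self.dims[1] - 1) for k in (0, self.dims[2] - 1)],
            dtype=float,
        )
        world = self.index_to_world(corners)
        return world.min(axis=0), world.max(axis=0)

    def same_grid(self, other: "GridSpec", tol: float = 1e-4) -> bool:
        return self.dims == other.dims and np.allclose(
            self.affine, other.affine, atol=tol
        )


def _check_payload(values: np.ndarray, payload: str) -> None:
    if payload not in PAYLOADS:
        raise VolumeError(f"unknown payload {payload!r}")
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return
    if payload in ("p", "q") and ((finite < 0).any() or (finite > 1).any()):
        raise VolumeError(f"payload {payload} must lie in [0, 1]")
    if payload == "r" and (np.abs(finite) > 1 + 1e-9).any():
        raise VolumeError("payload r must lie in [-1, 1]")
    if payload == "EF_Vm" and (finite < 0).any():
        raise VolumeError("payload EF_Vm must be nonnegative")
    if payload == "label" and (
        (finite < 0).any() or not np.allclose(finite, np.round(finite))
    ):
        raise VolumeError("payload label must be nonnegative integers")


@dataclass
class BrainVolume:
    """A scalar field on a :class:`GridSpec` (3-D, or 4-D for BOLD series)."""

    grid: GridSpec
    values: np.ndarray
    payload: str = "beta"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = self.grid.dims
        if self.payload == "bold":
            if self.values.ndim != 4 or self.values.shape[:3] != expected:
                raise VolumeError(
                    f"bold values must be dims + (T,), got {self.values.shape}"
                )
        elif self.values.shape != expected:
            raise VolumeError(
                f"values shape {self.values.shape} != grid dims {expected}"
            )
        _check_payload(self.values, self.payload)

    def with_values(self, values, payload=None) -> "BrainVolume":
        return BrainVolume(self.grid, values, payload or self.payload)


@dataclass
class Mask:
    """Boolean membership volume sharing a grid with the maps it masks."""

    grid: GridSpec
    member: np.ndarray

    def __post_init__(self):
        self.member = np.asarray(self.member, dtype=bool)
        if self.member.shape != self.grid.dims:
            raise VolumeError("mask shape does not match grid dims")

    @property
    def n_voxels(self) -> int:
        return int(self.member.sum())

    def indices(self) -> np.ndarray:
        """Flat (C-order) indices of member voxels, ascending."""
        return np.flatnonzero(self.member.ravel(order="C"))

    def __and__(self, other: "Mask") -> "Mask":
        if not self.grid.same_grid(other.grid):
            raise VolumeError("mask grids differ")
        return Mask(self.grid, self.member & other.member)


@dataclass
class AtlasParcellation:
    """Integer-labelled parcellation: 0 is background, labels are disjoint."""

    labels: BrainVolume
    table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.labels.payload != "label":
            raise VolumeError("atlas labels must have payload 'label'")
        present = set(np.unique(self.labels.values[self.labels.values > 0]).astype(int))
        missing = present - set(self.table)
        if missing:
            raise VolumeError(f"labels missing from table: {sorted(missing)}")

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def grid(self) -> GridSpec:
        return self.labels.grid

    def region_mask(self, label: int) -> Mask:
        return Mask(self.grid, self.labels.values == label)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"label": list(self.table), "name": list(self.table.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_files(cls, label_path, table_path) -> "AtlasParcellation":
        import pandas as pd

        vol = read_volume(label_path, payload="label")
        tab = pd.read_csv(table_path, sep="\t")
        return cls(vol, dict(zip(tab["label"].astype(int), tab["name"].astype(str))))


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path, payload: str = "beta") -> BrainVolume:
    """Read a 3-D (or 4-D ``bold``) NIfTI file; scl_slope/scl_inter applied."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim == 4:
        if payload != "bold":
            if data.shape[3] == 1:
                data = data[..., 0]
            else:
                raise VolumeError(
                    f"{path}: 4-D image; read with payload='bold' for a series"
                )
    elif data.ndim != 3:
        raise VolumeError(f"{path}: expected 3-D or 4-D image, got {data.ndim}-D")
    grid = GridSpec(data.shape[:3], np.asarray(img.affine))
    return BrainVolume(grid, data, payload)


def write_volume(vol: BrainVolume, path) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float32), np.asarray(vol.grid.affine))
    nib.save(img, str(path))


def write_mask(mask: Mask, path) -> None:
    img = nib.Nifti1Image(
        mask.member.astype(np.uint8), np.asarray(mask.grid.affine)
    )
    nib.save(img, str(path))


def read_mask(path) -> Mask:
    img = nib.load(str(path))
    return Mask(GridSpec(img.shape[:3], np.asarray(img.affine)),
                np.asarray(img.get_fdata()) > 0.5)


# ---------------------------------------------------------------------------
# Geometry operations


def resample_to_grid(vol: BrainVolume, target: GridSpec, method: str = "linear") -> BrainVolume:
    """Resample ``vol`` onto ``target`` (shared world frame).

    Linear interpolation for scalar payloads; nearest-neighbour is mandatory
    for label payloads.  Target voxels that map outside the source extent are
    filled with 0.
    """
    if method not in ("linear", "nearest"):
        raise VolumeError(f"unknown method {method!r}")
    if vol.payload == "label" and method == "linear":
        raise VolumeError("label payloads must be resampled with method='nearest'")
    if vol.grid.same_grid(target):
        return BrainVolume(target, vol.values.copy(), vol.payload)
    # voxel index map: target index -> world -> source index
    xform = np.linalg.inv(np.asarray(vol.grid.affine)) @ np.asarray(target.affine)
    ii, jj, kk = np.meshgrid(*(np.arange(d) for d in target.dims), indexing="ij")
    idx = np.stack([ii, jj, kk], axis=0).reshape(3, -1).astype(float)
    src = xform[:3, :3] @ idx + xform[:3, 3:4]
    order = 1 if method == "linear" else 0
    out = ndimage.map_coordinates(
        vol.values, src, order=order, mode="constant", cval=0.0
    )
    return BrainVolume(target, out.reshape(target.dims), vol.payload)


def make_sphere_mask(grid: GridSpec, center_mm, radius_mm: float) -> Mask:
    """Voxels whose centre lies within ``radius_mm`` (world mm) of ``center_mm``."""
    if radius_mm <= 0:
        raise VolumeError("radius_mm must be positive")
    centers = grid.voxel_centers()
    d2 = ((centers - np.asarray(center_mm, dtype=float)) ** 2).sum(axis=-1)
    member = d2 <= radius_mm**2
    if not member.any():
        raise VolumeError("sphere lies entirely outside the grid")
    return Mask(grid, member)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def connected_components(mask: Mask, connectivity: int = 18) -> list[Mask]:
    """Maximal connected sets, sorted by size descending.

    Ties are broken by the smallest flat voxel index occurring in the
    component.  Empty mask gives an empty list.
    """
    if connectivity not in _STRUCTURES:
        raise VolumeError("connectivity must be one of 6, 18, 26")
    labels, n = ndimage.label(mask.member, structure=_STRUCTURES[connectivity])
    if n == 0:
        return []
    flat = labels.ravel(order="C")
    sizes = np.bincount(flat)[1:]
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # first occurrence per label (iterate reversed so earlier index wins)
    np.minimum.at(first, flat[nz], nz)
    order = sorted(range(1, n + 1), key=lambda c: (-sizes[c - 1], first[c]))
    return [Mask(mask.grid, labels == c) for c in order]
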