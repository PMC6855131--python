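"""Brain-map I/O: NIfTI volumes, voxel masks, downsampling, flattening.

The flatten convention is fixed: in-mask voxels are numbered in C order
(last grid axis fastest) over the mask grid, and that numbering defines the
column order of every flat subject-by-voxel matrix.  All analyses downstream
are coordinate-agnostic, but selection-overlap reporting relies on this
stable voxel identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from neurofuse.errors import IncompatibleGeometryError, ConfigurationError


@dataclass
class VoxelMask:
    """Boolean 3-D mask with grid geometry and a fixed flatten order."""

    grid: np.ndarray
    voxel_size: float = 1.0
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    flatten_order: str = "C"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ConfigurationError("mask grid must be 3-D")
        if not self.grid.any():
            raise ConfigurationError("mask must contain at least one true voxel")
        if self.flatten_order != "C":
            raise ConfigurationError("only C flatten order is supported")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    def voxel_table(self) -> np.ndarray:
        """(n_voxels, 3) array: column index -> (i, j, k) grid coordinate."""
        return np.argwhere(self.grid)  # argwhere scans in C order

    def flatten(self, volume: np.ndarray) -> np.ndarray:
        volume = np.asarray(volume)
        if volume.shape != self.grid.shape:
            raise IncompatibleGeometryError(
                f"volume shape {volume.shape} != mask grid {self.grid.shape}"
            )
        return volume[self.grid]

    def unflatten(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        values = np.asarray(values)
        if values.shape != (self.n_voxels,):
            raise IncompatibleGeometryError(
                f"expected {self.n_voxels} values, got {values.shape}"
            )
        out = np.full(self.grid.shape, fill, dtype=float)
        out[self.grid] = values
        return out


@dataclass
class FlatDataset:
    """Subjects-by-voxels matrix tied to the mask that defined its columns."""

    matrix: np.ndarray
    mask_ref: VoxelMask
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.mask_ref.n_voxels:
            raise IncompatibleGeometryError(
                f"matrix has {self.matrix.shape} shape; mask has {self.mask_ref.n_voxels} voxels"
            )
        if np.isnan(self.matrix).any():
            raise ConfigurationError("flat dataset must not contain missing values")
        if not self.subject_ids:
            self.subject_ids = [f"s{i:04d}" for i in range(self.matrix.shape[0])]

    @property
    def voxel_table(self) -> np.ndarray:
        return self.mask_ref.voxel_table()


def intersect_masks(masks: list[VoxelMask]) -> VoxelMask:
    """Logical AND of masks sharing a grid and affine."""
    if not masks:
        raise ConfigurationError("need at least one mask")
    first = masks[0]
    grid = first.grid.copy()
    for other in masks[1:]:
        if other.grid.shape != first.grid.shape or not np.allclose(other.affine, first.affine):
            raise IncompatibleGeometryError("masks differ in grid shape or affine")
        grid &= other.grid
    if not grid.any():
        raise ConfigurationError("mask intersection is empty")
    return VoxelMask(grid=grid, voxel_size=first.voxel_size, affine=first.affine.copy())


def downsample_volume(
    volume: np.ndarray, mask: VoxelMask, factor: int
) -> tuple[np.ndarray, VoxelMask]:
    """Block-average ``volume`` by ``factor`` along each axis.

    Each coarse voxel is the mean over its in-mask children; a coarse mask
    voxel is true iff at least half of its ``factor**3`` children are in-mask
    (ties included).  Trailing voxels that do not fill a block are truncated.
    """
    if int(factor) != factor or factor < 1:
        raise ConfigurationError("factor must be an integer >= 1")
    factor = int(factor)
    volume = np.asarray(volume, dtype=float)
    if volume.shape != mask.grid.shape:
        raise IncompatibleGeometryError("volume does not match mask grid")
    if factor == 1:
        return volume.copy(), VoxelMask(
            grid=mask.grid.copy(), voxel_size=mask.voxel_size, affine=mask.affine.copy()
        )

    dims = tuple((s // factor) * factor for s in volume.shape)
    v = volume[: dims[0], : dims[1], : dims[2]]
    g = mask.grid[: dims[0], : dims[1], : dims[2]].astype(float)
    shape6 = (
        dims[0] // factor, factor, dims[1] // factor, factor, dims[2] // factor, factor
    )
    vb = v.reshape(shape6)
    gb = g.reshape(shape6)
    counts = gb.sum(axis=(1, 3, 5))
    sums = (vb * gb).sum(axis=(1, 3, 5))
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    coarse_mask_grid = counts * 2 >= factor**3

    new_affine = mask.affine.copy()
    new_affine[:3, :3] *= factor
    coarse_mask = VoxelMask(
        grid=coarse_mask_grid, voxel_size=mask.voxel_size * factor, affine=new_affine
    )
    return means, coarse_mask


def read_mask(path: str | Path) -> VoxelMask:
    img = nib.load(str(path))
    grid = np.asanyarray(img.dataobj) > 0
    voxel_size = float(np.abs(np.diag(img.affine)[:3]).mean())
    return VoxelMask(grid=grid, voxel_size=voxel_size, affine=np.asarray(img.affine))


def write_mask(mask: VoxelMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def read_subject_maps(
    paths: list[str | Path], mask: VoxelMask, subject_ids: list[str] | None = None
) -> FlatDataset:
    """Load one NIfTI volume per subject and flatten to a matrix in list order."""
    rows = []
    for path in paths:
        img = nib.load(str(path))
        vol = np.asanyarray(img.dataobj, dtype=float)
        if vol.shape != mask.grid.shape:
            raise IncompatibleGeometryError(
                f"{path}: volume shape {vol.shape} != mask grid {mask.grid.shape}"
            )
        if not np.allclose(np.asarray(img.affine), mask.affine, atol=1e-4):
            raise IncompatibleGeometryError(f"{path}: affine does not match mask")
        rows.append(mask.flatten(vol))
    return FlatDataset(
        matrix=np.vstack(rows),
        mask_ref=mask,
        subject_ids=list(subject_ids or []),
    )


def write_map_volume(values: np.ndarray, mask: VoxelMask, path: str | Path) -> None:
    """Write a flat voxel vector (or full volume) as a NIfTI file."""
    values = np.asarray(values, dtype=float)
    vol = values if values.ndim == 3 else mask.unflatten(values)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), mask.affine), str(path))


def read_flat_table(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a pre-flattened subject-by-voxel CSV/TSV (header = voxel ids).

    Returns (matrix, subject_ids, voxel_ids).
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]
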