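"""Volumetric ROI handling: NIfTI masks, sphere ROIs, anterior/posterior
splits and voxel-pattern extraction.

World coordinates are MNI millimetres obtained through the NIfTI affine;
voxel indices are 0-based, and sphere membership is decided by voxel centres
(no partial-volume weighting). All images in a run are assumed to share one
voxel grid — the pipeline does not register or normalise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .patterns import PatternMatrix

logger = logging.getLogger("gramrsa")

__all__ = [
    "VolumeError",
    "EmptyMaskError",
    "VoxelGrid",
    "ROIMask",
    "read_mask",
    "write_mask",
    "make_sphere_roi",
    "split_anterior_posterior",
    "extract_patterns",
    "read_roi_catalogue",
]


class VolumeError(ValueError):
    """Invalid volumetric input."""


class EmptyMaskError(VolumeError):
    """A mask or sphere contains no voxels."""


@dataclass(frozen=True)
class VoxelGrid:
    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, float)
        if affine.shape != (4, 4):
            raise VolumeError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise VolumeError("affine must be invertible")
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise VolumeError("grid shape must be three positive integers")

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        """World (mm) coordinates of voxel centres given integer indices."""
        return nib.affines.apply_affine(self.affine, np.asarray(ijk, float))

    def compatible(self, other: "VoxelGrid", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class ROIMask:
    """A set of voxel indices on a grid, with region and hemisphere labels."""

    grid: VoxelGrid
    voxels: np.ndarray  # (n, 3) integer indices, C-order sorted
    roi_id: str = ""
    hemisphere: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, int)
        if v.ndim != 2 or v.shape[1] != 3:
            raise VolumeError("voxels must be an (n, 3) index array")
        if v.shape[0] == 0:
            raise EmptyMaskError(f"ROI {self.roi_id!r} contains no voxels")
        shape = np.asarray(self.grid.shape)
        if np.any(v < 0) or np.any(v >= shape):
            raise VolumeError(f"ROI {self.roi_id!r} has out-of-grid voxels")
        # canonical C-order so pattern-row order is reproducible
        flat = np.ravel_multi_index(v.T, self.grid.shape)
        self.voxels = v[np.argsort(flat)]

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[0]

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.grid.shape, dtype=np.uint8)
        arr[tuple(self.voxels.T)] = 1
        return arr

    def world_coords(self) -> np.ndarray:
        return self.grid.world_coords(self.voxels)


def _grid_from_img(img: nib.spatialimages.SpatialImage) -> VoxelGrid:
    return VoxelGrid(shape=tuple(img.shape[:3]), affine=np.asarray(img.affine))


def read_mask(
    path: str | Path, roi_id: str = "", hemisphere: str = ""
) -> ROIMask:
    """Read a binary (or thresholdable) NIfTI mask; voxels where value > 0.5."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeError(f"{path}: mask must be 3-D, got {data.ndim}-D")
    voxels = np.argwhere(data > 0.5)
    if voxels.shape[0] == 0:
        raise EmptyMaskError(f"{path}: mask is empty")
    return ROIMask(
        grid=_grid_from_img(img),
        voxels=voxels,
        roi_id=roi_id or Path(path).stem.replace(".nii", ""),
        hemisphere=hemisphere,
    )


def write_mask(mask: ROIMask, path: str | Path) -> None:
    img = nib.Nifti1Image(
        mask.to_array(), affine=mask.grid.affine
    )
    nib.save(img, str(path))


def make_sphere_roi(
    center_mm: Sequence[float],
    radius_mm: float,
    grid: VoxelGrid,
    roi_id: str = "",
    hemisphere: str = "",
) -> ROIMask:
    """Voxels whose world-space centre lies within ``radius_mm`` of
    ``center_mm`` (Euclidean, MNI mm)."""
    if radius_mm < 0:
        raise VolumeError("radius must be >= 0")
    center = np.asarray(center_mm, float)
    idx = np.indices(grid.shape).reshape(3, -1).T
    coords = grid.world_coords(idx)
    d2 = np.sum((coords - center) ** 2, axis=1)
    inside = idx[d2 <= radius_mm**2 + 1e-9]
    if inside.shape[0] == 0:
        raise EmptyMaskError(
            f"sphere at {center.tolist()} r={radius_mm} mm misses the grid"
        )
    return ROIMask(grid=grid, voxels=inside, roi_id=roi_id,
                   hemisphere=hemisphere)


def split_anterior_posterior(
    mask: ROIMask,
    boundary_y_mm: float | None = None,
) -> tuple[ROIMask, ROIMask]:
    """Split a mask at a world-y coordinate: anterior = y > boundary.

    The boundary defaults to the mask's own median world-y, so the halves
    partition the region; outputs carry "a"/"p" prefixes on the roi_id.
    An empty half raises :class:`EmptyMaskError` naming the side.
    """
    ys = mask.world_coords()[:, 1]
    if boundary_y_mm is None:
        boundary_y_mm = float(np.median(ys))
    ant = mask.voxels[ys > boundary_y_mm]
    post = mask.voxels[ys <= boundary_y_mm]
    halves = []
    for prefix, vox in (("a", ant), ("p", post)):
        if vox.shape[0] == 0:
            raise EmptyMaskError(
                f"{'anterior' if prefix == 'a' else 'posterior'} half of "
                f"{mask.roi_id!r} is empty at y={boundary_y_mm:g} mm"
            )
        halves.append(
            ROIMask(
                grid=mask.grid,
                voxels=vox,
                roi_id=f"{prefix}{mask.roi_id}",
                hemisphere=mask.hemisphere,
            )
        )
    return halves[0], halves[1]


def extract_patterns(
    condition_images: Mapping[str, str | Path],
    mask: ROIMask,
    subject_id: str = "",
    condition_order: Sequence[str] | None = None,
) -> PatternMatrix:
    """Extract a voxel × condition matrix from per-condition NIfTI images.

    All images must share the mask's grid. Voxels with any non-finite value
    across conditions are dropped (with a logged count).
    """
    if condition_order is None:
        condition_order = list(condition_images)
    missing = [c for c in condition_order if c not in condition_images]
    if missing:
        raise VolumeError(f"missing condition images: {missing}")
    columns = []
    for cond in condition_order:
        img = nib.load(str(condition_images[cond]))
        grid = _grid_from_img(img)
        if not grid.compatible(mask.grid):
            raise VolumeError(
                f"image for condition {cond!r} is on a different grid "
                f"than ROI {mask.roi_id!r}"
            )
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        columns.append(data[tuple(mask.voxels.T)])
    values = np.column_stack(columns)
    finite = np.all(np.isfinite(values), axis=1)
    dropped = int(np.count_nonzero(~finite))
    if dropped:
        logger.warning(
            "dropping %d non-finite voxel(s) in ROI %s (subject %s)",
            dropped, mask.roi_id, subject_id,
        )
        values = values[finite]
    return PatternMatrix(
        values=values,
        conditions=tuple(condition_order),
        subject_id=subject_id,
        roi_id=mask.roi_id,
    )


def read_roi_catalogue(
    path: str | Path, grid: VoxelGrid | None = None
) -> list[ROIMask]:
    """Load ROIs from a catalogue TSV with columns roi_id, hemisphere,
    source_type (mask|sphere) and source.

    ``source`` is a mask path (relative to the catalogue) for masks, or
    "x,y,z,radius" in mm for spheres (which require ``grid``).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"roi_id", "hemisphere", "source_type", "source"}
    if not required.issubset(df.columns):
        raise VolumeError(f"ROI catalogue needs columns {sorted(required)}")
    rois = []
    for row in df.itertuples(index=False):
        if row.source_type == "mask":
            rois.append(
                read_mask(
                    path.parent / row.source,
                    roi_id=row.roi_id,
                    hemisphere=row.hemisphere or "",
                )
            )
        elif row.source_type == "sphere":
            if grid is None:
                raise VolumeError(
                    f"sphere ROI {row.roi_id!r} needs a reference grid"
                )
            x, y, z, r = (float(v) for v in row.source.split(","))
            rois.append(
                make_sphere_roi(
                    (x, y, z), r, grid,
                    roi_id=row.roi_id, hemisphere=row.hemisphere or "",
                )
            )
        else:
            raise VolumeError(
                f"unknown source_type {row.source_type!r} for {row.roi_id!r}"
            )
    return rois
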