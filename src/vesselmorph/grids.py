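"""Voxel grids, volumes, binary vessel masks, and NIfTI I/O.

All physical quantities downstream (lengths, radii, volumes) are derived
from the grid's affine, in millimetres. Voxel indices are 0-based and world
coordinates come exclusively from the 4x4 grid-to-world affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class GridError(ValueError):
    """Raised for inconsistent or degenerate grid definitions."""


def _affine_spacing(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel spacing: column norms of the affine's linear part."""
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


@dataclass(frozen=True)
class GridSpec:
    """A 3D voxel grid: shape, mm spacing, and grid-to-world affine.

    Either ``spacing`` or ``affine`` may be omitted; the missing one is
    derived (an axis-aligned affine centred at the origin when only
    spacing is given). When both are given they must agree to 1e-4.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = None  # type: ignore[assignment]
    affine: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise GridError(f"shape must be 3 positive integers, got {self.shape!r}")
        object.__setattr__(self, "shape", shape)

        if self.spacing is None and self.affine is None:
            raise GridError("GridSpec needs spacing and/or affine")
        if self.affine is None:
            sp = tuple(float(s) for s in self.spacing)
            aff = np.diag([*sp, 1.0])
        else:
            aff = np.array(self.affine, dtype=float)
            if aff.shape != (4, 4):
                raise GridError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise GridError("affine is singular (degenerate grid)")
        derived = _affine_spacing(aff)
        if self.spacing is None:
            sp = tuple(float(s) for s in derived)
        else:
            sp = tuple(float(s) for s in self.spacing)
            if np.max(np.abs(np.asarray(sp) - derived)) > 1e-4:
                raise GridError(
                    f"spacing {sp} inconsistent with affine column norms {tuple(derived)}"
                )
        if any(s <= 0 for s in sp):
            raise GridError(f"spacing must be strictly positive, got {sp}")
        object.__setattr__(self, "spacing", sp)
        aff.setflags(write=False)
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (N,3) voxel indices to (N,3) world coordinates in mm."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def same_grid(self, other: "GridSpec", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )


@dataclass
class Volume3D:
    """A scalar field on a :class:`GridSpec`."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise GridError("volume contains non-finite values")


@dataclass
class BinaryVesselMask(Volume3D):
    """A Volume3D restricted to {0, 1}: the segmentation object."""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if not np.isin(vals, (0, 1)).all():
            raise GridError("mask values must be exactly 0 or 1")
        self.values = vals.astype(np.uint8)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )


def load_volume(path: str | Path, cls: type[Volume3D] = Volume3D) -> Volume3D:
    """Load a NIfTI-1/NIfTI-2 image as a :class:`Volume3D`.

    Values, spacing and affine are taken faithfully from the header;
    no resampling is performed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise GridError(f"{path} is not a 3D volume (ndim={data.ndim})")
    if not np.all(np.isfinite(data)):
        raise GridError(f"{path} contains non-finite voxel values")
    grid = GridSpec(shape=data.shape, affine=np.asarray(img.affine))
    return cls(grid=grid, values=data)


def load_mask(path: str | Path) -> BinaryVesselMask:
    """Load a binary vessel mask, validating that values are {0,1}."""
    return load_volume(path, cls=BinaryVesselMask)  # type: ignore[return-value]


def save_volume(vol: Volume3D, path: str | Path) -> None:
    """Write a volume to NIfTI; round-trips values bit-exactly."""
    path = Path(path)
    data = vol.values
    if data.dtype == np.uint8:
        out = data
    else:
        out = np.asarray(data, dtype=np.float64)
    img = nib.Nifti1Image(out, np.asarray(vol.grid.affine))
    img.header.set_zooms(vol.grid.spacing)
    nib.save(img, str(path))


def resample_trilinear(vol: Volume3D, target: GridSpec) -> Volume3D:
    """Resample a volume onto ``target`` with trilinear interpolation.

    Each output voxel takes the trilinear interpolation of the source at
    the output voxel's world coordinate; world coordinates outside the
    source domain are filled with 0 (background).
    """
    src_inv = np.linalg.inv(np.asarray(vol.grid.affine))
    # output voxel index -> source voxel index
    m = src_inv @ np.asarray(target.affine)
    out = ndimage.affine_transform(
        np.asarray(vol.values, dtype=float),
        matrix=m[:3, :3],
        offset=m[:3, 3],
        output_shape=target.shape,
        order=1,
        mode="constant",
        cval=0.0,
    )
    return Volume3D(grid=target, values=out)


def binarize(vol: Volume3D, threshold: float = 0.5) -> BinaryVesselMask:
    """Threshold a volume into a BinaryVesselMask (1 iff value > threshold)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return BinaryVesselMask(grid=vol.grid, values=(vol.values > threshold).astype(np.uint8))


def resample_mask(mask: BinaryVesselMask, target: GridSpec, threshold: float = 0.5) -> BinaryVesselMask:
    """Linear-then-threshold mask resampling (threshold exposed explicitly)."""
    return binarize(resample_trilinear(mask, target), threshold)
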