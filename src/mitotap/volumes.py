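"""Voxel-grid data model and I/O for 3D image stacks and masks.

Volumes are stored in ``(z, y, x)`` index order, 0-based, so the slice
index of an acquisition stack is the first array axis.  Physical spacing
is carried in nanometres per voxel; the default 10 nm isotropic grid is
the analysis grid used throughout the quantification modules.

Supported on-disk layouts are multipage TIFF and directories of
zero-padded per-slice 2D images (PNG or TIFF, 8- or 16-bit grayscale).
Integer volumes round-trip bit-exactly through both layouts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import imageio.v3 as iio
import tifffile

__all__ = [
    "VoxelGrid",
    "ScalarVolume",
    "LabelVolume",
    "VolumeLoadError",
    "VolumeFormatError",
    "AnisotropicGridError",
    "read_volume",
    "write_volume",
    "reslice",
    "restack",
]

Axis = Literal["xy", "yz", "zx"]
Layout = Literal["multipage-tiff", "slice-directory"]

DEFAULT_SPACING_NM = (10.0, 10.0, 10.0)


class VolumeLoadError(RuntimeError):
    """A stack could not be loaded (missing slice, shape mismatch...)."""


class VolumeFormatError(ValueError):
    """Input data is not representable in the requested format."""


class AnisotropicGridError(ValueError):
    """An operation requiring isotropic voxels got an anisotropic grid."""


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a voxel lattice: shape ``(nz, ny, nx)``, spacing in nm."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = DEFAULT_SPACING_NM

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or any(n < 1 for n in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive reals (nm), got {self.spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)

    @property
    def isotropic(self) -> bool:
        sz, sy, sx = self.spacing
        return sz == sy == sx

    @property
    def voxel_volume_nm3(self) -> float:
        sz, sy, sx = self.spacing
        return sz * sy * sx

    @property
    def voxel_volume_um3(self) -> float:
        return self.voxel_volume_nm3 * 1e-9

    def face_area_nm2(self) -> float:
        """Area of one voxel face, nm².

        For an isotropic grid all three faces are equal; for an
        anisotropic grid the mean of the three face areas is returned.
        """
        sz, sy, sx = self.spacing
        return (sy * sx + sz * sx + sz * sy) / 3.0


@dataclass
class ScalarVolume:
    """3D scalar field on a voxel grid.

    ``vrange`` declares the admissible value range, e.g. ``(0.0, 1.0)``
    for probabilities or ``(0, 255)`` for confidence-coded / grayscale
    byte volumes.
    """

    grid: VoxelGrid
    values: np.ndarray
    vrange: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        lo, hi = self.vrange
        vmin, vmax = self.values.min(), self.values.max()
        if vmin < lo or vmax > hi:
            raise ValueError(
                f"values [{vmin}, {vmax}] outside declared range [{lo}, {hi}]"
            )

    @property
    def is_byte(self) -> bool:
        return self.vrange == (0, 255) and np.issubdtype(self.values.dtype, np.integer)


@dataclass
class LabelVolume:
    """3D non-negative integer field; 0 is background, k>0 an instance id."""

    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.shape != self.grid.shape:
            raise ValueError(
                f"labels shape {self.labels.shape} != grid shape {self.grid.shape}"
            )
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def ids(self) -> np.ndarray:
        """Sorted array of positive label ids present in the volume."""
        u = np.unique(self.labels)
        return u[u > 0]

    def binary(self) -> np.ndarray:
        return self.labels > 0


_SLICE_EXTS = {".png", ".tif", ".tiff"}


def _find_slice_files(path: Path) -> list[Path]:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _SLICE_EXTS)
    if not files:
        raise VolumeLoadError(f"no PNG/TIFF slices found in {path}")
    suffixes = {p.suffix.lower() for p in files}
    if ".png" in suffixes and suffixes & {".tif", ".tiff"}:
        raise VolumeLoadError(f"mixed slice dialects (PNG and TIFF) in {path}")
    # Verify zero-padded indices are contiguous when present in filenames.
    indices = []
    for p in files:
        m = re.search(r"(\d+)", p.stem)
        if m is None:
            indices = None
            break
        indices.append(int(m.group(1)))
    if indices is not None:
        expected = range(min(indices), min(indices) + len(indices))
        missing = sorted(set(expected) - set(indices))
        if missing:
            raise VolumeLoadError(
                f"slice directory {path} is missing slice index {missing[0]}"
            )
    return files


def read_volume(
    path: str | Path,
    layout: Layout | None = None,
    spacing: Sequence[float] = DEFAULT_SPACING_NM,
    as_labels: bool = False,
) -> ScalarVolume | LabelVolume:
    """Load a 3D volume from a multipage TIFF or a slice directory.

    Slices are stacked in index order as the z axis.  With
    ``as_labels=True`` integer data is returned as a :class:`LabelVolume`
    (two-level 0/255 masks are collapsed to 0/1).
    """
    path = Path(path)
    if not path.exists():
        raise VolumeLoadError(f"{path} does not exist")
    if layout is None:
        layout = "slice-directory" if path.is_dir() else "multipage-tiff"

    if layout == "multipage-tiff":
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise VolumeFormatError(
                f"{path}: expected grayscale stack, got shape {arr.shape}"
            )
    else:
        files = _find_slice_files(path)
        planes = []
        shape0 = None
        for f in files:
            plane = np.asarray(iio.imread(f))
            if plane.ndim != 2:
                raise VolumeFormatError(f"{f}: non-grayscale slice (shape {plane.shape})")
            if shape0 is None:
                shape0 = plane.shape
            elif plane.shape != shape0:
                raise VolumeLoadError(
                    f"{f}: slice shape {plane.shape} != first slice shape {shape0}"
                )
            planes.append(plane)
        arr = np.stack(planes, axis=0)

    grid = VoxelGrid(arr.shape, tuple(spacing))
    if as_labels:
        if not np.issubdtype(arr.dtype, np.integer):
            raise VolumeFormatError(f"{path}: non-integer data cannot become labels")
        distinct = np.unique(arr)
        if len(distinct) <= 2 and distinct.max(initial=0) == 255:
            arr = (arr > 0).astype(np.int32)
        return LabelVolume(grid, arr.astype(np.int64, copy=False))
    if np.issubdtype(arr.dtype, np.integer):
        return ScalarVolume(grid, arr, vrange=(0, int(max(255, arr.max()))))
    return ScalarVolume(grid, arr, vrange=(float(arr.min()), float(arr.max())))


def _as_storage_array(vol: ScalarVolume | LabelVolume) -> np.ndarray:
    if isinstance(vol, LabelVolume):
        arr = vol.labels
        mx = int(arr.max(initial=0))
        if set(np.unique(arr)) <= {0, 1}:
            return (arr * 255).astype(np.uint8)  # two-level mask coding
        if mx <= 255:
            return arr.astype(np.uint8)
        if mx <= 65535:
            return arr.astype(np.uint16)
        raise VolumeFormatError(f"label id {mx} exceeds 16-bit storage")
    arr = vol.values
    if np.issubdtype(arr.dtype, np.integer):
        if arr.min() < 0 or arr.max() > 65535:
            raise VolumeFormatError(
                f"integer values [{arr.min()}, {arr.max()}] not storable as 8/16-bit"
            )
        return arr.astype(np.uint8 if arr.max() <= 255 else np.uint16)
    raise VolumeFormatError(
        "floating-point volumes are not written to 8/16-bit image stacks; "
        "convert explicitly (e.g. round(255*p)) to avoid silent clipping"
    )


def write_volume(
    vol: ScalarVolume | LabelVolume,
    path: str | Path,
    layout: Layout = "multipage-tiff",
) -> None:
    """Write a volume; integer data round-trips bit-exactly with read_volume."""
    path = Path(path)
    arr = _as_storage_array(vol)
    if layout == "multipage-tiff":
        path.parent.mkdir(parents=True, exist_ok=True)
        # explicit grayscale pages: tifffile would otherwise store short
        # stacks (z <= 4) as RGB separate-component planes
        tifffile.imwrite(path, arr, photometric="minisblack")
    elif layout == "slice-directory":
        path.mkdir(parents=True, exist_ok=True)
        width = max(3, len(str(arr.shape[0] - 1)))
        for z in range(arr.shape[0]):
            iio.imwrite(path / f"{z:0{width}d}.png", arr[z])
    else:
        raise ValueError(f"unknown layout {layout!r}")


def _require_isotropic(grid: VoxelGrid, axis: Axis) -> None:
    if axis in ("yz", "zx") and not grid.isotropic:
        raise AnisotropicGridError(
            f"reslicing along {axis} requires an isotropic grid; "
            f"got spacing {grid.spacing} nm — resample first"
        )


def reslice(vol: ScalarVolume | LabelVolume | np.ndarray, axis: Axis) -> list[np.ndarray]:
    """Cut a volume into an ordered sequence of 2D planes.

    ``xy`` yields the stored slices (indexed by z); ``yz`` yields planes
    of shape (nz, ny) indexed by x; ``zx`` yields planes of shape
    (nz, nx) indexed by y.  Virtual side-view planes require isotropic
    voxels so that a model trained on one plane family applies to the
    other two.
    """
    if isinstance(vol, (ScalarVolume, LabelVolume)):
        _require_isotropic(vol.grid, axis)
        arr = vol.values if isinstance(vol, ScalarVolume) else vol.labels
    else:
        arr = np.asarray(vol)
    if axis == "xy":
        return [arr[z] for z in range(arr.shape[0])]
    if axis == "yz":
        return [arr[:, :, x] for x in range(arr.shape[2])]
    if axis == "zx":
        return [arr[:, y, :] for y in range(arr.shape[1])]
    raise ValueError(f"unknown axis {axis!r}")


def restack(planes: Iterable[np.ndarray], axis: Axis) -> np.ndarray:
    """Inverse of :func:`reslice`: rebuild the (z, y, x) array."""
    planes = list(planes)
    if axis == "xy":
        return np.stack(planes, axis=0)
    if axis == "yz":
        return np.stack(planes, axis=2)
    if axis == "zx":
        return np.stack(planes, axis=1)
    raise ValueError(f"unknown axis {axis!r}")
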