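"""Cristae class handling: gap channel, ratios, lamella separation, angles.

Cristae come in two classes — lamellar (flat sheets) and tubular
(tubes) — supplied as binary masks from the per-class prediction
channels (or the phantom generator); this module does not re-classify
geometry.  The "gap" channel marks non-crista voxels within 60 nm of a
crista and is used as a third training class to keep closely stacked
lamellae from bleeding into each other.

Orientation analysis: each separated lamella is a roughly planar voxel
set, so the third principal component of its voxel coordinates is the
plate normal.  The angle theta between that normal and the
mitochondrion's longitudinal axis is folded to [0, 90]°; theta = 0
means the crista plane is perpendicular to the mitochondrial
orientation, theta = 90 means parallel.  The inverse of the smallest
eigenvalue (1/λ3) is kept as a plot weight; per-mitochondrion summary
angles are unweighted means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .morphometry import DEFAULT_MIN_VOXELS, label_components, principal_axes
from .volumes import LabelVolume, VoxelGrid

__all__ = [
    "CristaeLabels",
    "OrientationRecord",
    "build_gap_mask",
    "tubular_ratio",
    "separate_lamellae",
    "lamella_orientation",
    "mean_crista_angle",
]


@dataclass
class CristaeLabels:
    """Per-class binary crista masks on one grid (classes are disjoint)."""

    lamellar: LabelVolume
    tubular: LabelVolume
    gap: LabelVolume | None = None

    def __post_init__(self) -> None:
        if self.lamellar.grid != self.tubular.grid:
            raise ValueError("lamellar and tubular masks must share one grid")
        if np.any(self.lamellar.binary() & self.tubular.binary()):
            raise ValueError("lamellar and tubular masks overlap")
        if self.gap is not None:
            if self.gap.grid != self.lamellar.grid:
                raise ValueError("gap mask on a different grid")
            if np.any(self.gap.binary() & self.cristae()):
                raise ValueError("gap mask overlaps cristae")

    @property
    def grid(self) -> VoxelGrid:
        return self.lamellar.grid

    def cristae(self) -> np.ndarray:
        """Union of both crista classes."""
        return self.lamellar.binary() | self.tubular.binary()


@dataclass(frozen=True)
class OrientationRecord:
    """Orientation of one lamella relative to its mitochondrion."""

    lamella_id: int
    normal: np.ndarray  # unit PC3, (z, y, x)
    theta_deg: float  # in [0, 90]
    weight: float  # 1 / λ3


def build_gap_mask(
    cristae_mask, grid: VoxelGrid, radius_nm: float = 60.0
) -> LabelVolume:
    """Non-crista voxels within ``radius_nm`` of the nearest crista voxel.

    Distances are Euclidean in physical units (the grid spacing is the
    EDT sampling), so the default 60 nm is 6 voxels on the 10 nm
    analysis grid.  The gap never intersects the cristae themselves.
    """
    mask = (
        cristae_mask.binary()
        if isinstance(cristae_mask, LabelVolume)
        else np.asarray(cristae_mask).astype(bool)
    )
    if not mask.any() or radius_nm <= 0:
        return LabelVolume(grid, np.zeros(mask.shape, dtype=np.int64))
    dist = ndimage.distance_transform_edt(~mask, sampling=grid.spacing)
    gap = (dist <= radius_nm) & ~mask
    return LabelVolume(grid, gap.astype(np.int64))


def tubular_ratio(
    tubular_value: float,
    lamellar_value: float,
    basis: Literal["volume", "surface"] = "volume",
) -> float | None:
    """Tubular fraction: tubular / (tubular + lamellar) on the given basis.

    Returns None (missing) when both values are zero — a mitochondrion
    without cristae has no defined ratio and is excluded downstream.
    """
    if tubular_value < 0 or lamellar_value < 0:
        raise ValueError("class values must be non-negative")
    total = tubular_value + lamellar_value
    if total == 0:
        return None
    return tubular_value / total


def separate_lamellae(
    lamellar,
    grid: VoxelGrid | None = None,
    erosion_iters: int = 1,
    min_voxels: int = DEFAULT_MIN_VOXELS,
) -> LabelVolume:
    """Split touching lamellar sheets into individual lamellae.

    The lamellar mask is eroded (6-connected element, ``erosion_iters``
    times) so sheets in contact separate, then 26-connected components
    are labeled; components below ``min_voxels`` are dropped (reusing
    the misannotation floor).  Plates thinner than ``2*erosion_iters+1``
    voxels vanish under erosion; such losses are reported with a warning
    rather than silently discarded.
    """
    if isinstance(lamellar, LabelVolume):
        grid = lamellar.grid
        mask = lamellar.binary()
    else:
        mask = np.asarray(lamellar).astype(bool)
        if grid is None:
            grid = VoxelGrid(mask.shape)
    if erosion_iters > 0:
        eroded = ndimage.binary_erosion(
            mask,
            structure=ndimage.generate_binary_structure(3, 1),
            iterations=erosion_iters,
            border_value=0,
        )
    else:
        eroded = mask
    labeled = label_components(eroded, connectivity=26, grid=grid)
    sizes = {
        int(i): int((labeled.labels == i).sum()) for i in labeled.ids
    }
    keep = np.isin(labeled.labels, [i for i, s in sizes.items() if s >= min_voxels])
    out = np.where(keep, labeled.labels, 0)
    if mask.any() and not out.any():
        warnings.warn(
            "all lamellae vanished under erosion/size filtering "
            f"(erosion_iters={erosion_iters}, min_voxels={min_voxels})",
            stacklevel=2,
        )
    return LabelVolume(grid, np.asarray(out, dtype=np.int64))


def lamella_orientation(
    lamella_coords: np.ndarray,
    mito_axis: np.ndarray,
    lamella_id: int = 0,
    degeneracy_tol: float = 1e-9,
) -> OrientationRecord | None:
    """Angle between a lamella's plate normal (PC3) and the mito long axis.

    ``theta = arccos(|normal . axis|)`` in degrees, folded to [0, 90]
    (eigenvector signs are arbitrary).  Lamellae without a well-defined
    normal (λ2 ≈ λ3) are skipped with a warning and None is returned.
    """
    axes, evals = principal_axes(np.asarray(lamella_coords, dtype=np.float64))
    # the normal is ambiguous only when λ2 ≈ λ3 (any vector in their plane
    # fits); a perfectly flat plate (λ3 = 0, λ2 > 0) has an exact normal
    if (evals[1] - evals[2]) <= degeneracy_tol * max(evals[1], 1.0):
        warnings.warn(
            f"lamella {lamella_id}: degenerate covariance (λ2≈λ3), orientation skipped",
            stacklevel=2,
        )
        return None
    normal = axes[2]
    u = np.asarray(mito_axis, dtype=np.float64)
    u = u / np.linalg.norm(u)
    cos = np.clip(abs(float(normal @ u)), 0.0, 1.0)
    theta = float(np.degrees(np.arccos(cos)))
    weight = 1.0 / float(evals[2]) if evals[2] > 0 else np.inf
    return OrientationRecord(
        lamella_id=lamella_id,
        normal=normal,
        theta_deg=theta,
        weight=weight,
    )


def mean_crista_angle(records: Sequence[OrientationRecord]) -> float | None:
    """Unweighted mean lamella angle for one mitochondrion (None if empty)."""
    records = [r for r in records if r is not None]
    if not records:
        return None
    return float(np.mean([r.theta_deg for r in records]))
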