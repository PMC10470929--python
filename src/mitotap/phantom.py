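"""Synthetic ground-truth phantoms for validating the quantification stack.

A phantom is a voxelized scene of ellipsoidal "mitochondria" containing
planted crista structures — lamellar plates (with controllable normal
direction, thickness, lateral extent and optional perforation), tubular
cylinders, and full septa — on a physical voxel grid.  Structures are
planted either contacting the mitochondrial boundary (so a crista
junction exists there by construction) or kept at a safe margin from it
(so no junction can be detected).  The generator emits the label
volumes the analysis modules consume plus a truth ledger (planted
junction count, plate normals and angles against the mitochondrial long
axis, per-class voxel masks, analytic volumes/surfaces) so every
detector can be scored against exactly known answers.

Renderers produce (a) a grayscale byte volume with the dark-membrane
convention of stained EM — crista and boundary-membrane voxels near a
low value, lumen near a high value, optional Gaussian noise — which
feeds the junction line-confirmation test, and (b) per-axis noisy
probability fields with a fixed per-voxel fidelity, together with mock
plane predictors that replay them, which exercise three-axes fusion
without a trained network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .cristae import CristaeLabels
from .tap import Predictor2D
from .volumes import Axis, LabelVolume, ScalarVolume, VoxelGrid, reslice

__all__ = [
    "PhantomSpecError",
    "Ellipsoid",
    "Plate",
    "Tube",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "render_grayscale",
    "render_probability",
    "FieldPredictor",
    "make_cj_phantom",
    "make_septum_phantom",
    "make_angle_phantom",
    "make_segregation_phantom",
    "demo_spec",
]

DEFAULT_CONTACT_MARGIN_NM = 70.0  # detached structures stay this far from the boundary


class PhantomSpecError(ValueError):
    """A planted structure is inconsistent with its mitochondrion."""


@dataclass(frozen=True)
class Ellipsoid:
    """Mitochondrion body: centre and semi-axes in nm, optional rotation.

    ``rotation`` maps local axes to world (z, y, x) coordinates; the
    local axis with the largest semi-axis is the longitudinal direction.
    """

    center_nm: tuple[float, float, float]
    semi_axes_nm: tuple[float, float, float]
    rotation: np.ndarray | None = None

    def _R(self) -> np.ndarray:
        return np.eye(3) if self.rotation is None else np.asarray(self.rotation)

    def long_axis(self) -> np.ndarray:
        """Unit world-space direction of the largest semi-axis."""
        local = np.zeros(3)
        local[int(np.argmax(self.semi_axes_nm))] = 1.0
        v = self._R() @ local
        return v / np.linalg.norm(v)

    def contains(self, points_nm: np.ndarray) -> np.ndarray:
        d = points_nm - np.asarray(self.center_nm)
        local = d @ self._R()  # R^T applied to rows
        q = local / np.asarray(self.semi_axes_nm)
        return (q * q).sum(axis=-1) <= 1.0

    def analytic_volume_um3(self) -> float:
        a, b, c = self.semi_axes_nm
        return 4.0 / 3.0 * np.pi * a * b * c * 1e-9

    def analytic_surface_um2(self) -> float:
        # Thomsen approximation, relative error < 1.1%
        p = 1.6075
        a, b, c = self.semi_axes_nm
        s = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
        return 4.0 * np.pi * s ** (1.0 / p) * 1e-6


@dataclass(frozen=True)
class Plate:
    """Lamellar crista: a slab through ``center_nm`` with unit ``normal``."""

    mito: int  # index into PhantomSpec.mitochondria
    center_nm: tuple[float, float, float]
    normal: tuple[float, float, float]  # (z, y, x), need not be unit
    thickness_nm: float = 30.0
    extent_nm: float | None = 200.0  # lateral half-extent; None = unbounded
    junction_contact: bool = False
    hole_radius_nm: float = 0.0  # central perforation


@dataclass(frozen=True)
class Tube:
    """Tubular crista: a cylinder around the segment start->end."""

    mito: int
    start_nm: tuple[float, float, float]
    end_nm: tuple[float, float, float]
    radius_nm: float = 30.0
    junction_contact: bool = False


@dataclass
class PhantomSpec:
    grid: VoxelGrid
    mitochondria: list[Ellipsoid]
    lamellae: list[Plate] = field(default_factory=list)
    tubules: list[Tube] = field(default_factory=list)
    septa: list[Plate] = field(default_factory=list)
    noise_sd: float = 10.0
    membrane_value: int = 40
    lumen_value: int = 200
    contact_margin_nm: float = DEFAULT_CONTACT_MARGIN_NM
    seed: int = 0


@dataclass
class PhantomTruth:
    """Generator ledger of planted structures, consistent with the volumes."""

    junction_count: int
    junction_classes: list[str]  # "tubular"/"lamellar" per contacting structure
    plate_normals: list[tuple[int, np.ndarray, float]]  # (mito id, normal, angle°)
    mito_long_axes: dict[int, np.ndarray]
    analytic: dict[int, dict[str, float]]  # per mito id: volume_um3, surface_um2
    septa_mitos: list[int]


def _voxel_centers_nm(grid: VoxelGrid) -> np.ndarray:
    nz, ny, nx = grid.shape
    sz, sy, sx = grid.spacing
    z, y, x = np.meshgrid(
        np.arange(nz) * sz, np.arange(ny) * sy, np.arange(nx) * sx, indexing="ij"
    )
    return np.stack([z, y, x], axis=-1)


def _plate_mask(
    plate: Plate, pts: np.ndarray, mito_mask: np.ndarray
) -> np.ndarray:
    n = np.asarray(plate.normal, dtype=np.float64)
    n = n / np.linalg.norm(n)
    d = pts - np.asarray(plate.center_nm)
    along = d @ n
    mask = np.abs(along) <= plate.thickness_nm / 2.0
    lateral2 = (d * d).sum(axis=-1) - along**2
    if plate.extent_nm is not None:
        mask &= lateral2 <= plate.extent_nm**2
    if plate.hole_radius_nm > 0:
        mask &= lateral2 > plate.hole_radius_nm**2
    return mask & mito_mask


def _tube_mask(tube: Tube, pts: np.ndarray, mito_mask: np.ndarray) -> np.ndarray:
    a = np.asarray(tube.start_nm, dtype=np.float64)
    b = np.asarray(tube.end_nm, dtype=np.float64)
    ab = b - a
    L2 = float(ab @ ab)
    d = pts - a
    t = np.clip((d @ ab) / L2, 0.0, 1.0) if L2 > 0 else np.zeros(pts.shape[:-1])
    closest = a + t[..., None] * ab
    dist2 = ((pts - closest) ** 2).sum(axis=-1)
    return (dist2 <= tube.radius_nm**2) & mito_mask


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[LabelVolume, CristaeLabels, PhantomTruth]:
    """Voxelize a phantom spec into mito labels, crista classes and truth."""
    grid = spec.grid
    pts = _voxel_centers_nm(grid)
    labels = np.zeros(grid.shape, dtype=np.int64)
    mito_masks: list[np.ndarray] = []
    for i, e in enumerate(spec.mitochondria):
        m = e.contains(pts)
        if not m.any():
            raise PhantomSpecError(f"mitochondrion {i} voxelizes to an empty set")
        if (labels[m] != 0).any():
            raise PhantomSpecError(f"mitochondrion {i} overlaps an earlier one")
        labels[m] = i + 1
        mito_masks.append(m)

    # distance of each mito voxel to its boundary (physical units)
    boundary_dist = ndimage.distance_transform_edt(labels > 0, sampling=grid.spacing)

    def _place(kind: str, idx: int, structure, base_mask: np.ndarray) -> np.ndarray:
        if structure.mito >= len(spec.mitochondria):
            raise PhantomSpecError(f"{kind} {idx} references missing mitochondrion")
        mask = base_mask & mito_masks[structure.mito]
        if not structure.junction_contact and kind != "septum":
            mask &= boundary_dist > spec.contact_margin_nm
        if not mask.any():
            raise PhantomSpecError(
                f"{kind} {idx} escapes mitochondrion {structure.mito} "
                "(no voxels remain inside)"
            )
        return mask

    lamellar = np.zeros(grid.shape, dtype=bool)
    tubular = np.zeros(grid.shape, dtype=bool)
    plate_normals: list[tuple[int, np.ndarray, float]] = []
    junction_classes: list[str] = []

    for idx, plate in enumerate(list(spec.lamellae) + list(spec.septa)):
        kind = "lamella" if idx < len(spec.lamellae) else "septum"
        base = _plate_mask(plate, pts, mito_masks[plate.mito])
        lamellar |= _place(kind, idx, plate, base)
        n = np.asarray(plate.normal, dtype=np.float64)
        n = n / np.linalg.norm(n)
        u = spec.mitochondria[plate.mito].long_axis()
        angle = float(np.degrees(np.arccos(np.clip(abs(n @ u), 0, 1))))
        plate_normals.append((plate.mito + 1, n, angle))
        if plate.junction_contact:
            junction_classes.append("lamellar")

    for idx, tube in enumerate(spec.tubules):
        base = _tube_mask(tube, pts, mito_masks[tube.mito])
        tubular |= _place("tubule", idx, tube, base)
        if tube.junction_contact:
            junction_classes.append("tubular")

    tubular &= ~lamellar  # classes are disjoint; plates take precedence

    mito = LabelVolume(grid, labels)
    cristae = CristaeLabels(
        lamellar=LabelVolume(grid, lamellar.astype(np.int64)),
        tubular=LabelVolume(grid, tubular.astype(np.int64)),
    )
    truth = PhantomTruth(
        junction_count=len(junction_classes),
        junction_classes=junction_classes,
        plate_normals=plate_normals,
        mito_long_axes={i + 1: e.long_axis() for i, e in enumerate(spec.mitochondria)},
        analytic={
            i + 1: {
                "volume_um3": e.analytic_volume_um3(),
                "surface_um2": e.analytic_surface_um2(),
            }
            for i, e in enumerate(spec.mitochondria)
        },
        septa_mitos=[p.mito + 1 for p in spec.septa],
    )
    return mito, cristae, truth


def render_grayscale(
    mito: LabelVolume,
    cristae: CristaeLabels | None = None,
    membrane_value: int = 40,
    lumen_value: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ScalarVolume:
    """Render a phantom as a grayscale byte volume (dark membranes).

    Crista voxels and the 1-voxel mitochondrial boundary shell take
    ``membrane_value``; everything else (matrix lumen and exterior)
    takes ``lumen_value``.  Gaussian noise of ``noise_sd`` gray levels is
    added and the result clipped to [0, 255].
    """
    if not 0 <= membrane_value <= 126 < lumen_value <= 255:
        raise ValueError(
            "need membrane_value <= 126 < lumen_value so membranous paths stay "
            f"below the junction confirmation bound; got {membrane_value}, {lumen_value}"
        )
    fg = mito.binary()
    shell = fg & ~ndimage.binary_erosion(
        fg, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    membrane = shell.copy()
    if cristae is not None:
        membrane |= cristae.cristae()
    img = np.where(membrane, float(membrane_value), float(lumen_value))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return ScalarVolume(mito.grid, img, vrange=(0, 255))


class FieldPredictor:
    """Mock 2D predictor replaying a precomputed 3D probability field.

    Calling it with the i-th plane of the field's volume along ``axis``
    returns the corresponding plane of the field, mimicking a model
    whose per-plane output happens to equal a known field.
    """

    def __init__(self, field_zyx: np.ndarray, axis: Axis):
        self.field = np.asarray(field_zyx, dtype=np.float64)
        self.axis: Axis = axis
        self._planes = reslice(self.field, axis)

    def __call__(self, plane: np.ndarray, index: int | None = None) -> np.ndarray:
        if index is None:
            raise ValueError("FieldPredictor needs the plane index")
        out = self._planes[index]
        if out.shape != plane.shape:
            raise ValueError("plane shape does not match the stored field")
        return out


def render_probability(
    mask,
    grid: VoxelGrid,
    fidelity: float = 0.8,
    seed: int = 0,
    axis: Axis = "xy",
) -> tuple[ScalarVolume, FieldPredictor]:
    """Noisy per-voxel probability field for one axis view, plus its mock predictor.

    Each voxel is classified correctly (probability on the right side of
    0.5) with probability ``fidelity``, independently per voxel; the
    field is 1.0/0.0 at correct/incorrect foreground calls.  Different
    seeds give independent views.
    """
    if not 0.5 < fidelity <= 1.0:
        raise ValueError(f"fidelity must be in (0.5, 1], got {fidelity}")
    m = mask.binary() if isinstance(mask, LabelVolume) else np.asarray(mask).astype(bool)
    rng = np.random.default_rng(seed)
    flip = rng.random(m.shape) > fidelity
    field = np.where(m ^ flip, 1.0, 0.0)
    return ScalarVolume(grid, field, vrange=(0.0, 1.0)), FieldPredictor(field, axis)


# ---------------------------------------------------------------------------
# Ready-made study phantoms
# ---------------------------------------------------------------------------


def _radial_directions(n: int) -> np.ndarray:
    """n well-separated unit directions (z, y, x)."""
    dirs = np.array(
        [
            [0.0, 0.0, 1.0],
            [0.0, 1.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.0, 0.0, -1.0],
            [0.0, -1.0, 0.0],
            [1.0, 1.0, 1.0],
            [-1.0, 1.0, -1.0],
            [-1.0, -1.0, 1.0],
        ]
    )
    if n > len(dirs):
        raise ValueError(f"at most {len(dirs)} planted directions supported")
    return dirs[:n] / np.linalg.norm(dirs[:n], axis=1, keepdims=True)


def make_cj_phantom(
    n_contact: int = 5, n_detached: int = 3, seed: int = 0
) -> tuple[LabelVolume, CristaeLabels, ScalarVolume, PhantomTruth]:
    """Spherical mitochondrion with radial tubular cristae.

    ``n_contact`` tubes reach the boundary through a membranous bridge
    (each plants exactly one junction); ``n_detached`` tubes stop well
    short of it (>= the contact margin), planting none.  Returns the
    mito mask, crista classes, rendered grayscale and the truth ledger.
    """
    grid = VoxelGrid((64, 64, 64), (10.0, 10.0, 10.0))
    c = (315.0, 315.0, 315.0)
    r = 250.0
    mito = Ellipsoid(c, (r, r, r))
    dirs = _radial_directions(n_contact + n_detached)
    tubes = []
    for i, u in enumerate(dirs):
        contact = i < n_contact
        start = tuple(np.asarray(c) + 60.0 * u)
        # contact tubes overshoot the surface (clipped to the mito mask);
        # detached ones stop 170 nm short of it
        reach = r + 30.0 if contact else r - 170.0
        end = tuple(np.asarray(c) + reach * u)
        tubes.append(Tube(0, start, end, radius_nm=30.0, junction_contact=contact))
    spec = PhantomSpec(grid, [mito], tubules=tubes, noise_sd=0.0, seed=seed)
    mito_vol, cristae, truth = generate_phantom(spec)
    gray = render_grayscale(mito_vol, cristae, noise_sd=0.0, seed=seed)
    return mito_vol, cristae, gray, truth


def make_septum_phantom(
    smaller_target: float = 0.4,
    perforated: bool = False,
    erosion: int = 4,
) -> tuple[LabelVolume, LabelVolume, float]:
    """Ellipsoid bisected by a full plate at a chosen volume split.

    The plate position is chosen on the eroded mitochondrion's x-profile
    so the smaller compartment holds ``smaller_target`` of the
    partitioned volume.  With ``perforated=True`` a 5-voxel-wide hole is
    punched through the plate centre, keeping the compartments connected.
    Returns (mito labels, lamellar labels, achieved target fraction).
    """
    grid = VoxelGrid((54, 54, 100), (10.0, 10.0, 10.0))
    c = (265.0, 265.0, 495.0)
    e = Ellipsoid(c, (220.0, 220.0, 440.0))
    pts = _voxel_centers_nm(grid)
    mask = e.contains(pts)
    eroded = ndimage.binary_erosion(
        mask,
        structure=ndimage.generate_binary_structure(3, 1),
        iterations=erosion,
        border_value=0,
    )
    profile = eroded.sum(axis=(0, 1)).astype(float)
    cum = np.cumsum(profile) / profile.sum()
    x_idx = int(np.searchsorted(cum, smaller_target))
    x_nm = x_idx * grid.spacing[2]
    plate = Plate(
        0,
        (c[0], c[1], x_nm),
        normal=(0.0, 0.0, 1.0),
        thickness_nm=30.0,
        extent_nm=None,
        junction_contact=True,
        hole_radius_nm=25.0 if perforated else 0.0,
    )
    spec = PhantomSpec(grid, [e], septa=[plate], noise_sd=0.0)
    mito_vol, cristae, _ = generate_phantom(spec)
    return mito_vol, cristae.lamellar, smaller_target


def make_angle_phantom(
    angles_deg: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0),
) -> tuple[LabelVolume, CristaeLabels, PhantomTruth]:
    """Elongated mitochondrion with one plate per requested angle.

    The mitochondrion's long axis is +x; each plate's normal is tilted
    ``angle`` degrees away from it (in the x-y plane), so the recovered
    plate-normal-to-long-axis angle should match the plant.  Plates are
    spaced along x so they never touch.
    """
    n = len(angles_deg)
    half_len = 300.0 * n + 200.0
    grid_x = int((2 * half_len + 200.0) / 10.0)
    grid = VoxelGrid((66, 66, grid_x), (10.0, 10.0, 10.0))
    c = (325.0, 325.0, half_len + 100.0)
    e = Ellipsoid(c, (300.0, 300.0, half_len))
    plates = []
    offsets = (np.arange(n) - (n - 1) / 2.0) * 600.0
    for angle, off in zip(angles_deg, offsets):
        a = np.radians(angle)
        # snap ~0 trig residue so axis-aligned plates are exactly aligned
        ny_, nx_ = (round(float(v), 12) for v in (np.sin(a), np.cos(a)))
        center = (c[0], c[1], c[2] + float(off))
        # 35 nm thickness keeps slab faces off the 10 nm lattice planes,
        # avoiding inclusion flips at exactly-on-boundary voxel centres
        plates.append(
            Plate(0, center, (0.0, ny_, nx_), thickness_nm=35.0, extent_nm=220.0)
        )
    spec = PhantomSpec(grid, [e], lamellae=plates, noise_sd=0.0)
    return generate_phantom(spec)


def make_segregation_phantom(
    seed: int = 0,
) -> tuple[LabelVolume, CristaeLabels, PhantomTruth]:
    """Mitochondrion whose crista classes occupy opposite ends.

    Tubular cristae fill part of the -x half and lamellar plates part of
    the +x half, with an empty band several subvolume diameters wide in
    between — a scene where every cristae-containing K-means subvolume
    should be dominated by a single class.
    """
    grid = VoxelGrid((50, 50, 160), (10.0, 10.0, 10.0))
    c = (245.0, 245.0, 795.0)
    e = Ellipsoid(c, (200.0, 200.0, 750.0))
    tubes = []
    for dy in (-80.0, 0.0, 80.0):
        tubes.append(
            Tube(
                0,
                (c[0], c[1] + dy, c[2] - 650.0),
                (c[0], c[1] + dy, c[2] - 250.0),
                radius_nm=40.0,
            )
        )
    plates = []
    for off in (300.0, 450.0, 600.0):
        plates.append(
            Plate(
                0,
                (c[0], c[1], c[2] + off),
                normal=(0.0, 0.0, 1.0),
                thickness_nm=30.0,
                extent_nm=150.0,
            )
        )
    spec = PhantomSpec(grid, [e], lamellae=plates, tubules=tubes, seed=seed)
    return generate_phantom(spec)


def demo_spec(seed: int = 0) -> PhantomSpec:
    """Small multi-mitochondrion scene exercising the whole pipeline.

    Four ellipsoids of different size/elongation, each with a mix of
    lamellar and tubular cristae, some boundary-contacting.  Serves the
    end-to-end examples and reproducibility checks.
    """
    grid = VoxelGrid((72, 112, 112), (10.0, 10.0, 10.0))
    mitos = [
        Ellipsoid((330.0, 270.0, 270.0), (230.0, 230.0, 230.0)),
        Ellipsoid((330.0, 270.0, 830.0), (200.0, 230.0, 260.0)),
        Ellipsoid((330.0, 830.0, 270.0), (180.0, 260.0, 220.0)),
        Ellipsoid((330.0, 830.0, 830.0), (230.0, 200.0, 250.0)),
    ]
    lamellae = [
        Plate(0, (330.0, 270.0, 270.0), (0.0, 0.0, 1.0), extent_nm=160.0),
        Plate(1, (330.0, 270.0, 770.0), (0.0, 1.0, 1.0), extent_nm=150.0),
        Plate(1, (330.0, 270.0, 890.0), (0.0, 0.0, 1.0), extent_nm=None,
              junction_contact=True),
        Plate(2, (330.0, 830.0, 270.0), (0.0, 1.0, 0.0), extent_nm=130.0),
        Plate(3, (330.0, 830.0, 830.0), (1.0, 0.0, 0.0), extent_nm=150.0),
    ]
    tubules = [
        # junction-contacting tubes overshoot the boundary (clipped to the mito)
        Tube(0, (330.0, 270.0, 180.0), (330.0, 270.0, 20.0), radius_nm=35.0,
             junction_contact=True),
        Tube(0, (250.0, 270.0, 270.0), (170.0, 270.0, 270.0), radius_nm=30.0),
        Tube(1, (330.0, 200.0, 830.0), (330.0, 20.0, 830.0), radius_nm=35.0,
             junction_contact=True),
        Tube(2, (330.0, 760.0, 270.0), (330.0, 550.0, 270.0), radius_nm=35.0,
             junction_contact=True),
        Tube(3, (330.0, 830.0, 740.0), (330.0, 830.0, 620.0), radius_nm=30.0),
        Tube(3, (300.0, 900.0, 830.0), (240.0, 980.0, 830.0), radius_nm=30.0),
    ]
    return PhantomSpec(
        grid, mitos, lamellae=lamellae, tubules=tubules, noise_sd=10.0, seed=seed
    )
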