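"""Three-axes prediction (TAP): orthogonal-plane fusion and confidence coding.

A 2D segmentation model trained on xy-plane images of an isotropic
volume can be applied unchanged to the virtual yz and zx planes, giving
three per-voxel probabilities.  Fusing them — by averaging (default) or
by majority vote of thresholded masks — suppresses the slice-to-slice
inconsistency that single-view 2D inference produces at object
boundaries.

The averaged probability is linearly expanded to a byte code in
[0, 255]; bytes above 127 are foreground, bytes in [1, 127] mark
low-confidence voxels that a human annotator should review, and 0 is
confident background.  (The boundary byte 127 is treated as low
confidence: an ambiguous voxel is flagged for review rather than
accepted.)

Also here: training-support utilities around a pluggable 2D predictor —
the BCE-dice loss, the border-exclusion mask used during evaluation, a
low-confidence-based ranking of slices for correction, and bookkeeping
for iterative human-in-the-loop (HITL) training sets.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass, field
from typing import Callable, Literal, Protocol, Sequence

import numpy as np

from .volumes import Axis, LabelVolume, ScalarVolume, VoxelGrid, reslice, restack

__all__ = [
    "Predictor2D",
    "ConfidenceVolume",
    "TrainingExample",
    "TrainingSet",
    "ConstantPredictor",
    "ThresholdPredictor",
    "predict_plane_stack",
    "fuse_mean",
    "fuse_majority",
    "classify_confidence",
    "edge_exclusion_mask",
    "bce_dice_loss",
    "rank_slices_for_correction",
    "merge_training_set",
    "BACKGROUND",
    "LOW_CONFIDENCE",
    "FOREGROUND",
]

BACKGROUND, LOW_CONFIDENCE, FOREGROUND = 0, 1, 2

#: byte value strictly above which a voxel counts as foreground
FOREGROUND_THRESHOLD = 127


class Predictor2D(Protocol):
    """Contract for a pluggable 2D model: grayscale plane -> probability plane.

    Output must have the same shape as the input and values in [0, 1].
    A predictor may additionally accept an ``index`` keyword giving the
    plane's position along the sliced axis (used by mock predictors that
    replay a precomputed field).
    """

    def __call__(self, plane: np.ndarray, **kwargs) -> np.ndarray: ...


class ConstantPredictor:
    """Mock predictor returning a uniform probability."""

    def __init__(self, p: float = 0.5):
        self.p = float(p)

    def __call__(self, plane: np.ndarray) -> np.ndarray:
        return np.full(plane.shape, self.p, dtype=np.float64)


class ThresholdPredictor:
    """Mock predictor: p=1 where grayscale < threshold (dark object), else 0."""

    def __init__(self, threshold: float = 128.0):
        self.threshold = float(threshold)

    def __call__(self, plane: np.ndarray) -> np.ndarray:
        return (np.asarray(plane) < self.threshold).astype(np.float64)


@dataclass
class ConfidenceVolume:
    """Byte-coded fused prediction plus its 3-way classification."""

    grid: VoxelGrid
    codes: np.ndarray  # uint8, 0..255

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.shape != self.grid.shape:
            raise ValueError("codes shape does not match grid")
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ValueError("codes must be byte-valued")
        if self.codes.min() < 0 or self.codes.max() > 255:
            raise ValueError("codes must lie in [0, 255]")
        self.codes = self.codes.astype(np.uint8)

    @property
    def classes(self) -> np.ndarray:
        """Total partition into {0 background, 1 low confidence, 2 foreground}."""
        out = np.full(self.codes.shape, LOW_CONFIDENCE, dtype=np.uint8)
        out[self.codes == 0] = BACKGROUND
        out[self.codes > FOREGROUND_THRESHOLD] = FOREGROUND
        return out

    @property
    def foreground(self) -> np.ndarray:
        return self.codes > FOREGROUND_THRESHOLD

    @property
    def low_confidence(self) -> np.ndarray:
        return (self.codes >= 1) & (self.codes <= FOREGROUND_THRESHOLD)


def _supports_index(predictor: Callable) -> bool:
    try:
        sig = inspect.signature(predictor)
    except (TypeError, ValueError):
        return False
    params = sig.parameters.values()
    return any(
        p.name == "index" or p.kind is inspect.Parameter.VAR_KEYWORD for p in params
    )


def predict_plane_stack(
    vol: ScalarVolume, predictor: Predictor2D, axis: Axis
) -> ScalarVolume:
    """Apply a 2D predictor plane-by-plane along ``axis`` and restack.

    The output voxel (z, y, x) equals the predictor's value on the plane
    containing that voxel, returned in the original (z, y, x) orientation
    as a probability volume in [0, 1].
    """
    planes = reslice(vol, axis)
    pass_index = _supports_index(predictor)
    out_planes = []
    for i, plane in enumerate(planes):
        pred = predictor(plane, index=i) if pass_index else predictor(plane)
        pred = np.asarray(pred, dtype=np.float64)
        if pred.shape != plane.shape:
            raise ValueError(
                f"predictor contract violation: output shape {pred.shape} != "
                f"input plane shape {plane.shape} (plane {i}, axis {axis})"
            )
        if pred.min() < 0 or pred.max() > 1:
            raise ValueError("predictor contract violation: output outside [0, 1]")
        out_planes.append(pred)
    return ScalarVolume(vol.grid, restack(out_planes, axis), vrange=(0.0, 1.0))


def _check_same_grid(*vols) -> VoxelGrid:
    g0 = vols[0].grid
    for v in vols[1:]:
        if v.grid != g0:
            raise ValueError(f"grid mismatch: {v.grid} != {g0}")
    return g0


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # deterministic round-half-away-from-zero for non-negative input
    return np.floor(x + 0.5)


def fuse_mean(
    p_xy: ScalarVolume, p_yz: ScalarVolume, p_zx: ScalarVolume
) -> ScalarVolume:
    """Average the three per-axis probabilities and expand to bytes.

    Per voxel: ``byte = round(255 * mean(p_xy, p_yz, p_zx))``, rounding
    half away from zero.  Symmetric in argument order.
    """
    grid = _check_same_grid(p_xy, p_yz, p_zx)
    mean = (
        np.asarray(p_xy.values, dtype=np.float64)
        + np.asarray(p_yz.values, dtype=np.float64)
        + np.asarray(p_zx.values, dtype=np.float64)
    ) / 3.0
    codes = _round_half_away(255.0 * mean).astype(np.uint8)
    return ScalarVolume(grid, codes, vrange=(0, 255))


def fuse_majority(
    b_xy: LabelVolume, b_yz: LabelVolume, b_zx: LabelVolume
) -> LabelVolume:
    """Majority vote of three binary per-axis predictions (>=2 of 3)."""
    grid = _check_same_grid(b_xy, b_yz, b_zx)
    arrs = []
    for v in (b_xy, b_yz, b_zx):
        a = v.labels
        if not set(np.unique(a)) <= {0, 1}:
            raise ValueError("fuse_majority requires binary (0/1) inputs")
        arrs.append(a)
    votes = arrs[0] + arrs[1] + arrs[2]
    return LabelVolume(grid, (votes >= 2).astype(np.int64))


def classify_confidence(cv: ScalarVolume) -> ConfidenceVolume:
    """Partition a byte-coded fusion into background / low confidence / foreground.

    0 is confident background; bytes exceeding 127 are foreground
    (annotated as mitochondria); everything in [1, 127] is low
    confidence, flagged for human review.
    """
    if not cv.is_byte:
        raise ValueError("classify_confidence requires a byte volume (0-255 integers)")
    return ConfidenceVolume(cv.grid, cv.values)


def edge_exclusion_mask(
    plane_shape: tuple[int, int], fraction: float = 0.10
) -> np.ndarray:
    """Binary mask of the evaluated plane region after border trimming.

    Predictions near image borders lack surrounding context and are
    systematically less accurate, so a band of ``floor(fraction * extent)``
    pixels on each of the four sides is excluded from evaluation.
    """
    if not 0 <= fraction < 0.5:
        raise ValueError(f"fraction must be in [0, 0.5), got {fraction}")
    ny, nx = plane_shape
    ty, tx = int(np.floor(fraction * ny)), int(np.floor(fraction * nx))
    mask = np.zeros((ny, nx), dtype=bool)
    mask[ty : ny - ty, tx : nx - tx] = True
    return mask


def bce_dice_loss(
    pred: np.ndarray, target: np.ndarray, epsilon: float = 1e-7
) -> float:
    """Binary cross-entropy + Dice loss used to train the 2D models.

    ``BCE + (1 - Dice)`` with ``Dice = (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps)``
    and predictions clipped to ``(eps, 1-eps)``.  Non-negative; tends to 0
    as the prediction approaches a binary target.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape}, target {target.shape}")
    p = np.clip(pred, epsilon, 1.0 - epsilon)
    bce = float(np.mean(-target * np.log(p) - (1.0 - target) * np.log(1.0 - p)))
    dice = (2.0 * float(np.sum(p * target)) + epsilon) / (
        float(np.sum(p)) + float(np.sum(target)) + epsilon
    )
    return bce + (1.0 - dice)


def rank_slices_for_correction(
    conf: ConfidenceVolume, axis: Axis = "xy"
) -> list[int]:
    """Order slices by descending fraction of low-confidence voxels.

    A proxy for the human choice of sections with suboptimal prediction
    accuracy during HITL iterations: the slices where the model is least
    certain are offered for correction first.  Ties break by ascending
    slice index (stable).
    """
    planes = reslice(conf.low_confidence, axis)
    fracs = [float(p.mean()) for p in planes]
    return sorted(range(len(fracs)), key=lambda i: (-fracs[i], i))


@dataclass(frozen=True)
class TrainingExample:
    """One annotated plane with its provenance."""

    index: int
    axis: Axis
    image: np.ndarray
    labels: np.ndarray
    iteration: int

    def __post_init__(self) -> None:
        if self.image.shape != self.labels.shape:
            raise ValueError(
                f"image shape {self.image.shape} != labels shape {self.labels.shape}"
            )


@dataclass
class TrainingSet:
    """HITL training set keyed by (slice index, axis); newest labels win."""

    examples: list[TrainingExample] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(e.index, e.axis) for e in self.examples]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (slice index, axis) in training set")

    def keys(self) -> set[tuple[int, Axis]]:
        return {(e.index, e.axis) for e in self.examples}

    def __len__(self) -> int:
        return len(self.examples)


def merge_training_set(
    ts: TrainingSet,
    corrected: Sequence[tuple[int, Axis, np.ndarray, np.ndarray]],
    iteration: int,
) -> TrainingSet:
    """Fold corrected planes into a training set for the next HITL cycle.

    Corrections on already-present slices replace the old labels; new
    slices are appended.  Per-iteration provenance is kept on each entry.
    """
    by_key = {(e.index, e.axis): e for e in ts.examples}
    order = [(e.index, e.axis) for e in ts.examples]
    for index, axis, image, labels in corrected:
        key = (index, axis)
        ex = TrainingExample(index, axis, np.asarray(image), np.asarray(labels), iteration)
        if key not in by_key:
            order.append(key)
        by_key[key] = ex
    return TrainingSet([by_key[k] for k in order])
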