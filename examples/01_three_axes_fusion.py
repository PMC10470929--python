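"""Three-axes prediction fusion on a noisy phantom.

Builds a spherical phantom, simulates three independent per-axis
predictions at 80% per-voxel fidelity, fuses them by per-voxel majority
vote, and compares the error rate against any single view.  The fused
rate should sit near the closed-form 3p^2(1-p) + p^3 = 10.4% for
p = 0.2 per-view error — the consistency gain that motivates predicting
on all three orthogonal plane families of an isotropic volume.
"""

import numpy as np

from mitotap.metrics import confusion_counts, precision_recall_f1
from mitotap.phantom import make_cj_phantom, render_probability
from mitotap.tap import classify_confidence, fuse_mean, fuse_majority
from mitotap.volumes import LabelVolume

mito, cristae, gray, truth = make_cj_phantom()
grid = mito.grid
target = mito.binary()

views, bins = [], []
for i, axis in enumerate(("xy", "yz", "zx")):
    vol, predictor = render_probability(mito, grid, fidelity=0.8, seed=i, axis=axis)
    views.append(vol)
    bins.append(LabelVolume(grid, (vol.values > 0.5).astype(np.int64)))
    err = ((vol.values > 0.5) != target).mean()
    print(f"view {axis}: single-view voxel error {100 * err:.2f}%")

fused = fuse_majority(*bins)
err = (fused.binary() != target).mean()
print(f"majority-fused voxel error {100 * err:.2f}%  (closed form: 10.40%)")

_, _, f1 = precision_recall_f1(confusion_counts(fused.binary(), target))
print(f"fused segmentation F1 {f1:.3f}")

conf = classify_confidence(fuse_mean(*views))
low = conf.low_confidence.mean()
print(
    f"{100 * low:.2f}% of voxels carry low-confidence byte codes [1, 127] — "
    "these are the voxels the three views disagree on, highlighted for review"
)
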