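# mitotap

Voxel-level quantification of 3D mitochondrial ultrastructure from
isotropic volume electron microscopy, built around two ideas:

1. **Three-axes prediction (TAP).** A 2D segmentation model trained on
   xy-plane images of an isotropic volume applies unchanged to the
   virtual yz and zx planes. Fusing the three per-voxel predictions —
   probability averaging with byte-coded confidence, or an explicit
   majority vote — suppresses the slice-to-slice jitter of single-view
   2D inference. For independent per-view error *p*, the majority-vote
   voxel error is 3*p*²(1−*p*) + *p*³ (10.4% at *p* = 0.2).
2. **Geometric quantification of cristae.** From mitochondrial and
   per-class crista masks (lamellar sheets vs tubular tubes) the library
   measures volume, boundary-voxel surface area, principal-axis lengths,
   aspect ratio and the mitochondrial complexity index
   MCI = SA³ / (16 π² V²); detects **crista junctions** by eroding the
   mitochondrion 3/4/5 voxels and confirming each candidate through a
   dark-membrane line test to the nearest surface voxel; discovers
   **septa** (lamellae that fully partition the matrix, smaller
   compartment > 15%); measures lamellar **orientation** (plate normal =
   PC3 of the lamella vs the mitochondrial long axis = PC1); and runs
   the unsupervised analyses — a nine-feature table, standardized PCA
   fitted on the control group, Ward clustering, and K-means subvolume
   composition (≈5×10⁻³ μm³ subvolumes).

Everything is validated against **synthetic phantoms**: voxelized
ellipsoidal mitochondria with planted plates, tubes, junction bridges
and septa whose ground truth (junction counts, normals, compartment
fractions, analytic volumes) is known exactly.

Intended users: microscopists and image analysts quantifying inner
mitochondrial membrane organisation from FIB-SEM or comparable
near-isotropic 3D EM, and method developers who need an exactly
controllable test bed for segmentation-fusion and ultrastructure
detectors.

## Worked example

`examples/03_crista_junctions.py` plants 5 boundary-contacting and
3 detached tubular cristae in a spherical mitochondrion and runs the
junction detector:

```
planted junction-contacting cristae: 5
detected crista junctions:           5
  CJ 1: 28 voxels, first shell 3 (30 nm), class tubular, near (29,10,31)
  CJ 2: 28 voxels, first shell 3 (30 nm), class tubular, near (29,31,10)
  CJ 3: 28 voxels, first shell 3 (30 nm), class tubular, near (29,31,53)
  CJ 4: 28 voxels, first shell 3 (30 nm), class tubular, near (29,53,31)
  CJ 5: 24 voxels, first shell 3 (30 nm), class tubular, near (53,29,31)
crista surface 0.2079 um^2 -> CJ density 24.1 per um^2 (count normalized by crista surface area)
```

All five planted junctions are recovered (each a cluster of confirmed
voxels first seen on the 30 nm erosion shell) and none of the detached
cristae produce a false positive; the CJ density is the count divided
by the crista surface area. The other examples cover fusion
(`01`, printing the ~10.4% fused error against ~20% single-view),
morphometry closed forms (`02`), septa and orientation angles (`04`),
and the full pipeline with PCA (`05`).

The library also installs a thin `mitotap` CLI (`fuse`, `classify`,
`score`, `smoothness`, `quantify`, `detect-cj`, `septa`, `run`) over
TIFF stacks or slice directories; `--spacing sz,sy,sx` is in nm.

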