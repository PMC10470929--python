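"""Subvolume partitioning, the nine-feature table, and unsupervised analyses.

Each mitochondrion can be split into roughly 5×10⁻³ μm³ subvolumes by
K-means on its voxel coordinates; per-subvolume crista-class
percentages quantify how well tubular and lamellar cristae segregate in
intramitochondrial space.

The per-mitochondrion feature table carries nine morphology features —
mitochondrial volume, mitochondrial area, aspect ratio, MCI, crista
volume, crista area, tubular volume ratio, tubular area ratio, and CJ
density — plus a group label.  Features are standardized (zero mean,
unit variance) and a PCA is fitted on the control group only, so
treatment mitochondria are projected into control feature space;
hierarchical clustering uses Ward's method with Euclidean distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .cristae import CristaeLabels
from .volumes import VoxelGrid

logger = logging.getLogger(__name__)

__all__ = [
    "SubvolumePartition",
    "FEATURE_COLUMNS",
    "kmeans_subvolumes",
    "subvolume_composition",
    "build_feature_table",
    "standardize_and_pca",
    "ward_clustering",
]

DEFAULT_TARGET_SUBVOLUME_UM3 = 5e-3

#: fixed nine-feature column order of the analysis table
FEATURE_COLUMNS = [
    "mito_volume_um3",
    "mito_surface_um2",
    "aspect_ratio",
    "mci",
    "crista_volume_um3",
    "crista_surface_um2",
    "tubular_volume_ratio",
    "tubular_surface_ratio",
    "cj_density_per_um2",
]


@dataclass
class SubvolumePartition:
    """K-means partition of one mitochondrion's voxels into subvolumes."""

    mito_id: int
    k: int
    coords: np.ndarray  # (N, 3) voxel indices (z, y, x)
    assignment: np.ndarray  # (N,) cluster id in [0, k)
    grid: VoxelGrid

    def cluster_volumes_um3(self) -> np.ndarray:
        counts = np.bincount(self.assignment, minlength=self.k)
        return counts * self.grid.voxel_volume_um3


def kmeans_subvolumes(
    mito_coords: np.ndarray,
    grid: VoxelGrid,
    target_volume_um3: float = DEFAULT_TARGET_SUBVOLUME_UM3,
    seed: int = 0,
    mito_id: int = 1,
) -> SubvolumePartition:
    """Partition a mitochondrion into ~``target_volume_um3`` subvolumes.

    ``K = max(1, round(V / target))`` clusters of the voxel physical
    coordinates, k-means++ seeded by ``seed`` (deterministic given seed).
    """
    coords = np.asarray(mito_coords)
    if coords.shape[0] == 0:
        raise ValueError("empty mitochondrion")
    volume = coords.shape[0] * grid.voxel_volume_um3
    k = max(1, int(round(volume / target_volume_um3)))
    k = min(k, coords.shape[0])
    phys = coords.astype(np.float64) * np.asarray(grid.spacing)
    if k == 1:
        assignment = np.zeros(coords.shape[0], dtype=np.int64)
    else:
        km = KMeans(n_clusters=k, random_state=seed, n_init=1)
        assignment = km.fit_predict(phys).astype(np.int64)
    return SubvolumePartition(mito_id, k, coords, assignment, grid)


def subvolume_composition(
    partition: SubvolumePartition, cristae: CristaeLabels
) -> pd.DataFrame:
    """Per-subvolume tubular/lamellar percentages of subvolume voxels.

    Returns one row per cluster with the cluster volume and the
    percentage of its voxels occupied by each crista class.
    """
    tub = cristae.tubular.binary()
    lam = cristae.lamellar.binary()
    z, y, x = partition.coords.T
    in_tub = tub[z, y, x]
    in_lam = lam[z, y, x]
    rows = []
    for c in range(partition.k):
        sel = partition.assignment == c
        n = int(sel.sum())
        rows.append(
            {
                "mito_id": partition.mito_id,
                "cluster": c,
                "volume_um3": n * partition.grid.voxel_volume_um3,
                "pct_tubular": 100.0 * int(in_tub[sel].sum()) / n,
                "pct_lamellar": 100.0 * int(in_lam[sel].sum()) / n,
            }
        )
    return pd.DataFrame(rows)


def build_feature_table(
    morph: pd.DataFrame,
    cristae_stats: pd.DataFrame,
    cj_stats: pd.DataFrame,
    groups: Mapping[int, str] | str = "control",
    size_outlier_mads: float | None = None,
) -> pd.DataFrame:
    """Assemble the nine-feature analysis table, one row per mitochondrion.

    Inputs are keyed by mitochondrion ``id``: ``morph`` from
    ``morphometry.records_to_frame``, ``cristae_stats`` with per-class
    volumes/surfaces and ratios, ``cj_stats`` with CJ densities.
    Mitochondria without cristae (undefined tubular ratio) are excluded
    with a logged reason; an optional size-outlier rule (volume beyond
    median ± ``size_outlier_mads`` MADs, disabled by default) mirrors the
    'deviated size' exclusion.
    """
    for name, frame in (("morph", morph), ("cristae_stats", cristae_stats), ("cj_stats", cj_stats)):
        if "id" not in frame.columns:
            raise ValueError(f"{name} table lacks an 'id' column")
    ids = set(morph["id"])
    for name, frame in (("cristae_stats", cristae_stats), ("cj_stats", cj_stats)):
        orphans = sorted(set(frame["id"]) ^ ids)
        if orphans:
            raise ValueError(f"{name} ids do not match morph ids; orphans: {orphans}")
    df = morph.merge(cristae_stats, on="id").merge(cj_stats, on="id")

    no_cristae = df["tubular_volume_ratio"].isna() | df["tubular_surface_ratio"].isna()
    for i in df.loc[no_cristae, "id"]:
        logger.info("excluding mitochondrion %s: no cristae", i)
    df = df.loc[~no_cristae].copy()

    if size_outlier_mads is not None and len(df):
        v = df["mito_volume_um3"] if "mito_volume_um3" in df else df["volume_um3"]
        med = v.median()
        mad = (v - med).abs().median()
        if mad > 0:
            outlier = (v - med).abs() > size_outlier_mads * mad
            for i in df.loc[outlier, "id"]:
                logger.info("excluding mitochondrion %s: deviated size", i)
            df = df.loc[~outlier].copy()

    if "mito_volume_um3" not in df.columns:
        df = df.rename(
            columns={"volume_um3": "mito_volume_um3", "surface_um2": "mito_surface_um2"}
        )
    if isinstance(groups, str):
        df["group"] = groups
    else:
        df["group"] = [groups[i] for i in df["id"]]
    out = df[["id"] + FEATURE_COLUMNS + ["group"]].reset_index(drop=True)
    if out[FEATURE_COLUMNS].isna().any().any():
        raise ValueError("feature table has missing cells after exclusions")
    return out


def standardize_and_pca(
    table: pd.DataFrame,
    fit_group: str = "control",
    n_components: int = 3,
) -> pd.DataFrame:
    """Fit scaler + PCA on the fit group only; transform all rows.

    Each feature is standardized to zero mean and unit variance over the
    fit group; PCA components are fitted on the fit group and applied to
    everything, so the non-fit group is described in the fit group's
    feature space.  Component signs are fixed (the largest-|loading|
    feature of each component is made positive) for reproducibility.
    """
    fit = table[table["group"] == fit_group]
    if len(fit) == 0:
        raise ValueError(f"fit group {fit_group!r} is empty")
    if len(fit) < n_components:
        raise ValueError(
            f"fit group has {len(fit)} rows < n_components={n_components}"
        )
    X_fit = fit[FEATURE_COLUMNS].to_numpy(dtype=np.float64)
    stds = X_fit.std(axis=0)
    for col, s in zip(FEATURE_COLUMNS, stds):
        if s == 0:
            raise ValueError(f"constant column in fit group: {col}")
    scaler = StandardScaler().fit(X_fit)
    pca = PCA(n_components=n_components, svd_solver="full").fit(
        scaler.transform(X_fit)
    )
    flip = np.ones(n_components)
    for i, comp in enumerate(pca.components_):
        if comp[np.argmax(np.abs(comp))] < 0:
            flip[i] = -1.0
    scores = pca.transform(
        scaler.transform(table[FEATURE_COLUMNS].to_numpy(dtype=np.float64))
    ) * flip
    out = pd.DataFrame(
        scores, columns=[f"pc{i + 1}" for i in range(n_components)]
    )
    out.insert(0, "id", table["id"].to_numpy())
    out["group"] = table["group"].to_numpy()
    return out


def ward_clustering(
    standardized: np.ndarray | pd.DataFrame, n_clusters: int | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Ward linkage with Euclidean distance; optional flat cut.

    Returns ``(linkage_matrix, flat_labels)``; ``flat_labels`` is None
    unless ``n_clusters`` is given.
    """
    if isinstance(standardized, pd.DataFrame):
        cols = [c for c in standardized.columns if c in FEATURE_COLUMNS] or [
            c for c in standardized.columns if standardized[c].dtype.kind == "f"
        ]
        X = standardized[cols].to_numpy(dtype=np.float64)
    else:
        X = np.asarray(standardized, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    Z = linkage(X, method="ward", metric="euclidean")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust") if n_clusters else None
    return Z, labels
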