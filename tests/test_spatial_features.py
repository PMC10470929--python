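"""Subvolume partitioning, the nine-feature table, PCA and Ward clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from mitotap.cristae import CristaeLabels
from mitotap.phantom import make_segregation_phantom
from mitotap.spatial_features import (
    FEATURE_COLUMNS,
    build_feature_table,
    kmeans_subvolumes,
    standardize_and_pca,
    subvolume_composition,
    ward_clustering,
)
from mitotap.volumes import LabelVolume, VoxelGrid


def _block_coords(n_voxels):
    side = int(round(n_voxels ** (1 / 3)))
    coords = np.argwhere(np.ones((side, side, max(1, n_voxels // side**2)), bool))
    return coords


class TestKmeansSubvolumes:
    def test_cluster_count_rule(self):
        grid = VoxelGrid((40, 40, 40), (10.0, 10.0, 10.0))
        coords = np.argwhere(np.ones((40, 40, 40), bool))[:50_000]  # 0.05 um^3
        part = kmeans_subvolumes(coords, grid, seed=0)
        assert part.k == 10  # round(0.05 / 0.005)

    def test_small_mitochondrion_single_cluster(self):
        grid = VoxelGrid((10, 10, 10))
        coords = np.argwhere(np.ones((10, 10, 10), bool))[:100]
        part = kmeans_subvolumes(coords, grid, seed=0)
        assert part.k == 1
        assert set(part.assignment) == {0}

    def test_volumes_conserved(self):
        grid = VoxelGrid((30, 30, 30))
        coords = np.argwhere(np.ones((30, 30, 30), bool))[:15_000]
        part = kmeans_subvolumes(coords, grid, seed=3)
        assert part.cluster_volumes_um3().sum() == pytest.approx(
            len(coords) * grid.voxel_volume_um3
        )

    def test_deterministic_given_seed(self):
        grid = VoxelGrid((20, 20, 20))
        coords = np.argwhere(np.ones((20, 20, 20), bool))
        a = kmeans_subvolumes(coords, grid, seed=11).assignment
        b = kmeans_subvolumes(coords, grid, seed=11).assignment
        assert np.array_equal(a, b)


class TestSubvolumeComposition:
    def _tiny_scene(self):
        grid = VoxelGrid((6, 6, 12))
        mito = np.ones(grid.shape, dtype=bool)
        tub = np.zeros(grid.shape, dtype=bool)
        tub[:, :, :3] = True
        lam = np.zeros(grid.shape, dtype=bool)
        lam[:, :, 9:] = True
        cl = CristaeLabels(
            lamellar=LabelVolume(grid, lam.astype(np.int64)),
            tubular=LabelVolume(grid, tub.astype(np.int64)),
        )
        return grid, mito, cl, tub, lam

    def test_class_voxels_conserved_across_clusters(self):
        grid, mito, cl, tub, lam = self._tiny_scene()
        part = kmeans_subvolumes(np.argwhere(mito), grid, target_volume_um3=1e-4, seed=0)
        comp = subvolume_composition(part, cl)
        counts = comp["volume_um3"] / grid.voxel_volume_um3
        assert (comp["pct_tubular"] / 100 * counts).sum() == pytest.approx(tub.sum())
        assert (comp["pct_lamellar"] / 100 * counts).sum() == pytest.approx(lam.sum())

    def test_crista_free_cluster_reports_zero(self):
        grid, mito, cl, *_ = self._tiny_scene()
        middle = np.argwhere(mito)[
            (np.argwhere(mito)[:, 2] >= 4) & (np.argwhere(mito)[:, 2] <= 7)
        ]
        part = kmeans_subvolumes(middle, grid, target_volume_um3=1.0, seed=0)
        comp = subvolume_composition(part, cl)
        assert (comp[["pct_tubular", "pct_lamellar"]].to_numpy() == 0).all()

    def test_segregated_phantom_dominant_class(self):
        mito, cristae, truth = make_segregation_phantom()
        part = kmeans_subvolumes(np.argwhere(mito.binary()), mito.grid, seed=0)
        comp = subvolume_composition(part, cristae)
        has = comp[(comp.pct_tubular > 0) | (comp.pct_lamellar > 0)]
        assert len(has) > 0
        share = has[["pct_tubular", "pct_lamellar"]].max(axis=1) / (
            has.pct_tubular + has.pct_lamellar
        )
        assert (share > 0.8).all()


def _fake_tables(n=6, seed=0, no_cristae_ids=()):
    rng = np.random.default_rng(seed)
    ids = list(range(1, n + 1))
    morph = pd.DataFrame(
        {
            "id": ids,
            "mito_volume_um3": rng.uniform(0.1, 0.5, n),
            "mito_surface_um2": rng.uniform(1.0, 3.0, n),
            "aspect_ratio": rng.uniform(1.0, 4.0, n),
            "mci": rng.uniform(0.2, 1.0, n),
        }
    )
    cristae = pd.DataFrame(
        {
            "id": ids,
            "crista_volume_um3": rng.uniform(0.01, 0.1, n),
            "crista_surface_um2": rng.uniform(0.5, 3.0, n),
            "tubular_volume_ratio": rng.uniform(0.1, 0.9, n),
            "tubular_surface_ratio": rng.uniform(0.1, 0.9, n),
        }
    )
    for i in no_cristae_ids:
        cristae.loc[cristae["id"] == i, ["tubular_volume_ratio", "tubular_surface_ratio"]] = np.nan
    cj = pd.DataFrame({"id": ids, "cj_density_per_um2": rng.uniform(0.0, 10.0, n)})
    return morph, cristae, cj


class TestFeatureTable:
    def test_all_rows_kept_without_exclusions(self):
        table = build_feature_table(*_fake_tables(3))
        assert len(table) == 3
        assert list(table.columns) == ["id"] + FEATURE_COLUMNS + ["group"]

    def test_mitochondria_without_cristae_excluded(self, caplog):
        import logging

        with caplog.at_level(logging.INFO):
            table = build_feature_table(*_fake_tables(5, no_cristae_ids=(2, 4)))
        assert list(table["id"]) == [1, 3, 5]
        assert "no cristae" in caplog.text

    def test_id_mismatch_lists_orphans(self):
        morph, cristae, cj = _fake_tables(4)
        cj = cj[cj["id"] != 3]
        with pytest.raises(ValueError, match="3"):
            build_feature_table(morph, cristae, cj)

    def test_size_outlier_rule_optional(self):
        morph, cristae, cj = _fake_tables(7)
        morph.loc[morph["id"] == 7, "mito_volume_um3"] = 50.0
        kept = build_feature_table(morph, cristae, cj)
        assert 7 in set(kept["id"])  # disabled by default
        trimmed = build_feature_table(morph, cristae, cj, size_outlier_mads=5.0)
        assert 7 not in set(trimmed["id"])


def _two_group_table(n=20, seed=0, effect=0.4):
    rng = np.random.default_rng(seed)
    rows = []
    for group, tub_mean in (("control", 0.6), ("treatment", 0.6 - effect)):
        for i in range(n):
            rows.append(
                {
                    "id": len(rows) + 1,
                    "mito_volume_um3": rng.normal(0.4, 0.05),
                    "mito_surface_um2": rng.normal(2.4, 0.3),
                    "aspect_ratio": rng.normal(2.5, 0.4),
                    "mci": rng.normal(0.5, 0.08),
                    "crista_volume_um3": rng.normal(0.06, 0.01),
                    "crista_surface_um2": rng.normal(3.0, 0.4),
                    "tubular_volume_ratio": rng.normal(tub_mean, 0.05),
                    "tubular_surface_ratio": rng.normal(tub_mean, 0.05),
                    "cj_density_per_um2": rng.normal(5.0, 1.0),
                    "group": group,
                }
            )
    return pd.DataFrame(rows)[["id"] + FEATURE_COLUMNS + ["group"]]


class TestPca:
    def test_fit_group_standardization(self):
        table = _two_group_table()
        scores = standardize_and_pca(table, n_components=3)
        fit_scores = scores[scores["group"] == "control"][["pc1", "pc2", "pc3"]]
        assert np.allclose(fit_scores.mean(), 0.0, atol=1e-10)
        cov = np.cov(fit_scores.to_numpy().T)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-10  # fit-group scores uncorrelated

    def test_populations_differing_in_tubular_ratio_separate(self):
        table = _two_group_table(effect=0.4)
        scores = standardize_and_pca(table)
        best = 0.0
        for pc in ("pc1", "pc2", "pc3"):
            a = scores.loc[scores["group"] == "control", pc]
            b = scores.loc[scores["group"] == "treatment", pc]
            d = abs(a.mean() - b.mean()) / np.sqrt((a.var() + b.var()) / 2)
            best = max(best, d)
        assert best > 3.0  # groups clearly separated along some component

    def test_constant_column_named_in_error(self):
        table = _two_group_table()
        table.loc[table["group"] == "control", "mci"] = 0.5
        with pytest.raises(ValueError, match="mci"):
            standardize_and_pca(table)

    def test_too_few_fit_rows(self):
        table = _two_group_table(n=2)
        with pytest.raises(ValueError, match="rows"):
            standardize_and_pca(table, n_components=3)

    def test_deterministic(self):
        table = _two_group_table()
        s1 = standardize_and_pca(table)
        s2 = standardize_and_pca(table)
        pd.testing.assert_frame_equal(s1, s2)


class TestWard:
    def test_two_blobs_recovered_exactly(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, size=(15, 4))
        b = rng.normal(10.0, 1.0, size=(15, 4))
        Z, labels = ward_clustering(np.vstack([a, b]), n_clusters=2)
        assert len(set(labels[:15])) == 1
        assert len(set(labels[15:])) == 1
        assert labels[0] != labels[15]

    def test_duplicate_rows_merge_at_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        Z, _ = ward_clustering(X)
        assert Z[0, 2] == 0.0

    def test_linkage_heights_non_decreasing(self):
        rng = np.random.default_rng(2)
        Z, _ = ward_clustering(rng.normal(size=(25, 5)))
        assert (np.diff(Z[:, 2]) >= -1e-12).all()
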