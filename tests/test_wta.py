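"""Partial correlation, winner-take-all labeling and map permutation tests."""

import numpy as np
import pandas as pd
import pytest

import scnwta as sw
from scnwta.core import GMVDataset
from scnwta.wta import lobe_mean_signals


class TestPartialCorrelation:
    def test_no_covariates_is_pearson(self):
        assert sw.partial_correlation([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)

    def test_covariate_absorbs_target(self, rng):
        z = rng.normal(size=30)
        x = rng.normal(size=30)
        y = 3.0 * z
        assert sw.partial_correlation(x, y, z) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_precision_matrix_identity(self, seed):
        # independent oracle: invert the covariance of (x, y, Z) and
        # normalize the off-diagonal of the precision matrix
        rng = np.random.default_rng(seed)
        n, k = 50, 5
        Z = rng.normal(size=(n, k))
        x = rng.normal(size=n) + Z @ rng.normal(size=k) * 0.5
        y = rng.normal(size=n) + Z @ rng.normal(size=k) * 0.5
        ours = sw.partial_correlation(x, y, Z)
        cov = np.cov(np.column_stack([x, y, Z]).T)
        prec = np.linalg.inv(cov)
        oracle = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_rank_deficient_design_rejected(self, rng):
        x, y = rng.normal(size=(2, 20))
        z = np.ones(20)  # duplicates the intercept
        with pytest.raises(ValueError, match="rank"):
            sw.partial_correlation(x, y, np.column_stack([z, z]))

    def test_constant_input_rejected(self, rng):
        with pytest.raises(ValueError, match="degenerate"):
            sw.partial_correlation(np.full(20, 2.0), rng.normal(size=20),
                                   rng.normal(size=20))

    def test_fully_absorbed_variable_gives_zero(self, rng):
        z = rng.normal(size=20)
        assert sw.partial_correlation(2 * z + 1, rng.normal(size=20), z) == 0.0


class TestSeedStructureMap:
    def test_in_territory_exceeds_out_territory(self, coupled_setup):
        cfg, atlas, truth, ds = coupled_setup
        rows = ds.group_rows("HC")
        r = sw.seed_structure_map(ds, 2, "thalamus", rows)
        sid = atlas.structure_id_by_name("thalamus")
        terr = truth.territory_labels[np.asarray(atlas.labels.data) == sid]
        # the dataset's column order within the structure is its lexicographic
        # voxel order, matching the territory volume flattened the same way
        ijk = ds.voxel_ijk[ds.label_columns(sid)]
        terr = truth.territory_labels[tuple(ijk.T)]
        assert r[terr == 2].mean() > r[terr != 2].mean()

    def test_invariant_to_subject_order(self, small_setup):
        *_, ds = small_setup
        rows = ds.group_rows("HC")
        r1 = sw.seed_structure_map(ds, 1, "striatum", rows)
        r2 = sw.seed_structure_map(ds, 1, "striatum", rows[::-1])
        assert np.allclose(r1, r2, atol=1e-12)

    def test_invariant_to_subject_duplication(self, small_setup):
        cfg, atlas, truth, ds = small_setup
        rows = ds.group_rows("HC")
        r1 = sw.seed_structure_map(ds, 3, "cerebellum", rows)
        dup = pd.concat([ds.cohort, ds.cohort], ignore_index=True)
        dup["subject_id"] = [f"s{i}" for i in range(len(dup))]
        ds2 = GMVDataset(np.vstack([ds.matrix, ds.matrix]), ds.voxel_ijk, dup, atlas)
        r2 = sw.seed_structure_map(ds2, 3, "cerebellum",
                                   np.concatenate([rows, rows + ds.n_subjects]))
        assert np.allclose(r1, r2, atol=1e-10)

    def test_covariate_rescaling_invariance(self, small_setup):
        # scaling TIV by a constant cannot change the partial correlations
        cfg, atlas, truth, ds = small_setup
        rows = ds.group_rows("GE_GTCS")
        r1 = sw.seed_structure_map(ds, 1, "thalamus", rows)
        cohort2 = ds.cohort.copy()
        cohort2["tiv"] = cohort2["tiv"] * 3.7
        ds2 = GMVDataset(ds.matrix, ds.voxel_ijk, cohort2, atlas)
        r2 = sw.seed_structure_map(ds2, 1, "thalamus", rows)
        assert np.allclose(r1, r2, atol=1e-10)

    def test_too_few_subjects_rejected(self, small_setup):
        *_, ds = small_setup
        with pytest.raises(ValueError, match="8 subjects"):
            sw.seed_structure_map(ds, 1, "thalamus", np.arange(8))


class TestWtaLabel:
    def test_signed_maximum_wins(self):
        all_r = np.array([[0.1], [0.5], [0.2], [-0.3], [0.0]])
        m = sw.wta_label(all_r)
        assert m.winner_label[0] == 2
        assert m.winner_r[0] == pytest.approx(0.5)

    def test_tie_breaks_to_lowest_lobe_and_is_counted(self):
        all_r = np.array([[0.4], [0.4], [0.1], [0.1], [0.1]])
        m = sw.wta_label(all_r)
        assert m.winner_label[0] == 1
        assert m.n_ties == 1

    def test_all_negative_voxel_stays_labeled(self):
        all_r = -np.abs(np.random.default_rng(0).normal(size=(5, 4)))
        m = sw.wta_label(all_r)
        assert np.all((m.winner_label >= 1) & (m.winner_label <= 5))

    def test_all_nonfinite_voxel_rejected(self):
        all_r = np.full((5, 2), np.nan)
        all_r[:, 0] = 0.1
        with pytest.raises(ValueError, match="finite"):
            sw.wta_label(all_r)

    def test_abs_mode_prefers_strong_negative(self):
        all_r = np.array([[0.3], [-0.8], [0.1], [0.0], [0.0]])
        assert sw.wta_label(all_r).winner_label[0] == 1
        assert sw.wta_label(all_r, use_abs=True).winner_label[0] == 2

    def test_recovery_of_planted_territories(self, coupled_setup):
        cfg, atlas, truth, ds = coupled_setup
        rows = ds.group_rows("HC")
        agree = total = 0
        for sname in ("striatum", "thalamus", "cerebellum"):
            m = sw.structure_wta_map(ds, sname, rows, group="HC")
            ijk = ds.voxel_ijk[m.voxel_columns]
            true_lobe = truth.territory_labels[tuple(ijk.T)]
            agree += (m.winner_label == true_lobe).sum()
            total += len(true_lobe)
        assert agree / total >= 0.9


class TestCounts:
    def test_all_one_lobe(self):
        all_r = np.vstack([np.full(100, 0.9), *[np.zeros(100)] * 4])
        m = sw.wta_label(all_r)
        assert list(sw.count_labels(m)) == [100, 0, 0, 0, 0]

    def test_counts_conserve_mask_size(self, small_setup):
        *_, ds = small_setup
        for sname in ("striatum", "thalamus", "cerebellum"):
            m = sw.structure_wta_map(ds, sname, ds.group_rows("HC"))
            assert sw.count_labels(m).sum() == len(m.voxel_columns)

    def test_radar_normalization_of_printed_counts(self):
        # reference voxel counts 2006 (patients) and 965 (controls)
        assert 2006 / 965 == pytest.approx(2.079, abs=5e-4)


class TestPermutationMapTest:
    def test_identical_groups_give_p_one(self, small_setup):
        # duplicate every HC subject under a different group label: the two
        # "groups" are subject-for-subject identical
        cfg, atlas, truth, ds = small_setup
        rows = ds.group_rows("HC")
        sub = ds.cohort.iloc[np.concatenate([rows, rows])].reset_index(drop=True)
        sub["subject_id"] = [f"s{i}" for i in range(len(sub))]
        sub.loc[:len(rows) - 1, "group"] = "GE_GTCS"
        sub.loc[len(rows):, "group"] = "FE_FBTS"
        sub["duration_months"] = 50.0
        ds2 = GMVDataset(ds.matrix[np.concatenate([rows, rows])], ds.voxel_ijk,
                         sub, atlas)
        cmp_ = sw.permutation_map_test(ds2, "GE_GTCS", "FE_FBTS", "thalamus",
                                       n_perm=199, seed=1)
        assert np.all(cmp_.table["diff"] == 0)
        assert np.all(cmp_.table["p_perm"] == 1.0)

    def test_overlapping_groups_rejected(self, small_setup):
        *_, ds = small_setup
        with pytest.raises(ValueError, match="overlap|unknown"):
            sw.permutation_map_test(ds, "HC", "HC", "thalamus", n_perm=100)

    def test_planted_difference_detected(self):
        # abolish one territory's coupling in one group: its voxels scatter
        # across lobes there, so that lobe's count drops detectably
        hits = 0
        for rep in range(5):
            w0 = {("GE_GTCS", "thalamus", 2): 0.0}
            cfg = sw.GeneratorConfig(grid=(24, 24, 24), n_per_group=60,
                                     seed=300 + rep, coupling_w0=w0,
                                     coupling_w0_default=0.06, noise_sd=0.03)
            atlas, truth = sw.generate_atlas(cfg)
            ds, _ = sw.generate_cohort(cfg, atlas, truth)
            cmp_ = sw.permutation_map_test(ds, "GE_GTCS", "HC", "thalamus",
                                           n_perm=199, seed=1)
            hits += cmp_.table.loc[cmp_.table.lobe == 2, "p_perm"].iloc[0] < 0.05
        assert hits >= 4

    def test_p_values_within_valid_range(self, small_setup):
        *_, ds = small_setup
        cmp_ = sw.permutation_map_test(ds, "GE_GTCS", "HC", "striatum",
                                       n_perm=199, seed=5)
        p = cmp_.table["p_perm"]
        assert np.all(p >= 1 / 200) and np.all(p <= 1.0)
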