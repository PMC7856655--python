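"""Duration-modulation GLMs: interaction t statistics and the one-tailed p."""

import numpy as np
import pytest
from scipy import integrate, stats

import scnwta as sw
from scnwta.core import STRUCTURE_NAMES


def _within_data(rng, n=111, w1=0.0):
    dur = np.abs(rng.normal(80, 40, n)) + 1
    seed_gm = rng.normal(0.5, 0.05, n)
    tiv = rng.normal(1500, 120, n)
    target = (0.3 + (0.4 + w1 * dur) * seed_gm + 1e-5 * tiv
              + rng.normal(0, 0.02, n))
    return target, seed_gm, dur, tiv


class TestOneTailedP:
    def test_t_zero_gives_half(self):
        assert sw.one_tailed_p(0.0, 50) == pytest.approx(0.5)

    @pytest.mark.parametrize("t,df,expect", [
        (1.659, 106, 0.050),
        (-2.284, 106, 0.012),
        (-2.966, 213, 0.002),
    ])
    def test_reference_convention_values(self, t, df, expect):
        assert round(sw.one_tailed_p(t, df), 3) == expect

    def test_matches_quadrature_of_t_density(self):
        df, t = 17, 1.83
        dens = lambda x: stats.t.pdf(x, df)
        val, _ = integrate.quad(dens, t, np.inf)
        assert sw.one_tailed_p(t, df) == pytest.approx(val, abs=1e-6)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            sw.one_tailed_p(1.0, 0)


class TestWithinGroupFit:
    def test_df_is_n_minus_5(self, rng):
        fit = sw.fit_within_group(*_within_data(rng))
        assert fit.df == 106
        assert fit.terms == ("intercept", "gm_seed", "duration",
                             "gm_seed:duration", "tiv")

    def test_negative_modulation_recovered(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(1000 + rep)
            fit = sw.fit_within_group(*_within_data(rng, w1=-0.003))
            hits += (fit.t_interaction < 0) and (fit.p_one_tailed < 0.05)
        assert hits >= 8

    def test_constant_duration_rejected(self, rng):
        t, s, d, v = _within_data(rng)
        with pytest.raises(ValueError, match="collinear"):
            sw.fit_within_group(t, s, np.full_like(d, 60.0), v)

    def test_centering_invariance_of_interaction_t(self, rng):
        t_gm, s, d, v = _within_data(rng, w1=-0.001)
        f1 = sw.fit_within_group(t_gm, s, d, v)
        f2 = sw.fit_within_group(t_gm, s - s.mean(), d - d.mean(), v)
        assert f1.t_interaction == pytest.approx(f2.t_interaction, abs=1e-8)

    def test_missing_values_rejected(self, rng):
        t, s, d, v = _within_data(rng)
        d[3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            sw.fit_within_group(t, s, d, v)


class TestBetweenGroupFit:
    def _both(self, rng, w1_a=0.0, w1_b=0.0, n=111):
        ta, sa, da, va = _within_data(rng, n, w1_a)
        tb, sb, db, vb = _within_data(rng, n, w1_b)
        g = np.array(["GE_GTCS"] * n + ["FE_FBTS"] * n)
        return (np.concatenate([ta, tb]), np.concatenate([sa, sb]),
                np.concatenate([da, db]), np.concatenate([va, vb]), g)

    def test_df_is_n_minus_9(self, rng):
        fit = sw.fit_between_group(*self._both(rng))
        assert fit.df == 213

    def test_null_rejection_rate_near_alpha(self):
        rejects = 0
        n_rep = 60
        for rep in range(n_rep):
            rng = np.random.default_rng(2000 + rep)
            fit = sw.fit_between_group(*self._both(rng, n=40))
            rejects += fit.p_one_tailed < 0.05
        # one-tailed p on the magnitude is two-sided in effect: the null
        # rejection rate at .05 should be near 0.10
        assert 0.01 <= rejects / n_rep <= 0.25

    def test_sign_tracks_modulation_difference(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(3000 + rep)
            fit = sw.fit_between_group(*self._both(rng, w1_a=-0.002, w1_b=0.0))
            hits += fit.direction == -1
        assert hits >= 8

    def test_group_recoding_invariance_of_t(self, rng):
        t_gm, s, d, v, g = self._both(rng, w1_a=-0.001)
        f1 = sw.fit_between_group(t_gm, s, d, v, g)
        g_pm = np.where(g == "GE_GTCS", 1.0, -1.0)
        f2 = sw.fit_between_group(t_gm, s, d, v, (g_pm + 1) / 2)
        f3 = sw.fit_between_group(t_gm, s, d, v, g_pm)  # +/-1 coding
        assert f1.t_interaction == pytest.approx(f2.t_interaction, abs=1e-8)
        assert abs(f1.t_interaction) == pytest.approx(abs(f3.t_interaction), abs=1e-8)

    def test_single_group_rejected(self, rng):
        t_gm, s, d, v, g = self._both(rng)
        with pytest.raises(ValueError, match="both groups"):
            sw.fit_between_group(t_gm, s, d, v, np.zeros(len(g)))


class TestScan:
    @pytest.fixture(scope="class")
    def setup(self):
        cfg = sw.GeneratorConfig(grid=(16, 16, 16), n_per_group=30, seed=19)
        atlas, truth = sw.generate_atlas(cfg)
        ds, _ = sw.generate_cohort(cfg, atlas, truth)
        rows = ds.group_rows("GE_GTCS")
        maps = {s: sw.structure_wta_map(ds, s, rows, group="GE_GTCS")
                for s in STRUCTURE_NAMES.values()}
        return ds, maps

    def test_sixty_rows_per_scope(self, setup):
        ds, maps = setup
        t1 = sw.subnetwork_modulation_scan(ds, maps, "within_group", "GE_GTCS")
        t2 = sw.subnetwork_modulation_scan(ds, maps, "between_group",
                                           ("GE_GTCS", "FE_FBTS"))
        assert len(t1) == 60 and len(t2) == 60
        assert set(t1["subnetwork"]) == set(sw.LOBE_NAMES.values())

    def test_seed_target_swap_changes_fit(self, setup):
        ds, maps = setup
        t = sw.subnetwork_modulation_scan(ds, maps, "within_group", "GE_GTCS")
        a = t[(t.subnetwork == "frontal") & (t.seed == "cortex")
              & (t.target == "thalamus")]["t"].iloc[0]
        b = t[(t.subnetwork == "frontal") & (t.seed == "thalamus")
              & (t.target == "cortex")]["t"].iloc[0]
        assert a != b

    def test_planted_modulation_concentrates_in_its_subnetwork(self):
        # negative duration-coupling slope planted only in the motor (lobe 2)
        # thalamic territory
        w1 = {("GE_GTCS", "thalamus", 2): -5e-4}
        cfg = sw.GeneratorConfig(grid=(24, 24, 24), n_per_group=111, seed=23,
                                 coupling_w0_default=0.12, coupling_w1=w1,
                                 noise_sd=0.02)
        atlas, truth = sw.generate_atlas(cfg)
        ds, _ = sw.generate_cohort(cfg, atlas, truth)
        rows = ds.group_rows("GE_GTCS")
        maps = {s: sw.structure_wta_map(ds, s, rows, group="GE_GTCS")
                for s in STRUCTURE_NAMES.values()}
        t = sw.subnetwork_modulation_scan(ds, maps, "within_group", "GE_GTCS")
        strong = t[t.p_one_tailed < 1e-6]
        # the overwhelmingly significant rows are exactly the planted circuit
        assert len(strong) > 0
        assert (strong.subnetwork == "motor_premotor").all()
        assert ((strong.seed == "thalamus") | (strong.target == "thalamus")).all()
        assert (strong.direction == -1).all()
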