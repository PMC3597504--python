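"""Island-conversion models: recursion, forward simulator, pulse ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import islandmix as im
from islandmix.sexbias import (MigrationModelParams, PulseModelParams,
                               ancestry_recursion, forward_ancestry,
                               forward_paint_calls, pulse_grid,
                               pulse_model_ratio, ratio_comparison)


class TestRecursion:
    def test_no_migration_is_constant(self):
        traj = ancestry_recursion(MigrationModelParams(m=0.0, R=0.5), 50)
        assert (traj[["p_auto", "p_x_pop", "p_mt", "p_y"]] == 1.0).all().all()

    def test_total_male_replacement_closed_forms(self):
        """R=0, m=1: autosomes halve every generation, mtDNA is immortal,
        the Y is lost immediately."""
        traj = ancestry_recursion(MigrationModelParams(m=1.0, R=0.0), 10)
        t = np.arange(11)
        assert np.allclose(traj["p_auto"], 0.5 ** t)
        assert (traj["p_mt"] == 1.0).all()
        assert traj["p_y"].iloc[1] == 0.0

    def test_male_biased_decay_and_increasing_ratio(self):
        """R=0 at the island's migration rate: p_auto = (1-m/2)^t and the
        X:autosome ratio increases strictly with time."""
        m = 0.0083
        traj = ancestry_recursion(MigrationModelParams(m=m, R=0.0), 1000)
        t = np.arange(1001)
        assert np.allclose(traj["p_auto"], (1 - m / 2) ** t)
        ratios = traj["ratio_x_auto"].to_numpy()
        assert (np.diff(ratios) > 0).all()

    def test_absorbing_state(self):
        """Immigrants carrying ancestry 1 keep every trajectory at 1."""
        traj = ancestry_recursion(MigrationModelParams(
            m=0.3, R=0.4, immigrant_ancestry=1.0), 100)
        cols = ["p_auto", "p_x_female", "p_x_male", "p_x_pop", "p_mt", "p_y"]
        assert np.allclose(traj[cols], 1.0)

    @settings(deadline=None, max_examples=30)
    @given(m=st.floats(0.001, 0.5), R=st.floats(0.0, 0.99),
           T=st.integers(2, 300))
    def test_ratio_at_least_one_when_male_biased(self, m, R, T):
        traj = ancestry_recursion(MigrationModelParams(m=m, R=R), T)
        assert (traj["ratio_x_auto"] >= 1.0 - 1e-12).all()

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            MigrationModelParams(m=1.5, R=0.0)
        with pytest.raises(ValueError):
            MigrationModelParams(m=0.1, R=-0.1)


class TestForwardAncestry:
    def test_unbiased_migration_equalizes_x_and_autosome(self):
        """R=1: E[X ancestry] = E[autosomal ancestry]; check within 2 SE
        over seeds."""
        diffs = []
        for s in range(6):
            fw = forward_ancestry(MigrationModelParams(m=0.01, R=1.0),
                                  1000, 150, seed=300 + s)
            diffs.append(fw["p_x_pop"].iloc[-1] - fw["p_auto"].iloc[-1])
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 2.5 * se

    def test_male_only_migration_enriches_x(self):
        """R=0: sampled X ancestry exceeds autosomal ancestry."""
        wins = 0
        for s in range(6):
            fw = forward_ancestry(MigrationModelParams(m=0.02, R=0.0),
                                  500, 150, seed=400 + s)
            wins += fw["p_x_pop"].iloc[-1] > fw["p_auto"].iloc[-1]
        assert wins >= 5

    def test_mtdna_never_lost_without_female_migration(self):
        fw = forward_ancestry(MigrationModelParams(m=0.05, R=0.0),
                              200, 200, seed=1)
        assert (fw["p_mt"] == 1.0).all()

    def test_matches_recursion_mean(self):
        """Mean trajectory converges to the deterministic recursion."""
        m = 0.0083
        runs = [forward_ancestry(MigrationModelParams(m=m, R=0.0),
                                 2000, 100, seed=500 + s)["p_auto"].iloc[-1]
                for s in range(5)]
        expected = ancestry_recursion(
            MigrationModelParams(m=m, R=0.0), 100)["p_auto"].iloc[-1]
        assert np.mean(runs) == pytest.approx(expected, rel=0.05)

    def test_tiny_population_rejected(self):
        with pytest.raises(ValueError):
            forward_ancestry(MigrationModelParams(m=0.1, R=0.0), 4, 10)


class TestForwardPaint:
    def test_zero_generations_all_donor(self, bear_calls):
        painted = forward_paint_calls(
            MigrationModelParams(m=0.1, R=0.0), bear_calls,
            donor_haplotype="polar3", immigrant_haplotype="brown2",
            n_individuals=20, generations=0, n_sampled=2, seed=2)
        di = painted.sample_index("polar3")
        for name in painted.scaffold_names():
            al = painted.alleles[name]
            for s in ("island1", "island2"):
                assert np.array_equal(al[:, painted.sample_index(s)],
                                      al[:, di])

    def test_converted_island_shows_excess_sharing(self, bear_calls):
        """A sampled islander after male-biased brown immigration still
        carries polar X ancestry: D(brown, islander, polar, black) >> 0."""
        painted = forward_paint_calls(
            MigrationModelParams(m=0.02, R=0.0), bear_calls,
            donor_haplotype="polar3", immigrant_haplotype="brown2",
            n_individuals=60, generations=80, n_sampled=2, seed=6)
        assert set(painted.scaffold_names()) == set(bear_calls.scaffold_names("X"))
        r = im.dstat(painted, ("brown1", "island1", "polar1", "black"),
                     chrom_class="X", block_span=1_000_000)
        assert r.D > 0.2


class TestPulseModel:
    def test_no_pulse_gives_null_d(self):
        res = pulse_model_ratio(PulseModelParams(f=1e-9), n_reps=200_000,
                                seed=4)
        assert abs(res.d_auto) < 3 * res.d_auto_se
        assert abs(res.d_x) < 3 * res.d_x_se

    def test_identical_scalings_give_unit_ratio(self):
        res = pulse_model_ratio(PulseModelParams(), n_reps=400_000, seed=5,
                                x_ne_factor=1.0, f_x_factor=1.0)
        rel_se = np.hypot(res.d_auto_se / res.d_auto, res.d_x_se / res.d_x)
        assert res.ratio == pytest.approx(1.0, abs=3.5 * rel_se)

    def test_agrees_with_independent_coalescent_engine(self):
        """The vectorized replicate-genealogy sampler matches msprime run
        on the same demography (independent oracle)."""
        p = PulseModelParams()
        mc = pulse_model_ratio(p, n_reps=400_000, seed=6)
        ms = pulse_model_ratio(p, n_reps=20_000, seed=7, engine="msprime")
        for a, b, sa, sb in ((mc.d_auto, ms.d_auto, mc.d_auto_se, ms.d_auto_se),
                             (mc.d_x, ms.d_x, mc.d_x_se, ms.d_x_se)):
            assert abs(a - b) < 3.5 * np.hypot(sa, sb)

    def test_degenerate_times_rejected(self):
        with pytest.raises(ValueError):
            PulseModelParams(t_gf=30_000, t_p2=20_000)


@pytest.fixture(scope="module")
def grid():
    return pulse_grid(size_factors=(0.5, 1.0), tgf_fractions=(0.5,),
                      n_reps=100_000, seed=8)


class TestRatioComparison:
    def test_unit_ratio_compatible_with_both(self, grid):
        rep = ratio_comparison(grid, MigrationModelParams(m=0.0083, R=0.0), 1.0)
        assert rep["verdict"] == "both"

    def test_observed_fourteen_requires_continuous_model(self, grid):
        rep = ratio_comparison(grid, MigrationModelParams(m=0.0083, R=0.0),
                               14.0)
        assert rep["pulse_compatible"] is False
        assert rep["continuous_compatible"] is True
        assert rep["verdict"] == "continuous-only"

    def test_subunit_ratio_fits_neither(self, grid):
        rep = ratio_comparison(grid, MigrationModelParams(m=0.0083, R=0.0), 0.5)
        assert rep["verdict"] == "neither"
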