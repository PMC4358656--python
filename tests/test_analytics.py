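"""Analytics tests: growth classification/fitting, fate windows, race bound,
kin statistics, population summaries, and parameter recovery on synthetic
lineages."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bcelldyn import analytics
from bcelldyn.analytics import (
    classify_growth, fate_fractions, fit_growth, kin_correlations,
    population_summaries, race_lower_bound,
)
from bcelldyn.lineage import LineageTree, TrackRecord


def track(cell_id="c0", parent=None, gen=0, t0=0.0, t1=40.0, fate="censored",
          times=None, volumes=None):
    if times is None:
        times = np.linspace(t0, t1, 81)
    return TrackRecord(cell_id=cell_id, parent_id=parent, generation=gen,
                       t_birth=t0, t_end=t1, fate=fate,
                       times=times, volumes=volumes)


def piecewise(times, v0, tgro, k):
    tau = times - times[0]
    return np.where(tau < tgro, v0, v0 * np.exp(k * (tau - tgro)))


class TestClassifyGrowth:
    def test_flat_track_is_non_grower(self):
        t = track(volumes=np.full(81, 250.0))
        assert classify_growth(t) == "non_grower"

    def test_grower_by_both_rules(self):
        times = np.linspace(0, 40, 81)
        t = track(times=times, volumes=np.linspace(300, 850, 81))
        assert classify_growth(t) == "grower"

    def test_threshold_sensitivity_reruns(self):
        """Delta = 400 μm³ (300→700): grower at ×0.75 thresholds, non-grower
        at ×1.25."""
        times = np.linspace(0, 40, 81)
        t = track(times=times, volumes=np.linspace(300, 700, 81))
        assert classify_growth(t, 350 * 0.75, 800 * 0.75) == "grower"
        assert classify_growth(t, 350 * 1.25, 800 * 1.25) == "non_grower"

    def test_grew_then_shrank_is_non_grower(self):
        times = np.linspace(0, 40, 81)
        v = np.concatenate([np.linspace(300, 700, 41), np.linspace(690, 320, 40)])
        assert classify_growth(track(times=times, volumes=v)) == "non_grower"

    @given(st.floats(0.8, 1.5), st.floats(0.8, 1.5))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_thresholds(self, s1, s2):
        """Raising thresholds never converts a non-grower into a grower."""
        times = np.linspace(0, 40, 81)
        t = track(times=times, volumes=np.linspace(310, 740, 81))
        lo, hi = sorted((s1, s2))
        if classify_growth(t, 350 * lo, 800 * lo) == "non_grower":
            assert classify_growth(t, 350 * hi, 800 * hi) == "non_grower"

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="undetermined"):
            classify_growth(track(times=np.array([0.0]), volumes=np.array([300.0]),
                                  t1=1.0))


class TestFitGrowth:
    def test_recovers_noiseless_parameters(self):
        times = np.arange(0.0, 40.0, 0.5)
        t = track(times=times, volumes=piecewise(times, 250.0, 10.0, 0.15), t1=40)
        fit = fit_growth(t)
        assert fit.v0 == pytest.approx(250.0, rel=0.01)
        assert fit.k == pytest.approx(0.15, rel=0.01)
        assert abs(fit.t_gro - 10.0) <= 0.5  # one sampling step
        assert fit.rmsd < 1.0

    def test_constant_trajectory_degenerate_fit(self):
        times = np.arange(0.0, 20.0, 0.5)
        t = track(times=times, volumes=np.full_like(times, 400.0), t1=20)
        fit = fit_growth(t)
        assert fit.k == 0.0
        assert fit.rmsd == 0.0
        assert fit.t_gro == pytest.approx(times[-1] - times[0])

    def test_never_worse_than_best_constant_fit(self, rng):
        """The piecewise family nests the constant model."""
        times = np.arange(0.0, 30.0, 0.5)
        for _ in range(5):
            v = piecewise(times, 300.0, rng.uniform(2, 20), rng.uniform(0.02, 0.2))
            v = v * rng.normal(1.0, 0.05, size=v.shape)
            v = np.maximum(v, 10.0)
            t = track(times=times, volumes=v, t1=30)
            fit = fit_growth(t)
            const_rmsd = np.sqrt(np.mean((v - v.mean()) ** 2))
            assert fit.rmsd <= const_rmsd + 1e-9

    def test_deterministic(self):
        times = np.arange(0.0, 30.0, 0.5)
        v = piecewise(times, 280.0, 8.0, 0.12)
        t = track(times=times, volumes=v, t1=30)
        f1, f2 = fit_growth(t), fit_growth(t)
        assert (f1.v0, f1.t_gro, f1.k, f1.rmsd) == (f2.v0, f2.t_gro, f2.k, f2.rmsd)


def toy_tree():
    """10 generation-0 cells: 4 divide at 20-30 h, 2 die at 15 h, 4 censored
    at 36 h."""
    recs = []
    for i in range(4):
        recs.append(track(f"d{i}", t1=20.0 + 2.5 * i, fate="divided",
                          times=np.array([0.0, 20.0 + 2.5 * i]),
                          volumes=np.array([300.0, 900.0])))
    for i in range(2):
        recs.append(track(f"x{i}", t1=15.0, fate="died",
                          times=np.array([0.0, 15.0]), volumes=np.array([300.0, 310.0])))
    for i in range(4):
        recs.append(track(f"c{i}", t1=36.0, fate="censored",
                          times=np.array([0.0, 36.0]), volumes=np.array([300.0, 320.0])))
    return LineageTree.from_records(recs)


class TestFateFractions:
    def test_hand_counted_fractions(self):
        stats = fate_fractions(toy_tree())
        row = stats.table[stats.table.generation == 0].iloc[0]
        assert row.fraction_divided == pytest.approx(0.4)
        assert row.fraction_died == pytest.approx(0.2)
        assert row.err == pytest.approx(1 / 10)

    def test_all_dividing_inside_window(self):
        recs = [track(f"d{i}", t1=24.0, fate="divided",
                      times=np.array([0.0, 24.0]), volumes=np.array([300.0, 900.0]))
                for i in range(5)]
        stats = fate_fractions(LineageTree.from_records(recs))
        assert stats.table.iloc[0].fraction_divided == 1.0

    def test_cells_censored_before_window_end_excluded(self):
        recs = [track("a", t1=30.0, fate="divided", times=np.array([0.0, 30.0]),
                      volumes=np.array([300.0, 900.0])),
                track("b", t1=20.0, fate="censored", times=np.array([0.0, 20.0]),
                      volumes=np.array([300.0, 310.0]))]
        stats = fate_fractions(LineageTree.from_records(recs))
        row = stats.table.iloc[0]
        assert row.n_eligible == 1
        assert row.fraction_divided == 1.0


class TestRaceLowerBound:
    def test_growth_always_after_death_gives_zero(self):
        assert race_lower_bound([50, 60], [5, 10], 0.9).p_race == 0.0

    def test_growth_always_before_death_gives_f_resp(self):
        assert race_lower_bound([1, 2], [10, 20], 1.0).p_race == 1.0

    def test_hand_computed_example(self):
        rb = race_lower_bound([5, 10, 20], [8, 15], 0.9)
        assert rb.p_race == pytest.approx(0.45)
        assert rb.p_decision == 0.0

    def test_agrees_with_monte_carlo_race_oracle(self, rng):
        """Under the race model with independent clocks, the fraction of
        dying cells that started growing equals E[F_gro(Tdie)]; the
        estimator must agree with a direct simulation within 3 SE."""
        tgro = rng.lognormal(np.log(12.0), 0.4, size=400)
        tdie = rng.lognormal(np.log(18.0), 0.5, size=300)
        f_resp = 1.0
        est = race_lower_bound(tgro, tdie, f_resp).p_race

        n_mc = 1_000_000
        g = rng.choice(tgro, size=n_mc, replace=True)
        d = rng.choice(tdie, size=n_mc, replace=True)
        mc = np.mean(g <= d)
        se = np.sqrt(mc * (1 - mc) / n_mc) + 1e-6
        assert est == pytest.approx(mc, abs=max(3 * se, 2e-3))

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_bounded_and_monotone_in_f_resp(self, f1, f2):
        tgro = [3.0, 9.0, 14.0]
        tdie = [5.0, 12.0]
        lo, hi = sorted((f1, f2))
        p_lo = race_lower_bound(tgro, tdie, lo).p_race
        p_hi = race_lower_bound(tgro, tdie, hi).p_race
        assert 0.0 <= p_lo <= p_hi <= 1.0

    def test_empty_samples_signaled(self):
        with pytest.raises(ValueError):
            race_lower_bound([], [5.0], 0.5)
        with pytest.raises(ValueError):
            race_lower_bound([5.0], [], 0.5)


def kin_tree(concordant=3, discordant=1):
    """Tree with `concordant` same-fate sister pairs and `discordant`
    opposite-fate pairs."""
    recs = []
    k = 0
    for i in range(concordant + discordant):
        recs.append(track(f"m{i}", t1=10.0, fate="divided",
                          times=np.array([0.0, 10.0]), volumes=np.array([300.0, 900.0])))
        fates = ("divided", "divided") if i < concordant else ("divided", "died")
        for j, fate in enumerate(fates):
            dur = 10.0 + 2.0 * i + 0.1 * j
            recs.append(track(f"m{i}.{j}", parent=f"m{i}", gen=1, t0=10.0,
                              t1=10.0 + dur, fate=fate,
                              times=np.array([10.0, 10.0 + dur]),
                              volumes=np.array([300.0, 900.0])))
        k += 1
    return LineageTree.from_records(recs)


class TestKinCorrelations:
    def test_hand_counted_same_fate_probability(self):
        kin = kin_correlations(kin_tree(3, 1), tgro={})
        assert kin["sister"]["same_fate_prob"] == pytest.approx(0.75)

    def test_synchronized_sisters_give_perfect_stats(self):
        kin = kin_correlations(kin_tree(4, 0), tgro={})
        assert kin["sister"]["same_fate_prob"] == 1.0
        # sisters differ by a constant 0.1 h; the symmetrized correlation
        # treats that offset as a tiny within-pair variance
        assert kin["sister"]["r2_interdivision"] == pytest.approx(1.0, abs=0.01)

    def test_no_pairs_signaled(self):
        recs = [track("a", t1=10.0, fate="divided", times=np.array([0.0, 10.0]),
                      volumes=np.array([300.0, 900.0]))]
        with pytest.raises(ValueError):
            kin_correlations(LineageTree.from_records(recs), tgro={})

    def test_undefined_statistics_reported_as_none(self):
        kin = kin_correlations(kin_tree(1, 1), tgro={})
        assert kin["cousin"]["r2_interdivision"] is None
        assert kin["sister"]["pr_dtgro_le_4h"] is None


class TestPopulationSummaries:
    def test_no_events_constant_count_and_zero_divisions(self):
        recs = [track(f"c{i}", t1=50.0, fate="censored",
                      times=np.array([0.0, 50.0]), volumes=np.array([300.0, 310.0]))
                for i in range(5)]
        pop = population_summaries(LineageTree.from_records(recs),
                                   grid=np.array([0.0, 25.0, 49.0]))
        assert np.allclose(pop.counts_total, 1.0)
        assert pop.expected_divisions == 0.0

    def test_single_division_chain_gives_one_expected_division(self):
        """f = (1, 0): every founder divides once, daughters never."""
        recs = []
        for i in range(3):
            recs.append(track(f"f{i}", t1=10.0, fate="divided",
                              times=np.array([0.0, 10.0]), volumes=np.array([300.0, 900.0])))
            for j in range(2):
                recs.append(track(f"f{i}.{j}", parent=f"f{i}", gen=1, t0=10.0,
                                  t1=40.0, fate="censored",
                                  times=np.array([10.0, 40.0]),
                                  volumes=np.array([300.0, 320.0])))
        pop = population_summaries(LineageTree.from_records(recs))
        assert pop.expected_divisions == pytest.approx(1.0)
        assert pop.max_relative_count == pytest.approx(2.0)

    def test_average_growth_curves_shapes(self, fixture_tree_2000):
        _, tree, _ = fixture_tree_2000
        curves = analytics.average_growth_curves(tree, n_bins=10)
        assert {"mean_volume", "n_cells"} <= set(curves.columns)
        gen0 = curves.loc[0]
        assert "grower" in gen0.index.get_level_values(0)


class TestFixtureParameterRecovery:
    """Round-trip: analytics on the synthetic generator's output recover the
    generator's parameters within sampling error (n = 2,000 founders)."""

    def test_division_fractions_recovered(self, fixture_tree_2000):
        params, tree, truth = fixture_tree_2000
        t = tree.tracks
        for g in (0, 1, 2):
            sub = truth[truth.generation == g]
            n = len(sub)
            f_hat = sub.divided.mean()
            f_true = params.fractions[g]
            se = np.sqrt(f_true * (1 - f_true) / n)
            assert abs(f_hat - f_true) < max(3 * se, 0.02)

    def test_median_interdivision_time_recovered(self, fixture_tree_2000):
        params, tree, _ = fixture_tree_2000
        t = tree.tracks
        div1 = t[(t.generation == 1) & (t.fate == "divided")]
        med = (div1.t_end_h - div1.t_birth_h).median()
        assert med == pytest.approx(params.tdiv1[0], rel=0.08)

    def test_sister_latent_weight_orders_sister_correlation(self):
        from bcelldyn.fixtures import FixtureParams, generate_lineages
        from dataclasses import replace
        base = FixtureParams(fractions=(1.0, 0.9, 0.8, 0.0))
        r2 = {}
        for w in (0.0, 0.9):
            tree, _ = generate_lineages(replace(base, sister_weight=w), 800, seed=3)
            kin = kin_correlations(tree, tgro={})
            r2[w] = kin["sister"]["r2_interdivision"]
        assert r2[0.9] > r2[0.0] + 0.2

    def test_fate_fraction_windows_on_fixture(self, fixture_tree_2000):
        params, tree, _ = fixture_tree_2000
        stats = fate_fractions(tree)
        assert set(stats.table.columns) >= {"generation", "fraction_divided",
                                            "fraction_died", "err"}
        assert ((stats.table.fraction_divided + stats.table.fraction_died) <= 1.0 + 1e-9).all()
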