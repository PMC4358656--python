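"""Unit and invariant tests for the integrated per-cell model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bcelldyn import _kernels
from bcelldyn.engine import default_config, equilibrate, _quiescent_guess
from bcelldyn.model_core import (
    BCLXL, CDH1, CPARP, GM, MASS, NRELA, NCREL, N_SPECIES, SPECIES_SCALE,
    ConfigurationError, IkkProfile, assemble_rhs, default_model,
    gm_growth_rate, hill, ikk_input, rhs,
)


def mean_extrinsic():
    cfg = default_config()
    return {e.param: e.mean for e in cfg.noise.entries}


def equilibrated_mean_state(model=None, extr=None):
    model = model or default_model()
    extr = extr or mean_extrinsic()
    y0 = _quiescent_guess(model.pack_params(extr, stimulated=False), 1.0, None)
    y_eq, info = equilibrate(y0, model, extr)
    return model, extr, y_eq


class TestHill:
    def test_zero_activator_gives_zero(self):
        assert hill(0.0, 10.0, 2.0) == 0.0

    @pytest.mark.parametrize("h", [1.0, 2.0, 4.0, 7.5])
    def test_half_maximal_at_K_for_any_cooperativity(self, h):
        assert hill(3.0, 3.0, h) == pytest.approx(0.5)

    def test_twofold_excess_with_h4(self):
        assert hill(2.0, 1.0, 4.0) == pytest.approx(16.0 / 17.0)

    @given(st.floats(0.0, 1e6), st.floats(0.0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_monotone_increasing(self, a, b):
        lo, hi = sorted((a, b))
        assert hill(lo, 100.0, 3.0) <= hill(hi, 100.0, 3.0) + 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hill(-1.0, 10.0, 2.0)
        with pytest.raises(ConfigurationError):
            hill(1.0, 0.0, 2.0)
        with pytest.raises(ConfigurationError):
            hill(1.0, 10.0, 0.5)


class TestGmGrowthRate:
    def test_zero_myc_zero_basal_gives_zero(self):
        params = {"gm_basal": 0.0, "gm_myc_max": 0.1, "K_gm_myc": 100.0, "h_gm": 2.0}
        assert gm_growth_rate(1.0, 0.0, params) == 0.0

    def test_linear_in_mass_at_saturating_myc(self):
        r1 = gm_growth_rate(1.0, 1e9)
        r2 = gm_growth_rate(2.0, 1e9)
        assert r2 == pytest.approx(2.0 * r1)

    def test_monotone_in_myc(self):
        assert gm_growth_rate(1.0, 50.0) <= gm_growth_rate(1.0, 500.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            gm_growth_rate(0.0, 10.0)
        with pytest.raises(ValueError):
            gm_growth_rate(1.0, -1.0)


class TestIkkInput:
    def test_basal_before_onset(self):
        prof = IkkProfile(basal=50.0, amp=1e4, decay=0.1, t_on=5.0)
        assert ikk_input(2.0, prof) == pytest.approx(50.0)

    def test_collapses_to_basal_for_fast_decay(self):
        prof = IkkProfile(basal=50.0, amp=1e4, decay=1e6)
        assert ikk_input(1.0, prof) == pytest.approx(50.0, rel=1e-6)

    def test_doubling_decay_halves_integrated_exposure(self):
        # closed form: integral of amp*exp(-k t) over [0, inf) = amp / k
        k = 0.05
        t = np.linspace(0, 2000, 400_001)
        for basal in (0.0,):
            slow = IkkProfile(basal=basal, amp=1e4, decay=k)
            fast = IkkProfile(basal=basal, amp=1e4, decay=2 * k)
            auc_slow = np.trapezoid([ikk_input(x, slow) for x in t], t)
            auc_fast = np.trapezoid([ikk_input(x, fast) for x in t], t)
            assert auc_fast == pytest.approx(auc_slow / 2, rel=1e-3)
            assert auc_slow == pytest.approx(1e4 / k, rel=1e-3)

    def test_negative_decay_rejected(self):
        with pytest.raises(ConfigurationError):
            IkkProfile(decay=-0.1)


class TestAssembleRhs:
    def test_unknown_parameter_named_in_error(self):
        model = default_model()
        with pytest.raises(ConfigurationError, match="no_such_param"):
            assemble_rhs(model, {"no_such_param": 1.0})

    def test_zero_dimer_activity_reduces_hill_fluxes_to_basal(self):
        model = default_model()
        f = assemble_rhs(model, mean_extrinsic())
        y = np.zeros(N_SPECIES)
        y[MASS] = 1.0
        dy = f(0.0, y)
        p = model.params
        # with no nuclear NF-kB, each target's synthesis flux is its basal term
        assert dy[4] == pytest.approx(p["tr_myc"] * p["myc_basal"])
        assert dy[5] == pytest.approx(p["tr_cycd"] * p["cycd_basal"])
        assert dy[6] == pytest.approx(p["tr_bcl"] * p["bcl_basal"])

    def test_matches_independent_rk4_oracle_over_10h(self):
        """Production integrator vs an independent fixed-step RK4 at dt=1e-3."""
        model, extr, y_eq = equilibrated_mean_state()
        p = model.pack_params(extr, stimulated=True)
        grid = np.array([2.5, 5.0, 10.0])
        prod = _kernels.integrate_grid(y_eq, p, 0.0, grid, 0.005)

        # independent RK4, written out in full here
        f = assemble_rhs(model, extr)
        y = y_eq.copy()
        dt = 1e-3
        t = 0.0
        oracle = []
        for target in grid:
            n = int(round((target - t) / dt))
            for _ in range(n):
                k1 = f(t, y)
                k2 = f(t + dt / 2, y + dt / 2 * k1)
                k3 = f(t + dt / 2, y + dt / 2 * k2)
                k4 = f(t + dt, y + dt * k3)
                y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                t += dt
            oracle.append(y.copy())
        oracle = np.array(oracle)
        rel = np.abs(prod - oracle) / (np.abs(oracle) + 1e-3 * SPECIES_SCALE)
        assert rel.max() < 1e-4


class TestTrajectoryInvariants:
    def test_species_remain_nonnegative_along_trajectory(self):
        model, extr, y_eq = equilibrated_mean_state()
        p = model.pack_params(extr, stimulated=True)
        grid = np.linspace(0.0, 60.0, 121)
        traj = _kernels.integrate_grid(y_eq, p, 0.0, grid, 0.005)
        assert (traj >= -1e-9 * SPECIES_SCALE).all()

    def test_cparp_quiet_without_death_signaling(self):
        """Death signaling off: cPARP stays below 1% of threshold for 144 h."""
        model, extr, y_eq = equilibrated_mean_state()
        p = model.pack_params(extr, stimulated=False)
        traj = _kernels.integrate_grid(y_eq, p, 0.0, np.array([72.0, 144.0]), 0.005)
        assert traj[:, CPARP].max() < 0.01 * 25_000

    def test_nfkb_rises_then_partially_adapts_under_sustained_ikk(self):
        """Sustained saturating IKK: nuclear NF-κB peak exceeds late plateau."""
        model = default_model(ikk_decay=0.0)  # sustained stimulation
        extr = mean_extrinsic()
        y0 = _quiescent_guess(model.pack_params(extr, stimulated=False), 1.0, None)
        y_eq, _ = equilibrate(y0, model, extr)
        p = model.pack_params(extr, stimulated=True)
        grid = np.linspace(0.0, 72.0, 289)
        traj = _kernels.integrate_grid(y_eq, p, 0.0, grid, 0.005)
        # RelA:p50 shows the classic IkB-feedback adaptation; the cRel pool
        # instead accumulates over days, so the test reads the RelA dimer
        nrela = traj[:, NRELA]
        peak = nrela[grid <= 24].max()
        plateau = nrela[grid >= 60].mean()
        assert peak > plateau

    def test_quiescent_fixed_point_without_stimulation(self):
        """Basal IKK, no death signal: no mitosis-readout crossing in 48 h."""
        model, extr, y_eq = equilibrated_mean_state()
        p = model.pack_params(extr, stimulated=False)
        traj = _kernels.integrate_grid(y_eq, p, 0.0, np.linspace(0, 48, 97), 0.005)
        assert traj[:, CDH1].max() < 0.2

    def test_crel_removal_spares_growth_but_drops_bclxl(self):
        """cRel translation = 0: Bcl-XL decays to its basal level while the
        mass/GM trajectory stays within 20% of wild type over one cycle."""
        extr_wt = mean_extrinsic()
        model_wt, _, y_wt = equilibrated_mean_state(default_model(), extr_wt)
        extr_ko = dict(extr_wt, tr_crel=0.0)
        model_ko = default_model(tr_crel=0.0, crel_ind=0.0)
        y0 = _quiescent_guess(model_ko.pack_params(extr_ko, stimulated=False), 1.0, None)
        y_ko, _ = equilibrate(y0, model_ko, extr_ko)

        grid = np.linspace(0.0, 36.0, 73)
        twt = _kernels.integrate_grid(y_wt, model_wt.pack_params(extr_wt), 0.0, grid, 0.005)
        tko = _kernels.integrate_grid(y_ko, model_ko.pack_params(extr_ko), 0.0, grid, 0.005)

        p = model_ko.params
        bcl_basal_level = p["tr_bcl"] * p["bcl_basal"] / p["dg_bcl"]
        assert tko[-1, BCLXL] == pytest.approx(bcl_basal_level, rel=0.05)
        mass_ratio = tko[:, MASS] / twt[:, MASS]
        assert np.all(np.abs(mass_ratio - 1.0) < 0.20)

    def test_model_rejects_duplicate_or_unknown_species_params(self):
        with pytest.raises(ConfigurationError):
            default_model(not_a_param=1.0)
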