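"""Compartment model: flux structure, dosing, integration, linearity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nasalpbpk as npk
from nasalpbpk import reference as ref
from nasalpbpk.model import (IDX, N_STATES, DepositionFractions, DoseEvent,
                             Regimen, apply_dose, build_rate_matrix, rhs,
                             simulate, superpose_check)
from nasalpbpk.nca import nca_single_dose


class TestRhs:
    def test_zero_state_is_equilibrium(self, phys, us):
        assert np.all(rhs(np.zeros(N_STATES), 0.0, phys, us) == 0.0)

    def test_gi_absorption_split(self, phys, us):
        """A_GI = 1000 ng splits FA*ka into central, (1-FA)*ka to waste."""
        state = np.zeros(N_STATES)
        state[IDX["GI"]] = 1000.0
        d = rhs(state, 0.0, phys, us)
        assert d[IDX["central"]] == pytest.approx(0.9 * 1.036 * 1000.0)
        assert d[IDX["unabsorbed"]] == pytest.approx(0.1 * 1.036 * 1000.0)
        assert d[IDX["GI"]] == pytest.approx(-1.036 * 1000.0)

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2 ** 31 - 1))
    def test_mass_conservation_any_state(self, phys, us, seed):
        """Total derivative is zero at any state: the system is closed."""
        state = np.random.default_rng(seed).uniform(0.0, 1e6, N_STATES)
        assert abs(rhs(state, 0.0, phys, us).sum()) < 1e-6 * state.sum()

    def test_rate_matrix_columns_sum_to_zero(self, phys, us):
        M = build_rate_matrix(phys, us)
        assert np.allclose(M.sum(axis=0), 0.0, atol=1e-12)


class TestApplyDose:
    def test_intranasal_split(self, phys, nasal_frac):
        state = apply_dose(np.zeros(N_STATES),
                           DoseEvent(0.0, "intranasal", 60_000.0),
                           nasal_frac, phys)
        assert state[IDX["ELF_Nose"]] == pytest.approx(32_820.0)
        assert state[IDX["GI"]] == pytest.approx(60_000.0 * 7.6375e-7)
        assert state[IDX["unabsorbed"]] == pytest.approx(
            60_000.0 * (1 - nasal_frac.total))
        assert state.sum() == pytest.approx(60_000.0)

    def test_null_deposition_all_unabsorbed(self, phys, us):
        frac = DepositionFractions(F1=0, F2=0)
        sim = simulate(phys, us, frac, Regimen.single_dose(60_000.0))
        assert np.all(sim.C_plasma == 0.0)
        assert sim.amounts("unabsorbed")[-1] == pytest.approx(60_000.0)

    def test_oral_routing(self, phys, oral_frac):
        state = apply_dose(np.zeros(N_STATES), DoseEvent(0.0, "oral", 1e6),
                           oral_frac, phys)
        assert state[IDX["GI"]] == 1e6
        assert state.sum() == 1e6


class TestSimulate:
    def test_empty_regimen_all_zero(self, phys, us, oral_frac):
        sim = simulate(phys, us, oral_frac, Regimen(events=()),
                       grid=[0.0, 1.0, 2.0])
        assert np.all(sim.states == 0.0)
        assert np.all(sim.C_plasma == 0.0)

    def test_oral_profile_matches_bateman(self, phys, us, oral_frac):
        """With tiny respiratory volumes the oral profile is the lagged
        one-compartment first-order-absorption closed form to <0.5%."""
        grid = np.array([0, 0.5, 1, 2, 3, 3.4, 4, 6, 8, 12, 16, 24, 36, 48, 72])
        sim = simulate(phys, us, oral_frac,
                       Regimen.single_dose(1e6, route="oral"), grid)
        k = us.CL / us.Vc
        t = np.clip(grid - us.tlag, 0.0, None)
        bateman = (phys.FA * 1e6 * us.ka / (us.Vc * (us.ka - k))
                   * (np.exp(-k * t) - np.exp(-us.ka * t)))
        assert np.max(np.abs(sim.C_plasma - bateman)) < 5e-3 * bateman.max()
        assert 3.85 < sim.C_plasma.max() < 4.05  # ~3.9-4.0 ng/mL near 3.4 h

    def test_nasal_tissue_auc_equals_deposited_over_ps(self, phys, us, nasal_frac):
        """Everything deposited on the nasal mucosa transits the tissue, so
        AUCinf of nasal tissue conc ~ F1*dose / (fu_tissue*PS_Nose) (plus a
        small plasma-backflux term)."""
        dense = np.unique(np.concatenate([[0.0], np.geomspace(0.01, 96, 400)]))
        sim = simulate(phys, us, nasal_frac, Regimen.single_dose(60_000.0), dense)
        r = nca_single_dose(dense, sim.C_nasal, 60_000.0)
        absorbed = 0.547 * 60_000.0 + phys.FA * 7.6375e-7 * 60_000.0
        analytic = (0.547 * 60_000.0
                    + phys.PS["Nose"] * phys.fu_p * absorbed / us.CL
                    ) / (phys.PS["Nose"] * phys.fu_tissue)
        assert r.AUCinf == pytest.approx(analytic, rel=1e-3)
        assert r.AUCinf == pytest.approx(7164.89, rel=0.05)  # reference value

    def test_mass_balance_all_regimens(self, phys, us, nasal_frac, bid_sim):
        assert bid_sim.mass_balance_error() < 1e-3
        single = simulate(phys, us, nasal_frac, Regimen.single_dose(60_000.0))
        assert single.mass_balance_error() < 1e-3
        mixed = Regimen(events=(DoseEvent(0.0, "oral", 1e6),
                                DoseEvent(5.0, "intranasal", 6e4),
                                DoseEvent(12.0, "oral", 5e5)))
        assert simulate(phys, us, nasal_frac, mixed).mass_balance_error() < 1e-3

    def test_dose_linearity(self, phys, us, nasal_frac):
        reg1 = Regimen.single_dose(60_000.0)
        reg2 = Regimen.single_dose(120_000.0)
        s1 = simulate(phys, us, nasal_frac, reg1)
        s2 = simulate(phys, us, nasal_frac, reg2)
        assert np.allclose(2.0 * s1.C_plasma, s2.C_plasma, rtol=1e-10)
        assert np.allclose(2.0 * s1.C_nasal, s2.C_nasal, rtol=1e-10)

    def test_pharynx_only_equals_lagless_oral(self, phys, us):
        """F2=1 routes the whole spray to the swallow path: the profile is
        the oral one with the lag removed."""
        frac = DepositionFractions(F1=0.0, F2=1.0)
        grid = np.array([0, 1, 2, 4, 8, 12, 24, 48])
        nasal = simulate(phys, us, frac, Regimen.single_dose(1e6), grid)
        oral = simulate(phys, us, frac, Regimen.single_dose(1e6, route="oral"),
                        np.concatenate([[0.0], grid[1:] + us.tlag]))
        assert np.allclose(nasal.C_plasma[1:], oral.C_plasma[1:], rtol=1e-9)

    def test_lsoda_agrees_with_expm(self, phys, us, nasal_frac):
        reg = Regimen.single_dose(60_000.0)
        a = simulate(phys, us, nasal_frac, reg)
        b = simulate(phys, us, nasal_frac, reg, method="lsoda")
        assert np.max(np.abs(a.C_plasma - b.C_plasma)) < 1e-6 * a.C_plasma.max()

    def test_terminal_slopes_parallel(self, phys, us, nasal_frac):
        """Bidirectional tissue-plasma exchange forces the nasal and plasma
        terminal phases parallel (within 2%)."""
        dense = np.unique(np.concatenate(
            [npk.default_grid(Regimen.single_dose(6e4)), [96.0, 120.0]]))
        sim = simulate(phys, us, nasal_frac, Regimen.single_dose(6e4), dense)
        tail = dense >= 36.0
        lam_p = -np.polyfit(dense[tail], np.log(sim.C_plasma[tail]), 1)[0]
        lam_n = -np.polyfit(dense[tail], np.log(sim.C_nasal[tail]), 1)[0]
        assert lam_n == pytest.approx(lam_p, rel=0.02)


class TestSuperposition:
    def test_two_doses(self, phys, us, nasal_frac):
        single = Regimen.single_dose(6e4)
        multi = Regimen(events=(DoseEvent(0.0, "intranasal", 6e4),
                                DoseEvent(12.0, "intranasal", 6e4)))
        assert superpose_check(phys, us, nasal_frac, single, multi) < 1e-6

    def test_bid_train(self, phys, us, nasal_frac, bid_regimen):
        single = Regimen.single_dose(6e4)
        assert superpose_check(phys, us, nasal_frac, single, bid_regimen) < 1e-6

    def test_self_identity(self, phys, us, nasal_frac):
        single = Regimen.single_dose(6e4)
        assert superpose_check(phys, us, nasal_frac, single, single) < 1e-12
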