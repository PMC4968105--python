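"""Deterministic model: dynamics, steady state, post-processing."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from bispec import ParameterError
from bispec import ode
from bispec.ode import (
    SurfaceState,
    binding_curve,
    effective_avidity,
    equilibrium_composition_curve,
    half_life,
    rhs,
    simulate_binding,
    simulate_dissociation,
    steady_state,
    to_mfi,
    wash_correction,
)
from bispec.params import AssayConfig
from bispec.rates import close_rate_set


def no_crosslink(k):
    """Variant with the surface reactions disabled (monovalent limit)."""
    return k.replace(k3=0.0, k4=0.0, k_neg3=0.0, k_neg4=0.0)


class TestRhs:
    def test_empty_system_is_fixed_point(self, variants, cells):
        cell = cells["dual_positive"]
        s = SurfaceState(0, 0, 0, cell.total_surface_conc("T1"),
                         cell.total_surface_conc("T2"), 0.0)
        assert rhs(s, variants["parent"]) == (0.0, 0.0, 0.0)

    def test_saturated_ternary_decay_rate(self, variants, cells):
        # all targets cross-linked, no antibody: only the two ternary
        # dissociation terms survive in d[AT1T2]/dt
        k = variants["parent"]
        cell = cells["dual_positive"]
        T1 = cell.total_surface_conc("T1")
        T2 = cell.total_surface_conc("T2")
        C = min(T1, T2)
        s = SurfaceState(0.0, T2 - C, C, T1, T2, 0.0)  # T2 excess monovalent
        s0 = SurfaceState(0.0, 0.0, C, T1, T2, 0.0)
        dC = rhs(s0, k)[2]
        assert dC == pytest.approx(-(k.k_neg3 + k.k_neg4) * C, rel=1e-12)

    def test_finite_difference_matches_rhs(self, variants, cells):
        # 4th-order central differences of a tightly integrated trajectory
        # (after the fast cross-linking transient) reproduce the analytic
        # right-hand side
        k = variants["parent"]
        cell = cells["dual_positive"]
        T1 = cell.total_surface_conc("T1")
        T2 = cell.total_surface_conc("T2")
        A = 1e-9
        ts = np.linspace(5, 50, 2001)
        sol = solve_ivp(lambda t, y: ode._rhs_arrays(y, k, A, T1, T2),
                        (0, 50), np.zeros(3), method="LSODA",
                        jac=lambda t, y: ode._jac_arrays(y, k, A, T1, T2),
                        t_eval=ts, rtol=1e-12, atol=1e-26)
        y = sol.y
        dt = ts[1] - ts[0]
        d4 = (-y[:, 4:] + 8 * y[:, 3:-1] - 8 * y[:, 1:-3] + y[:, :-4]) / (12 * dt)
        exact = np.array([ode._rhs_arrays(y[:, i], k, A, T1, T2)
                          for i in range(2, y.shape[1] - 2)]).T
        assert np.max(np.abs(d4 - exact) / np.abs(exact)) < 1e-6

    def test_inconsistent_state_rejected(self, variants, cells):
        cell = cells["dual_positive"]
        T1 = cell.total_surface_conc("T1")
        with pytest.raises(ParameterError):
            SurfaceState(T1, 0.0, T1, T1, cell.total_surface_conc("T2"), 0.0)


class TestSimulateBinding:
    def test_zero_antibody_stays_zero(self, variants, cells):
        tc = simulate_binding(variants["parent"], cells["dual_positive"],
                              0.0, 3600.0)
        assert np.all(tc.total_bound == 0.0)

    def test_monovalent_limit_reaches_langmuir(self, variants, cells):
        k = no_crosslink(variants["parent"])
        cell = cells["dual_positive"]
        A = k.Kd1  # half-saturates the CD4 arm
        tc = simulate_binding(k, cell, A, 3600.0 * 50)
        T1 = cell.total_surface_conc("T1")
        T2 = cell.total_surface_conc("T2")
        assert tc.AT1[-1] == pytest.approx(T1 / 2, rel=1e-3)
        assert tc.AT2[-1] == pytest.approx(T2 * A / (A + k.Kd2), rel=1e-3)

    def test_one_hour_reaches_steady_state_at_10nM(self, variants, cells):
        k = variants["parent"]
        cell = cells["dual_positive"]
        tc = simulate_binding(k, cell, 1e-8, 3600.0)
        ss = steady_state(k, cell, 1e-8)
        assert tc.total_bound[-1] == pytest.approx(ss.total_bound, rel=0.02)

    @pytest.mark.parametrize("A", [1e-11, 1e-9, 1e-7])
    def test_conservation_and_nonnegativity(self, variants, cells, A):
        k = variants["VkR94A+VhY99A"]
        cell = cells["dual_positive"]
        tc = simulate_binding(k, cell, A, 3600.0)
        T1 = cell.total_surface_conc("T1")
        T2 = cell.total_surface_conc("T2")
        assert np.all(tc.AT1 >= 0) and np.all(tc.AT2 >= 0) and np.all(tc.AT1T2 >= 0)
        free1 = T1 - tc.AT1 - tc.AT1T2
        free2 = T2 - tc.AT2 - tc.AT1T2
        assert np.min(free1) > -1e-8 * T1
        assert np.min(free2) > -1e-8 * T2


class TestSteadyState:
    def test_zero_antibody(self, variants, cells):
        s = steady_state(variants["parent"], cells["dual_positive"], 0.0)
        assert s.total_bound == 0.0

    def test_monovalent_limit_closed_form(self, variants, cells):
        k = no_crosslink(variants["parent"])
        cell = cells["dual_positive"]
        A = 3e-9
        s = steady_state(k, cell, A)
        T1 = cell.total_surface_conc("T1")
        T2 = cell.total_surface_conc("T2")
        assert s.AT1 == pytest.approx(T1 * A / (A + k.Kd1), rel=1e-9)
        assert s.AT2 == pytest.approx(T2 * A / (A + k.Kd2), rel=1e-9)

    def test_matches_long_integration_at_1pM(self, variants, cells):
        k = variants["parent"]
        cell = cells["dual_positive"]
        s = steady_state(k, cell, 1e-12)
        tc = simulate_binding(k, cell, 1e-12, 1e4 * 3600.0)
        assert tc.AT1T2[-1] == pytest.approx(s.AT1T2, rel=0.01)

    def test_detailed_balance_fluxes(self, variants, cells):
        k = variants["parent"]
        cell = cells["dual_positive"]
        A = 1e-8
        s = steady_state(k, cell, A)
        pairs = [
            (k.k1 * A * s.T1_free, k.k_neg1 * s.AT1),
            (k.k2 * A * s.T2_free, k.k_neg2 * s.AT2),
            (k.k3 * s.AT1 * s.T2_free, k.k_neg3 * s.AT1T2),
            (k.k4 * s.AT2 * s.T1_free, k.k_neg4 * s.AT1T2),
        ]
        for fwd, back in pairs:
            assert abs(fwd - back) <= 1e-6 * fwd


class TestDissociation:
    def test_empty_initial_state_stays_zero(self, variants, cells):
        cell = cells["dual_positive"]
        init = SurfaceState(0, 0, 0, cell.total_surface_conc("T1"),
                            cell.total_surface_conc("T2"), 0.0)
        tc = simulate_dissociation(variants["parent"], cell, init, 100.0)
        assert np.all(tc.total_bound == 0.0)

    def test_pure_monovalent_decay_is_exponential(self, variants, cells):
        k = no_crosslink(variants["parent"])
        cell = cells["dual_positive"]
        T1 = cell.total_surface_conc("T1")
        init = SurfaceState(T1 * 0.8, 0, 0, T1,
                            cell.total_surface_conc("T2"), 0.0)
        tc = simulate_dissociation(k, cell, init, 4 * 3600.0)
        hl = half_life(tc, "AT1")
        assert hl == pytest.approx(math.log(2) / k.k_neg1, rel=1e-3)

    def test_ternary_dissociation_far_slower_than_monovalent(self, variants, cells):
        # cross-linked antibody of the weakest variant persists orders of
        # magnitude longer than its 19 s monovalent half-life, and the
        # decay decelerates (non-first-order kinetics)
        k = variants["VkR94A+VhY99A"]
        cell = cells["dual_positive"]
        T1 = cell.total_surface_conc("T1")
        T2 = cell.total_surface_conc("T2")
        init = SurfaceState(0, 0, min(T1, T2), T1, T2, 0.0)
        tc = simulate_dissociation(k, cell, init, 2e3 * 3600.0, n_out=800)
        hl = half_life(tc)
        assert hl is not None
        assert hl > 1000.0 * (math.log(2) / k.k_neg1)
        frac = tc.total_bound / tc.total_bound[0]
        i80 = int(np.argmin(np.abs(frac - 0.8)))
        i30 = int(np.argmin(np.abs(frac - 0.3)))

        def log_slope(i):
            return -(np.log(frac[i + 1]) - np.log(frac[i - 1])) / (
                tc.times[i + 1] - tc.times[i - 1])

        assert log_slope(i80) > log_slope(i30)

    def test_total_bound_nonincreasing(self, variants, cells):
        k = variants["parent"]
        cell = cells["dual_positive"]
        T1 = cell.total_surface_conc("T1")
        T2 = cell.total_surface_conc("T2")
        init = SurfaceState(0, T2 - T1, T1, T1, T2, 0.0)
        tc = simulate_dissociation(k, cell, init, 3600.0 * 100)
        assert np.all(np.diff(tc.total_bound) <= 1e-10 * tc.total_bound[0])


class TestHalfLife:
    def test_exponential_decay(self, variants, cells):
        k = no_crosslink(variants["parent"])  # k_neg2 = 4.9e-3 1/s
        cell = cells["cd70_only"]
        T2 = cell.total_surface_conc("T2")
        init = SurfaceState(0, T2 * 0.9, 0, 0.0, T2, 0.0)
        tc = simulate_dissociation(k, cell, init, 1200.0, n_out=600)
        assert half_life(tc) == pytest.approx(141.4, rel=5e-3)

    def test_constant_trajectory_not_reached(self, variants, cells):
        k = variants["parent"].replace(k_neg1=0.0, k_neg3=0.0)
        cell = cells["cd4_only"]
        T1 = cell.total_surface_conc("T1")
        init = SurfaceState(T1 * 0.5, 0, 0, T1,
                            cell.total_surface_conc("T2"), 0.0)
        tc = simulate_dissociation(k, cell, init, 100.0)
        assert half_life(tc, "AT1") is None

    def test_invariant_under_grid_refinement(self, variants, cells):
        k = no_crosslink(variants["parent"])
        cell = cells["cd4_only"]
        T1 = cell.total_surface_conc("T1")
        init = SurfaceState(T1 * 0.5, 0, 0, T1,
                            cell.total_surface_conc("T2"), 0.0)
        coarse = simulate_dissociation(k, cell, init, 4 * 3600.0, n_out=100)
        fine = simulate_dissociation(k, cell, init, 4 * 3600.0, n_out=800)
        h1, h2 = half_life(coarse, "AT1"), half_life(fine, "AT1")
        assert abs(h1 - h2) / h2 < 0.005

    def test_increasing_observable_rejected(self, variants, cells):
        tc = simulate_binding(variants["parent"], cells["dual_positive"],
                              1e-8, 600.0)
        with pytest.raises(ParameterError):
            half_life(tc)


class TestWashAndMfi:
    def test_zero_wash_is_identity(self, variants, cells):
        cell = cells["dual_positive"]
        s = SurfaceState(1e-13, 2e-13, 3e-12, cell.total_surface_conc("T1"),
                         cell.total_surface_conc("T2"), 0.0)
        w = wash_correction(s, variants["parent"], 0.0)
        assert (w.AT1, w.AT2, w.AT1T2) == (s.AT1, s.AT2, s.AT1T2)

    def test_survival_factors(self, variants, cells):
        k = variants["parent"]
        cell = cells["dual_positive"]
        s = SurfaceState(1e-13, 1e-13, 1e-12, cell.total_surface_conc("T1"),
                         cell.total_surface_conc("T2"), 0.0)
        w = wash_correction(s, k, 240.0)
        assert w.AT2 / s.AT2 == pytest.approx(0.3085, rel=1e-3)
        assert w.AT1 / s.AT1 == pytest.approx(0.9395, rel=1e-3)
        assert w.AT1T2 == s.AT1T2

    def test_mfi_conversion(self):
        assay = AssayConfig()
        assert to_mfi(1180.0, assay) == pytest.approx(1000.0)
        assert to_mfi(0.0, assay) == 0.0
        assert to_mfi(123.4, assay) * assay.mfi_conversion == pytest.approx(123.4)


class TestBindingCurve:
    def test_cd4_only_is_langmuir_times_wash_survival(self, variants, cells, assay):
        k = variants["parent"]
        cell = cells["cd4_only"]
        conc = np.array([1e-7])
        unwashed = binding_curve(k, cell, assay, apply_wash=False,
                                 concentrations_M=conc)
        langmuir = 68000 * 1e-7 / (1e-7 + k.Kd1)
        assert unwashed.bound_total[0] == pytest.approx(langmuir, rel=0.02)
        washed = binding_curve(k, cell, assay, apply_wash=True,
                               concentrations_M=conc)
        survival = math.exp(-k.k_neg1 * assay.wash_time_s)
        assert washed.bound_total[0] == pytest.approx(
            unwashed.bound_total[0] * survival, rel=1e-9)

    def test_monotone_in_concentration_all_variants_and_cells(
            self, variants, cells, assay):
        conc = np.geomspace(1e-11, 1e-7, 7)
        for k in variants.values():
            for cell in cells.values():
                c = binding_curve(k, cell, assay, concentrations_M=conc)
                assert np.all(np.diff(c.bound_total)
                              >= -1e-9 * c.bound_total.max())

    def test_cell_type_ordering_for_parent(self, variants, cells, assay):
        conc = np.geomspace(1e-11, 1e-7, 7)
        k = variants["parent"]
        dual = binding_curve(k, cells["dual_positive"], assay,
                             concentrations_M=conc).bound_total
        cd4 = binding_curve(k, cells["cd4_only"], assay,
                            concentrations_M=conc).bound_total
        cd70 = binding_curve(k, cells["cd70_only"], assay,
                             concentrations_M=conc).bound_total
        assert np.all(dual >= cd4 * (1 - 1e-9))
        assert np.all(cd4 >= cd70 * (1 - 1e-9))

    def test_empty_grid_rejected(self, variants, cells, assay):
        with pytest.raises(ParameterError):
            binding_curve(variants["parent"], cells["dual_positive"], assay,
                          concentrations_M=[])

    def test_anchor_choice_does_not_change_curves(self, variants, cells, assay):
        # surface off-rate anchoring (CD70 vs CD4 arm) is immaterial
        k = variants["parent"]
        alt = close_rate_set(k.k1, k.k_neg1, k.k2, k.k_neg2, k.k3,
                             anchor="cd4", variant_name="alt")
        conc = np.geomspace(1e-11, 1e-7, 7)
        c1 = binding_curve(k, cells["dual_positive"], assay,
                           concentrations_M=conc).bound_total
        c2 = binding_curve(alt, cells["dual_positive"], assay,
                           concentrations_M=conc).bound_total
        assert np.max(np.abs(c1 - c2) / c1) < 0.05


class TestEquilibriumComposition:
    def test_langmuir_limit_across_six_decades(self, variants, cells):
        k = no_crosslink(variants["parent"])
        conc = np.geomspace(1e-12, 1e-6, 13)
        eq = equilibrium_composition_curve(k, cells["cd4_only"], conc)
        langmuir = 68000 * conc / (conc + k.Kd1)
        assert np.max(np.abs(eq.bound_total - langmuir) / langmuir) < 1e-3

    def test_ternary_dominates_at_10nM(self, variants, cells):
        conc = np.array([1e-8])
        eq = equilibrium_composition_curve(variants["parent"],
                                           cells["dual_positive"], conc)
        assert eq.bound_AT1T2[0] > 10 * (eq.bound_AT1[0] + eq.bound_AT2[0])

    def test_binary_accumulates_at_micromolar(self, variants, cells):
        conc = np.array([1e-8, 1e-6, 1e-4])
        eq = equilibrium_composition_curve(variants["parent"],
                                           cells["dual_positive"], conc)
        mono = eq.bound_AT1 + eq.bound_AT2
        assert mono[2] > mono[0]
        assert eq.bound_AT1T2[2] < eq.bound_AT1T2.max()

    def test_cd70_only_is_monovalent_isotherm(self, variants, cells):
        k = variants["parent"]
        conc = np.geomspace(1e-10, 1e-6, 9)
        eq = equilibrium_composition_curve(k, cells["cd70_only"], conc)
        langmuir = 55000 * conc / (conc + k.Kd2)
        assert np.max(np.abs(eq.bound_total - langmuir) / langmuir) < 1e-3


class TestEffectiveAvidity:
    def test_parent_enhancement_about_four_logs(self, variants, cells):
        kd_eff, enh = effective_avidity(variants["parent"],
                                        cells["dual_positive"])
        assert kd_eff < variants["parent"].Kd1
        assert enh == pytest.approx(4.0, abs=0.5)

    def test_no_crosslink_no_enhancement(self, variants, cells):
        # without cross-linking Kd_eff is set by the sum of the two
        # monovalent isotherms: near min(Kd1, Kd2), exactly at the
        # closed-form half-max of AT1 + AT2 (the lower-affinity arm drags
        # it slightly above Kd1)
        from scipy.optimize import brentq
        k = no_crosslink(variants["parent"])
        cell = cells["dual_positive"]
        kd_eff, enh = effective_avidity(k, cell)
        T1, T2 = 82000.0, 92000.0

        def total(A):
            return T1 * A / (A + k.Kd1) + T2 * A / (A + k.Kd2)

        expected = brentq(lambda A: total(A) - 0.5 * total(1e-8), 1e-16, 1e-8)
        assert kd_eff == pytest.approx(expected, rel=1e-3)
        assert abs(enh) < 0.2
        assert kd_eff > variants["parent"].Kd1  # no enhancement, slight penalty

    def test_monotone_in_surface_rate(self, variants, cells):
        k = variants["parent"]
        enh = []
        for f in (0.1, 1.0, 10.0):
            kk = close_rate_set(k.k1, k.k_neg1, k.k2, k.k_neg2, k.k3 * f,
                                variant_name=f"x{f}")
            enh.append(effective_avidity(kk, cells["dual_positive"])[1])
        assert enh[0] < enh[1] < enh[2]


class TestFiniteBath:
    def test_depletion_lowers_binding(self, variants, cells):
        k = variants["parent"]
        cell = cells["dual_positive"]
        # a bath holding barely more antibody than the targets can absorb
        small_volume = 1e-12  # dm^3/cell; 1e-9 M * V * N_A ~ 6e2 molecules
        const = simulate_binding(k, cell, 1e-9, 3600.0)
        finite = simulate_binding(k, cell, 1e-9, 3600.0,
                                  constant_antibody=False,
                                  solution_volume_dm3_per_cell=small_volume)
        assert finite.total_bound[-1] < const.total_bound[-1]
        assert finite.A_solution[-1] < 1e-9

    def test_large_bath_approaches_constant_mode(self, variants, cells):
        k = variants["parent"]
        cell = cells["dual_positive"]
        const = simulate_binding(k, cell, 1e-8, 1800.0)
        finite = simulate_binding(k, cell, 1e-8, 1800.0,
                                  constant_antibody=False,
                                  solution_volume_dm3_per_cell=1e-4)
        assert finite.total_bound[-1] == pytest.approx(
            const.total_bound[-1], rel=1e-3)
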