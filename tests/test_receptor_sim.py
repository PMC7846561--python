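"""Glutamate transient, EPSP template, Mg block and receptor dynamics.

Heavier scenario-level orderings (full grids, Mg-free delay series) live in
the acceptance suite; here each operation is checked against closed-form
oracles and conservation laws at short durations.
"""

import numpy as np
import pytest

from nanosyn.receptor_sim import (
    AVOGADRO_PER_UM3_UM,
    ClusterGeometry,
    GlutamateParams,
    MgBlockParams,
    Scenario,
    ampa_scheme,
    epsp_template,
    glutamate_conc,
    integrate_meanfield,
    load_default_rates,
    mg_rates,
    nmda_scheme,
    simulate_scenario,
    voltage_trace,
)


class TestGlutamateConc:
    def test_mass_conserved_without_clearance(self):
        p = GlutamateParams(tau_clear_ms=1e12)
        r_nm = np.linspace(0, 3000, 30001)
        for t in (0.01, 0.1, 1.0):
            c_um3 = glutamate_conc(r_nm, t, p) * AVOGADRO_PER_UM3_UM
            h_um = p.cleft_height_nm / 1000.0
            total = np.trapezoid(c_um3 * 2 * np.pi * (r_nm / 1000), r_nm / 1000) * h_um
            assert total == pytest.approx(p.n_glu, rel=1e-3)

    def test_monotone_decay_at_origin(self):
        t = np.linspace(0.001, 5, 2000)
        c = glutamate_conc(0.0, t)
        assert np.all(np.diff(c) < 0)

    def test_peak_time_matches_calculus(self):
        # dC/dt = 0 at t* = r^2 / (4D) when clearance is negligible
        p = GlutamateParams(tau_clear_ms=1e12)
        t = np.linspace(1e-4, 0.1, 100_000)
        c = glutamate_conc(100.0, t, p)
        t_star = (100.0 / 1000.0) ** 2 / (4 * p.D_um2_per_ms)
        assert t[np.argmax(c)] == pytest.approx(t_star, rel=1e-3)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            glutamate_conc(0.0, 0.0)


class TestEPSPTemplate:
    def test_peak_amplitude_and_two_thirds_decline(self):
        t = np.linspace(0, 15, 15001)
        v = epsp_template(t)
        assert v.max() == pytest.approx(25.0)
        assert t[np.argmax(v)] == pytest.approx(4.0)
        assert epsp_template(8.0) == pytest.approx(25.0 * 2 / 3)

    def test_zero_outside_support(self):
        assert epsp_template(-1.0) == 0.0
        assert epsp_template(0.0) == 0.0
        assert epsp_template(15.0) == 0.0
        assert epsp_template(40.0) == 0.0

    def test_near_rest_by_ten_ms(self):
        assert epsp_template(10.0) == pytest.approx(2.0)


class TestVoltageTrace:
    def test_clamped_modes(self):
        sc = Scenario(events=[], voltage_mode="clamped_depol", depol_mV=45.0)
        v = voltage_trace(sc)(np.array([0.0, 10.0]))
        assert np.all(v == -25.0)
        sc = Scenario(events=[], voltage_mode="clamped_rest")
        assert np.all(voltage_trace(sc)(np.array([3.0])) == -70.0)

    def test_epsp_no_events_is_rest(self):
        sc = Scenario(events=[], voltage_mode="epsp_coupled")
        assert np.all(voltage_trace(sc)(np.linspace(0, 50, 100)) == -70.0)

    def test_two_event_summation_and_cap(self):
        sc1 = Scenario(events=[(0.0, "AMPA_cluster")], voltage_mode="epsp_coupled")
        sc2 = Scenario(
            events=[(0.0, "AMPA_cluster"), (5.0, "AMPA_cluster")],
            voltage_mode="epsp_coupled",
        )
        t = np.linspace(0, 25, 2501)
        v1, v2 = voltage_trace(sc1)(t), voltage_trace(sc2)(t)
        assert v2.max() > v1.max()
        assert v2.max() <= -70.0 + 45.0 + 1e-9

    def test_amplitude_attenuates_with_distance_from_ampa_cluster(self):
        t = np.linspace(0, 15, 1501)
        near = Scenario(events=[(0.0, "AMPA_cluster")], voltage_mode="epsp_coupled")
        far = Scenario(events=[(0.0, "NMDA_cluster")], voltage_mode="epsp_coupled")
        v_near = voltage_trace(near)(t).max() + 70.0
        v_far = voltage_trace(far)(t).max() + 70.0
        assert v_near == pytest.approx(25.0)
        assert v_far == pytest.approx(12.5, rel=0.01)  # half at 100 nm


class TestMgBlock:
    def test_zero_mv_rates_are_base_constants(self):
        p = MgBlockParams()
        kb, ku = mg_rates(0.0, p)
        assert kb == pytest.approx(p.k_block0_per_mM_ms * p.mg_mM)
        assert ku == pytest.approx(p.k_unblock0_per_ms)

    def test_blocked_fraction_decreases_with_depolarization(self):
        v = np.linspace(-90, 10, 101)
        kb, ku = mg_rates(v)
        frac = kb / (kb + ku)
        assert np.all(np.diff(frac) < 0)

    def test_hand_computed_fractions(self):
        p = MgBlockParams()
        for v in (-70.0, -25.0):
            kb = p.k_block0_per_mM_ms * p.mg_mM * np.exp(-v / p.v_block_slope_mV)
            ku = p.k_unblock0_per_ms * np.exp(v / p.v_unblock_slope_mV)
            kb2, ku2 = mg_rates(v, p)
            assert (kb2, ku2) == (pytest.approx(kb), pytest.approx(ku))


class TestMeanfieldIntegration:
    def test_zero_glutamate_stays_at_rest(self):
        scheme = ampa_scheme()
        t, occ = integrate_meanfield(
            scheme, lambda t: np.array([0.0]), lambda t: np.array([-70.0]),
            duration_ms=5.0, dt_ms=0.002,
        )
        assert np.allclose(occ[:, 0, 0], 1.0)

    def test_saturating_ligand_equilibrium(self):
        # 2-state scheme C <-> O at saturating ligand: open frac = b/(a+b)
        from nanosyn.receptor_sim import KineticScheme

        scheme = KineticScheme(
            "toy", ["C", "O"],
            [("C", "O", "glu", 0.001), ("O", "C", "const", 2.0)],
        )
        glu = 10_000.0  # effective opening rate 10/ms
        t, occ = integrate_meanfield(
            scheme, lambda t: np.array([glu]), lambda t: np.array([-70.0]),
            duration_ms=10.0, dt_ms=0.002,
        )
        assert occ[-1, 0, 1] == pytest.approx(10.0 / 12.0, rel=1e-4)

    def test_deactivation_eigenvalue(self):
        # after ligand removal a C <-> O toy decays at rate a (single eigenmode)
        from nanosyn.receptor_sim import KineticScheme

        scheme = KineticScheme(
            "toy", ["C", "O"], [("O", "C", "const", 0.5)],
        )
        t, occ = integrate_meanfield(
            scheme, lambda t: np.array([0.0]), lambda t: np.array([-70.0]),
            duration_ms=8.0, dt_ms=0.002, p0=np.array([[0.0, 1.0]]),
        )
        assert occ[-1, 0, 1] == pytest.approx(np.exp(-0.5 * 8.0), rel=1e-4)

    def test_occupancy_sums_to_one(self):
        sc = Scenario(events=[(0.0, "AMPA_cluster")], voltage_mode="clamped_rest",
                      duration_ms=5.0, dt_us=1)
        geom = ClusterGeometry()
        from nanosyn.receptor_sim import _conc_fn

        conc = _conc_fn(sc, geom, np.array(geom.ampa.position), GlutamateParams())
        t, occ = integrate_meanfield(
            nmda_scheme(), lambda t: np.atleast_1d(conc(t)),
            lambda t: np.array([-70.0]), 5.0, 0.001,
        )
        assert np.allclose(occ.sum(axis=2), 1.0, atol=1e-9)
        assert np.all(occ >= 0)

    def test_too_large_dt_rejected(self):
        with pytest.raises(ValueError):
            integrate_meanfield(
                ampa_scheme(), lambda t: np.array([0.0]),
                lambda t: np.array([-70.0]), 1.0, 0.05,
            )


class TestScenarios:
    def test_no_release_no_opening(self):
        sc = Scenario(events=[], voltage_mode="clamped_rest", duration_ms=10,
                      dt_us=2)
        res = simulate_scenario(sc)
        assert res.auc["AMPA"] == 0.0 and res.auc["NMDA"] == 0.0

    def test_release_at_ampa_cluster_favors_ampa_at_rest(self):
        sc = Scenario(events=[(0.0, "AMPA_cluster")], voltage_mode="clamped_rest",
                      duration_ms=20, dt_us=2)
        res = simulate_scenario(sc)
        assert res.peak["AMPA"] > 5 * res.peak["NMDA"]

    def test_ampa_desensitization_paired_pulse(self):
        sc = Scenario(
            events=[(0.0, "AMPA_cluster"), (8.0, "AMPA_cluster")],
            voltage_mode="clamped_rest", duration_ms=25, dt_us=2,
        )
        res = simulate_scenario(sc, kinds=["AMPA"])
        t, tr = res.time_ms, res.open_count["AMPA"]
        assert tr[t >= 8.0].max() < tr[t < 8.0].max()

    def test_stochastic_matches_meanfield(self):
        sc = Scenario(events=[(0.0, "AMPA_cluster")], voltage_mode="clamped_rest",
                      duration_ms=25, dt_us=2, trials=48, seed=4)
        mf = simulate_scenario(sc, kinds=["AMPA"])
        st = simulate_scenario(sc, mode="stochastic", kinds=["AMPA"])
        se = st.per_trial_auc["AMPA"].std(ddof=1) / np.sqrt(sc.trials)
        assert abs(mf.auc["AMPA"] - st.auc["AMPA"]) < 3 * se

    def test_event_outside_duration_rejected(self):
        with pytest.raises(ValueError):
            Scenario(events=[(300.0, "AMPA_cluster")], duration_ms=250).validate()

    def test_random_site_reproducible(self):
        sc = Scenario(events=[(0.0, "random")], voltage_mode="clamped_rest",
                      duration_ms=5, dt_us=2, seed=7)
        r1 = simulate_scenario(sc, kinds=["AMPA"]).auc["AMPA"]
        r2 = simulate_scenario(sc, kinds=["AMPA"]).auc["AMPA"]
        assert r1 == r2


def test_default_rates_yaml_loads():
    rates = load_default_rates()
    assert set(rates) >= {"ampa", "nmda", "mg_block", "glutamate"}
    assert rates["glutamate"]["n_glu"] == 2000.0
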