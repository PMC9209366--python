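"""Cabin balance equations: RHS, closed-form steady states, transients."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cabinaer as ca
from conftest import flat_filter


def _flat(scenario, eta):
    return replace(scenario, filter_spec=flat_filter(eta), eta_mode="upper")


class TestParticleRHS:
    def test_zero_everywhere(self, simple_scenario, grid):
        s = replace(simple_scenario,
                    cenv_particles=ca.SizeDistribution(np.zeros(25), "count", grid))
        np.testing.assert_allclose(ca.particle_rhs(np.zeros(25), s), 0.0)

    def test_hand_checked_value(self, simple_scenario):
        # (Qoa+Qps)(1-eta) Cenv / Vcabin with empty cabin, no deposition
        s = _flat(replace(simple_scenario,
                          vehicle=ca.VehicleSpec(vcabin_m3=4.1, beta_per_h=0.0)), 0.5)
        # re-add Qdep = 0.002 m3/s as an explicit beta
        beta = 0.002 * 3600.0 / 4.1
        s = replace(s, vehicle=ca.VehicleSpec(vcabin_m3=4.1, beta_per_h=beta))
        rhs = ca.particle_rhs(np.zeros(25), s)
        np.testing.assert_allclose(rhs, 1.25 / 4.1, rtol=1e-12)

    def test_vanishes_at_steady_state(self, simple_scenario):
        s = _flat(simple_scenario, 0.4)
        css = ca.steady_state_particles(s)
        np.testing.assert_allclose(ca.particle_rhs(css.values, s), 0.0,
                                   atol=1e-12)

    def test_average_mode_needs_explicit_bound(self, simple_scenario):
        s = replace(simple_scenario, eta_mode="average")
        with pytest.raises(ValueError, match="average"):
            ca.particle_rhs(np.zeros(25), s)


class TestSteadyStateParticles:
    def test_perfect_filter_empties_cabin(self, simple_scenario):
        css = ca.steady_state_particles(_flat(simple_scenario, 1.0))
        np.testing.assert_allclose(css.values, 0.0)

    def test_no_removal_equalizes(self, simple_scenario):
        s = _flat(replace(simple_scenario,
                          vehicle=ca.VehicleSpec(vcabin_m3=4.1, beta_per_h=0.0)), 0.0)
        css = ca.steady_state_particles(s)
        np.testing.assert_allclose(css.values,
                                   simple_scenario.cenv_particles.values,
                                   rtol=1e-12)

    def test_hand_checked_value(self, simple_scenario):
        # Cin = (Qoa+Qps)(1-eta) Cenv / (Qoa+Qps+Qdep+Qrec eta) = 39.0625
        beta = 0.002 * 3600.0 / 4.1
        s = _flat(replace(simple_scenario,
                          vehicle=ca.VehicleSpec(vcabin_m3=4.1, beta_per_h=beta)), 0.5)
        css = ca.steady_state_particles(s)
        np.testing.assert_allclose(css.values, 39.0625, rtol=1e-12)
        assert ca.io_ratio(css.values[0], 100.0) == pytest.approx(0.390625)

    def test_average_mode_is_mean_of_bound_solutions(self, simple_scenario):
        s = replace(simple_scenario, eta_mode="average")
        avg = ca.steady_state_particles(s)
        up = ca.steady_state_particles(s, "upper")
        lo = ca.steady_state_particles(s, "lower")
        np.testing.assert_allclose(avg.values, 0.5 * (up.values + lo.values))
        # the steady state is nonlinear in eta: averaging solutions differs
        # from solving at the mean efficiency
        fs = s.filter_spec
        mean_eta = 0.5 * (fs.eta_upper + fs.eta_lower)
        s_mean = replace(s, eta_mode="upper", filter_spec=replace(
            fs, eta_upper=mean_eta, eta_lower=mean_eta))
        mid = ca.steady_state_particles(s_mean)
        assert not np.allclose(avg.values, mid.values, rtol=1e-6)

    def test_all_loss_zero_channel_named(self, simple_scenario, grid):
        # perfectly sealed (frev=0) parked vehicle with the fan off
        s = replace(
            simple_scenario,
            vehicle=ca.VehicleSpec(vcabin_m3=4.1, beta_per_h=0.0, frev=0.0),
            vent=ca.VentilationState(0.0, 0.0, 0.0, qps_m3s=0.0),
        )
        with pytest.raises(ValueError, match="10"):
            ca.steady_state_particles(_flat(s, 0.0))

    def test_no_source_bound_io_below_one(self):
        # with alpha <= 1 and eta >= 0, cabin never exceeds outdoors
        for scenario in ca.random_scenarios(20, seed=7):
            css = ca.steady_state_particles(scenario)
            assert np.all(css.values <= scenario.cenv_particles.values + 1e-12)

    def test_linear_in_outdoor_concentration(self, simple_scenario):
        s = replace(simple_scenario, eta_mode="average")
        doubled = replace(s, cenv_particles=2.0 * s.cenv_particles)
        np.testing.assert_allclose(ca.steady_state_particles(doubled).values,
                                   2.0 * ca.steady_state_particles(s).values,
                                   rtol=1e-12)

    @pytest.mark.parametrize("knob", ["eta", "beta", "qrec"])
    def test_monotone_in_removal_knobs(self, simple_scenario, knob):
        values = []
        for level in (0.1, 0.4, 0.8):
            s = _flat(simple_scenario, level if knob == "eta" else 0.5)
            if knob == "beta":
                s = replace(s, vehicle=replace(s.vehicle, beta_per_h=level * 12.0))
            if knob == "qrec":
                s = replace(s, vent=replace(s.vent, qrec_m3s=level * 0.05))
            values.append(ca.steady_state_particles(s).values[0])
        assert values[0] >= values[1] >= values[2]


class TestCO2:
    def test_rhs_zero_without_source_at_equilibrium(self, simple_scenario):
        s = replace(simple_scenario, occupants=ca.OccupantLoad(n=0))
        assert ca.co2_rhs(716.0, s) == pytest.approx(0.0)

    def test_rhs_hand_checked(self, grid):
        # 2 occupants breathing 6.5 L/min at 40000 ppm into 2.9 m3
        s = ca.Scenario(
            vehicle=ca.VehicleSpec(vcabin_m3=2.9, beta_per_h=1.0),
            vent=ca.VentilationState(qoa_m3s=0.02, vspeed_kmh=0.0, qps_m3s=0.0),
            filter_spec=ca.load_filter_fixture("new", "off"),
            occupants=ca.OccupantLoad(n=2, vbr_lpm=6.5, cbr_ppm=40000.0),
            cenv_particles=ca.SizeDistribution(np.zeros(25), "count", grid),
            cenv_co2_ppm=716.0,
        )
        assert ca.co2_rhs(716.0, s) == pytest.approx(2.989, rel=1e-3)

    def test_steady_state_no_source(self, simple_scenario):
        s = replace(simple_scenario, occupants=ca.OccupantLoad(n=0))
        assert ca.steady_state_co2(s) == pytest.approx(716.0)

    def test_steady_state_hand_checked(self, simple_scenario):
        s = replace(simple_scenario,
                    vent=ca.VentilationState(qoa_m3s=0.02, qps_m3s=0.0),
                    occupants=ca.OccupantLoad(n=2, vbr_lpm=6.5, cbr_ppm=40000.0))
        assert ca.steady_state_co2(s) == pytest.approx(1149.33, abs=0.01)

    def test_dilution_limit(self, simple_scenario):
        s = replace(simple_scenario,
                    vent=ca.VentilationState(qoa_m3s=500.0, qps_m3s=0.0))
        assert ca.steady_state_co2(s) == pytest.approx(716.0, abs=0.1)

    def test_full_recirculation_with_occupants_is_an_error(self, simple_scenario):
        s = replace(simple_scenario,
                    vehicle=replace(simple_scenario.vehicle, frev=0.0),
                    vent=ca.VentilationState(qoa_m3s=0.0, qrec_m3s=0.04,
                                             vspeed_kmh=0.0, qps_m3s=0.0))
        with pytest.raises(ValueError, match="transient"):
            ca.steady_state_co2(s)

    def test_monotone_in_recirculation_at_fixed_total_flow(self, simple_scenario):
        co2 = []
        for d in (0.0, 0.3, 0.5, 0.7):
            vent = ca.VentilationState.from_total_flow(0.04, d, qps_m3s=0.0)
            co2.append(ca.steady_state_co2(replace(simple_scenario, vent=vent)))
        assert co2 == sorted(co2)


class TestTransient:
    def test_starts_at_steady_state_stays_there(self, simple_scenario):
        s = _flat(simple_scenario, 0.5)
        css = ca.steady_state_particles(s)
        co2ss = ca.steady_state_co2(s)
        res = ca.transient_solve(s, np.linspace(0, 600, 11),
                                 cin0_particles=css, cin0_co2_ppm=co2ss)
        np.testing.assert_allclose(
            res.particles, np.tile(css.values, (len(res.t_s), 1)), rtol=1e-5)
        np.testing.assert_allclose(res.co2_ppm, co2ss, rtol=1e-6)

    def test_conservation_with_all_flows_zero(self, simple_scenario, grid):
        s = replace(
            simple_scenario,
            vehicle=ca.VehicleSpec(vcabin_m3=4.1, beta_per_h=0.0, frev=0.0),
            vent=ca.VentilationState(0.0, 0.0, 0.0, qps_m3s=0.0),
            occupants=ca.OccupantLoad(n=0),
        )
        init = ca.SizeDistribution(np.full(25, 42.0), "count", grid)
        res = ca.transient_solve(s, np.linspace(0, 600, 5),
                                 cin0_particles=init, cin0_co2_ppm=500.0)
        np.testing.assert_allclose(res.particles, 42.0, rtol=1e-9)
        np.testing.assert_allclose(res.co2_ppm, 500.0, rtol=1e-9)

    def test_co2_matches_analytic_exponential(self, simple_scenario):
        # linear ODE: Cin(t) = Css + (C0 - Css) exp(-Q t / V)
        s = replace(simple_scenario,
                    vent=ca.VentilationState(qoa_m3s=0.02, qps_m3s=0.0))
        t = np.linspace(0, 1200, 25)
        res = ca.transient_solve(s, t, cin0_co2_ppm=716.0)
        css = ca.steady_state_co2(s)
        q_over_v = 0.02 / s.vehicle.vcabin_m3
        analytic = css + (716.0 - css) * np.exp(-q_over_v * t)
        np.testing.assert_allclose(res.co2_ppm, analytic, rtol=1e-6)

    def test_converges_to_closed_form(self, simple_scenario):
        s = replace(simple_scenario, eta_mode="average")
        # ~15 residence times
        t_end = 15.0 * s.vehicle.vcabin_m3 / s.vent.qoa_m3s
        res = ca.transient_solve(s, np.array([0.0, t_end]))
        css = ca.steady_state_particles(s)
        np.testing.assert_allclose(res.particles[-1], css.values,
                                   rtol=1e-6, atol=1e-12)
        np.testing.assert_allclose(res.co2_ppm[-1], ca.steady_state_co2(s),
                                   rtol=1e-6)

    def test_fixed_point_iteration_oracle(self, simple_scenario):
        # brute-force forward-Euler fixed point of the particle balance
        s = _flat(simple_scenario, 0.35)
        cin = np.zeros(25)
        dt = 5.0
        for _ in range(20000):
            cin = cin + dt * ca.particle_rhs(cin, s)
        np.testing.assert_allclose(cin, ca.steady_state_particles(s).values,
                                   rtol=1e-8)

    def test_bad_time_grid_rejected(self, simple_scenario):
        with pytest.raises(ValueError):
            ca.transient_solve(simple_scenario, np.array([0.0, 0.0, 1.0]))


class TestIORatio:
    def test_identity_and_zero(self):
        assert ca.io_ratio(50.0, 50.0) == 1.0
        assert ca.io_ratio(0.0, 50.0) == 0.0

    def test_zero_outdoor_rejected(self):
        with pytest.raises(ValueError):
            ca.io_ratio(1.0, 0.0)
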