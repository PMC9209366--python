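"""Coupled cabin mass balances for size-resolved particles and CO2.

Both pollutants obey a well-mixed single-zone balance on the cabin volume.
Per size channel i (count N/cm^3 or mass ug/m^3 basis — the equation is
identical because all particles in a channel share one diameter and density):

    Vcabin dCin_i/dt = [(Qoa+Qps)(1-eta_i) + Qinf*alpha] * Cenv_i
                       - [Qoa+Qps+Qinf+Qdep_i+Qrec*eta_i] * Cin_i

Outside air and passive ventilation pass the filter (efficiency eta_i);
infiltrating air bypasses it but loses a fraction (1-alpha) of particles in
the cracks; recirculated air is re-filtered, contributing the loss term
Qrec*eta_i. Exfiltration is implicit in the outflow Qoa+Qps+Qinf.

CO2 (ppm) is a passive tracer — not filtered, not deposited — with an
occupant breath source N*Vbr*Cbr:

    Vcabin dCin/dt = (Qoa+Qps+Qinf) * (Cenv - Cin) + N*Vbr*Cbr

Recirculation is absent from the CO2 balance: recirculated air returns
unchanged. Both balances are linear, so the steady states have closed forms
and the transient solutions are exponentials toward them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .aerosol import (
    FilterSpec,
    OccupantLoad,
    SizeDistribution,
    VehicleSpec,
    aggregate,
    count_to_mass,
)
from .airflows import InfiltrationResult, VentilationState, deposition_flow, infiltration

ETA_MODES = ("upper", "lower", "average")


@dataclass
class CabinState:
    """Instantaneous cabin air state."""

    cin_particles: SizeDistribution
    cin_co2_ppm: float
    t_s: float = 0.0

    def __post_init__(self) -> None:
        if self.cin_co2_ppm < 0:
            raise ValueError("CO2 concentration must be non-negative")


@dataclass
class Scenario:
    """A complete, constant-condition operating scenario of the cabin model."""

    vehicle: VehicleSpec
    vent: VentilationState
    filter_spec: FilterSpec
    occupants: OccupantLoad
    cenv_particles: SizeDistribution
    cenv_co2_ppm: float
    eta_mode: str = "average"
    particle_density_kg_m3: float = 1000.0

    def __post_init__(self) -> None:
        if self.eta_mode not in ETA_MODES:
            raise ValueError(f"eta_mode must be one of {ETA_MODES}")
        if self.cenv_co2_ppm < 0:
            raise ValueError("outdoor CO2 must be non-negative")
        if self.particle_density_kg_m3 <= 0:
            raise ValueError("particle density must be positive")

    @property
    def qps_m3s(self) -> float:
        return self.vent.qps(self.vehicle)

    def infiltration_result(self) -> InfiltrationResult:
        return infiltration(
            self.vent.vspeed_kmh, self.vent.qoa_m3s, self.qps_m3s, self.vehicle
        )

    @property
    def qinf_m3s(self) -> float:
        return self.infiltration_result().qinf_m3s

    @property
    def qdep_m3s(self) -> np.ndarray:
        return deposition_flow(self.vehicle.vcabin_m3, self.vehicle.beta_per_h)

    def eta_bounds(self) -> list[str]:
        """The eta bound(s) the configured mode evaluates."""
        return ["upper", "lower"] if self.eta_mode == "average" else [self.eta_mode]


def _resolve_eta(scenario: Scenario, eta_mode: str | None) -> np.ndarray:
    mode = eta_mode or scenario.eta_mode
    if mode == "average":
        raise ValueError(
            "eta_mode 'average' averages the upper- and lower-bound solutions; "
            "evaluate the RHS with an explicit bound ('upper' or 'lower')"
        )
    eta = scenario.filter_spec.eta(mode)
    if np.any((eta < 0) | (eta > 1)):
        raise ValueError("filter efficiencies must lie in [0, 1]")
    return eta


def particle_rhs(cin: np.ndarray, scenario: Scenario,
                 eta_mode: str | None = None) -> np.ndarray:
    """dCin/dt per channel (concentration units per second) at cabin
    concentrations ``cin``, for one eta bound."""
    eta = _resolve_eta(scenario, eta_mode)
    q_filtered = scenario.vent.qoa_m3s + scenario.qps_m3s
    qinf = scenario.qinf_m3s
    source = (q_filtered * (1.0 - eta) + qinf * scenario.vehicle.alpha) \
        * scenario.cenv_particles.values
    loss = (q_filtered + qinf + scenario.qdep_m3s
            + scenario.vent.qrec_m3s * eta) * np.asarray(cin, dtype=float)
    return (source - loss) / scenario.vehicle.vcabin_m3


def steady_state_particles(scenario: Scenario,
                           eta_mode: str | None = None) -> SizeDistribution:
    """Closed-form steady state of the particle balance.

    With ``eta_mode='average'`` the upper- and lower-bound solutions are
    averaged (the steady state is nonlinear in eta, so this differs from
    solving at the mean efficiency).
    """
    mode = eta_mode or scenario.eta_mode
    if mode == "average":
        upper = steady_state_particles(scenario, "upper")
        lower = steady_state_particles(scenario, "lower")
        return 0.5 * (upper + lower)
    eta = _resolve_eta(scenario, mode)
    q_filtered = scenario.vent.qoa_m3s + scenario.qps_m3s
    qinf = scenario.qinf_m3s
    den = q_filtered + qinf + scenario.qdep_m3s + scenario.vent.qrec_m3s * eta
    zero = np.flatnonzero(den <= 0)
    if zero.size:
        nm = np.asarray(scenario.cenv_particles.grid.midpoints_nm)[zero]
        raise ValueError(
            f"particle balance has no loss pathway in channel(s) {nm.tolist()} nm; "
            "steady state undefined"
        )
    num = (q_filtered * (1.0 - eta) + qinf * scenario.vehicle.alpha) \
        * scenario.cenv_particles.values
    return SizeDistribution(num / den, scenario.cenv_particles.basis,
                            scenario.cenv_particles.grid)


def co2_rhs(cin_ppm: float, scenario: Scenario) -> float:
    """dCin/dt for cabin CO2 (ppm/s)."""
    q = scenario.vent.qoa_m3s + scenario.qps_m3s + scenario.qinf_m3s
    source = scenario.occupants.co2_source_m3_s
    return (q * (scenario.cenv_co2_ppm - cin_ppm) + source) / scenario.vehicle.vcabin_m3


def steady_state_co2(scenario: Scenario) -> float:
    """Closed-form steady-state cabin CO2 (ppm):
    Cin = Cenv + N*Vbr*Cbr / (Qoa+Qps+Qinf)."""
    q = scenario.vent.qoa_m3s + scenario.qps_m3s + scenario.qinf_m3s
    if q <= 0:
        if scenario.occupants.n > 0:
            raise ValueError(
                "no outside-air exchange (Qoa+Qps+Qinf = 0) with occupants "
                "present: CO2 accumulates without bound (e.g. 100% "
                "recirculation at standstill); use transient_solve to study "
                "the build-up"
            )
        return scenario.cenv_co2_ppm
    return scenario.cenv_co2_ppm + scenario.occupants.co2_source_m3_s / q


@dataclass
class TransientResult:
    """Integrated trajectory on a time grid: particles per channel and CO2."""

    t_s: np.ndarray
    particles: np.ndarray  # (n_t, n_channels), basis of the scenario boundary
    co2_ppm: np.ndarray
    scenario: Scenario = field(repr=False)

    def state(self, i: int) -> CabinState:
        return CabinState(
            SizeDistribution(self.particles[i], self.scenario.cenv_particles.basis,
                             self.scenario.cenv_particles.grid),
            float(self.co2_ppm[i]),
            float(self.t_s[i]),
        )


def transient_solve(scenario: Scenario, t_grid: np.ndarray,
                    cin0_particles: SizeDistribution | None = None,
                    cin0_co2_ppm: float | None = None,
                    rtol: float = 1e-8, atol: float = 1e-9) -> TransientResult:
    """Integrate the coupled balances over ``t_grid`` (s) from an initial
    cabin state (defaults: particle-free cabin at outdoor CO2).

    The system is linear; an implicit (BDF) scheme is used so widely split
    loss-rate channels pose no stiffness problem. With ``eta_mode='average'``
    the particle trajectories of the two efficiency bounds are averaged,
    consistent with the steady-state convention.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D array")
    nchan = len(scenario.cenv_particles.grid)
    if cin0_particles is None:
        p0 = np.zeros(nchan)
    else:
        if cin0_particles.basis != scenario.cenv_particles.basis:
            raise ValueError("initial particle state must match the boundary basis")
        p0 = cin0_particles.values
    c0 = scenario.cenv_co2_ppm if cin0_co2_ppm is None else float(cin0_co2_ppm)
    if c0 < 0:
        raise ValueError("initial CO2 must be non-negative")

    trajectories = []
    for bound in scenario.eta_bounds():
        def rhs(_t: float, y: np.ndarray, _bound=bound) -> np.ndarray:
            return np.concatenate([
                particle_rhs(y[:nchan], scenario, _bound),
                [co2_rhs(y[nchan], scenario)],
            ])

        sol = solve_ivp(rhs, (t[0], t[-1]), np.concatenate([p0, [c0]]),
                        t_eval=t, method="BDF", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"transient integration failed: {sol.message}")
        trajectories.append(sol.y.T)

    y = np.mean(trajectories, axis=0)
    # clip integrator noise below zero
    y = np.clip(y, 0.0, None)
    return TransientResult(t, y[:, :nchan], y[:, nchan], scenario)


def io_ratio(cin_aggregate: float, cenv_aggregate: float) -> float:
    """Indoor-to-outdoor concentration ratio Cin/Cenv."""
    if cenv_aggregate <= 0:
        raise ValueError("outdoor aggregate concentration must be positive")
    return cin_aggregate / cenv_aggregate


def steady_summary(scenario: Scenario) -> dict:
    """Steady-state exposure summary: PM2.5 (ug/m^3), UFP (N/cm^3) when the
    boundary is count-basis, CO2 (ppm), I/O ratios and airflows."""
    cin = steady_state_particles(scenario)
    cenv = scenario.cenv_particles
    rho = scenario.particle_density_kg_m3
    if cenv.basis == "count":
        pm_in = aggregate(count_to_mass(cin, rho))
        pm_out = aggregate(count_to_mass(cenv, rho))
        ufp_in = aggregate(cin)
        ufp_out = aggregate(cenv)
    else:
        pm_in, pm_out = aggregate(cin), aggregate(cenv)
        ufp_in = ufp_out = float("nan")
    co2_in = steady_state_co2(scenario)
    inf = scenario.infiltration_result()
    out = {
        "pm25_in_ugm3": pm_in,
        "pm25_out_ugm3": pm_out,
        "pm25_io_ratio": io_ratio(pm_in, pm_out) if pm_out > 0 else float("nan"),
        "ufp_in_ncm3": ufp_in,
        "ufp_out_ncm3": ufp_out,
        "co2_in_ppm": co2_in,
        "co2_out_ppm": scenario.cenv_co2_ppm,
        "qoa_m3s": scenario.vent.qoa_m3s,
        "qrec_m3s": scenario.vent.qrec_m3s,
        "qps_m3s": scenario.qps_m3s,
        "qinf_m3s": inf.qinf_m3s,
        "dpmech_pa": inf.dpmech_pa,
        "dpaero_pa": inf.dpaero_pa,
        "recirculation_degree": scenario.vent.recirculation_degree,
        "cin_per_channel": cin.values.tolist(),
    }
    if cenv.basis == "count" and ufp_out > 0:
        out["ufp_io_ratio"] = io_ratio(ufp_in, ufp_out)
    return out
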