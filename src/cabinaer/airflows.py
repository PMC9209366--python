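"""Airflow submodels feeding the cabin balance equations.

Three airflow paths reach the cabin: the fan-driven outside-air flow Qoa,
speed-induced passive ventilation Qps through the HVAC path (filtered, hence
not infiltration), and uncontrolled envelope leakage Qinf which occurs only
when the exterior aerodynamic pressure exceeds the cabin pressure built up by
mechanical ventilation. Particle deposition to interior surfaces is expressed
as an equivalent flow Qdep = Vcabin * beta per size channel.

Unit conventions
----------------
The leakage power law is parameterised in m^3/h and Pa (kf in m^3/h/Pa^n), as
in cabin pressurization test reports; the cabin balance operates in SI
(m^3/s). Converters are exact.

The passive-ventilation coefficient 0.21 is treated as a per-km air-change
coefficient: Qps [m^3/h] = 0.21 * vspeed [km/h] * Vcabin [m^3], i.e. an air
change rate of 0.21/h per km/h of speed. This reproduces plausible passive
flows (~24 L/s at 100 km/h for a 4.1 m^3 cabin, comparable to the 23-86 L/s
fan range). Coefficient configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .aerosol import VehicleSpec

logger = logging.getLogger(__name__)

#: Passive ventilation air-change coefficient per km of travel (1/km).
PASSIVE_VENT_COEFF = 0.21


def m3h_to_m3s(q: float) -> float:
    return q / 3600.0


def m3s_to_m3h(q: float) -> float:
    return q * 3600.0


def lps_to_m3s(q: float) -> float:
    return q / 1000.0


def passive_ventilation(vspeed_kmh: float, vcabin_m3: float,
                        coeff_per_km: float = PASSIVE_VENT_COEFF) -> float:
    """Speed-induced passive ventilation flow Qps in m^3/s.

    Linear in vehicle speed: Qps[m^3/h] = coeff * vspeed[km/h] * Vcabin[m^3].
    """
    if vspeed_kmh < 0:
        raise ValueError("vehicle speed must be non-negative")
    if vcabin_m3 <= 0:
        raise ValueError("cabin volume must be positive")
    return m3h_to_m3s(coeff_per_km * vspeed_kmh * vcabin_m3)


def mechanical_pressure(q_total_m3h: float, kf: float, n: float) -> float:
    """Cabin pressurization dPmech (Pa) from the total HVAC outside-air
    intake (Qoa + Qps, m^3/h), by inverting the leakage power law:
    dPmech = ((Qoa+Qps)/kf)^(1/n).

    Zero total flow is the no-fan, parked limit and returns 0 Pa.
    """
    if kf <= 0 or n <= 0:
        raise ValueError("kf and n must be positive")
    if q_total_m3h < 0:
        raise ValueError("flow must be non-negative")
    if q_total_m3h == 0:
        logger.debug("mechanical_pressure at zero flow: returning 0 Pa limit")
        return 0.0
    return float((q_total_m3h / kf) ** (1.0 / n))


def aero_pressure(vspeed_kmh: float, a: float, b: float, kp: float) -> float:
    """Exterior aerodynamic pressure rise dPaero = kp * a * exp(b * vspeed), Pa."""
    if vspeed_kmh < 0:
        raise ValueError("vehicle speed must be non-negative")
    return float(kp * a * np.exp(b * vspeed_kmh))


def infiltration_flow(dpinf_pa: float, kf: float, n: float, frev: float) -> float:
    """Envelope infiltration flow (m^3/h) from the net exterior pressure
    excess: Qinf = Frev * kf * dPinf^n for dPinf > 0, else 0."""
    if kf <= 0 or n <= 0:
        raise ValueError("kf and n must be positive")
    if not 0 <= frev <= 1:
        raise ValueError("Frev must lie in [0, 1]")
    if dpinf_pa <= 0:
        return 0.0
    return float(frev * kf * dpinf_pa**n)


def deposition_flow(vcabin_m3: float, beta_per_h: np.ndarray | float) -> np.ndarray:
    """Deposition-equivalent flow Qdep = Vcabin * beta, returned in m^3/s
    (per channel when beta is a vector)."""
    if vcabin_m3 <= 0:
        raise ValueError("cabin volume must be positive")
    beta = np.asarray(beta_per_h, dtype=float)
    if np.any(beta < 0):
        raise ValueError("deposition rates must be non-negative")
    return vcabin_m3 * beta / 3600.0


@dataclass(frozen=True)
class InfiltrationResult:
    """Pressure-balance outcome: dPmech, dPaero, their difference, and Qinf."""

    dpmech_pa: float
    dpaero_pa: float
    dpinf_pa: float
    qinf_m3s: float


def infiltration(vspeed_kmh: float, qoa_m3s: float, qps_m3s: float,
                 vehicle: VehicleSpec) -> InfiltrationResult:
    """Full pressure-balance infiltration chain for one operating point.

    The fan intake and passive ventilation pressurize the cabin
    (dPmech); the moving vehicle raises the exterior surface pressure
    (dPaero); leakage through cracks occurs only when dPinf = dPaero -
    dPmech > 0 and is attenuated by the reverse-flow correction Frev.
    """
    q_total_m3h = m3s_to_m3h(qoa_m3s + qps_m3s)
    dpmech = mechanical_pressure(q_total_m3h, vehicle.kf, vehicle.n)
    dpaero = aero_pressure(vspeed_kmh, vehicle.a, vehicle.b, vehicle.kp)
    dpinf = dpaero - dpmech
    qinf_m3h = infiltration_flow(dpinf, vehicle.kf, vehicle.n, vehicle.frev)
    return InfiltrationResult(dpmech, dpaero, dpinf, m3h_to_m3s(qinf_m3h))


@dataclass
class VentilationState:
    """HVAC operating point: outside-air and recirculated flows (m^3/s) and
    vehicle speed (km/h). Qps is derived from speed unless given explicitly."""

    qoa_m3s: float
    qrec_m3s: float = 0.0
    vspeed_kmh: float = 0.0
    qps_m3s: float | None = None

    def __post_init__(self) -> None:
        if self.qoa_m3s < 0 or self.qrec_m3s < 0:
            raise ValueError("flows must be non-negative")
        if self.vspeed_kmh < 0:
            raise ValueError("vehicle speed must be non-negative")
        if self.qps_m3s is not None and self.qps_m3s < 0:
            raise ValueError("passive ventilation flow must be non-negative")

    @property
    def recirculation_degree(self) -> float:
        """Qrec / (Qrec + Qoa), in [0, 1]; 0 when the fan supplies nothing."""
        total = self.qoa_m3s + self.qrec_m3s
        if total == 0:
            return 0.0
        return self.qrec_m3s / total

    def qps(self, vehicle: VehicleSpec) -> float:
        if self.qps_m3s is not None:
            return self.qps_m3s
        return passive_ventilation(self.vspeed_kmh, vehicle.vcabin_m3)

    @classmethod
    def from_total_flow(cls, q_total_m3s: float, recirculation_degree: float,
                        vspeed_kmh: float = 0.0, **kw) -> "VentilationState":
        """Split a total supply flow into Qoa/Qrec at a recirculation degree."""
        if not 0 <= recirculation_degree <= 1:
            raise ValueError("recirculation degree must lie in [0, 1]")
        return cls(
            qoa_m3s=q_total_m3s * (1.0 - recirculation_degree),
            qrec_m3s=q_total_m3s * recirculation_degree,
            vspeed_kmh=vspeed_kmh,
            **kw,
        )
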