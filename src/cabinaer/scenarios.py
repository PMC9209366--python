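"""Synthetic scenarios, outdoor-aerosol generation and parameter sweeps.

No public dataset accompanies the model, so everything needed to exercise it
is generated here: traffic-influenced outdoor size distributions (multimodal
lognormals peaking below 100 nm, as measured near roads), tunnel or open-road
CO2 boundaries, and the canonical sensitivity sweeps (filter efficiency
+-0.05 over 52-352 nm, common airflow scaling, leakage coefficient kf,
deposition rate beta, and the recirculation-degree trade-off).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .aerosol import (
    SizeDistribution,
    SizeGrid,
    DEFAULT_GRID,
    OccupantLoad,
    count_to_mass,
    aggregate,
    load_filter_fixture,
    suv_vehicle,
)
from .airflows import VentilationState, lps_to_m3s
from .cabin import Scenario, steady_state_particles, steady_summary

logger = logging.getLogger(__name__)

#: Literature tunnel CO2 levels (ppm) from two comparable tunnel campaigns;
#: the boundary default is their mean.
TUNNEL_CO2_SOURCES_PPM = (710.0, 722.0)

#: Resting minute-ventilation range (L/min) for seated adults; the default
#: Vbr is the midpoint.
RESTING_VBR_RANGE_LPM = (5.0, 8.0)

#: Open-road background CO2 (ppm).
OPEN_ROAD_CO2_PPM = 420.0

#: Exhaled-air CO2 concentration (ppm).
EXHALED_CO2_PPM = 40000.0

#: Nominal fan-level supply flows (L/s).
FAN_LEVELS_LPS = {"xlow": 23.0, "low": 40.0, "medium": 59.0, "high": 86.0}

#: Sensitivity grid for the leakage flow coefficient (m^3/h/Pa^n): the
#: baseline vehicle value and the largest value reported across vehicle models.
KF_SENSITIVITY_VALUES = (18.78, 69.39)

#: Literature range of cabin deposition rates (1/h) used for beta sweeps.
BETA_RANGE_PER_H = (0.5, 12.6)


def tunnel_co2_ppm() -> float:
    """Default tunnel CO2 boundary: mean of the two literature values."""
    return float(np.mean(TUNNEL_CO2_SOURCES_PPM))


def resting_minute_ventilation_lpm() -> float:
    """Default minute ventilation: midpoint of the seated-at-rest range."""
    lo, hi = RESTING_VBR_RANGE_LPM
    return (lo + hi) / 2.0


@dataclass
class OutdoorAerosolModel:
    """Multimodal lognormal number-size distribution of outdoor aerosol.

    ``modes`` are (number fraction, geometric mean diameter nm, geometric SD)
    triples; fractions must sum to 1 and GSDs exceed 1. ``total_count`` is
    the total number concentration (N/cm^3). ``noise_gsd`` > 1 applies
    reproducible per-channel lognormal sampling noise (geometric SD) driven
    by ``seed``.
    """

    modes: tuple[tuple[float, float, float], ...] = ((0.6, 30.0, 1.8), (0.4, 90.0, 2.0))
    total_count: float = 2.0e4
    seed: int = 0
    noise_gsd: float = 1.0

    def __post_init__(self) -> None:
        if self.total_count < 0:
            raise ValueError("total count must be non-negative")
        fracs = [m[0] for m in self.modes]
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("mode number fractions must sum to 1")
        if any(f < 0 for f in fracs):
            raise ValueError("mode fractions must be non-negative")
        if any(m[2] <= 1.0 for m in self.modes):
            raise ValueError("geometric standard deviations must exceed 1")
        if self.noise_gsd < 1.0:
            raise ValueError("noise_gsd must be >= 1")


#: Default traffic-influenced roadside aerosol: nucleation/Aitken mode at
#: 30 nm plus an accumulation shoulder at 90 nm; >50% of counts ultrafine.
DEFAULT_TRAFFIC_MODEL = OutdoorAerosolModel()


def generate_outdoor_distribution(model: OutdoorAerosolModel,
                                  grid: SizeGrid | None = None) -> SizeDistribution:
    """Discretize the lognormal mixture onto the size grid (count basis).

    Per-channel probability mass comes from CDF differences at the channel
    edges, renormalized over the grid span so the grid total equals
    ``total_count`` exactly (the truncated tail fraction is logged). Output
    is deterministic for a fixed seed.
    """
    grid = grid or DEFAULT_GRID
    edges = np.log(grid.edges_nm())
    weights = np.zeros(len(grid))
    covered = 0.0
    for frac, gmd, gsd in model.modes:
        if not grid.edges_nm()[0] <= gmd <= grid.edges_nm()[-1]:
            logger.warning(
                "mode diameter %.1f nm lies outside the grid span; its mass "
                "is renormalized onto the grid", gmd,
            )
        cdf = sps.norm.cdf(edges, loc=np.log(gmd), scale=np.log(gsd))
        weights += frac * np.diff(cdf)
        covered += frac * (cdf[-1] - cdf[0])
    if covered <= 0:
        raise ValueError("no mode mass falls inside the size grid")
    truncated = 1.0 - covered
    if truncated > 1e-3:
        logger.info("%.2f%% of the mixture lies outside the grid span "
                    "(renormalized)", 100 * truncated)
    values = model.total_count * weights / weights.sum() \
        if model.total_count > 0 else weights * 0.0
    if model.noise_gsd > 1.0 and model.total_count > 0:
        rng = np.random.default_rng(model.seed)
        noise = rng.lognormal(0.0, np.log(model.noise_gsd), size=len(grid))
        values = values * noise
        values *= model.total_count / values.sum()
    return SizeDistribution(values, "count", grid)


def example_scenario(seed: int = 0, recirculation_degree: float = 0.0,
                     vspeed_kmh: float = 60.0) -> Scenario:
    """Packaged illustrative scenario: aged filter, ionization off, Low fan
    (40 L/s), two occupants, tunnel CO2 boundary and a synthetic
    traffic-influenced outdoor aerosol. Illustrative of a polluted commute;
    not a reproduction of any measured case."""
    model = replace(DEFAULT_TRAFFIC_MODEL, seed=seed)
    return Scenario(
        vehicle=suv_vehicle(),
        vent=VentilationState.from_total_flow(
            lps_to_m3s(FAN_LEVELS_LPS["low"]), recirculation_degree, vspeed_kmh
        ),
        filter_spec=load_filter_fixture("aged_500h", "off"),
        occupants=OccupantLoad(n=2, vbr_lpm=resting_minute_ventilation_lpm(),
                               cbr_ppm=EXHALED_CO2_PPM),
        cenv_particles=generate_outdoor_distribution(model),
        cenv_co2_ppm=tunnel_co2_ppm(),
    )


@dataclass
class SweepSpec:
    """A named parameter sweep over a base scenario."""

    parameter: str  # eta_52_352 | airflow | kf | beta | recirculation
    values: tuple
    base: Scenario = field(repr=False)


def _scenario_hash(s: Scenario) -> str:
    payload = {
        "vcabin": s.vehicle.vcabin_m3, "kf": s.vehicle.kf, "n": s.vehicle.n,
        "qoa": s.vent.qoa_m3s, "qrec": s.vent.qrec_m3s, "v": s.vent.vspeed_kmh,
        "filter": [s.filter_spec.status, s.filter_spec.ionization],
        "eta_mode": s.eta_mode, "occupants": s.occupants.n,
        "cenv": np.round(s.cenv_particles.values, 9).tolist(),
        "co2": s.cenv_co2_ppm,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _pm25_io(scenario: Scenario) -> float:
    cin = steady_state_particles(scenario)
    rho = scenario.particle_density_kg_m3
    if cin.basis == "count":
        pm_in = aggregate(count_to_mass(cin, rho))
        pm_out = aggregate(count_to_mass(scenario.cenv_particles, rho))
    else:
        pm_in = aggregate(cin)
        pm_out = aggregate(scenario.cenv_particles)
    return pm_in / pm_out


def _with_eta_delta(base: Scenario, delta: float,
                    lo_nm: float = 52.0, hi_nm: float = 352.0) -> Scenario:
    mids = np.asarray(base.filter_spec.grid.midpoints_nm)
    mask = (mids >= lo_nm) & (mids <= hi_nm)
    fs = base.filter_spec
    upper = fs.eta_upper.copy()
    lower = fs.eta_lower.copy()
    upper[mask] = np.clip(upper[mask] + delta, 0.0, 1.0)
    lower[mask] = np.clip(lower[mask] + delta, 0.0, 1.0)
    return replace(base, filter_spec=replace(fs, eta_upper=upper, eta_lower=lower))


def sweep_eta(base: Scenario, delta: float = 0.05) -> pd.DataFrame:
    """Perturb filter efficiency by +-``delta`` in the 52-352 nm channels
    (the most-penetrating / count-dominant range), clipped to [0, 1];
    returns the PM2.5 I/O ratio of the original and both perturbations."""
    rows = [
        {"variant": "original", "eta_delta": 0.0, "pm25_io_ratio": _pm25_io(base)},
        {"variant": "decreased", "eta_delta": -delta,
         "pm25_io_ratio": _pm25_io(_with_eta_delta(base, -delta))},
        {"variant": "increased", "eta_delta": +delta,
         "pm25_io_ratio": _pm25_io(_with_eta_delta(base, +delta))},
    ]
    df = pd.DataFrame(rows)
    df.attrs.update(parameter="eta_52_352", base_hash=_scenario_hash(base))
    return df


def sweep_airflow(base: Scenario,
                  factors: tuple = (-0.7, -0.5, -0.3, -0.1, 0.0,
                                    0.1, 0.3, 0.5, 0.7)) -> pd.DataFrame:
    """Scale Qoa and Qrec together by each relative factor (the
    recirculation degree is preserved); reports the PM2.5 I/O ratio."""
    rows = []
    for f in factors:
        vent = replace(base.vent, qoa_m3s=base.vent.qoa_m3s * (1 + f),
                       qrec_m3s=base.vent.qrec_m3s * (1 + f))
        rows.append({"airflow_change": f,
                     "pm25_io_ratio": _pm25_io(replace(base, vent=vent))})
    df = pd.DataFrame(rows)
    df.attrs.update(parameter="airflow", base_hash=_scenario_hash(base))
    return df


def sweep_kf(base: Scenario, kf_values: tuple = KF_SENSITIVITY_VALUES) -> pd.DataFrame:
    """Vary the leakage flow coefficient; reports infiltration flow and the
    PM2.5 I/O ratio."""
    rows = []
    for kf in kf_values:
        s = replace(base, vehicle=replace(base.vehicle, kf=kf))
        rows.append({"kf": kf, "qinf_m3s": s.qinf_m3s,
                     "pm25_io_ratio": _pm25_io(s)})
    df = pd.DataFrame(rows)
    df.attrs.update(parameter="kf", base_hash=_scenario_hash(base))
    return df


def sweep_beta(base: Scenario,
               beta_values: tuple = (0.5, 3.2, 6.5, 12.6)) -> pd.DataFrame:
    """Vary the (scalar, broadcast) deposition rate within the literature
    range; reports the PM2.5 I/O ratio."""
    rows = []
    for b in beta_values:
        lo, hi = BETA_RANGE_PER_H
        if not lo <= b <= hi:
            raise ValueError(f"beta {b} outside the literature range {BETA_RANGE_PER_H}")
        s = replace(base, vehicle=replace(base.vehicle, beta_per_h=b))
        rows.append({"beta_per_h": b, "pm25_io_ratio": _pm25_io(s)})
    df = pd.DataFrame(rows)
    df.attrs.update(parameter="beta", base_hash=_scenario_hash(base))
    return df


def sweep_recirculation(base: Scenario,
                        degrees: tuple = (0.0, 0.3, 0.5, 0.7)) -> pd.DataFrame:
    """Vary the recirculation degree at fixed total supply flow; reports
    steady-state cabin PM2.5 and CO2 — the air-quality trade-off:
    recirculated air is re-filtered (PM down) but carries occupant CO2
    back (CO2 up)."""
    q_total = base.vent.qoa_m3s + base.vent.qrec_m3s
    rows = []
    for d in degrees:
        vent = VentilationState.from_total_flow(
            q_total, d, base.vent.vspeed_kmh, qps_m3s=base.vent.qps_m3s
        )
        s = replace(base, vent=vent)
        summary = steady_summary(s)
        rows.append({
            "recirculation_degree": d,
            "pm25_in_ugm3": summary["pm25_in_ugm3"],
            "co2_in_ppm": summary["co2_in_ppm"],
            "pm25_io_ratio": summary["pm25_io_ratio"],
        })
    df = pd.DataFrame(rows)
    df.attrs.update(parameter="recirculation", base_hash=_scenario_hash(base))
    return df


_SWEEPS = {
    "eta_52_352": lambda spec: sweep_eta(spec.base, *(spec.values or ())),
    "airflow": lambda spec: sweep_airflow(spec.base, tuple(spec.values)),
    "kf": lambda spec: sweep_kf(spec.base, tuple(spec.values)),
    "beta": lambda spec: sweep_beta(spec.base, tuple(spec.values)),
    "recirculation": lambda spec: sweep_recirculation(spec.base, tuple(spec.values)),
}


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Dispatch a :class:`SweepSpec` to its sweep operation."""
    if spec.parameter not in _SWEEPS:
        raise ValueError(
            f"unknown sweep parameter {spec.parameter!r}; "
            f"expected one of {sorted(_SWEEPS)}"
        )
    return _SWEEPS[spec.parameter](spec)


def random_scenarios(n: int, seed: int = 0) -> list[Scenario]:
    """Draw ``n`` random but physically plausible constant-condition
    scenarios (for cross-checking solvers): fan levels across the supported
    range, recirculation 0-90%, speeds 0-120 km/h, both filter statuses,
    0-4 occupants and randomized outdoor aerosol totals."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        status = rng.choice(["new", "aged_500h"])
        ion = rng.choice(["on", "off"])
        q_total = lps_to_m3s(rng.uniform(15.0, 90.0))
        model = OutdoorAerosolModel(
            total_count=float(rng.uniform(2e3, 1e5)),
            seed=int(rng.integers(0, 2**31 - 1)),
            noise_gsd=1.3,
        )
        out.append(Scenario(
            vehicle=suv_vehicle() if rng.random() < 0.5
            else replace(suv_vehicle(), vcabin_m3=2.9),
            vent=VentilationState.from_total_flow(
                q_total, float(rng.uniform(0.0, 0.9)),
                float(rng.uniform(0.0, 120.0)),
            ),
            filter_spec=load_filter_fixture(status, ion),
            occupants=OccupantLoad(n=int(rng.integers(0, 5))),
            cenv_particles=generate_outdoor_distribution(model),
            cenv_co2_ppm=float(rng.uniform(400.0, 900.0)),
            eta_mode=str(rng.choice(["upper", "lower", "average"])),
        ))
    return out
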