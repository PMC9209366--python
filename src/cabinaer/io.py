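"""Configuration parsing and file-format plumbing.

Scenario files are YAML; size distributions travel as CSV in either a long
form (columns ``midpoint_nm,value``) or a wide one-row form (columns named
``c_<midpoint>nm``); the wide form is written. Flows in config files carry
explicit unit suffixes ("40 L/s", "144 m3/h", "0.04 m3/s") and are stored
internally in m^3/s.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aerosol import (
    DEFAULT_GRID,
    OccupantLoad,
    SizeDistribution,
    SizeGrid,
    VehicleSpec,
    load_filter_fixture,
)
from .airflows import VentilationState, lps_to_m3s, m3h_to_m3s
from .cabin import Scenario
from .scenarios import (
    EXHALED_CO2_PPM,
    FAN_LEVELS_LPS,
    OutdoorAerosolModel,
    generate_outdoor_distribution,
    resting_minute_ventilation_lpm,
)

_FLOW_UNITS = {
    "l/s": lps_to_m3s,
    "m3/h": m3h_to_m3s,
    "m3/s": lambda q: q,
}


def parse_flow(value) -> float:
    """Parse a flow with unit suffix into m^3/s; bare numbers are m^3/s."""
    if isinstance(value, (int, float)):
        return float(value)
    parts = str(value).split()
    if len(parts) != 2:
        raise ValueError(
            f"flow {value!r} must be '<number> <unit>' with unit in "
            f"{sorted(_FLOW_UNITS)} (or a bare number in m3/s)"
        )
    num, unit = float(parts[0]), parts[1].lower().replace("³", "3")
    if unit not in _FLOW_UNITS:
        raise ValueError(f"unknown flow unit {parts[1]!r}; use one of {sorted(_FLOW_UNITS)}")
    return _FLOW_UNITS[unit](num)


def flow_row(q_m3s: float) -> dict:
    """A flow in the three reporting units."""
    return {"m3/s": q_m3s, "L/s": q_m3s * 1000.0, "m3/h": q_m3s * 3600.0}


def read_distribution_csv(path, basis: str = "count",
                          grid: SizeGrid | None = None) -> SizeDistribution:
    """Read a per-channel distribution CSV (long or wide dialect)."""
    grid = grid or DEFAULT_GRID
    df = pd.read_csv(path)
    if {"midpoint_nm", "value"} <= set(df.columns):
        df = df.sort_values("midpoint_nm")
        mids = df["midpoint_nm"].to_numpy(dtype=float)
        if not np.allclose(mids, grid.midpoints_nm):
            raise ValueError(f"{path}: channel midpoints do not match the size grid")
        values = df["value"].to_numpy(dtype=float)
    else:
        cols = [f"c_{int(m)}nm" for m in grid.midpoints_nm]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing channel columns {missing[:3]}...")
        values = df[cols].to_numpy(dtype=float)[0]
    return SizeDistribution(values, basis, grid)


def write_distribution_csv(dist: SizeDistribution, path) -> None:
    """Write a distribution in the wide one-row dialect."""
    cols = {f"c_{int(m)}nm": [v] for m, v in
            zip(dist.grid.midpoints_nm, dist.values)}
    pd.DataFrame(cols).to_csv(path, index=False)


def _coerce_onoff(value) -> str:
    # YAML 1.1 parses a bare on/off as a boolean
    if isinstance(value, bool):
        return "on" if value else "off"
    return str(value)


def _build_vent(cfg: dict) -> VentilationState:
    vspeed = float(cfg.get("vspeed_kmh", 0.0))
    extra = {}
    if "qps" in cfg:
        extra["qps_m3s"] = parse_flow(cfg["qps"])
    if "qoa" in cfg:
        return VentilationState(parse_flow(cfg["qoa"]),
                                parse_flow(cfg.get("qrec", 0.0)), vspeed, **extra)
    if "fan_level" in cfg:
        total = lps_to_m3s(FAN_LEVELS_LPS[str(cfg["fan_level"]).lower()])
    elif "total_flow" in cfg:
        total = parse_flow(cfg["total_flow"])
    else:
        raise ValueError("vent config needs 'qoa', 'fan_level' or 'total_flow'")
    return VentilationState.from_total_flow(
        total, float(cfg.get("recirculation_degree", 0.0)), vspeed, **extra)


def _build_outdoor_particles(cfg: dict, base_dir: Path,
                             grid: SizeGrid) -> SizeDistribution:
    if "csv" in cfg:
        path = Path(cfg["csv"])
        if not path.is_absolute():
            path = base_dir / path
        return read_distribution_csv(path, cfg.get("basis", "count"), grid)
    if "model" in cfg:
        m = cfg["model"]
        kwargs = {}
        if "modes" in m:
            kwargs["modes"] = tuple(tuple(mode) for mode in m["modes"])
        for key in ("total_count", "seed", "noise_gsd"):
            if key in m:
                kwargs[key] = m[key]
        return generate_outdoor_distribution(OutdoorAerosolModel(**kwargs), grid)
    raise ValueError("outdoor.particles config needs 'csv' or 'model'")


def load_scenario(path) -> Scenario:
    """Build a :class:`Scenario` from a YAML scenario file."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: scenario file must be a YAML mapping")
    try:
        vcfg = dict(cfg["vehicle"])
        beta = vcfg.pop("beta_per_h", None)
        if isinstance(beta, str) and beta.lower() == "default":
            beta = None
        vehicle = VehicleSpec(beta_per_h=beta, **vcfg)

        fcfg = cfg["filter"]
        filter_spec = load_filter_fixture(
            str(fcfg["status"]), _coerce_onoff(fcfg["ionization"]))

        vent = _build_vent(dict(cfg["vent"]))

        occ = dict(cfg.get("occupants", {}))
        occupants = OccupantLoad(
            n=int(occ.get("n", 0)),
            vbr_lpm=float(occ.get("vbr_lpm", resting_minute_ventilation_lpm())),
            cbr_ppm=float(occ.get("cbr_ppm", EXHALED_CO2_PPM)),
        )

        outdoor = dict(cfg["outdoor"])
        cenv_particles = _build_outdoor_particles(
            dict(outdoor["particles"]), path.parent, vehicle.grid)

        return Scenario(
            vehicle=vehicle,
            vent=vent,
            filter_spec=filter_spec,
            occupants=occupants,
            cenv_particles=cenv_particles,
            cenv_co2_ppm=float(outdoor["co2_ppm"]),
            eta_mode=str(cfg.get("eta_mode", "average")),
            particle_density_kg_m3=float(cfg.get("particle_density_kg_m3", 1000.0)),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing required config key {exc}") from exc


def file_sha256(path) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


def write_summary_json(path, payload: dict, *, seed: int | None,
                       inputs: dict[str, str] | None = None) -> None:
    """Write a JSON summary with provenance (package version, seed, input
    hashes), atomically."""
    from . import __version__

    doc = {
        "package": "cabinaer",
        "version": __version__,
        "seed": seed,
        "input_hashes": inputs or {},
        **payload,
    }
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, path)
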