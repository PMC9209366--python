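"""Core aerosol types: size grid, size distributions, filter efficiency, vehicle.

The model discretizes the aerosol between 10 nm and 2.5 um aerodynamic
diameter into 25 size channels (matching the resolution of common mobility /
optical sizer combinations used in cabin measurements). Each channel is
represented by its midpoint diameter; the balance equations act per channel,
so no channel-width integration is performed.

Filter removal efficiencies are size dependent and are shipped as a packaged
CSV fixture with four (filter status, ionization status) combinations, each
with an upper and a lower efficiency bound reflecting the spread of component
test results.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Channel midpoint aerodynamic diameters (nm) of the 25-channel grid.
DEFAULT_CHANNELS_NM: tuple[float, ...] = (
    10, 14, 19, 27, 37, 52, 72, 100, 139, 193, 253, 298, 352,
    414, 488, 576, 679, 800, 943, 1112, 1310, 1545, 1821, 2146, 2530,
)

FILTER_STATUSES = ("new", "aged_500h")
IONIZATION_STATUSES = ("on", "off")


@dataclass(frozen=True)
class SizeGrid:
    """Discretization of the particle size axis into channel midpoints."""

    midpoints_nm: tuple[float, ...] = DEFAULT_CHANNELS_NM

    def __post_init__(self) -> None:
        mids = tuple(float(m) for m in self.midpoints_nm)
        object.__setattr__(self, "midpoints_nm", mids)
        if len(mids) != 25:
            raise ValueError(f"size grid must have 25 channels, got {len(mids)}")
        if any(b <= a for a, b in zip(mids, mids[1:])):
            raise ValueError("channel midpoints must be strictly increasing")

    def __len__(self) -> int:
        return len(self.midpoints_nm)

    @property
    def midpoints_m(self) -> np.ndarray:
        return np.asarray(self.midpoints_nm) * 1e-9

    def edges_nm(self) -> np.ndarray:
        """Channel boundaries: geometric means of adjacent midpoints.

        The outermost edges extend the first/last geometric half-width,
        so the grid spans slightly beyond [10, 2530] nm.
        """
        m = np.asarray(self.midpoints_nm)
        inner = np.sqrt(m[:-1] * m[1:])
        first = m[0] ** 2 / inner[0]
        last = m[-1] ** 2 / inner[-1]
        return np.concatenate([[first], inner, [last]])

    def ufp_mask(self, boundary_nm: float = 100.0) -> np.ndarray:
        """Boolean mask of ultrafine channels (midpoint strictly below the
        boundary; the boundary channel itself is excluded)."""
        return np.asarray(self.midpoints_nm) < boundary_nm


DEFAULT_GRID = SizeGrid()


@dataclass
class SizeDistribution:
    """Per-channel particle concentrations on a :class:`SizeGrid`.

    ``basis`` is ``"count"`` (N/cm^3 per channel) or ``"mass"``
    (ug/m^3 per channel).
    """

    values: np.ndarray
    basis: str = "count"
    grid: SizeGrid = field(default_factory=lambda: DEFAULT_GRID)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.basis not in ("count", "mass"):
            raise ValueError(f"basis must be 'count' or 'mass', got {self.basis!r}")
        if self.values.shape != (len(self.grid),):
            raise ValueError(
                f"expected {len(self.grid)} channel values, got shape {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("concentrations must be non-negative")

    def __add__(self, other: "SizeDistribution") -> "SizeDistribution":
        self._check_compatible(other)
        return SizeDistribution(self.values + other.values, self.basis, self.grid)

    def __mul__(self, scalar: float) -> "SizeDistribution":
        return SizeDistribution(self.values * scalar, self.basis, self.grid)

    __rmul__ = __mul__

    def _check_compatible(self, other: "SizeDistribution") -> None:
        if self.basis != other.basis:
            raise ValueError("cannot combine count- and mass-basis distributions")
        if self.grid.midpoints_nm != other.grid.midpoints_nm:
            raise ValueError("distributions are on different size grids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"midpoint_nm": self.grid.midpoints_nm, "value": self.values}
        )


def count_to_mass(dist: SizeDistribution, density_kg_m3: float = 1000.0) -> SizeDistribution:
    """Convert a count-basis distribution (N/cm^3) to mass basis (ug/m^3).

    All particles in a channel are assumed spherical with the channel
    midpoint diameter and a common density. With d in m, rho in kg/m^3 and
    counts in N/cm^3, the per-channel mass is

        mass [ug/m^3] = N [cm^-3] * 1e6 [cm^3/m^3] * (pi/6) d^3 [m^3]
                        * rho [kg/m^3] * 1e9 [ug/kg]
    """
    if dist.basis != "count":
        raise ValueError("count_to_mass requires a count-basis distribution")
    if density_kg_m3 <= 0:
        raise ValueError("particle density must be positive")
    d = dist.grid.midpoints_m
    factor = (math.pi / 6.0) * d**3 * density_kg_m3 * 1e15
    return SizeDistribution(dist.values * factor, "mass", dist.grid)


def mass_to_count(dist: SizeDistribution, density_kg_m3: float = 1000.0) -> SizeDistribution:
    """Inverse of :func:`count_to_mass` (ug/m^3 -> N/cm^3)."""
    if dist.basis != "mass":
        raise ValueError("mass_to_count requires a mass-basis distribution")
    if density_kg_m3 <= 0:
        raise ValueError("particle density must be positive")
    d = dist.grid.midpoints_m
    factor = (math.pi / 6.0) * d**3 * density_kg_m3 * 1e15
    return SizeDistribution(dist.values / factor, "count", dist.grid)


def aggregate(dist: SizeDistribution, mode: str | None = None,
              ufp_boundary_nm: float = 100.0) -> float:
    """Collapse a distribution to a scalar exposure metric.

    mass basis -> PM2.5 (ug/m^3): sum over all channels.
    count basis -> UFP count (N/cm^3): sum over channels with midpoint below
    ``ufp_boundary_nm`` (default: ultrafine, < 100 nm). ``mode="total"``
    sums a count distribution over all channels instead.
    """
    if mode is None:
        mode = "pm" if dist.basis == "mass" else "ufp"
    if mode == "pm":
        if dist.basis != "mass":
            raise ValueError("PM aggregation requires a mass-basis distribution")
        return float(np.sum(dist.values))
    if mode == "ufp":
        if dist.basis != "count":
            raise ValueError("UFP aggregation requires a count-basis distribution")
        return float(np.sum(dist.values[dist.grid.ufp_mask(ufp_boundary_nm)]))
    if mode == "total":
        return float(np.sum(dist.values))
    raise ValueError(f"unknown aggregation mode {mode!r}")


@dataclass
class FilterSpec:
    """Size-dependent HVAC filter removal efficiency with bounds.

    ``eta_upper``/``eta_lower`` are the per-channel upper and lower limits of
    the efficiencies observed in component tests for a given (filter status,
    ionization status) combination. Ionization is represented purely through
    these efficiency values.
    """

    status: str
    ionization: str
    eta_upper: np.ndarray
    eta_lower: np.ndarray
    grid: SizeGrid = field(default_factory=lambda: DEFAULT_GRID)

    def __post_init__(self) -> None:
        if self.status not in FILTER_STATUSES:
            raise ValueError(f"unknown filter status {self.status!r}")
        if self.ionization not in IONIZATION_STATUSES:
            raise ValueError(f"unknown ionization status {self.ionization!r}")
        self.eta_upper = np.asarray(self.eta_upper, dtype=float)
        self.eta_lower = np.asarray(self.eta_lower, dtype=float)
        n = len(self.grid)
        if self.eta_upper.shape != (n,) or self.eta_lower.shape != (n,):
            raise ValueError(f"efficiency vectors must have {n} channels")
        for name, eta in (("eta_upper", self.eta_upper), ("eta_lower", self.eta_lower)):
            if np.any((eta < 0) | (eta > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        crossed = self.eta_lower > self.eta_upper
        if np.any(crossed):
            # The published component-test table itself contains one such
            # crossing (new filter, ionization off, 352 nm channel), so this
            # is reported rather than rejected.
            chans = np.asarray(self.grid.midpoints_nm)[crossed]
            logger.warning(
                "eta_lower exceeds eta_upper in channel(s) %s nm for %s/%s "
                "(kept as provided)", chans.tolist(), self.status, self.ionization,
            )

    def eta(self, mode: str) -> np.ndarray:
        """Per-channel efficiency for ``mode`` in {'upper', 'lower'}."""
        if mode == "upper":
            return self.eta_upper
        if mode == "lower":
            return self.eta_lower
        raise ValueError(f"eta mode must be 'upper' or 'lower', got {mode!r}")


def _fixture_frame() -> pd.DataFrame:
    with resources.files("cabinaer").joinpath("data/filter_efficiency.csv").open() as fh:
        return pd.read_csv(fh)


def load_filter_fixture(status: str, ionization: str,
                        grid: SizeGrid | None = None) -> FilterSpec:
    """Load the packaged filter-efficiency table for one condition.

    ``status`` in {'new', 'aged_500h'}, ``ionization`` in {'on', 'off'}.
    """
    if status not in FILTER_STATUSES or ionization not in IONIZATION_STATUSES:
        raise ValueError(
            f"unknown filter condition ({status!r}, {ionization!r}); "
            f"expected status in {FILTER_STATUSES}, ionization in {IONIZATION_STATUSES}"
        )
    grid = grid or DEFAULT_GRID
    df = _fixture_frame()
    eta_cols = [f"eta_{int(m)}" for m in grid.midpoints_nm]
    rows = df[(df["status"] == status) & (df["ionization"] == ionization)]
    upper = rows[rows["bound"] == "upper"][eta_cols].to_numpy(dtype=float)[0]
    lower = rows[rows["bound"] == "lower"][eta_cols].to_numpy(dtype=float)[0]
    return FilterSpec(status, ionization, upper, lower, grid)


def filter_fixture_table() -> pd.DataFrame:
    """The full packaged efficiency table (8 rows x 25 channels) as a frame."""
    return _fixture_frame()


def default_beta_profile(grid: SizeGrid | None = None) -> np.ndarray:
    """Per-channel particle deposition rates beta (1/h), documented stand-in.

    Surface deposition in cabins is strongest for the smallest (diffusion)
    and largest (settling/impaction) particles and weakest in the
    accumulation mode; reported cabin values span roughly 0.5-12.6 1/h
    overall and 3.2-11.8 1/h for ultrafines. The default is a smooth
    U-shape in log-diameter anchored at (10 nm, 8 /h), (200 nm, 1 /h),
    (2530 nm, 4 /h), clipped to [0.5, 12.6]. It emulates the literature
    shape; it is not a fit to any specific vehicle's data.
    """
    grid = grid or DEFAULT_GRID
    anchors_d = np.log([10.0, 200.0, 2530.0])
    anchors_b = np.log([8.0, 1.0, 4.0])
    coeffs = np.polyfit(anchors_d, anchors_b, 2)
    beta = np.exp(np.polyval(coeffs, np.log(grid.midpoints_nm)))
    return np.clip(beta, 0.5, 12.6)


@dataclass
class VehicleSpec:
    """Vehicle envelope and cabin parameters for the balance equations.

    kf (m^3/h/Pa^n) and n are the leakage power-law parameters from cabin
    pressurization tests; a (Pa), b (per km/h) and kp (dimensionless) set the
    exterior aerodynamic pressure rise with speed; Frev corrects reverse
    leakage flow; alpha is the crack penetration loss applied to infiltrating
    particles; beta_per_h are per-channel first-order deposition rates.
    """

    vcabin_m3: float
    kf: float = 18.78
    n: float = 0.66
    a: float = 0.45
    b: float = 0.03
    kp: float = 1.0
    frev: float = 0.5
    alpha: float = 0.6
    beta_per_h: np.ndarray | float | None = None
    grid: SizeGrid = field(default_factory=lambda: DEFAULT_GRID)

    def __post_init__(self) -> None:
        if self.vcabin_m3 <= 0:
            raise ValueError("cabin volume must be positive")
        if self.kf <= 0 or self.n <= 0:
            raise ValueError("leakage parameters kf and n must be positive")
        if not 0 <= self.frev <= 1:
            raise ValueError("Frev must lie in [0, 1]")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.beta_per_h is None:
            self.beta_per_h = default_beta_profile(self.grid)
        else:
            self.beta_per_h = np.broadcast_to(
                np.asarray(self.beta_per_h, dtype=float), (len(self.grid),)
            ).copy()
        if np.any(self.beta_per_h < 0):
            raise ValueError("deposition rates must be non-negative")


@dataclass
class OccupantLoad:
    """Occupant CO2 source: N passengers breathing Vbr L/min at Cbr ppm CO2."""

    n: int = 0
    vbr_lpm: float = 6.5
    cbr_ppm: float = 40000.0

    def __post_init__(self) -> None:
        if self.n < 0 or self.n != int(self.n):
            raise ValueError("passenger count must be a non-negative integer")
        if self.n > 0 and self.vbr_lpm <= 0:
            raise ValueError("minute ventilation must be positive with occupants")
        if self.cbr_ppm <= 0:
            raise ValueError("exhaled CO2 concentration must be positive")

    @property
    def co2_source_m3_s(self) -> float:
        """Volumetric CO2 source term N*Vbr*Cbr in ppm*m^3/s."""
        return self.n * (self.vbr_lpm / 1000.0 / 60.0) * self.cbr_ppm


# The two vehicles the model was developed around: a large SUV and a sedan
# sharing the same HVAC platform.
def suv_vehicle(**overrides) -> VehicleSpec:
    return VehicleSpec(vcabin_m3=4.1, **overrides)


def sedan_vehicle(**overrides) -> VehicleSpec:
    return VehicleSpec(vcabin_m3=2.9, **overrides)
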