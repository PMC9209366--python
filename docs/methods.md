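# Methods

## Model

`cabinaer` simulates the air quality inside a passenger-car cabin as a
single well-mixed zone. Two pollutants are tracked: airborne particles
between 10 nm and 2.5 µm aerodynamic diameter, resolved into 25 size
channels, and CO₂ as a volume-mixing-ratio tracer (ppm).

### Particle balance

Per size channel *i* (the equation is identical on a count basis, N/cm³, or
a mass basis, µg/m³, because all particles in a channel are assumed to share
one diameter and density):

```
Vcabin dCin_i/dt = [(Qoa + Qps)(1 − η_i) + Qinf·α] · Cenv_i
                   − [Qoa + Qps + Qinf + Qdep_i + Qrec·η_i] · Cin_i
```

- `Qoa` — fan-driven outside-air flow; passes the filter.
- `Qps` — speed-induced passive ventilation through the HVAC path; also
  passes the filter, so it is not infiltration.
- `Qrec` — recirculated cabin air; it is re-filtered, which is the entire
  particle benefit of recirculation (loss term `Qrec·η_i`).
- `Qinf` — envelope leakage, unfiltered but attenuated by the crack
  penetration coefficient α (default 0.6).
- `Qdep_i = Vcabin·β_i` — deposition to interior surfaces expressed as an
  equivalent flow, with a size-dependent first-order rate β_i (1/h).
- Exfiltration is implicit: the loss term already carries
  `Qoa + Qps + Qinf` as the cabin outflow; no separate term is added.

Because the coefficients are constant per scenario, the steady state has a
closed form (`steady_state_particles`) and the transient is a per-channel
exponential approach to it (`transient_solve`, scipy BDF, rtol 1e-8 / atol
1e-9 — conservative for a linear system).

Physical consequences that the property tests pin down: with no in-cabin
particle source and α ≤ 1, the steady-state cabin concentration never
exceeds the outdoor concentration in any channel (I/O ratio ≤ 1); the
steady state is monotone decreasing in η_i, β_i and Qrec; and it is linear
in the outdoor boundary.

### Filter efficiency

The per-channel removal efficiency η is shipped as a packaged CSV fixture
(`data/filter_efficiency.csv`) with four conditions — filter status
new / aged 500 h (end of service interval) × ionization on / off — each
with an **upper and lower bound** reflecting the spread of component tests.
Ionization appears only through these efficiency values; no ionization
physics is modelled. The default `eta_mode="average"` solves the balance
once per bound and averages the *solutions* (the steady state is nonlinear
in η, so this differs from solving at the mean efficiency and matches how a
prediction band's midpoint is usually reported).

Two quirks of the fixture are kept verbatim rather than smoothed: the sharp
efficiency step between the 352 and 414 nm channels, and one crossing where
the new/off *lower* bound (0.69) exceeds the *upper* bound (0.68) at
352 nm. `FilterSpec` logs a warning for such crossings instead of rejecting
them, because the shipped table itself contains one.

### CO₂ balance

```
Vcabin dCin/dt = (Qoa + Qps + Qinf)(Cenv − Cin) + N·Vbr·Cbr
```

CO₂ is not filtered and not deposited, so recirculation is absent from the
balance — recirculated air returns unchanged, which is why increasing the
recirculation degree at fixed total supply raises steady-state CO₂ (less
outside air) while lowering PM2.5 (more re-filtering). That trade-off is the
model's main application and is asserted as a property over the
{0, 30, 50, 70}% recirculation grid.

At 100% recirculation with occupants and no passive/infiltration exchange
the steady state does not exist (unbounded accumulation); the closed-form
solver raises and points to `transient_solve`.

Defaults: exhaled CO₂ `Cbr` = 40 000 ppm; minute ventilation `Vbr` =
6.5 L/min, the midpoint of the 5–8 L/min seated-at-rest range; outdoor CO₂
716 ppm in a road tunnel (mean of two comparable tunnel campaigns, 710 and
722 ppm) or 420 ppm on the open road.

### Airflow submodels

- **Passive ventilation**: `Qps[m³/h] = 0.21 × vspeed[km/h] × Vcabin[m³]`.
  The literature coefficient "0.21 m⁻¹" is dimensionally ambiguous; it is
  interpreted here as a per-km air-change coefficient (0.21/h per km/h),
  which yields plausible flows — ≈24 L/s at 100 km/h for a 4.1 m³ cabin,
  comparable to the 23–86 L/s fan range. The coefficient is configurable.
- **Cabin pressurization**: `dPmech = ((Qoa+Qps)/kf)^(1/n)`, the inverse of
  the envelope leakage power law; `kf` carries m³/h·Pa⁻ⁿ so the two are
  mutually consistent. At zero total flow the parked, fan-off limit of 0 Pa
  is returned instead of the undefined logarithm.
- **Aerodynamic exterior pressure**: `dPaero = kp·a·e^(b·vspeed)`.
- **Infiltration**: only when `ΔPinf = dPaero − dPmech > 0`, as
  `Qinf = Frev·kf·ΔPinf^n`, with the reverse-flow correction `Frev`.

### Vehicle parameter defaults (documented stand-ins)

The per-vehicle envelope parameters are not publicly tabulated, so the
defaults are stand-ins chosen inside cited ranges and, for the aerodynamic
parameters, *derived* from the qualitative infiltration regime reported for
the two studied cabins (4.1 m³ SUV, 2.9 m³ sedan):

| parameter | default | basis |
|---|---|---|
| kf | 18.78 m³/h·Pa⁻ⁿ | reported baseline; 69.39 is the cross-vehicle maximum used in sweeps |
| n | 0.66 | typical crack-flow pressure exponent (0.5–1) |
| Frev | 0.5 | mid-range reverse-flow correction |
| α | 0.6 | experienced crack penetration value |
| β_i | U-shape, 1–8 h⁻¹ | log-quadratic through (10 nm, 8 h⁻¹), (200 nm, 1 h⁻¹), (2.53 µm, 4 h⁻¹), clipped to the cited 0.5–12.6 h⁻¹ range |
| a, b, kp | 0.45 Pa, 0.03 per km/h, 1.0 | solved from the regime constraints below |

Regime constraints used for a, b, kp (with kf = 18.78, n = 0.66): (i) no
infiltration whenever the outside-air supply is at least 58 m³/h and speed
at most 103 km/h, for either cabin; (ii) infiltration onset at the lowest
fan levels with high recirculation only above ≈105 km/h; (iii) no
infiltration at Medium/High fan levels within the 13–114 km/h driving
envelope. These are regime reproductions, not measured values; per-vehicle
values should replace them when available (`VehicleSpec` fields).

## Synthetic scenarios

No public dataset accompanies the model, so the `scenarios` module
generates everything needed to exercise it:

- **Outdoor aerosol**: a multimodal lognormal number distribution
  discretized onto the 25 channels by CDF differences at the geometric
  channel edges, renormalized over the grid span (tail truncation logged)
  so the grid total equals the requested count exactly. The default
  traffic model — 60% in a 30 nm mode (GSD 1.8), 40% in a 90 nm mode
  (GSD 2.0), 2×10⁴ N/cm³ total — places well over half of all counts below
  100 nm, as observed near roads. Optional per-channel lognormal noise is
  seeded and bit-reproducible. What it does **not** emulate: correlated
  temporal fluctuations, size-dependent composition/density, coarse-mode
  dust events — so passing tests demonstrate the balance mechanics, not
  fidelity to any specific campaign.
- **Sweeps**: filter efficiency ±0.05 over 52–352 nm (the count-dominant,
  most-penetrating range), common ±10/30/50/70% scaling of Qoa and Qrec
  (recirculation degree preserved), kf ∈ {18.78, 69.39}, β within
  0.5–12.6 h⁻¹, and the recirculation grid {0, 30, 50, 70}% at fixed total
  supply.
- The packaged example (`example_scenario`) — aged filter, ionization off,
  Low fan 40 L/s, two occupants, tunnel CO₂ — is illustrative of a polluted
  commute, not a reproduction of any measured case.

## Numerical and design choices

- UFP aggregation counts channels with midpoint strictly below 100 nm
  (channels 10–72 nm); the 100 nm channel is excluded. Boundary
  configurable.
- Count↔mass conversion assumes spherical particles at the channel midpoint
  diameter with density 1000 kg/m³ by default (no published density);
  configurable per scenario. The conversion round-trips to 1e-12 relative.
- Channel midpoints are used as-is; no channel-width integration, since the
  efficiency table and balances operate on discrete channels.
- Evaluation metrics follow the standard Hanna/Chang definitions; the FB
  sign convention (positive = underprediction) is pinned by the relation
  P̄/Ō = (1 − 0.5 FB)/(1 + 0.5 FB). FAC2 endpoints are inclusive. Pairs with
  zeros are excluded from MG/VG with a logged count and rejected above 10%.
  Metrics are computed per sample, not per group mean.
- Problem sizes in the test suite (100 randomized scenarios for the
  transient/steady-state cross-check, grids of ~200 points for the
  infiltration regime) were chosen as the smallest sets that exercise every
  regime; all are seeded and deterministic.

## Known limitations

- Well-mixed single zone: no spatial gradients, no short-term mixing delay.
- No particle phase change, coagulation, resuspension or in-cabin sources;
  occupant respiration losses/gains of particles are neglected.
- Filter efficiency is independent of the face velocity (component data at
  one airflow only), so accuracy degrades away from the Medium fan level.
- The climate/energy side of cabin HVAC (compressor/heater power) is out of
  scope; this package covers the air-quality side only.
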