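"""Transient CO2 build-up after two occupants enter a cabin.

Integrates the coupled balances from a clean cabin at outdoor CO2 and
compares the CO2 trajectory against the closed-form exponential of the
linear balance — they agree to solver tolerance, and both approach the
closed-form steady state.
"""

import numpy as np

import cabinaer as ca

scenario = ca.example_scenario(seed=1)
t = np.linspace(0.0, 1800.0, 7)  # half an hour
result = ca.transient_solve(scenario, t)

q = scenario.vent.qoa_m3s + scenario.qps_m3s + scenario.qinf_m3s
css = ca.steady_state_co2(scenario)
analytic = css + (scenario.cenv_co2_ppm - css) * np.exp(
    -q * t / scenario.vehicle.vcabin_m3)

print("   t [min]   CO2 model [ppm]   CO2 analytic [ppm]")
for ti, ci, ai in zip(t, result.co2_ppm, analytic):
    print(f"{ti / 60:9.1f} {ci:16.1f} {ai:19.1f}")
print(f"steady state: {css:.1f} ppm "
      f"(reached to {abs(result.co2_ppm[-1] / css - 1):.1e} after 30 min)")
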