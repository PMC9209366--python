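"""The recirculation trade-off: particles down, CO2 up.

Sweeps the recirculation degree over {0, 30, 50, 70}% at fixed total supply
flow. Recirculated cabin air is passed through the filter again, so the
steady-state PM2.5 falls; but recirculation displaces outside air, so
occupant CO2 accumulates. The table shows whether each setting keeps CO2
under the 1500 ppm comfort target while pushing PM2.5 down.
"""

import cabinaer as ca

scenario = ca.example_scenario(seed=1)
table = ca.sweep_recirculation(scenario, degrees=(0.0, 0.3, 0.5, 0.7))

print("recirc [%]   PM2.5 [ug/m3]   CO2 [ppm]   CO2 < 1500 ppm?")
for _, row in table.iterrows():
    ok = "yes" if row.co2_in_ppm < 1500 else "NO"
    print(f"{row.recirculation_degree * 100:9.0f} {row.pm25_in_ugm3:15.2f} "
          f"{row.co2_in_ppm:11.0f}   {ok}")
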