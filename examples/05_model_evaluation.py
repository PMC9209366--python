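"""Evaluating predictions with the standard air-quality metric suite.

Simulates an imperfect model by perturbing synthetic 'measurements' with
lognormal scatter and a mild bias, then computes r, FAC2, FB, MG, NMSE and
VG and checks the published acceptance criteria. Also demonstrates the
FB <-> mean-ratio relation: FB = 0.67 means underprediction by a factor 2.
"""

import numpy as np

import cabinaer as ca

rng = np.random.default_rng(1)
observed = rng.lognormal(np.log(20.0), 0.8, 120)       # PM2.5-like, ug/m3
predicted = observed * 0.9 * rng.lognormal(0.0, 0.25, 120)

report, checks = ca.evaluate(observed, predicted)
for name, value in report.to_dict().items():
    status = "pass" if checks[name] else "FAIL"
    print(f"{name.upper():5s} = {value:7.3f}   [{status}]")
print("overall:", "acceptable" if checks["overall"] else "not acceptable")

fb = ca.ratio_to_fb(0.5)
print(f"\nFB for a factor-2 underprediction: {fb:.2f} "
      f"(mean P/O = {ca.fb_to_ratio(fb):.2f})")
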