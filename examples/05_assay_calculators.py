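"""ACE-inhibition IC50 and ABTS TEAC from (simulated) plate readings.

The plate simulator produces fluorescence readings from a four-parameter
logistic dose-response with a known IC50; the calculator inverts them through
the inhibition formula and interpolates 50 % on a log-concentration axis.
The ABTS simulator produces Trolox-calibration and sample responses with a
known slope ratio, recovered as the TEAC.
"""

from oleopep import ic50, inhibition_curve, teac
from oleopep.simulate import AssaySimConfig, simulate_abts, simulate_plate

cfg = AssaySimConfig(true_ic50=3.76, hill=1.0, noise_cv=0.02, true_teac=3.20, seed=3)

plate = simulate_plate(cfg)
print("concentration (uM) -> mean inhibition (%):")
for conc, inh in inhibition_curve(plate):
    print(f"  {conc:8.3f} -> {inh:5.1f}")

for method in ("loglinear", "4pl"):
    result = ic50(plate, method=method)
    print(f"IC50 ({method}): {result.value_uM:.2f} uM  (truth {cfg.true_ic50})")

cal, sample = simulate_abts(cfg)
print(f"\nTrolox calibration slope {cal.slope:.4f} (r^2 = {cal.r_squared:.4f})")
print(f"TEAC (sample slope / Trolox slope): {teac(cal, sample):.2f}  "
      f"(truth {cfg.true_teac})")
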