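"""Simulate one 11-day bottle incubation and inspect its exact ground truth.

A 1:1 mixture of daphnia carcasses (bioavailable, natural-abundance 13C)
and labelled leaf material (persistent, ~10 atom% 13C) degrades under the
complex-community parameters; priming lets the biomass grown on carcass
carbon accelerate leaf decay.
"""

import isopart as ip

presets = ip.scenario_presets()
preset = presets["DL1:1"]
truth = ip.simulate_incubation(preset.config, preset.treatment)

print(f"treatment {preset.treatment.id}: "
      f"{preset.treatment.daphnia_mg_l} mg/l daphnia + "
      f"{preset.treatment.leaf_mg_l} mg/l leaves, "
      f"{preset.treatment.community} community")
print(f"{'day':>4} {'daphnia C':>10} {'leaf C':>8} {'biomass':>8} "
      f"{'CO2(daph)':>10} {'CO2(leaf)':>10}   [umol C/l]")
for i, day in enumerate(truth.days):
    print(f"{day:4.0f} {truth.c_daphnia[i]:10.1f} {truth.c_leaf[i]:8.1f} "
          f"{truth.biomass[i]:8.1f} {truth.co2_daphnia[i]:10.1f} "
          f"{truth.co2_leaf[i]:10.1f}")

print()
print(f"final daphnia share of respired C : {truth.f_daphnia_co2:.3f}")
print(f"IE vs additive twin (priming off) : {truth.ie_true_percent:.1f} %")
print(f"isotope conservation error        : {truth.conservation_error():.2e}")
print()
print("The daphnia pool is largely mineralised within the 11 days while the")
print("leaf pool declines slowly; the positive IE is the extra CO2 produced")
print("because carcass-fed biomass stimulates (primes) leaf decay.")
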