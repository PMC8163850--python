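"""Isotope-notation conversions, mixing-mode bias and gas processing.

Shows the delta / ratio / atom-fraction algebra, quantifies the error of
the conventional delta-space mixing model against exact atom-fraction mass
balance when one endmember is strongly labelled, propagates instrument
noise into the source fraction, and reconstructs dissolved CO2 from a
headspace-equilibrated sample.
"""

import isopart as ip

leaf = ip.IsotopeValue(0.10, ip.ATOM_FRACTION)   # ~10 atom% label
daphnia = ip.IsotopeValue(-25.0)                 # natural-abundance biomass
print(f"leaf label: 10 atom% 13C = {leaf.as_delta():+.1f} permil vs V-PDB")
print(f"daphnia:    {daphnia.value:+.1f} permil = "
      f"{100 * daphnia.as_atom_fraction():.4f} atom%")
print()

ends = ip.Endmembers(daphnia, leaf)
bias = ip.mixing_mode_bias(ends)
peak = bias.loc[bias.bias.abs().idxmax()]
print("delta-space vs exact atom-fraction inversion with the labelled leaf:")
print(f"  max |bias| = {abs(peak.bias):.4f} at true daphnia fraction "
      f"{peak.f_true:.2f} (zero at 0 and 1)")
print("  -> with an enriched endmember, prefer mode='atom_fraction'.")
print()

sd_f = ip.propagate_fraction_sd(0.2, ends)
print(f"0.2 permil instrument accuracy over the {ends.separation_permil:.0f} "
      f"permil endmember separation")
print(f"  -> source-fraction uncertainty {sd_f:.2e} (the label makes the")
print("     partition essentially immune to measurement noise)")
print()

conc = ip.dissolved_co2_from_headspace(
    1000.0, temperature_c=20.0, headspace_vol_ml=5.0, water_vol_ml=12.0
)
print("headspace equilibration: 1000 ppm CO2 over 12 ml water at 20 C")
print(f"  -> original dissolved CO2 = {conc:.1f} umol/l "
      f"(Weiss-type K0 solubility)")
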