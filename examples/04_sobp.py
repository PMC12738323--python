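"""Build a spread-out Bragg peak from weighted pristine layers and
characterize its plateau and PVDR reduction.

The five default layers (100-110 MeV, heaviest weight on the deepest) form
a dose plateau over 7-9 cm.  For a collimated minibeam delivery the
central-axis maximum sits proximal to the plateau, and the biological PVDR
stays below the physical one at every depth.
"""

import numpy as np

import minipvdr as m

spec = m.SOBPSpec()
print("SOBP layers (MeV, weight):", spec.layers)

# open-field (no collimator) analytic depth dose; 1.1% energy spread is
# the commissioning value interpolated to the 100-110 MeV layer range
z = np.linspace(0.0, 11.0, 1101)
d = m.sobp_depth_dose(z, spec, energy_spread_pct=1.1)
pm = m.plateau_metrics(z, d, spec)
print(f"open-field plateau mean    : {pm.plateau_mean:.3f} (arb. units)")
print(f"plateau flatness           : {pm.flatness_percent:.1f} %")
print(f"distal 90% depth           : {pm.distal_depth_cm:.2f} cm "
      f"(110 MeV range = {m.range_from_energy(110.0):.2f} cm)")

# collimated minibeam SOBP phantom
phantom = m.build_sobp_phantom(
    spec, m.CollimatorSpec(2.0, 6.0),
    m.GeometrySpec(air_gap=5.0, scoring_dims=(4.0, 4.0, 11.0),
                   dose_voxel=(0.5, 0.5, 2.0)),
    m.GeneratorParams(), prescription=2.0, seed=3)

for rec in m.analyze_dataset(phantom, m.TissueModelSpec("mcnamara", 3.0),
                             depths=(1.0, 4.0, 8.0)):
    print(f"depth {rec['depth_cm']:4.1f} cm : PVDR_phys = "
          f"{rec['pvdr_phys']:6.2f}  PVDR_biol = {rec['pvdr_biol']:6.2f}  "
          f"reduction = {rec['reduction_percent']:5.1f} %")

print("\nEven in the clinically shaped SOBP field the RBE-weighted valley "
      "dose erodes the peak-to-valley contrast at every depth.")
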