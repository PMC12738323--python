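"""Generate a collimated 70 MeV minibeam phantom and inspect one lateral
dose profile.

The phantom emulates Monte Carlo scoring output for a hexagonally
collimated proton field in water: 2 mm apertures at 6 mm center-to-center
spacing, 5 cm air gap.  The printed profile shows the alternating
peak/valley structure at 1 cm depth; the PVDR is the mean peak dose over
the mean valley dose.
"""

import numpy as np

import minipvdr as m

geometry = m.GeometrySpec(air_gap=5.0, scoring_dims=(6.0, 6.0, 6.0))
phantom = m.generate_phantom(
    beam=m.default_beam(70.0),
    collimator=m.CollimatorSpec(hole_diameter=2.0, ctc=6.0),
    geometry=geometry,
    params=m.GeneratorParams(),
    prescription=2.0,
    seed=1,
)

profile = m.extract_lateral_profile(phantom, depth=1.0)
pv = m.find_peaks_valleys(profile, phantom.collimator)
pvdr, mean_peak, mean_valley, _, _ = m.compute_pvdr(profile, pv)

print("lateral dose profile at 1 cm depth (every 6th sample):")
for x, d in list(zip(profile.positions, profile.dose))[::6]:
    bar = "#" * int(40 * d / profile.dose.max())
    print(f"  x = {x:6.1f} mm   D = {d:6.3f} Gy  {bar}")

print(f"\npeaks at x = {np.round(profile.positions[pv.peak_indices], 1)} mm")
print(f"mean peak dose   : {mean_peak:.3f} Gy")
print(f"mean valley dose : {mean_valley:.4f} Gy")
print(f"PVDR             : {pvdr:.1f}")
print("\nPeaks sit under the collimator apertures; valleys receive only "
      "scattered dose, so a PVDR of ~25 means the inter-beam tissue sees "
      "~4% of the peak dose.")
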