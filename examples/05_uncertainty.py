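"""Propagate per-voxel statistical uncertainties through RBE, biological
dose and the PVDR.

Shows the delta-method chain at a single (dose, LET) point against a
Monte Carlo perturbation check, then the phantom-level effect: biological
PVDR uncertainties dwarf the physical ones because the LET noise enters
through the RBE model.
"""

import numpy as np

import minipvdr as m

UV = m.UncertainValue
spec = m.TissueModelSpec("mcnamara", 3.0)

dose = UV(2.0, 0.02)   # 1% dose noise
let = UV(1.0, 0.10)    # 10% LET noise

r = m.rbe_sigma(spec, dose, let)
b = m.bio_dose_sigma(spec, dose, let)
print(f"RBE      = {r.value:.4f} +- {r.sigma:.5f}")
print(f"D_biol   = {b.value:.4f} +- {b.sigma:.5f} Gy")

rng = np.random.default_rng(1)
n = 10_000
dmc = dose.value + dose.sigma * rng.standard_normal(n)
lmc = let.value + let.sigma * rng.standard_normal(n)
print(f"MC check : sigma(RBE) = {np.std(m.rbe(spec, dmc, lmc)):.5f}, "
      f"sigma(D_biol) = {np.std(dmc * m.rbe(spec, dmc, lmc)):.5f}")

phantom = m.generate_phantom(
    m.default_beam(70.0), m.CollimatorSpec(2.0, 6.0),
    m.GeometrySpec(scoring_dims=(6.0, 6.0, 3.0)),
    m.GeneratorParams(), prescription=2.0, seed=1)
rec = m.analyze_dataset(phantom, spec, depths=(1.0,))[0]
print(f"\nreference phantom at 1 cm depth:")
print(f"  PVDR_phys = {rec['pvdr_phys']:.2f} +- {rec['pvdr_phys_sigma']:.3f}"
      f"  ({100 * rec['pvdr_phys_sigma'] / rec['pvdr_phys']:.2f} % rel.)")
print(f"  PVDR_biol = {rec['pvdr_biol']:.2f} +- {rec['pvdr_biol_sigma']:.3f}"
      f"  ({100 * rec['pvdr_biol_sigma'] / rec['pvdr_biol']:.2f} % rel.)")
print("\nThe biological PVDR carries the larger relative uncertainty: LET "
      "noise feeds in through dRBE/dLET on top of the dose noise.")
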