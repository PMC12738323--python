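# minipvdr

Physical versus biological peak-to-valley dose ratio (PVDR) analysis for
proton minibeam radiotherapy (pMBRT).

## The problem

Spatially fractionated proton therapy delivers dose through
millimeter-scale collimator apertures, producing alternating high-dose
*peaks* and low-dose *valleys*.  Its tissue-sparing promise is almost
always quantified by the physical PVDR — mean peak dose over mean valley
dose along a lateral profile.  But valley dose is deposited by scattered,
energy-degraded protons with elevated dose-averaged LET (LET_d), and
relative biological effectiveness (RBE) rises with LET.  Weighting the dose
voxel-wise by an LET-dependent RBE, D_biol = D·RBE(D, LET_d, α/β), raises
valleys more than peaks, so the biological PVDR is systematically lower
than the physical one — most strongly in late-responding normal tissue
(α/β ≈ 3 Gy), which is exactly what minibeams are meant to spare.

`minipvdr` packages that analysis for physicists and radiobiology
modelers: synthetic minibeam dose/LET_d phantoms with Monte-Carlo-like
structure (Bortfeld Bragg curves, hexagonal beamlet lattices, valley LET
elevation, per-voxel statistical noise), three closed-form RBE models
(McNamara, Carabe-Fernandez, Wedenberg) with the shared linear-quadratic
form

    RBE = (1/2D)·(√((α/β)² + 4D(α/β)·RBE_max(L) + 4D²·RBE_min(L)²) − α/β),

profile extraction and peak/valley detection, PVDR_phys / PVDR_biol with
analytic (delta-method) uncertainty propagation, parameter sweeps over
collimation geometry, and spread-out Bragg peak (SOBP) construction.
Grids read and write as MetaImage (.mhd/.raw); results as CSV/JSON.  See
`docs/methods.md` for the full model description and assumptions.

## A worked example

```python
import minipvdr as m

phantom = m.generate_phantom(
    beam=m.default_beam(70.0),                      # 70 MeV, commissioning phase space
    collimator=m.CollimatorSpec(hole_diameter=2.0, ctc=6.0),
    geometry=m.GeometrySpec(air_gap=5.0, scoring_dims=(6.0, 6.0, 6.0)),
    params=m.GeneratorParams(),                     # valley LET excess 5 keV/um, 1% noise
    prescription=2.0, seed=1)

for rec in m.analyze_dataset(phantom, m.TissueModelSpec("mcnamara", 3.0),
                             depths=(1.0, 2.0, 4.0)):
    print(f"depth {rec['depth_cm']:.0f} cm: "
          f"PVDR_phys = {rec['pvdr_phys']:5.2f} ± {rec['pvdr_phys_sigma']:.2f}  "
          f"PVDR_biol = {rec['pvdr_biol']:5.2f} ± {rec['pvdr_biol_sigma']:.2f}  "
          f"reduction = {rec['reduction_percent']:4.1f} %")
```

prints

```
depth 1 cm: PVDR_phys = 24.91 ± 0.17  PVDR_biol = 16.48 ± 0.13  reduction = 33.9 %
depth 2 cm: PVDR_phys = 20.77 ± 0.14  PVDR_biol = 13.83 ± 0.11  reduction = 33.4 %
depth 4 cm: PVDR_phys =  6.10 ± 0.04  PVDR_biol =  4.15 ± 0.03  reduction = 31.9 %
```

Read: at 1 cm depth the physical dose contrast is ~25:1, but once the
elevated valley LET is translated into RBE-weighted dose the contrast drops
to ~16:1 — a third of the apparent tissue-sparing modulation is an artifact
of scoring physical dose.  The contrast itself fades with depth as the
beamlets widen by multiple Coulomb scattering.  Repeating with
`TissueModelSpec("mcnamara", 10.0)` (tumor-like tissue) gives reductions of
only ~14%, and the physical PVDR falls as the air gap grows — the
parametric orderings the analysis is built to expose.

The `examples/` directory holds one short script per capability: phantom
generation and profiles, the RBE models, the geometry sweep, SOBP
construction, and uncertainty propagation.  A thin CLI wraps the same
library calls:

```bash
minipvdr simulate --energy 70 --hole-diameter 2 --ctc 6 --air-gap 5 \
         --seed 1 --out runs/reference
minipvdr analyze --in runs/reference/dataset --out runs/reanalysis
```

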