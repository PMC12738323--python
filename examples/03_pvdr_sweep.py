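"""Physical vs biological PVDR across a small parameter sweep.

Varies the air gap at the reference collimation (2 mm holes, 6 mm c-t-c,
70 MeV) and reports PVDR_phys, PVDR_biol (McNamara model) and the percent
reduction at three depths, echoing the study-style parametric analysis.
"""

import minipvdr as m

cfg = m.SweepConfig(
    energies=(70.0,),
    hole_diameters=(2.0,),
    ctc_factors=(3.0,),
    air_gaps=(5.0, 10.0, 15.0),
    depths={70.0: (1.0, 2.0, 4.0)},
    models=("mcnamara",),
    alpha_betas=(3.0, 10.0),
    prescriptions=(2.0,),
    geometry=m.GeometrySpec(scoring_dims=(6.0, 6.0, 6.0)),
    seed=7,
)
df = m.run_parameter_sweep(cfg)

cols = ["gap_cm", "depth_cm", "alpha_beta", "pvdr_phys", "pvdr_biol",
        "reduction_percent"]
print(df[cols].round(2).to_string(index=False))

print("\nper-configuration reduction summary (max / mean over depths):")
print(m.summarize_reductions(df)[
    ["gap_cm", "alpha_beta", "max_reduction_percent",
     "mean_reduction_percent"]].round(1).to_string(index=False))

print("\nPVDR falls with depth (beamlet widening) and with air gap "
      "(in-air divergence); the biological PVDR is consistently lower, "
      "and the gap is widest for alpha/beta = 3 Gy — evaluating minibeam "
      "plans on physical dose alone overstates the tissue-sparing "
      "contrast.")
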