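# Methods

`minipvdr` quantifies how much of the peak-to-valley dose ratio (PVDR) of a
collimated proton minibeam field survives when the dose is weighted by a
variable, LET-dependent relative biological effectiveness (RBE).  It does
this on synthetic dose / dose-averaged-LET grids whose statistical and
geometric structure emulates Monte Carlo scoring output, so every stage of
the analysis is testable without transport simulation.

## The analysis model

**PVDR.**  A lateral profile is extracted along a lattice row (+x through
the field center, y = 0) at the dose-grid resolution, at the nearest z
plane to the requested depth.  Peaks are the local dose maxima within
±c-t-c/4 of each projected aperture center (a "guided" search; a blind
local-extrema mode exists as an option).  Valleys are the minimum samples
between consecutive retained peaks.  Peaks and valleys within 10 mm of the
field edge are excluded.  PVDR = mean(peak samples)/mean(valley samples);
the same index sets are reused for the physical and the RBE-weighted
channel, and the biological reduction is
100·(PVDR_phys − PVDR_biol)/PVDR_phys.

**RBE models.**  Three phenomenological linear-quadratic models share the
closed form

    RBE(D, α/β, L) = (1/2D)·(√((α/β)² + 4D(α/β)·RBE_max + 4D²·RBE_min²) − α/β)

with model-specific LET parametrizations of the asymptotes:

| model     | RBE_max                       | RBE_min                      |
|-----------|-------------------------------|------------------------------|
| McNamara  | 0.99064 + 0.35605·L/(α/β)     | 1.1012 − 0.0038703·√(α/β)·L  |
| Carabe    | 0.843 + 0.154·(2.686/(α/β))·L | 1.09 + 0.006·(2.686/(α/β))·L |
| Wedenberg | 1 + 0.434·L/(α/β)             | 1                            |

D is the physical dose (Gy), L the dose-averaged LET (keV/µm).  The radical
is evaluated in the grouped form √((α/β + 2D·RBE_min)² + 4D(α/β)(RBE_max −
RBE_min)) so the degenerate case RBE_max = RBE_min (Wedenberg at L = 0,
where RBE must be exactly 1) does not pass through a rounded square root.
Dose 0 is a domain error — the closed form divides by D, and the D→0 limit
(RBE_max) is deliberately not substituted; voxels below a dose floor
(default 10⁻⁶ of the grid maximum, configurable) are exempted from RBE
weighting, carried through unchanged, and flagged.

A genuine property of the McNamara form worth knowing: because its RBE_min
slope is negative, dRBE/dLET = (p1 + 2D·RBE_min·p3·√(α/β))/√(...) changes
sign above D ≈ 13.2 Gy for α/β = 10 Gy — at extreme doses RBE is no longer
monotone in LET.  The monotonicity tests therefore run on the monotone
domain (D ≤ 12 Gy) and a dedicated test pins the sign flip.

**Biological dose.**  D_biol = D·RBE(D, L) voxel-wise, after the coarse LET
grid is trilinearly interpolated onto the fine dose grid (clamped at the
source boundary; the resampler reproduces any trilinear field exactly).

**Uncertainty propagation.**  First-order (delta-method) propagation with
dose and LET noise treated as independent:

* σ_RBE² = (∂RBE/∂D)²σ_D² + (∂RBE/∂L)²σ_L², with analytic partial
  derivatives for McNamara and central finite differences (relative step
  10⁻⁵) for Carabe and Wedenberg;
* σ_biol² = (RBE + D·∂RBE/∂D)²σ_D² + (D·∂RBE/∂L)²σ_L² — the full chain
  rule, keeping the correlation between the explicit dose factor and the
  dose dependence of RBE.  An independent-combination variant
  ((RBE·σ_D)² + (D·σ_RBE)²) is available behind `correlated=False`; with
  ∂RBE/∂D < 0 it is slightly conservative.  Which variant was used is part
  of the call signature, not a hidden default switch;
* peak/valley means carry the standard error √(Σσ_i²)/n (per-sample sigmas
  uncorrelated across voxels), and PVDR uncertainty is standard ratio
  propagation of the two means, treated as uncorrelated.

All four operations are validated against 10⁴-sample Monte Carlo
perturbation within 5% relative.

## The synthetic phantom generator

The generator produces the study conditions downstream stages assume; it is
first-class, tested code, not a fixture.

* **Depth dose** is the Bortfeld closed-form analytic Bragg curve
  (parabolic cylinder functions), built on the water range power law
  R = αE^p with α = 0.0022 cm·MeV⁻ᵖ, p = 1.77 (4.06 cm at 70 MeV, 15.6 cm
  at 150 MeV), straggling width σ = 0.012·R^0.935 combined in quadrature
  with the range spread induced by the beam's fractional energy spread.
  Far upstream of the peak the equivalent power-law form is used to avoid
  overflow of the parabolic-cylinder product.
* **Lateral beamlets** are area-normalized two-Gaussian mixtures per
  aperture: a core of width σ(z) and a halo of width 4σ(z) carrying
  `halo_fraction` = 0.015 of the fluence, standing in for in-air and
  in-phantom scatter.  σ(z)² = σ_exit² + (divergence·air gap)² + σ_MCS(z)²
  with σ_exit = hole radius and σ_MCS = k_MCS·R·(z/R)^1.7, k_MCS = 0.02 —
  two non-physical fit parameters chosen once to give few-mm spreading at
  range, both configurable.  The halo fraction is calibrated so the
  reference configuration (70 MeV, 2 mm holes at 6 mm c-t-c, 5 cm air gap)
  yields PVDR ≈ 25 at 1 cm depth.
* **LET** is an open-field depth curve rising from `entrance_let`
  (1 keV/µm) to `peak_let` (8 keV/µm) at the Bragg depth as
  (z/R)^3, capped beyond, plus a valley excess
  `valley_let_excess`·(1 − w), where w is the narrow-beam (core-only) dose
  fraction normalized to 1 at aperture centers.  The default excess,
  5 keV/µm, is the midpoint of the 3.5–7 keV/µm LET elevation measured in
  collimated proton fields; the additive form is this package's stated
  assumption, not a measured depth dependence.
* **Noise**: Gaussian, relative levels 1% (dose) and 2% (LET) by default,
  independent draws, exact per-voxel sigmas stored alongside.  One RNG per
  phantom, seeded; identical specs and seed give bit-identical output.
  An optional uniform background dose (default 0) covers the possibility of
  a room-scatter floor.
* **Grids**: dose on 0.5×0.5×1.0 mm³ voxels, LET on 1.0×1.0×10.0 mm³
  (coarser to avoid low-dose LET singularities), both over a central
  scoring region of a 10×10×20 cm³ water phantom.  z = 0 at the phantom
  entrance, values at voxel centers, and one voxel center placed exactly on
  the beam axis (for even counts the region shifts by half a voxel) so
  axis and lattice-row samples hit aperture centers.
* **Beam phase space** defaults to commissioning values (70 MeV:
  σ = 5.74 mm, 6.91 mrad, ρ = 0.798, ΔE = 1.36%; 150 MeV: 4.11 mm,
  3.47 mrad, 0.625, 0.84%), linearly interpolated for intermediate
  energies such as the SOBP layers.

What the generator does *not* emulate: particle transport, nuclear
interactions, collimator edge-scatter microphysics, secondary-fragment LET,
and the detailed spectral evolution of valley protons.  Passing tests
therefore demonstrate the correctness and internal consistency of the
analysis chain and the qualitative structure of minibeam fields (peak
placement, LET contrast, depth/air-gap trends) — not agreement of absolute
PVDR-reduction percentages with transport-simulated or measured fields.

## Hexagonal lattice geometry

Apertures form a triangular lattice with nearest-neighbor distance equal to
the c-t-c spacing, one hole on the axis and a row along +x, clipped to the
square field (half-width 25 mm by default).  The open-area fraction is
π(d/2)²/((√3/2)·ctc²) ≈ 10% for 2 mm holes at 6 mm spacing.  The
dose-uniformity criterion used when choosing c-t-c spacings — the minimal
σ/c-t-c ratio at which a hexagonal array of Gaussian beamlets is laterally
uniform within 95–105% — is computed by brute force: unit Gaussians on ≥ 7
rings of neighbors, the central primitive cell sampled on a 48² grid, the
ratio scanned in steps of 0.005.  The scan returns 0.43, inside the
published 0.40–0.44 band, and agrees with a finer refinement scan (step
0.001, more rings and samples) within one coarse step.

## SOBP construction

Layer phantoms are generated per energy on the raw per-fluence dose scale
(no per-layer peak normalization), superposed with the weights, then the
central-axis mean over the plateau window (7–9 cm) is scaled to the
prescription.  The combined LET is the dose-weighted mean of the layer
LETs — standard practice for dose-averaged quantities, stated here as a
package decision — with layer dose sampled at the coarse LET voxel centers
as the weight field; zero-dose voxels have no defined LET and are flagged.
Weights are used as given (the default set sums to 1.000).  Layer seeds
derive deterministically from the run seed.  The resulting minibeam SOBP
central axis is proximally dominated: the plateau sits below the proximal
maximum because beamlet widening depresses the peak dose faster than the
Bragg superposition raises it.

## Numerical choices and defaults

| parameter | default | meaning |
|---|---|---|
| `range_alpha`, `range_p` | 0.0022, 1.77 | water range power law (cm, MeV) |
| `entrance_let`, `peak_let` | 1, 8 keV/µm | open-field LET_d endpoints |
| `valley_let_excess` | 5 keV/µm | scatter-driven valley LET elevation |
| `halo_fraction`, `halo_sigma_scale` | 0.015, 4 | beamlet scatter halo |
| `k_mcs`, `mcs_power` | 0.02, 1.7 | in-phantom beamlet widening |
| `noise_rel_dose`, `noise_rel_let` | 1%, 2% | statistical noise levels |
| dose floor | 10⁻⁶ × grid max | RBE-weighting exemption |
| edge margin | 10 mm | peak/valley exclusion near the field edge |
| α/β | 3 or 10 Gy | late-responding vs tumor-like tissue |

Ties and degenerate inputs: peak search windows use half-open voxel
indexing with `argmax` (first maximum wins on exact ties); profiles with
fewer than two in-margin peaks raise `InsufficientModulationError`;
non-positive valley samples raise `UndefinedRatioError` rather than
returning an infinite ratio; resampling a degenerate (single-plane) source
axis is an error.

Problem sizes: the bundled tests and examples run the full lateral extent
at the study voxel sizes but truncate the scored depth range to what each
check needs (e.g. 6 cm of water for the 70 MeV analyses, 11 cm with 2 mm
z-voxels for the SOBP); one smoke test exercises the full 6×6×20 cm³ grid.
These are the package's default demonstration sizes; all grids are
configurable through `GeometrySpec`.

## Known limitations

* Absolute PVDR-reduction percentages depend on the assumed valley LET
  model and beamlet halo; only their signs, orderings and trends are
  claims of this package.
* The LQ-based RBE models are first-order descriptions; they carry no
  validity claim at the >8–10 Gy/fraction doses reachable in minibeam
  peaks, and no endpoint beyond cell survival (no vascular/immune effects,
  no fractionation conversion).
* Uncertainties are statistical only; model-form uncertainty of the RBE
  parametrizations is out of scope, as are covariances across depths.
* Profiles are one-dimensional along a single lattice row; 2-D/3-D PVDR
  maps and dose-volume statistics are non-goals.  Additional rows can be
  extracted with the `y_mm` offset of `extract_lateral_profile` and
  averaged by the caller, but the reported PVDRs follow the single-row
  convention.
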