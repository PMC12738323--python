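"""Input specifications for phantom generation.

The dataclasses here describe the irradiation setup of a collimated proton
minibeam field: the incident pencil-beam-scanning field (:class:`BeamSpec`),
the perforated brass collimator (:class:`CollimatorSpec`), the water phantom
and scoring grids (:class:`GeometrySpec`), and the knobs of the analytic
dose/LET generator (:class:`GeneratorParams`).  All specs are frozen so they
can be hashed, cached and serialized for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


def _as_tuple3(v) -> tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected a 3-vector, got {v!r}")
    return t


@dataclass(frozen=True)
class BeamSpec:
    """Phase-space description of the scanned field at the collimator entrance.

    Defaults are the 70 MeV commissioning values: lateral spread
    sigma_x = sigma_y = 5.74 mm, divergence 6.91 mrad, spatial-angular
    correlation 0.798, energy spread 1.36%, delivered as an 11x11 spot array
    with 5 mm inter-spot spacing.
    """

    energy: float  # MeV
    sigma_spot: float = 5.74  # mm
    divergence: float = 6.91  # mrad
    correlation: float = 0.798
    energy_spread: float = 1.36  # percent of nominal energy
    spot_spacing: float = 5.0  # mm
    spots_per_side: int = 11

    def __post_init__(self):
        if self.energy <= 0:
            raise ValueError("energy must be positive")
        if self.sigma_spot <= 0:
            raise ValueError("sigma_spot must be positive")
        if abs(self.correlation) > 1:
            raise ValueError("correlation must lie in [-1, 1]")
        if self.spots_per_side < 1:
            raise ValueError("spots_per_side must be >= 1")


#: Commissioning phase-space parameters keyed by nominal energy (MeV):
#: (sigma_spot mm, divergence mrad, correlation, energy spread %).
PHASE_SPACE_TABLE = {
    70.0: (5.74, 6.91, 0.798, 1.36),
    150.0: (4.11, 3.47, 0.625, 0.84),
}


def default_beam(energy: float) -> BeamSpec:
    """Beam spec at ``energy`` using the tabulated commissioning phase space.

    Values between the tabulated 70 and 150 MeV anchors are linearly
    interpolated; values outside are clamped to the nearest anchor.
    """
    e_lo, e_hi = 70.0, 150.0
    lo, hi = PHASE_SPACE_TABLE[e_lo], PHASE_SPACE_TABLE[e_hi]
    t = min(1.0, max(0.0, (energy - e_lo) / (e_hi - e_lo)))
    sigma, div, rho, espread = (a + t * (b - a) for a, b in zip(lo, hi))
    return BeamSpec(energy=energy, sigma_spot=sigma, divergence=div,
                    correlation=rho, energy_spread=espread)


@dataclass(frozen=True)
class CollimatorSpec:
    """Hexagonally perforated collimator (default: 2 mm holes, 6 mm c-t-c,
    6.35 cm thick brass, 5x5 cm² field)."""

    hole_diameter: float = 2.0  # mm
    ctc: float = 6.0  # mm, center-to-center spacing
    thickness: float = 6.35  # cm
    pattern: str = "hexagonal"
    field_half_width: float = 25.0  # mm

    def __post_init__(self):
        if not 0 < self.hole_diameter < self.ctc:
            raise ValueError("require 0 < hole_diameter < ctc")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if self.pattern != "hexagonal":
            raise ValueError(f"unsupported pattern {self.pattern!r}")
        if self.field_half_width <= 0:
            raise ValueError("field_half_width must be positive")


@dataclass(frozen=True)
class GeometrySpec:
    """Phantom and scoring-grid geometry.

    Defaults mirror a 10x10x20 cm³ water phantom with a central 6x6x20 cm³
    scoring region, dose scored on 0.5x0.5x1.0 mm³ voxels and dose-averaged
    LET on coarser 1.0x1.0x10.0 mm³ voxels.  z = 0 is the phantom entrance;
    x/y are centered on the beam axis; voxel values live at voxel centers.
    """

    air_gap: float = 5.0  # cm, collimator exit to phantom entrance
    phantom_dims: tuple = (10.0, 10.0, 20.0)  # cm
    scoring_dims: tuple = (6.0, 6.0, 20.0)  # cm
    dose_voxel: tuple = (0.5, 0.5, 1.0)  # mm
    let_voxel: tuple = (1.0, 1.0, 10.0)  # mm

    def __post_init__(self):
        object.__setattr__(self, "phantom_dims", _as_tuple3(self.phantom_dims))
        object.__setattr__(self, "scoring_dims", _as_tuple3(self.scoring_dims))
        object.__setattr__(self, "dose_voxel", _as_tuple3(self.dose_voxel))
        object.__setattr__(self, "let_voxel", _as_tuple3(self.let_voxel))
        if self.air_gap < 0:
            raise ValueError("air_gap must be >= 0")
        if any(lv < dv for lv, dv in zip(self.let_voxel, self.dose_voxel)):
            raise ValueError("let_voxel must be >= dose_voxel componentwise")
        if any(s > p for s, p in zip(self.scoring_dims, self.phantom_dims)):
            raise ValueError("scoring region exceeds phantom")
        if any(v <= 0 for v in self.dose_voxel + self.let_voxel):
            raise ValueError("voxel sizes must be positive")

    def grid_shape(self, voxel_mm: tuple) -> tuple[int, int, int]:
        return tuple(max(1, round(d * 10.0 / v))
                     for d, v in zip(self.scoring_dims, voxel_mm))

    def grid_origin(self, voxel_mm: tuple) -> tuple[float, float, float]:
        """Origin (center of voxel [0,0,0]) in mm.

        A voxel center lies exactly on the beam axis (x = y = 0), so the
        central-axis and lattice-row samples hit aperture centers; for even
        voxel counts the region is therefore offset by half a voxel.  z = 0
        is the phantom entrance, first center at dz/2.
        """
        nx, ny, nz = self.grid_shape(voxel_mm)
        dx, dy, dz = voxel_mm
        return (-((nx - 1) // 2) * dx, -((ny - 1) // 2) * dy, dz / 2.0)


@dataclass(frozen=True)
class GeneratorParams:
    """Tunables of the analytic dose/LET phantom generator.

    ``valley_let_excess`` defaults to 5 keV/um, the midpoint of the 3.5-7
    keV/um LET elevation reported for collimated proton fields.  The two-
    Gaussian beamlet (core + halo, area-normalized mixture) is calibrated so
    the reference configuration (70 MeV, 2 mm holes at 6 mm c-t-c, 5 cm air
    gap) gives PVDR ~ 25 at 1 cm depth.
    """

    entrance_let: float = 1.0  # keV/um, open-field LET_d at the surface
    peak_let: float = 8.0  # keV/um, open-field LET_d at the Bragg depth
    valley_let_excess: float = 5.0  # keV/um added in fully scattered regions
    halo_fraction: float = 0.015  # fraction of beamlet fluence in the halo
    halo_sigma_scale: float = 4.0  # halo width / core width
    noise_rel_dose: float = 0.01  # relative per-voxel dose noise
    noise_rel_let: float = 0.02  # relative per-voxel LET noise
    range_alpha: float = 0.0022  # cm MeV^-p, water range power law
    range_p: float = 1.77
    k_mcs: float = 0.02  # multiple-Coulomb-scattering growth amplitude
    mcs_power: float = 1.7  # MCS growth exponent in (z/R)
    let_rise_power: float = 3.0  # shape of the open-field LET rise
    background: float = 0.0  # uniform dose floor, fraction of prescription

    def __post_init__(self):
        if not self.peak_let > self.entrance_let > 0:
            raise ValueError("require peak_let > entrance_let > 0")
        if self.valley_let_excess < 0:
            raise ValueError("valley_let_excess must be >= 0")
        if not 0 <= self.halo_fraction < 1:
            raise ValueError("halo_fraction must lie in [0, 1)")
        if self.halo_sigma_scale <= 1:
            raise ValueError("halo_sigma_scale must exceed 1")
        if self.range_alpha <= 0 or self.range_p <= 0:
            raise ValueError("range power-law parameters must be positive")
        if self.noise_rel_dose < 0 or self.noise_rel_let < 0:
            raise ValueError("noise levels must be >= 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")


def spec_to_dict(spec) -> dict:
    return dataclasses.asdict(spec)
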