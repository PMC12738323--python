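"""PVDR analysis: LET resampling, lateral profiles, peak/valley detection
and physical vs biological peak-to-valley dose ratios.

The analysis path mirrors how minibeam Monte Carlo output is evaluated: the
coarse LET grid is trilinearly interpolated onto the fine dose grid, a
lateral profile is extracted along a lattice row (+x through the field
center) at a given depth, peaks are located at the projected aperture
centers, valleys at the minima between retained peaks, and the PVDR is the
mean peak dose over the mean valley dose.  Peaks and valleys within 10 mm of
the field boundary are excluded to avoid edge effects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import find_peaks as _scipy_find_peaks

from .grids import PhantomDataset, VoxelGrid3D
from .rbe import TissueModelSpec, biological_dose_grid
from .specs import (CollimatorSpec, GeneratorParams, GeometrySpec,
                    default_beam)
from .uncertainty import UncertainValue, bio_dose_sigma, mean_with_sem, pvdr_sigma


class InsufficientModulationError(ValueError):
    """Raised when a profile has too few peaks for a PVDR."""


class UndefinedRatioError(ValueError):
    """Raised when a valley sample is non-positive."""


def resample_trilinear(src: VoxelGrid3D, target: VoxelGrid3D) -> VoxelGrid3D:
    """Resample ``src`` onto the geometry of ``target`` by trilinear
    interpolation between the 8 surrounding source voxel centers.

    Target points outside the source extent are clamped to the boundary.
    Reproduces any trilinear field exactly.
    """
    axes = [src.axis_coords(a) for a in range(3)]
    for a, c in enumerate(axes):
        if c.size < 2:
            raise ValueError(f"source axis {a} is degenerate (size {c.size}); "
                             "cannot interpolate")
    interp = RegularGridInterpolator(axes, src.values, method="linear",
                                     bounds_error=False, fill_value=None)
    tcoords = [np.clip(target.axis_coords(a), axes[a][0], axes[a][-1])
               for a in range(3)]
    xx, yy, zz = np.meshgrid(*tcoords, indexing="ij")
    out = interp(np.stack([xx, yy, zz], axis=-1))
    return VoxelGrid3D(out, target.origin, target.spacing, src.quantity)


@dataclass
class LateralProfile:
    """All channels of one lateral profile along +x at y = 0."""

    positions: np.ndarray  # mm
    depth: float  # cm
    dose: np.ndarray
    dose_sigma: np.ndarray
    let: np.ndarray
    let_sigma: np.ndarray
    bio_dose: np.ndarray | None = None
    bio_sigma: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.positions)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        for name in ("dose", "dose_sigma", "let", "let_sigma",
                     "bio_dose", "bio_sigma"):
            ch = getattr(self, name)
            if ch is not None and len(ch) != n:
                raise ValueError(f"channel {name} length mismatch")

    def channel(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """(values, sigmas) for the 'physical' or 'biological' channel."""
        if which == "physical":
            return self.dose, self.dose_sigma
        if which == "biological":
            if self.bio_dose is None:
                raise ValueError("profile carries no biological channel")
            return self.bio_dose, self.bio_sigma
        raise ValueError(f"unknown channel {which!r}")


@dataclass
class PeakValleySet:
    """Indices of detected peaks and valleys in a LateralProfile."""

    peak_indices: list
    valley_indices: list
    excluded_margin: float = 10.0  # mm


@dataclass
class PVDRResult:
    """Physical and biological PVDR at one (configuration, depth, model,
    alpha/beta) with propagated sigmas and the percent reduction."""

    pvdr_phys: float
    pvdr_phys_sigma: float
    pvdr_biol: float
    pvdr_biol_sigma: float
    reduction_percent: float


def extract_lateral_profile(dataset: PhantomDataset,
                            let_fine: VoxelGrid3D | None = None,
                            let_sigma_fine: VoxelGrid3D | None = None,
                            bio: VoxelGrid3D | None = None,
                            bio_sigma: np.ndarray | None = None,
                            depth: float = 1.0,
                            y_mm: float = 0.0) -> LateralProfile:
    """Sample all channels along +x through the field center at ``depth`` cm.

    Channels are sampled at the dose-grid resolution on the nearest z plane
    and the nearest y row to ``y_mm`` (default: the lattice row on the
    axis).  ``let_fine`` is the LET grid already resampled to the dose
    geometry (computed here if omitted).
    """
    dose = dataset.dose
    zmm = depth * 10.0
    zcoords = dose.axis_coords(2)
    if not (zcoords[0] - dose.spacing[2] / 2 <= zmm
            <= zcoords[-1] + dose.spacing[2] / 2):
        raise ValueError(f"depth {depth} cm outside the scored z range")
    iz = dose.nearest_index(2, zmm)
    iy = dose.nearest_index(1, y_mm)
    if let_fine is None:
        let_fine = resample_trilinear(dataset.let, dose)
    if let_sigma_fine is None:
        let_sigma_fine = resample_trilinear(dataset.let_sigma, dose)
    return LateralProfile(
        positions=dose.axis_coords(0),
        depth=depth,
        dose=dose.values[:, iy, iz].copy(),
        dose_sigma=dataset.dose_sigma.values[:, iy, iz].copy(),
        let=let_fine.values[:, iy, iz].copy(),
        let_sigma=let_sigma_fine.values[:, iy, iz].copy(),
        bio_dose=None if bio is None else bio.values[:, iy, iz].copy(),
        bio_sigma=None if bio_sigma is None else bio_sigma[:, iy, iz].copy(),
    )


def projected_aperture_x(collimator: CollimatorSpec) -> np.ndarray:
    """x positions (mm) of the aperture centers on the +x lattice row."""
    a = collimator.ctc
    kmax = int(np.floor(collimator.field_half_width / a))
    return a * np.arange(-kmax, kmax + 1)


def find_peaks_valleys(profile: LateralProfile, collimator: CollimatorSpec,
                       field_half_width: float | None = None,
                       margin: float = 10.0,
                       mode: str = "guided") -> PeakValleySet:
    """Locate peaks and valleys of the dose channel.

    ``guided`` (default): peaks are the local dose maxima within +-ctc/4 of
    each projected aperture center -- robust at depth where modulation
    fades.  ``blind``: scipy local-extrema detection.  Valleys are the
    minimum samples between consecutive retained peaks.  Peaks within
    ``margin`` mm of the field boundary are excluded.
    """
    if field_half_width is None:
        field_half_width = collimator.field_half_width
    x, d = profile.positions, profile.dose
    xmax = field_half_width - margin

    peaks: list[int] = []
    if mode == "guided":
        for xc in projected_aperture_x(collimator):
            if abs(xc) > xmax:
                continue
            win = np.nonzero(np.abs(x - xc) <= collimator.ctc / 4.0)[0]
            if win.size == 0:
                continue
            peaks.append(int(win[np.argmax(d[win])]))
    elif mode == "blind":
        idx, _ = _scipy_find_peaks(d)
        peaks = [int(i) for i in idx if abs(x[i]) <= xmax]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    peaks = sorted(set(peaks))

    if len(peaks) < 2:
        raise InsufficientModulationError(
            "fewer than 2 peaks inside the field margin; the profile is not "
            "modulated enough for a PVDR")

    valleys = []
    for i, j in zip(peaks[:-1], peaks[1:]):
        seg = np.arange(i + 1, j)
        if seg.size:
            valleys.append(int(seg[np.argmin(d[seg])]))
    if not valleys:
        raise InsufficientModulationError("no valley samples between peaks")
    return PeakValleySet(peak_indices=peaks, valley_indices=valleys,
                         excluded_margin=margin)


def compute_pvdr(profile: LateralProfile, pv: PeakValleySet,
                 channel: str = "physical"):
    """(pvdr, mean_peak, mean_valley, sem_peak, sem_valley) for one channel.

    PVDR is the mean of the peak samples over the mean of the valley
    samples; the standard errors come from the stored per-sample sigmas.
    """
    if len(pv.peak_indices) < 2 or len(pv.valley_indices) < 1:
        raise InsufficientModulationError("need >= 2 peaks and >= 1 valley")
    vals, sigs = profile.channel(channel)
    pk = UncertainValue(vals[pv.peak_indices], sigs[pv.peak_indices])
    vl_vals = vals[pv.valley_indices]
    if np.any(vl_vals <= 0):
        raise UndefinedRatioError("non-positive valley sample; PVDR undefined")
    vl = UncertainValue(vl_vals, sigs[pv.valley_indices])
    mp, mv = mean_with_sem(pk), mean_with_sem(vl)
    r = pvdr_sigma(mp, mv)
    return r.value, mp.value, mv.value, mp.sigma, mv.sigma


def pvdr_reduction(pvdr_phys: float, pvdr_biol: float) -> float:
    """Percent reduction 100 (PVDR_phys - PVDR_biol) / PVDR_phys."""
    if pvdr_phys <= 0:
        raise ValueError("pvdr_phys must be positive")
    return 100.0 * (pvdr_phys - pvdr_biol) / pvdr_phys


def analyze_dataset(dataset: PhantomDataset, spec: TissueModelSpec,
                    depths, margin: float = 10.0,
                    correlated: bool = True) -> list[dict]:
    """Full PVDR analysis of one phantom for one tissue model.

    Resamples LET onto the dose grid, computes the voxel-wise biological
    dose and its propagated sigma, and returns one record per depth with
    PVDR_phys, PVDR_biol, their sigmas and the percent reduction.
    """
    dose = dataset.dose
    let_fine = resample_trilinear(dataset.let, dose)
    let_sig_fine = resample_trilinear(dataset.let_sigma, dose)
    bio, below = biological_dose_grid(dose, let_fine, spec)
    bio_sig = dataset.dose_sigma.values.copy()
    ok = ~below
    if np.any(ok):
        u = bio_dose_sigma(
            spec,
            UncertainValue(dose.values[ok], dataset.dose_sigma.values[ok]),
            UncertainValue(let_fine.values[ok], let_sig_fine.values[ok]),
            correlated=correlated)
        bio_sig[ok] = u.sigma
    records = []
    for depth in depths:
        profile = extract_lateral_profile(dataset, let_fine, let_sig_fine,
                                          bio, bio_sig, depth)
        pv = find_peaks_valleys(profile, dataset.collimator, margin=margin)
        pp, _, _, _, _ = compute_pvdr(profile, pv, "physical")
        pb, _, _, _, _ = compute_pvdr(profile, pv, "biological")
        _, mp, mv, sp, sv = compute_pvdr(profile, pv, "physical")
        phys = pvdr_sigma(UncertainValue(mp, sp), UncertainValue(mv, sv))
        _, mpb, mvb, spb, svb = compute_pvdr(profile, pv, "biological")
        biol = pvdr_sigma(UncertainValue(mpb, spb), UncertainValue(mvb, svb))
        res = PVDRResult(
            pvdr_phys=phys.value, pvdr_phys_sigma=phys.sigma,
            pvdr_biol=biol.value, pvdr_biol_sigma=biol.sigma,
            reduction_percent=pvdr_reduction(pp, pb))
        records.append({
            "depth_cm": depth, "model": spec.model,
            "alpha_beta": spec.alpha_beta,
            "pvdr_phys": res.pvdr_phys,
            "pvdr_phys_sigma": res.pvdr_phys_sigma,
            "pvdr_biol": res.pvdr_biol,
            "pvdr_biol_sigma": res.pvdr_biol_sigma,
            "reduction_percent": res.reduction_percent,
            "n_peaks": len(pv.peak_indices),
            "n_valleys": len(pv.valley_indices),
        })
    return records


#: Depths (cm) analyzed per pristine energy (MeV).
DEFAULT_DEPTHS = {70.0: (1.0, 2.0, 4.0), 150.0: (5.0, 10.0, 15.0)}


@dataclass
class SweepConfig:
    """Cartesian parameter study over geometry, model and prescription."""

    energies: tuple = (70.0,)
    hole_diameters: tuple = (1.0, 2.0, 3.0)  # mm
    ctc_factors: tuple = (2.0, 3.0, 4.0)  # c-t-c as multiples of the hole
    air_gaps: tuple = (5.0, 10.0, 15.0)  # cm
    depths: dict = field(default_factory=lambda: dict(DEFAULT_DEPTHS))
    models: tuple = ("mcnamara",)
    alpha_betas: tuple = (3.0, 10.0)
    prescriptions: tuple = (2.0,)  # Gy
    geometry: GeometrySpec = GeometrySpec()
    params: GeneratorParams = GeneratorParams()
    field_half_width: float = 25.0  # mm
    seed: int = 0

    def __post_init__(self):
        if not (self.energies and self.hole_diameters and self.ctc_factors
                and self.air_gaps and self.models and self.alpha_betas
                and self.prescriptions):
            raise ValueError("sweep config has an empty dimension")


def run_parameter_sweep(config: SweepConfig) -> pd.DataFrame:
    """One PVDR record per (energy, hole, c-t-c, gap, depth, model,
    alpha/beta, prescription) combination.

    Phantoms are generated once per geometric configuration at unit
    prescription and rescaled per prescription level; failures (e.g. a
    configuration whose modulation washes out at depth) are recorded
    per-row, not fatal.  Deterministic for a fixed seed.
    """
    rows = []
    geom_id = 0
    for energy, hole, fac, gap in itertools.product(
            config.energies, config.hole_diameters, config.ctc_factors,
            config.air_gaps):
        ctc = hole * fac
        beam = default_beam(energy)
        coll = CollimatorSpec(hole_diameter=hole, ctc=ctc,
                              field_half_width=config.field_half_width)
        geometry = GeometrySpec(
            air_gap=gap, phantom_dims=config.geometry.phantom_dims,
            scoring_dims=config.geometry.scoring_dims,
            dose_voxel=config.geometry.dose_voxel,
            let_voxel=config.geometry.let_voxel)
        depths = config.depths.get(energy, DEFAULT_DEPTHS.get(energy, (1.0,)))
        base = generate_phantom_cached(beam, coll, geometry, config.params,
                                       config.seed + geom_id)
        geom_id += 1
        for presc in config.prescriptions:
            ds = _rescale(base, presc)
            for model, ab in itertools.product(config.models,
                                               config.alpha_betas):
                spec = TissueModelSpec(model=model, alpha_beta=ab)
                common = {"energy_MeV": energy, "hole_mm": hole,
                          "ctc_mm": ctc, "gap_cm": gap,
                          "prescription_Gy": presc}
                try:
                    for rec in analyze_dataset(ds, spec, depths):
                        rows.append({**common, **rec, "error": ""})
                except (InsufficientModulationError,
                        UndefinedRatioError, ValueError) as exc:
                    rows.append({**common, "model": model, "alpha_beta": ab,
                                 "error": str(exc)})
    return pd.DataFrame(rows)


def generate_phantom_cached(beam, coll, geometry, params, seed):
    # local import avoids a cycle at module load
    from .phantom import generate_phantom
    return generate_phantom(beam, coll, geometry, params,
                            prescription=1.0, seed=seed)


def _rescale(ds: PhantomDataset, prescription: float) -> PhantomDataset:
    """Scale a unit-prescription phantom to ``prescription`` Gy (dose and
    dose sigma scale linearly; LET is unchanged)."""
    return PhantomDataset(
        dose=ds.dose.like(ds.dose.values * prescription),
        dose_sigma=ds.dose_sigma.like(ds.dose_sigma.values * prescription),
        let=ds.let, let_sigma=ds.let_sigma, beam=ds.beam,
        collimator=ds.collimator, geometry=ds.geometry, params=ds.params,
        prescription=prescription, seed=ds.seed,
        meta=dict(ds.meta, rescaled=True))


def summarize_reductions(df: pd.DataFrame) -> pd.DataFrame:
    """Per-configuration max and mean PVDR reduction over depths."""
    ok = df[df["error"] == ""].copy()
    keys = ["energy_MeV", "hole_mm", "ctc_mm", "gap_cm", "model",
            "alpha_beta", "prescription_Gy"]
    agg = ok.groupby(keys)["reduction_percent"].agg(["max", "mean"])
    return agg.rename(columns={"max": "max_reduction_percent",
                               "mean": "mean_reduction_percent"}).reset_index()
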