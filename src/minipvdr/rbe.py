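"""Phenomenological LET-dependent proton RBE models.

Three closed-form models of relative biological effectiveness as a function
of physical dose D (Gy), dose-averaged LET (keV/um) and the tissue
radiosensitivity ratio alpha/beta (Gy), all sharing the linear-quadratic
form

    RBE = (1 / 2D) * (sqrt((a/b)^2 + 4 D (a/b) RBE_max + 4 D^2 RBE_min^2)
                      - (a/b))

and differing only in their LET parametrizations of RBE_max (the low-dose
asymptote) and RBE_min (the high-dose asymptote):

* McNamara:  RBE_max = p0 + p1 * LET / (a/b),
             RBE_min = p2 + p3 * sqrt(a/b) * LET,
             p0 = 0.99064, p1 = 0.35605, p2 = 1.1012, p3 = -0.0038703;
* Carabe-Fernandez (V79 reference, (a/b)_ref = 2.686 Gy):
             RBE_max = 0.843 + 0.154 * (2.686 / (a/b)) * LET,
             RBE_min = 1.09 + 0.006 * (2.686 / (a/b)) * LET;
* Wedenberg: RBE_max = 1 + 0.434 * LET / (a/b), RBE_min = 1
             (hence RBE = 1 exactly at LET = 0).

Analytic partial derivatives dRBE/dD and dRBE/dLET are provided for the
McNamara model (used for uncertainty propagation); the other models fall
back to central finite differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grids import VoxelGrid3D

MCNAMARA_COEFFS = {"p0": 0.99064, "p1": 0.35605, "p2": 1.1012, "p3": -0.0038703}
CARABE_COEFFS = {"a_max": 0.843, "b_max": 0.154, "a_min": 1.09,
                 "b_min": 0.006, "ab_ref": 2.686}
WEDENBERG_COEFFS = {"q": 0.434}

MODEL_NAMES = ("mcnamara", "carabe", "wedenberg")


@dataclass(frozen=True)
class TissueModelSpec:
    """An RBE model identity plus the tissue alpha/beta ratio (Gy)."""

    model: str = "mcnamara"
    alpha_beta: float = 3.0

    def __post_init__(self):
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown RBE model {self.model!r}; "
                             f"choose from {MODEL_NAMES}")
        if self.alpha_beta <= 0:
            raise ValueError("alpha_beta must be positive")

    @property
    def coefficients(self) -> dict:
        return dict({"mcnamara": MCNAMARA_COEFFS, "carabe": CARABE_COEFFS,
                     "wedenberg": WEDENBERG_COEFFS}[self.model])


def rbe_max_min(spec: TissueModelSpec, let_d):
    """(RBE_max, RBE_min) at the given dose-averaged LET (keV/um)."""
    let = np.asarray(let_d, dtype=float)
    if np.any(let < 0):
        raise ValueError("let_d must be >= 0")
    ab = spec.alpha_beta
    if spec.model == "mcnamara":
        c = MCNAMARA_COEFFS
        rmax = c["p0"] + c["p1"] * let / ab
        rmin = c["p2"] + c["p3"] * math.sqrt(ab) * let
    elif spec.model == "carabe":
        c = CARABE_COEFFS
        rmax = c["a_max"] + c["b_max"] * (c["ab_ref"] / ab) * let
        rmin = c["a_min"] + c["b_min"] * (c["ab_ref"] / ab) * let
    else:  # wedenberg
        rmax = 1.0 + WEDENBERG_COEFFS["q"] * let / ab
        rmin = np.ones_like(let)
    if np.isscalar(let_d):
        return float(rmax), float(rmin)
    return rmax, rmin


def _radical(dose, ab, rmax, rmin):
    # algebraically sqrt(ab^2 + 4 D ab rmax + 4 D^2 rmin^2); grouped as
    # sqrt((ab + 2 D rmin)^2 + 4 D ab (rmax - rmin)) so the degenerate case
    # rmax == rmin (e.g. Wedenberg at LET = 0) is exact, not a rounded sqrt
    term = ab + 2.0 * dose * rmin
    extra = 4.0 * dose * ab * (rmax - rmin)
    return np.where(extra == 0.0, term, np.sqrt(term**2 + extra))


def rbe(spec: TissueModelSpec, dose, let_d):
    """RBE at physical dose ``dose`` (Gy) and LET ``let_d`` (keV/um).

    The shared closed form divides by dose; a zero dose is a domain error
    (the D -> 0 limit equals RBE_max and is not silently substituted).
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dose must be > 0 for RBE evaluation")
    rmax, rmin = rbe_max_min(spec, let_d)
    ab = spec.alpha_beta
    out = (_radical(d, ab, rmax, rmin) - ab) / (2.0 * d)
    if np.isscalar(dose) and np.isscalar(let_d):
        return float(out)
    return out


def mcnamara_partials(spec: TissueModelSpec, dose, let_d):
    """Analytic (dRBE/dD, dRBE/dLET) for the McNamara model."""
    if spec.model != "mcnamara":
        raise ValueError("analytic partials are available for the McNamara "
                         "model only; use finite_difference_partials")
    d = np.asarray(dose, dtype=float)
    let = np.asarray(let_d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dose must be > 0")
    if np.any(let < 0):
        raise ValueError("let_d must be >= 0")
    c = MCNAMARA_COEFFS
    ab = spec.alpha_beta
    rmax, rmin = rbe_max_min(spec, let)
    s = _radical(d, ab, rmax, rmin)
    d_let = (c["p1"] + 2.0 * d * rmin * c["p3"] * math.sqrt(ab)) / s
    ds_dd = (4.0 * ab * rmax + 8.0 * d * rmin**2) / (2.0 * s)
    d_dose = ds_dd / (2.0 * d) - (s - ab) / (2.0 * d**2)
    if np.isscalar(dose) and np.isscalar(let_d):
        return float(d_dose), float(d_let)
    return d_dose, d_let


def finite_difference_partials(spec: TissueModelSpec, dose, let_d,
                               rel_step: float = 1e-5):
    """Central finite-difference (dRBE/dD, dRBE/dLET) for any model."""
    d = np.asarray(dose, dtype=float)
    let = np.asarray(let_d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dose must be > 0")
    hd = rel_step * d  # relative step keeps the stencil inside dose > 0
    hl = rel_step * np.maximum(np.abs(let), 1.0)
    # keep the LET stencil inside the domain near LET = 0
    lo = np.maximum(let - hl, 0.0)
    d_dose = (rbe(spec, d + hd, let) - rbe(spec, d - hd, let)) / (2.0 * hd)
    d_let = (rbe(spec, d, let + hl) - rbe(spec, d, lo)) / (let + hl - lo)
    if np.isscalar(dose) and np.isscalar(let_d):
        return float(d_dose), float(d_let)
    return d_dose, d_let


def partials(spec: TissueModelSpec, dose, let_d):
    """Model partials: analytic for McNamara, finite differences otherwise."""
    if spec.model == "mcnamara":
        return mcnamara_partials(spec, dose, let_d)
    return finite_difference_partials(spec, dose, let_d)


@dataclass
class RBEEvaluation:
    """RBE with its asymptotes and partial derivatives at one point."""

    rbe: float
    rbe_max: float
    rbe_min: float
    d_rbe_d_dose: float
    d_rbe_d_let: float


def evaluate(spec: TissueModelSpec, dose: float, let_d: float) -> RBEEvaluation:
    rmax, rmin = rbe_max_min(spec, let_d)
    dd, dl = partials(spec, dose, let_d)
    return RBEEvaluation(rbe=rbe(spec, dose, let_d), rbe_max=rmax,
                         rbe_min=rmin, d_rbe_d_dose=dd, d_rbe_d_let=dl)


def biological_dose_grid(dose: VoxelGrid3D, let: VoxelGrid3D,
                         spec: TissueModelSpec,
                         dose_floor: float | None = None
                         ) -> tuple[VoxelGrid3D, np.ndarray]:
    """Voxel-wise RBE-weighted dose D_BIOL = D * RBE(D, LET).

    ``let`` must already be resampled onto the dose geometry.  Voxels with
    dose below ``dose_floor`` (default 1e-6 of the grid maximum, mirroring
    the exclusion of near-empty voxels that would make the RBE form
    singular) keep D_BIOL = D and are returned flagged in the mask.
    """
    if not dose.same_geometry(let):
        raise ValueError("dose and LET grids must share geometry; resample "
                         "the LET grid first")
    d = dose.values
    if dose_floor is None:
        dose_floor = 1e-6 * float(d.max()) if d.size else 0.0
    below = d < dose_floor
    bio = d.copy()
    if np.any(~below):
        bio[~below] = d[~below] * rbe(spec, d[~below], let.values[~below])
    return dose.like(bio, "dose_Gy"), below
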