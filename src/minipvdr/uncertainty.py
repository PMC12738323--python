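"""First-order (delta-method) propagation of per-voxel statistical
uncertainties through RBE, biological dose and the peak-to-valley dose
ratio.

Dose and LET uncertainties are treated as independent; peak and valley means
are treated as uncorrelated; per-sample sigmas are uncorrelated across
voxels.  For the biological dose D_BIOL = D * RBE(D, L) the default is the
full chain rule, which keeps the correlation between the explicit dose
factor and the dose dependence of RBE; an independent-combination variant
(sigma² = (RBE sigma_D)² + (D sigma_RBE)²) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rbe import TissueModelSpec, partials, rbe


@dataclass
class UncertainValue:
    """A value with a one-standard-deviation statistical uncertainty.

    Works elementwise for array-valued ``value``/``sigma``.
    """

    value: float | np.ndarray
    sigma: float | np.ndarray = 0.0

    def __post_init__(self):
        if np.any(np.asarray(self.sigma) < 0):
            raise ValueError("sigma must be >= 0")

    @property
    def relative(self):
        return np.abs(np.asarray(self.sigma) / np.asarray(self.value))


def ratio_sigma(numerator: UncertainValue,
                denominator: UncertainValue) -> UncertainValue:
    """Standard ratio error propagation for independent inputs:
    sigma(N/V) = |N/V| sqrt((sN/N)² + (sV/V)²)."""
    n, v = np.asarray(numerator.value), np.asarray(denominator.value)
    if np.any(v == 0):
        raise ZeroDivisionError("ratio denominator is zero")
    ratio = n / v
    rel = np.sqrt((np.asarray(numerator.sigma) / n) ** 2
                  + (np.asarray(denominator.sigma) / v) ** 2)
    out = np.abs(ratio) * rel
    if np.isscalar(numerator.value) and np.isscalar(denominator.value):
        return UncertainValue(float(ratio), float(out))
    return UncertainValue(ratio, out)


def rbe_sigma(spec: TissueModelSpec, dose: UncertainValue,
              let: UncertainValue) -> UncertainValue:
    """RBE with sigma_RBE = sqrt((dRBE/dD sD)² + (dRBE/dL sL)²)."""
    dd, dl = partials(spec, dose.value, let.value)
    val = rbe(spec, dose.value, let.value)
    sig = np.sqrt((dd * np.asarray(dose.sigma)) ** 2
                  + (dl * np.asarray(let.sigma)) ** 2)
    if np.isscalar(dose.value) and np.isscalar(let.value):
        return UncertainValue(float(val), float(sig))
    return UncertainValue(val, sig)


def bio_dose_sigma(spec: TissueModelSpec, dose: UncertainValue,
                   let: UncertainValue,
                   correlated: bool = True) -> UncertainValue:
    """Biological dose D * RBE(D, L) with propagated uncertainty.

    ``correlated=True`` (default) uses the full chain rule
    sigma² = (RBE + D dRBE/dD)² sD² + (D dRBE/dL)² sL²; ``correlated=False``
    combines sigma_D and sigma_RBE as if independent.
    """
    d = np.asarray(dose.value, dtype=float)
    r = rbe(spec, dose.value, let.value)
    dd, dl = partials(spec, dose.value, let.value)
    sd, sl = np.asarray(dose.sigma), np.asarray(let.sigma)
    if correlated:
        var = ((r + d * dd) * sd) ** 2 + (d * dl * sl) ** 2
    else:
        s_rbe = np.sqrt((dd * sd) ** 2 + (dl * sl) ** 2)
        var = (r * sd) ** 2 + (d * s_rbe) ** 2
    val = d * r
    sig = np.sqrt(var)
    if np.isscalar(dose.value) and np.isscalar(let.value):
        return UncertainValue(float(val), float(sig))
    return UncertainValue(val, sig)


def mean_with_sem(samples: UncertainValue) -> UncertainValue:
    """Mean of samples with the standard error from their stored sigmas:
    sigma(mean) = sqrt(sum sigma_i²) / n."""
    v = np.atleast_1d(np.asarray(samples.value, dtype=float))
    s = np.broadcast_to(np.asarray(samples.sigma, dtype=float), v.shape)
    n = v.size
    if n == 0:
        raise ValueError("cannot average zero samples")
    return UncertainValue(float(v.mean()), float(np.sqrt((s**2).sum()) / n))


def pvdr_sigma(mean_peak: UncertainValue,
               mean_valley: UncertainValue) -> UncertainValue:
    """PVDR with uncertainty: the ratio of the peak and valley means, each
    carrying its standard error."""
    if np.any(np.asarray(mean_valley.value) <= 0):
        raise ZeroDivisionError("valley mean must be positive")
    return ratio_sigma(mean_peak, mean_valley)
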