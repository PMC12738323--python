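"""Hexagonal aperture lattice geometry.

The collimator holes form a triangular (hexagonally packed) lattice with
nearest-neighbor distance equal to the center-to-center spacing, one hole on
the beam axis and a lattice row along +x.  Besides enumerating aperture
positions, this module provides the open-area fraction of the pattern and a
brute-force scan for the minimal Gaussian-width-to-spacing ratio that merges
a hexagonal array of beamlets into a laterally uniform (95-105%) field --
the classic dose-uniformity criterion used when choosing c-t-c spacings.
"""

from __future__ import annotations

import math

import numpy as np

from .specs import CollimatorSpec

SQRT3 = math.sqrt(3.0)


def hex_lattice_positions(collimator: CollimatorSpec) -> np.ndarray:
    """Aperture centers (N, 2) in mm, clipped to the square field.

    The lattice contains the origin, has a row along +x, and every interior
    point sits at distance ``ctc`` from its nearest neighbors.
    """
    a = collimator.ctc
    hw = collimator.field_half_width
    jmax = int(math.floor(hw / (a * SQRT3 / 2.0))) + 1
    pts = []
    for j in range(-jmax, jmax + 1):
        y = a * SQRT3 / 2.0 * j
        if abs(y) > hw:
            continue
        xoff = a / 2.0 * j
        imin = int(math.floor((-hw - xoff) / a))
        imax = int(math.ceil((hw - xoff) / a))
        for i in range(imin, imax + 1):
            x = a * i + xoff
            if abs(x) <= hw:
                pts.append((x, y))
    if not pts:
        raise ValueError("field too small to contain any aperture")
    pts = np.array(sorted(pts, key=lambda p: (p[1], p[0])))
    return pts


def aperture_fill_fraction(collimator: CollimatorSpec) -> float:
    """Open-area fraction of the hexagonal pattern.

    One hole of diameter d per primitive cell of area (sqrt(3)/2) ctc²;
    ~0.10 for 2 mm holes at 6 mm c-t-c, i.e. the peaks occupy roughly a
    tenth of the tissue cross-section.
    """
    d, a = collimator.hole_diameter, collimator.ctc
    if d >= a:
        raise ValueError("holes overlap: hole_diameter must be < ctc")
    return math.pi * (d / 2.0) ** 2 / (SQRT3 / 2.0 * a**2)


def _infinite_lattice(a: float, rings: int) -> np.ndarray:
    idx = np.arange(-rings, rings + 1)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    x = a * (ii + 0.5 * jj)
    y = a * (SQRT3 / 2.0) * jj
    return np.column_stack([x.ravel(), y.ravel()])


def lattice_uniformity_extrema(ratio: float, n_samples: int = 48,
                               rings: int = 8) -> tuple[float, float]:
    """(min/mean, max/mean) of a hex superposition of unit Gaussians.

    Unit-amplitude isotropic 2-D Gaussians of width sigma = ratio * a are
    placed on a hexagonal lattice (``rings`` rings of neighbors, >= 7 for
    convergence); the central primitive cell (rhombus spanned by the two
    lattice vectors) is sampled on an ``n_samples``² grid.
    """
    a = 1.0  # the criterion is scale invariant in the spacing
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    pts = _infinite_lattice(a, rings)
    sigma = ratio * a
    u = (np.arange(n_samples) + 0.5) / n_samples
    uu, vv = np.meshgrid(u, u, indexing="ij")
    x = a * uu + a / 2.0 * vv
    y = a * (SQRT3 / 2.0) * vv
    d2 = (x[..., None] - pts[:, 0]) ** 2 + (y[..., None] - pts[:, 1]) ** 2
    f = np.exp(-d2 / (2.0 * sigma**2)).sum(axis=-1)
    m = f.mean()
    return float(f.min() / m), float(f.max() / m)


def lattice_uniformity_threshold(scan_lo: float = 0.30, scan_hi: float = 0.55,
                                 step: float = 0.005, n_samples: int = 48,
                                 rings: int = 8,
                                 band: tuple = (0.95, 1.05)) -> float | None:
    """Smallest sigma/c-t-c ratio giving 95-105% lateral dose uniformity.

    Scans ``[scan_lo, scan_hi]`` in steps of ``step`` and returns the first
    ratio for which every sample of the central primitive cell lies within
    ``band`` of the cell mean, or ``None`` if no scanned ratio qualifies.
    """
    if not 0 < scan_lo < scan_hi:
        raise ValueError("require 0 < scan_lo < scan_hi")
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round((scan_hi - scan_lo) / step))
    for k in range(n + 1):
        ratio = scan_lo + k * step
        lo, hi = lattice_uniformity_extrema(ratio, n_samples, rings)
        if lo >= band[0] and hi <= band[1]:
            return float(ratio)
    return None
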