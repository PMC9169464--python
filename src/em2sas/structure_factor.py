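"""Structure factors from g(r), plus a brute-force Debye-sum oracle.

The structure factor S(q) encodes inter-particle spatial correlations.
For an isotropic system it is a one-dimensional transform of g(r) - 1:

* planar-3d (spherically symmetric, sinc kernel):
      S(q) = 1 + 4 pi rho   ∫ [g(r) - 1] r^2 sin(qr)/(qr) dr
* 2d (cylindrically symmetric, J0 Hankel kernel):
      S(q) = 1 + 2 pi rho_A ∫ [g(r) - 1] r J0(qr) dr

Both integrals run over the finite window [0, r_max] of the binned
g(r) by the trapezoid rule.  ``debye_sum`` computes S(q) directly from
the particle coordinates by exact O(N^2) pair enumeration and serves
as an independent cross-check of the transforms.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import pdist
from scipy.special import j0

from .form_factor import QGrid, ScatteringCurve
from .particle_extraction import ParticleSet
from .spatial_stats import RadialDistribution

__all__ = [
    "structure_factor_3d",
    "structure_factor_2d",
    "structure_factor_planar",
    "debye_sum",
    "find_primary_peak",
]


def _check_nonnegative(values: np.ndarray) -> None:
    if values.min() < -1e-12:
        warnings.warn(
            f"S(q) dips to {values.min():.3g} < 0; the underlying g(r) is "
            "probably under-resolved (values are reported unclipped)",
            stacklevel=3,
        )


def _taper(r: np.ndarray, r_max: float, lorch: bool) -> np.ndarray:
    if not lorch:
        return np.ones_like(r)
    # Lorch window sin(pi r / r_max)/(pi r / r_max): damps truncation ringing.
    x = np.pi * r / r_max
    out = np.ones_like(r)
    nz = x > 1e-12
    out[nz] = np.sin(x[nz]) / x[nz]
    return out


def structure_factor_3d(
    rdf: RadialDistribution, qs: np.ndarray, lorch: bool = False
) -> ScatteringCurve:
    """S(q) from a planar-3d g(r) via the isotropic sinc-kernel transform."""
    if rdf.mode != "planar-3d":
        raise ValueError(f"expected an rdf in mode 'planar-3d', got {rdf.mode!r}")
    q = QGrid.validate(qs)
    r = rdf.r_centers
    h = (rdf.g - 1.0) * _taper(r, rdf.r_max, lorch)
    x = q[:, None] * r[None, :]
    sinc = np.ones_like(x)
    nz = x > 1e-12
    sinc[nz] = np.sin(x[nz]) / x[nz]
    integrand = h[None, :] * r[None, :] ** 2 * sinc
    values = 1.0 + 4.0 * np.pi * rdf.rho * np.trapezoid(integrand, r, axis=1)
    _check_nonnegative(values)
    return ScatteringCurve(q=q, values=values, kind="structure_factor")


def structure_factor_2d(
    rdf: RadialDistribution, qs: np.ndarray, lorch: bool = False
) -> ScatteringCurve:
    """S(q) from a 2-D g(r) via the zeroth-order Hankel transform."""
    if rdf.mode != "2d":
        raise ValueError(f"expected an rdf in mode '2d', got {rdf.mode!r}")
    q = QGrid.validate(qs)
    r = rdf.r_centers
    h = (rdf.g - 1.0) * _taper(r, rdf.r_max, lorch)
    integrand = h[None, :] * r[None, :] * j0(q[:, None] * r[None, :])
    values = 1.0 + 2.0 * np.pi * rdf.rho * np.trapezoid(integrand, r, axis=1)
    _check_nonnegative(values)
    return ScatteringCurve(q=q, values=values, kind="structure_factor")


def structure_factor_planar(
    rdf: RadialDistribution, qs: np.ndarray, depth: float, lorch: bool = False
) -> ScatteringCurve:
    """S(q) for a monolayer of particles embedded in a 3-D slab.

    The pair correlations of a monolayer live entirely in its plane,
    so g(r) is measured with the 2-D estimator; but the scattering
    experiment averages over a 3-D volume of depth ``depth`` (Å), so
    the density entering the sinc-kernel transform is the slab density
    rho = rho_A / depth:

        S(q) = 1 + 4 pi (rho_A / D) ∫ [g_2D(r) - 1] r^2 sinc(qr) dr.

    Because that density is small for any macroscopic depth, S(q)
    stays close to 1 at every q — in-plane ordering clearly visible in
    the image leaves no trace in the measured intensity.
    """
    if rdf.mode != "2d":
        raise ValueError(
            f"expected an in-plane rdf (mode '2d'), got {rdf.mode!r}"
        )
    if not depth > 0:
        raise ValueError(f"depth must be > 0, got {depth}")
    q = QGrid.validate(qs)
    r = rdf.r_centers
    h = (rdf.g - 1.0) * _taper(r, rdf.r_max, lorch)
    x = q[:, None] * r[None, :]
    sinc = np.ones_like(x)
    nz = x > 1e-12
    sinc[nz] = np.sin(x[nz]) / x[nz]
    rho = rdf.rho / depth  # areal density spread over the slab depth
    values = 1.0 + 4.0 * np.pi * rho * np.trapezoid(h[None, :] * r[None, :] ** 2 * sinc, r, axis=1)
    _check_nonnegative(values)
    return ScatteringCurve(q=q, values=values, kind="structure_factor")


def debye_sum(particles: ParticleSet, qs: np.ndarray, kernel: str = "sinc") -> ScatteringCurve:
    """Exact S(q) by pair enumeration: S(q) = 1 + (1/N) sum_{j != k} K(q d_jk).

    ``kernel`` is "sinc" (isotropic 3-D average) or "J0" (2-D in-plane
    average).  O(N^2) in time and memory over the pair distances; this
    is the brute-force oracle the g(r)-transform route is checked
    against.
    """
    if kernel not in ("sinc", "J0"):
        raise ValueError(f"kernel must be 'sinc' or 'J0', got {kernel!r}")
    q = QGrid.validate(qs)
    n = particles.n
    if n < 1:
        raise ValueError("need at least one particle")
    if n == 1:
        return ScatteringCurve(q=q, values=np.ones_like(q), kind="structure_factor")
    d = pdist(particles.coords)  # unique pairs j < k
    x = q[:, None] * d[None, :]
    if kernel == "sinc":
        k = np.ones_like(x)
        nz = x > 1e-12
        k[nz] = np.sin(x[nz]) / x[nz]
    else:
        k = j0(x)
    # each unordered pair appears twice in sum_{j != k}
    values = 1.0 + (2.0 / n) * k.sum(axis=1)
    return ScatteringCurve(q=q, values=values, kind="structure_factor")


def find_primary_peak(curve: ScatteringCurve, q_lo: float, q_hi: float) -> float:
    """Locate the q of the maximum of a curve within [q_lo, q_hi].

    The grid maximum is refined by a parabola through the three
    surrounding points.  A maximum sitting on the window boundary, or a
    flat window, triggers a warning (the true peak may lie outside).
    """
    q, v = curve.q, curve.values
    mask = (q >= q_lo) & (q <= q_hi)
    if mask.sum() < 3:
        raise ValueError(
            f"window [{q_lo:g}, {q_hi:g}] must contain at least 3 grid points"
        )
    qw, vw = q[mask], v[mask]
    if np.ptp(vw) == 0:
        warnings.warn(
            "curve is flat in the window; no peak to locate", stacklevel=2
        )
        return float(qw[0])
    i = int(np.argmax(vw))
    if i in (0, qw.size - 1):
        warnings.warn(
            "maximum lies on the window boundary; the peak may lie outside "
            f"[{q_lo:g}, {q_hi:g}]",
            stacklevel=2,
        )
        return float(qw[i])
    # parabolic refinement through (q_{i-1}, q_i, q_{i+1})
    x0, x1, x2 = qw[i - 1], qw[i], qw[i + 1]
    y0, y1, y2 = vw[i - 1], vw[i], vw[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:  # degenerate curvature; keep the grid maximum
        return float(x1)
    vertex = -b / (2.0 * a)
    if not (x0 <= vertex <= x2):
        return float(x1)
    return float(vertex)
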