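"""Analytical form factors with Gaussian polydispersity.

The form factor P(q) carries the size-and-shape contribution of a
single scatterer to the small-angle scattering intensity.  Two
geometries are supported:

* a homogeneous sphere of radius r,
      P(q) = [3 (sin(qr) - qr cos(qr)) / (qr)^3]^2,
* the cross-section of an infinitely long cylinder of radius r,
      P(q) = [2 J1(qr) / (qr)]^2.

Both are normalized so that P(0) = 1; the particle-volume factor V(r)^2
that scales scattered intensity enters only as the weight of the
polydispersity average, so polydisperse curves also satisfy P(0) = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .particle_extraction import SizeDistribution

__all__ = [
    "GEOMETRIES",
    "QGrid",
    "ScatteringCurve",
    "make_qgrid",
    "sphere_form_factor",
    "cylinder_form_factor",
    "polydisperse_form_factor",
]

GEOMETRIES = ("planar-spheres", "parallel-cylinders")


def make_qgrid(q_min: float = 1e-3, q_max: float = 1.0, n_q: int = 200) -> np.ndarray:
    """Log-spaced momentum-transfer grid in Å⁻¹ (q = 0 excluded)."""
    if not 0 < q_min < q_max:
        raise ValueError(f"need 0 < q_min < q_max, got {q_min}, {q_max}")
    if n_q < 2:
        raise ValueError(f"need at least 2 grid points, got {n_q}")
    return np.geomspace(q_min, q_max, n_q)


class QGrid:
    """Validator for momentum-transfer grids: strictly increasing, > 0."""

    @staticmethod
    def validate(q: np.ndarray) -> np.ndarray:
        q = np.atleast_1d(np.asarray(q, dtype=float))
        if q.ndim != 1 or q.size == 0:
            raise ValueError("q grid must be a non-empty 1-D array")
        if q[0] <= 0:
            raise ValueError("q grid must be strictly positive (q = 0 excluded)")
        if q.size > 1 and np.any(np.diff(q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        return q


@dataclass(frozen=True)
class ScatteringCurve:
    """A curve on a q grid: P(q), S(q) or I(q).

    ``kind`` is one of {"form_factor", "structure_factor", "intensity"};
    ``geometry`` (optional) records which case study produced it.
    """

    q: np.ndarray
    values: np.ndarray
    kind: str
    geometry: str | None = None

    KINDS = ("form_factor", "structure_factor", "intensity")

    def __post_init__(self) -> None:
        q = QGrid.validate(self.q)
        values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if values.shape != q.shape:
            raise ValueError(
                f"values shape {values.shape} does not match q grid {q.shape}"
            )
        if self.kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}, got {self.kind!r}")
        if self.geometry is not None and self.geometry not in GEOMETRIES:
            raise ValueError(
                f"geometry must be one of {GEOMETRIES}, got {self.geometry!r}"
            )
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "values", values)


def _sphere_amplitude(x: np.ndarray) -> np.ndarray:
    """3 (sin x - x cos x) / x^3 with its x -> 0 limit of 1."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    big = np.abs(x) > 1e-4
    xb = x[big]
    out[big] = 3.0 * (np.sin(xb) - xb * np.cos(xb)) / xb**3
    small = ~big
    # Taylor: 1 - x^2/10 + x^4/280
    xs = x[small]
    out[small] = 1.0 - xs**2 / 10.0 + xs**4 / 280.0
    return out


def _cylinder_amplitude(x: np.ndarray) -> np.ndarray:
    """2 J1(x) / x with its x -> 0 limit of 1."""
    from scipy.special import j1

    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    big = np.abs(x) > 1e-4
    xb = x[big]
    out[big] = 2.0 * j1(xb) / xb
    xs = x[~big]
    out[~big] = 1.0 - xs**2 / 8.0 + xs**4 / 192.0
    return out


def sphere_form_factor(q, r: float):
    """Normalized sphere form factor, P(0) = 1.  q in Å⁻¹, r in Å."""
    if not r > 0:
        raise ValueError(f"radius must be > 0, got {r}")
    q = np.asarray(q, dtype=float)
    if q.size and q.min() < 0:
        raise ValueError("q must be >= 0")
    result = _sphere_amplitude(q * r) ** 2
    return result if result.ndim else float(result)


def cylinder_form_factor(q, r: float):
    """Normalized infinite-cylinder cross-section form factor, P(0) = 1."""
    if not r > 0:
        raise ValueError(f"radius must be > 0, got {r}")
    q = np.asarray(q, dtype=float)
    if q.size and q.min() < 0:
        raise ValueError("q must be >= 0")
    result = _cylinder_amplitude(q * r) ** 2
    return result if result.ndim else float(result)


def _volume_weight(r: np.ndarray, geometry: str) -> np.ndarray:
    if geometry == "planar-spheres":
        return (4.0 / 3.0 * np.pi * r**3) ** 2
    return (np.pi * r**2) ** 2  # cylinder cross-section per unit length


def polydisperse_form_factor(
    qs: np.ndarray,
    dist: SizeDistribution,
    geometry: str,
    weighting: str = "volume2",
    n_nodes: int = 101,
) -> ScatteringCurve:
    """Form factor averaged over a truncated-Gaussian size distribution.

    P(q) = ∫ p(r) w(r) P1(q, r) dr / ∫ p(r) w(r) dr, where P1 is the
    monodisperse form factor and w(r) is the intensity weight: V(r)^2
    for ``weighting="volume2"`` (the default; scattered intensity scales
    with the squared particle volume) or 1 for ``weighting="number"``.
    The quadrature is a trapezoid rule on ``n_nodes`` points over
    r in [max(eps, mu - 4 sigma), mu + 4 sigma]; by construction
    P(q -> 0) = 1.  ``sigma_r = 0`` returns the monodisperse curve.
    """
    q = QGrid.validate(qs)
    if geometry not in GEOMETRIES:
        raise ValueError(f"geometry must be one of {GEOMETRIES}, got {geometry!r}")
    if weighting not in ("volume2", "number"):
        raise ValueError(f"weighting must be 'volume2' or 'number', got {weighting!r}")
    if n_nodes < 3:
        raise ValueError(f"need at least 3 quadrature nodes, got {n_nodes}")

    mono = (
        sphere_form_factor if geometry == "planar-spheres" else cylinder_form_factor
    )
    if dist.sigma_r == 0:
        values = mono(q, dist.mu_r)
        return ScatteringCurve(q=q, values=values, kind="form_factor", geometry=geometry)

    lo = dist.mu_r - 4.0 * dist.sigma_r
    hi = dist.mu_r + 4.0 * dist.sigma_r
    eps = dist.mu_r / 100.0
    if hi <= eps:
        raise ValueError("size distribution has no support at positive radii")
    if lo < eps:
        if dist.sigma_r >= dist.mu_r:
            warnings.warn(
                "size distribution extends far below r = 0; truncating the "
                f"quadrature at r = {eps:.3g} Å",
                stacklevel=2,
            )
        lo = eps
    r = np.linspace(lo, hi, n_nodes)
    weight = dist.pdf(r)
    if weighting == "volume2":
        weight = weight * _volume_weight(r, geometry)
    norm = np.trapezoid(weight, r)
    x = q[:, None] * r[None, :]
    amp = _sphere_amplitude(x) if geometry == "planar-spheres" else _cylinder_amplitude(x)
    values = np.trapezoid(weight[None, :] * amp**2, r, axis=1) / norm
    return ScatteringCurve(q=q, values=values, kind="form_factor", geometry=geometry)
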