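"""Particle extraction from instance-segmentation label maps.

An instance segmentation assigns every pixel of an electron-microscopy
image an integer label: 0 for background, k >= 1 for particle k.  Given
such a label map and the physical pixel size (Å/px), this module turns
each instance into a point scatterer with a physical centroid and a
circle-equivalent radius r = sqrt(A/pi), the quantities all downstream
scattering computations consume.

Conventions
-----------
* 0-based pixel indices; x = column index, y = row index.
* A centroid is the arithmetic mean of member-pixel indices times the
  pixel size (no half-pixel offset — constant offsets cancel in every
  pairwise-distance computation downstream).
* Pixels sharing a label are one particle even if disconnected; the
  upstream segmenter is trusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "LabelMap",
    "ParticleSet",
    "SizeDistribution",
    "InsufficientDataError",
    "read_label_map",
    "extract_particles",
    "fit_size_distribution",
    "read_particle_csv",
    "write_particle_csv",
]


class InsufficientDataError(ValueError):
    """Raised when too few particles are available for a statistic."""


@dataclass(frozen=True)
class LabelMap:
    """Integer raster of particle instances with a physical pixel size.

    Parameters
    ----------
    labels
        2-D array of non-negative integers; 0 is background, each
        nonzero value denotes one particle instance.
    pixel_size
        Physical size of one pixel in Å (> 0).
    """

    labels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError(f"label map must be 2-D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise TypeError(f"label map must hold integers, got dtype {labels.dtype}")
        if labels.size and labels.min() < 0:
            raise ValueError("label values must be non-negative")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "labels", labels)

    @property
    def height_px(self) -> int:
        return self.labels.shape[0]

    @property
    def width_px(self) -> int:
        return self.labels.shape[1]

    @property
    def instance_labels(self) -> np.ndarray:
        """Sorted array of distinct nonzero labels present in the map."""
        values = np.unique(self.labels)
        return values[values > 0]

    @property
    def n_instances(self) -> int:
        return int(self.instance_labels.size)


@dataclass(frozen=True)
class ParticleSet:
    """Particle centroids and equivalent radii in physical units (Å).

    ``coords`` is an (N, 2) array of (x, y) positions, ``radii`` an (N,)
    array of circle-equivalent radii, and ``extent`` the (W, H) physical
    size of the imaged field.
    """

    coords: np.ndarray
    radii: np.ndarray
    extent: tuple[float, float]

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if coords.size == 0:
            coords = coords.reshape(0, 2)
        if coords.shape != (radii.size, 2):
            raise ValueError(
                f"coords shape {coords.shape} inconsistent with {radii.size} radii"
            )
        if radii.size and radii.min() <= 0:
            raise ValueError("all radii must be > 0")
        w, h = self.extent
        if not (w > 0 and h > 0):
            raise ValueError(f"extent must be positive, got {self.extent}")
        if coords.size:
            x, y = coords[:, 0], coords[:, 1]
            if x.min() < 0 or y.min() < 0 or x.max() > w or y.max() > h:
                raise ValueError("coordinates fall outside [0, W] x [0, H]")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "extent", (float(w), float(h)))

    @property
    def n(self) -> int:
        return int(self.radii.size)


@dataclass(frozen=True)
class SizeDistribution:
    """Gaussian radius distribution truncated to r > 0.

    ``mu_r`` and ``sigma_r`` are the mean and standard deviation (Å) of
    the *untruncated* Gaussian; ``pdf`` renormalizes over r > 0 so the
    density integrates to 1.  ``sigma_r = 0`` denotes the monodisperse
    (delta-distribution) limit.
    """

    mu_r: float
    sigma_r: float

    def __post_init__(self) -> None:
        if not self.mu_r > 0:
            raise ValueError(f"mu_r must be > 0, got {self.mu_r}")
        if self.sigma_r < 0:
            raise ValueError(f"sigma_r must be >= 0, got {self.sigma_r}")

    def pdf(self, r: np.ndarray) -> np.ndarray:
        """Truncated-Gaussian density p(r), zero for r <= 0."""
        r = np.asarray(r, dtype=float)
        if self.sigma_r == 0:
            raise ValueError("pdf undefined for the monodisperse limit sigma_r = 0")
        a = (0.0 - self.mu_r) / self.sigma_r  # truncation at r = 0
        return stats.truncnorm.pdf(r, a=a, b=np.inf, loc=self.mu_r, scale=self.sigma_r)


def read_label_map(path: str | Path, pixel_size: float) -> LabelMap:
    """Read a raster label map (PNG or TIFF) into a :class:`LabelMap`.

    The file must carry integer sample values; 8- and 16-bit PNG and
    any integer TIFF are accepted.  ``pixel_size`` is in Å per pixel.
    """
    if not pixel_size > 0:
        raise ValueError(f"pixel_size must be > 0, got {pixel_size}")
    data = np.asarray(iio.imread(Path(path)))
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    if data.ndim != 2:
        raise ValueError(
            f"label map must be a single-channel 2-D raster, got shape {data.shape}"
        )
    if not np.issubdtype(data.dtype, np.integer):
        raise TypeError(
            f"label map pixels must be integers, got dtype {data.dtype}"
        )
    return LabelMap(labels=data, pixel_size=float(pixel_size))


def _border_labels(labels: np.ndarray) -> np.ndarray:
    edge = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    edge = np.unique(edge)
    return edge[edge > 0]


def extract_particles(label_map: LabelMap) -> ParticleSet:
    """Convert a label map into physical-unit centroids and radii.

    For each instance k the centroid is the mean of its pixel indices
    (x = column, y = row) times the pixel size, and the equivalent
    radius is r = sqrt(area_px / pi) * pixel_size.  An empty map yields
    an empty ParticleSet.  Instances touching the image border are kept
    (their truncated area biases r) and reported via a warning.
    """
    labels = label_map.labels
    px = label_map.pixel_size
    extent = (label_map.width_px * px, label_map.height_px * px)
    index = label_map.instance_labels
    if index.size == 0:
        return ParticleSet(
            coords=np.empty((0, 2)), radii=np.empty(0), extent=extent
        )

    border = _border_labels(labels)
    if border.size:
        warnings.warn(
            f"{border.size} particle(s) touch the image border "
            f"(labels {border.tolist()}); their truncated areas bias "
            "the equivalent radii",
            stacklevel=2,
        )

    # (row, col) centroids; areas via label-value histogram.
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels, index)
    centroids = np.asarray(centroids, dtype=float)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index)
    coords = centroids[:, ::-1] * px  # (x, y) = (col, row)
    radii = np.sqrt(areas / np.pi) * px
    return ParticleSet(coords=coords, radii=radii, extent=extent)


def fit_size_distribution(particles: ParticleSet) -> SizeDistribution:
    """Fit a Gaussian radius distribution by sample mean and SD (n-1)."""
    if particles.n < 2:
        raise InsufficientDataError(
            f"need at least 2 particles to fit a size distribution, got {particles.n}"
        )
    return SizeDistribution(
        mu_r=float(np.mean(particles.radii)),
        sigma_r=float(np.std(particles.radii, ddof=1)),
    )


def write_particle_csv(particles: ParticleSet, path: str | Path) -> None:
    """Write a particle table with columns x_A, y_A, r_A (all Å)."""
    frame = pd.DataFrame(
        {
            "x_A": particles.coords[:, 0],
            "y_A": particles.coords[:, 1],
            "r_A": particles.radii,
        }
    )
    with open(path, "w") as handle:
        w, h = particles.extent
        handle.write(f"# units: Angstrom; extent_W_A={w:.9g}; extent_H_A={h:.9g}\n")
        frame.to_csv(handle, index=False)


def read_particle_csv(path: str | Path, extent: tuple[float, float] | None = None) -> ParticleSet:
    """Read a particle table (columns x_A, y_A, r_A in Å).

    The field extent is taken from the header comment written by
    :func:`write_particle_csv` if present, else from ``extent``, else
    from the maximum coordinates.
    """
    header_extent = None
    with open(path) as handle:
        first = handle.readline()
    if first.startswith("#") and "extent_W_A=" in first:
        fields = dict(
            part.strip().split("=")
            for part in first.lstrip("#").split(";")
            if "=" in part
        )
        header_extent = (float(fields["extent_W_A"]), float(fields["extent_H_A"]))
    frame = pd.read_csv(path, comment="#")
    missing = {"x_A", "y_A", "r_A"} - set(frame.columns)
    if missing:
        raise ValueError(f"particle CSV missing columns: {sorted(missing)}")
    coords = frame[["x_A", "y_A"]].to_numpy(dtype=float)
    radii = frame["r_A"].to_numpy(dtype=float)
    if extent is None:
        extent = header_extent
    if extent is None:
        extent = (float(coords[:, 0].max()), float(coords[:, 1].max()))
    return ParticleSet(coords=coords, radii=radii, extent=extent)
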