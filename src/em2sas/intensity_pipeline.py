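"""End-to-end assembly of I(q) = P(q) * S(q) from a segmentation.

The pipeline runs: extract particles -> fit the size distribution ->
(optionally rescale coordinates by a shrinkage factor) -> bin g(r) in
the convention matching the geometry -> smooth -> transform to S(q) ->
polydisperse P(q) -> I(q).  Contrast and additive background are
deliberately absent: intensities are in arbitrary units, computed from
image information alone.

Geometries
----------
planar-spheres
    Spherical particles lying on a plane, imaged in projection.  g(r)
    uses the planar-3d convention, whose small volume density drives
    S(q) toward 1 — structure visible in the image does not survive
    into I(q).
parallel-cylinders
    Parallel fibrils normal to the image plane, modelled as infinitely
    long cylinders.  The problem is genuinely 2-D: areal g(r), Hankel
    transform, and a low-q structure-factor peak that coexists with
    higher-q form-factor oscillations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .form_factor import (
    GEOMETRIES,
    ScatteringCurve,
    make_qgrid,
    polydisperse_form_factor,
)
from .particle_extraction import (
    LabelMap,
    ParticleSet,
    SizeDistribution,
    extract_particles,
    fit_size_distribution,
)
from .spatial_stats import (
    RadialDistribution,
    apply_coordinate_scale,
    compute_rdf,
    smooth_rdf,
)
from .structure_factor import structure_factor_2d, structure_factor_planar

__all__ = [
    "RunConfig",
    "PipelineResult",
    "assemble_intensity",
    "run_pipeline",
    "write_curve",
    "read_curve",
]

logger = logging.getLogger("em2sas")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Parameters
    ----------
    geometry
        "planar-spheres" or "parallel-cylinders".
    pixel_size
        Å per pixel; used only when the input is a label map.
    q_min, q_max, n_q
        Log-spaced q grid (Å⁻¹).
    dr, r_max
        g(r) binning (Å); None selects r_max = min(W, H)/4 and
        dr = r_max/200.
    depth
        Slab depth D (Å) for the planar-3d density; None selects
        max(W, H).
    sg_window, sg_polyorder
        Savitzky–Golay smoothing of g(r); window 0 disables smoothing.
    shrinkage_scale
        Coordinate scale factor correcting sample contraction during
        EM preparation (1.0 = no correction; 1.225 undoes the cornea
        shrinkage of the fibril case study).
    polydispersity_weighting
        "volume2" (intensity-weighted) or "number".
    include_structure_factor
        When False, S is not computed and I(q) = P(q).
    """

    geometry: str = "planar-spheres"
    pixel_size: float = 1.0
    q_min: float = 1e-3
    q_max: float = 1.0
    n_q: int = 200
    dr: float | None = None
    r_max: float | None = None
    depth: float | None = None
    sg_window: int = 11
    sg_polyorder: int = 3
    shrinkage_scale: float = 1.0
    polydispersity_weighting: str = "volume2"
    include_structure_factor: bool = True

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}, got {self.geometry!r}")
        if not 0 < self.q_min < self.q_max:
            raise ValueError("need 0 < q_min < q_max")
        if self.n_q < 16:
            raise ValueError(f"n_q must be >= 16, got {self.n_q}")
        if not self.shrinkage_scale > 0:
            raise ValueError("shrinkage_scale must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat key:value config (JSON, or YAML if available)."""
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a flat mapping")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass(frozen=True)
class PipelineResult:
    """Curves and intermediates of one pipeline run."""

    P: ScatteringCurve
    S: ScatteringCurve | None
    I: ScatteringCurve
    particles: ParticleSet
    size_distribution: SizeDistribution
    rdf: RadialDistribution | None
    report: dict = field(default_factory=dict)


def assemble_intensity(P: ScatteringCurve, S: ScatteringCurve) -> ScatteringCurve:
    """I(q) = P(q) * S(q), elementwise on identical q grids.

    A grid mismatch is an error — curves are never silently
    interpolated onto each other.
    """
    if P.kind != "form_factor" or S.kind != "structure_factor":
        raise ValueError(
            f"expected kinds (form_factor, structure_factor), got ({P.kind}, {S.kind})"
        )
    if P.q.shape != S.q.shape or not np.array_equal(P.q, S.q):
        raise ValueError("P and S are on different q grids; recompute on a shared grid")
    return ScatteringCurve(
        q=P.q, values=P.values * S.values, kind="intensity", geometry=P.geometry
    )


def run_pipeline(map_or_table: LabelMap | ParticleSet, cfg: RunConfig) -> PipelineResult:
    """Run the full image-to-intensity calculation.

    ``map_or_table`` is either a LabelMap (particles are extracted
    first) or an already-extracted ParticleSet.
    """
    if isinstance(map_or_table, LabelMap):
        particles = extract_particles(map_or_table)
    elif isinstance(map_or_table, ParticleSet):
        particles = map_or_table
    else:
        raise TypeError(
            f"expected a LabelMap or ParticleSet, got {type(map_or_table).__name__}"
        )
    report: dict = {"n_particles": particles.n, "warnings": []}
    if particles.n < 2:
        raise ValueError(
            f"pipeline needs at least 2 particles, got {particles.n}"
        )

    dist = fit_size_distribution(particles)
    report["mu_r_A"] = dist.mu_r
    report["sigma_r_A"] = dist.sigma_r
    logger.info("extracted N=%d particles, mu_r=%.3g A, sigma_r=%.3g A",
                particles.n, dist.mu_r, dist.sigma_r)

    if cfg.shrinkage_scale != 1.0:
        particles_s = apply_coordinate_scale(particles, cfg.shrinkage_scale)
        logger.info("applied shrinkage correction s=%.4g", cfg.shrinkage_scale)
    else:
        particles_s = particles

    q = make_qgrid(cfg.q_min, cfg.q_max, cfg.n_q)
    P = polydisperse_form_factor(
        q, dist, cfg.geometry, weighting=cfg.polydispersity_weighting
    )

    S = None
    rdf = None
    if cfg.include_structure_factor:
        import warnings as _warnings

        # Pair correlations are measured in the image plane for both
        # geometries; the geometries differ in the transform: a true
        # 2-D system uses the Hankel kernel with the areal density,
        # while a monolayer in 3-D uses the sinc kernel with the small
        # slab density rho_A / D, which drives S toward 1.
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            rdf = compute_rdf(
                particles_s, dr=cfg.dr, r_max=cfg.r_max, mode="2d"
            )
            if cfg.sg_window:
                rdf = smooth_rdf(rdf, window=cfg.sg_window, polyorder=cfg.sg_polyorder)
            if cfg.geometry == "planar-spheres":
                w, h = particles_s.extent
                depth = max(w, h) if cfg.depth is None else cfg.depth
                S = structure_factor_planar(rdf, q, depth=depth)
                rho = rdf.rho / depth
            else:
                S = structure_factor_2d(rdf, q)
                rho = rdf.rho
        report["warnings"] = [str(w.message) for w in caught]
        report["rho"] = rho
        report["n_origins"] = rdf.n_origins
        logger.info("g(r): geometry=%s rho=%.4g n_origins=%d dr=%.4g A",
                    cfg.geometry, rho, rdf.n_origins, rdf.dr)
        I = assemble_intensity(P, S)
    else:
        I = ScatteringCurve(q=q, values=P.values.copy(), kind="intensity",
                            geometry=cfg.geometry)

    return PipelineResult(
        P=P, S=S, I=I, particles=particles, size_distribution=dist,
        rdf=rdf, report=report,
    )


def write_curve(curve: ScatteringCurve, path: str | Path) -> None:
    """Write a curve as two-column ASCII: q (Å⁻¹) and value."""
    header = f"kind={curve.kind}"
    if curve.geometry:
        header += f" geometry={curve.geometry}"
    np.savetxt(
        path,
        np.column_stack([curve.q, curve.values]),
        fmt="%.9e",
        header=header + "\n q_invA  value",
    )


def read_curve(path: str | Path, kind: str | None = None) -> ScatteringCurve:
    """Read a two-column ASCII curve; '#' header lines are ignored.

    ``kind`` overrides the kind recorded in the header (defaulting to
    "intensity" when neither is available).
    """
    path = Path(path)
    header_kind = None
    with open(path) as handle:
        for line in handle:
            if line.startswith("#"):
                if "kind=" in line:
                    header_kind = line.split("kind=")[1].split()[0]
                continue
            break
    try:
        data = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"malformed curve file {path}: {exc}") from exc
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] == 0:
        raise ValueError(f"curve file {path} must have two columns (q, value)")
    q, values = data[:, 0], data[:, 1]
    if np.any(np.diff(q) <= 0):
        raise ValueError(f"curve file {path} has a non-monotone q column")
    kind = kind or header_kind or "intensity"
    return ScatteringCurve(q=q, values=values, kind=kind)
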