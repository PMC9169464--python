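# em2sas

Small-angle scattering (SAS) intensity functions computed from 2-D
electron-microscopy instance segmentations.

EM and SAS probe the same nanostructural length scales but are measured
and analysed separately. Given an instance-segmented EM image (an
integer label map: 0 = background, k = particle k) and the physical
pixel size, `em2sas` calculates the SAS intensity the imaged structure
would produce,

```
I(q) ∝ P(q) · S(q)
```

where the form factor `P(q)` carries particle size and shape and the
structure factor `S(q)` carries inter-particle spatial correlations.
Contrast and additive background are omitted: all information comes
from the image. Two sample geometries are supported:

* **planar-spheres** — spherical particles lying on a plane (e.g. a
  nanoparticle monolayer imaged by TEM). `P(q)` is the polydisperse
  sphere form factor `[3(sin qr − qr cos qr)/(qr)³]²` averaged over a
  truncated-Gaussian radius distribution fitted to the segmentations;
  `S(q)` follows from the in-plane radial-distribution function g(r)
  through the isotropic (sinc-kernel) transform with the slab number
  density ρ = N/(W·H·D). Because a monolayer's volume density is tiny,
  S(q) ≈ 1 at every q: ordering plainly visible in the image leaves no
  trace in the measured intensity.
* **parallel-cylinders** — fibrils modelled as parallel, infinitely
  long cylinders normal to the image plane (e.g. collagen in cornea).
  `P(q) = [2 J₁(qr)/(qr)]²`, and `S(q) = 1 + 2πρ_A ∫ (g(r)−1) r J₀(qr) dr`
  from the 2-D g(r) with areal density ρ_A = N/(W·H). A coordinate
  scale factor (e.g. 1.225) corrects sample shrinkage incurred during
  EM preparation, moving structure-factor peaks reciprocally in q while
  leaving the form factor untouched.

The package also provides a Debye pair-sum oracle
`S(q) = 1 + (1/N) Σ_{j≠k} K(q·d_jk)` for cross-checking, a
Savitzky–Golay smoother for g(r), and a synthetic-microstructure
generator (Gaussian radii; Poisson or hard-disk RSA placement; disk
rasterization to label maps) so the whole pipeline is testable without
any microscopy data.

## Worked example

Simulate a field of fibril cross-sections (300 disks, mean radius
183 Å, hard minimum centre distance 420 Å in a 1.2 μm field), run the
parallel-cylinders pipeline with and without the shrinkage correction,
and locate the interfibril structure-factor peak:

```python
import numpy as np
from em2sas import (FixtureSpec, RunConfig, place_points, run_pipeline,
                    find_primary_peak)

particles = place_points(FixtureSpec(
    n_particles=300, extent=(12000.0, 12000.0), mu_r=183.0, sigma_r=15.5,
    placement="rsa-hard-disk", min_center_distance=420.0, seed=2))

common = dict(geometry="parallel-cylinders", q_min=4e-3, q_max=0.1, n_q=400)
base = run_pipeline(particles, RunConfig(**common))
corrected = run_pipeline(particles, RunConfig(shrinkage_scale=1.225, **common))

print("mean radius: %.1f A" % base.report["mu_r_A"])
print("S peak:           %.5f 1/A" % find_primary_peak(base.S, 8e-3, 0.03))
print("S peak corrected: %.5f 1/A" %
      find_primary_peak(corrected.S, 8e-3 / 1.225, 0.03 / 1.225))
```

prints

```
mean radius: 182.2 A
S peak:           0.01290 1/A
S peak corrected: 0.01053 1/A
```

The interfibril peak sits near 0.013 Å⁻¹ and moves to ≈ 0.0105 Å⁻¹
(a factor 1/1.225) when the coordinates are rescaled — the mechanism by
which EM-sample shrinkage misplaces structure-factor peaks relative to
experimental SAS. Cylinder form-factor features start at the first J₁
root divided by the radius, ≈ 0.021 Å⁻¹ here, and are untouched by the
rescaling.

A command-line interface mirrors the library
(`em2sas simulate | extract | rdf | sq | pq | intensity | run`); run
`em2sas --help` for details.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs both case-study pipelines from scratch on seeded synthetic
fixtures — a rendered-and-re-extracted sphere monolayer, and an RSA
fibril field with the shrinkage correction — and prints the computed
run summary (particle statistics, structure-factor flatness for the
monolayer, peak positions for the fibrils) to stdout, writing the
reported-targets JSON object to `--out`.
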