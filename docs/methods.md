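# Methods

## Model

The scattering intensity of a dilute-contrast system factorizes as
I(q) ∝ P(q)·S(q). `em2sas` computes both factors from a single
instance-segmented EM image: particle areas give circle-equivalent
radii r = √(A/π) for the form factor, and particle centroids give the
radial-distribution function g(r) for the structure factor. Contrast
and additive-background terms of an experimental I(q) are omitted
throughout; intensities are in arbitrary units.

### Form factors

Both form factors are normalized to P(0) = 1:

* sphere: P(q, r) = [3(sin qr − qr cos qr)/(qr)³]²
* infinite-cylinder cross-section: P(q, r) = [2 J₁(qr)/(qr)]²

Small arguments (qr < 10⁻⁴) are evaluated by Taylor series to avoid
cancellation. Polydispersity is handled by averaging over a Gaussian
radius distribution truncated to r > 0 and renormalized:

P(q) = ∫ p(r) w(r) P(q, r) dr / ∫ p(r) w(r) dr

with weight w(r) = V(r)² by default (V = 4πr³/3 for spheres, πr² per
unit length for cylinders) because scattered intensity scales with the
squared particle volume; `weighting="number"` (w = 1) is available
since the literature uses both conventions. Quadrature is a trapezoid
rule on 101 nodes over r ∈ [max(μ/100, μ−4σ), μ+4σ]. With σ = 0 the
monodisperse curve is returned exactly.

### Radial-distribution function

g(r) is estimated on uniform bins of width δr up to r_max, counting
neighbours only around *origin* particles at least r_max from every
field edge — every counted shell then lies fully inside the field, so
no analytic edge-weighting is needed. Defaults: r_max = min(W, H)/4,
δr = r_max/200. Conventions:

* `2d`: g = η/(2πr·δr·ρ_A), ρ_A = N/(W·H)
* `planar-3d`: g = η/(4πr²·δr·ρ), ρ = N/(W·H·D), slab depth D
  defaulting to max(W, H)

where η(r) is the mean per-origin neighbour count in [r, r+δr).
Distances are between centroids only; radii never enter g(r). Fewer
than ~200 particles triggers a warning (the g(r) estimate becomes
noisy below that). Optional Savitzky–Golay smoothing (default window
11 bins, polynomial order 3 — the source work names the filter but no
parameters) preserves polynomials up to the chosen order; negative
excursions are clipped at zero since g is a density ratio.

### Structure factors

For isotropic/cylindrically symmetric systems the transforms reduce to
one-dimensional integrals over the binned g(r) (trapezoid rule, hard
truncation at r_max; an optional Lorch taper is available because hard
truncation can ring):

* planar-3d: S(q) = 1 + 4πρ ∫ (g−1) r² sinc(qr) dr
* 2d:        S(q) = 1 + 2πρ_A ∫ (g−1) r J₀(qr) dr

`debye_sum` provides the exact pair-enumeration alternative
S(q) = 1 + (1/N)Σ_{j≠k} K(q d_jk) (K = sinc or J₀, O(N²)), used as an
independent oracle in the tests. Negative S values are warned about
but never clipped — they indicate an under-resolved g(r).

### The monolayer (planar-spheres) structure factor

A monolayer's pair correlations live entirely in its plane, so g(r) is
measured with the 2-D estimator; but a scattering experiment averages
over a 3-D volume of depth D, so the density entering the sinc-kernel
transform is the slab density ρ = ρ_A/D
(`structure_factor_planar`). Because ρ is small for any macroscopic
depth, S(q) stays within a few percent of 1 at every q — in-plane
ordering clearly visible in the image is invisible in I(q), and
I(q) ≈ P(q). This is the route the planar-spheres pipeline takes.

The alternative of normalizing g itself with the 3-D shell volume
(mode `planar-3d`) yields, once transformed, exactly the sinc-kernel
Debye sum of the planar coordinates — a quantity that is independent
of D and grows like 2πρ_A/q² at low q (the forward scattering of a
correlated sheet). Both conventions are exposed; they answer different
questions, and only the slab-density route reproduces the vanishing
structure factor seen experimentally for particle monolayers.

### Shrinkage correction

EM sample preparation can contract the matrix between scatterers while
leaving particle cross-sections intact. `apply_coordinate_scale`
multiplies coordinates and field extent by s (default pipeline value
1.0; 1.225 is the factor that aligns the fibril case study with
experiment), leaving radii unchanged. Since the default binning scales
with the extent, g_s(r) = g(r/s) bin-for-bin and S_s(q) = S(q·s): the
structure-factor peak moves from q₀ to q₀/s while P(q) is untouched.

## Synthetic fixtures

`synthetic` generates the stated world of the two case studies:
Gaussian radii (e.g. μ = 34 Å, σ = 2.3 Å for the nanoparticle
monolayer; μ = 183 Å, σ = 15.5 Å for fibril cross-sections, matching a
366 ± 31 Å diameter), centres placed either i.i.d.-uniform (Poisson)
or by random sequential adsorption (RSA) with a hard minimum centre
distance, and disks rasterized by the pixel-centre-inside rule with
overlap pixels assigned to the nearest centre. RSA was chosen over
Metropolis equilibration: it is simple, deterministic under a seed,
and produces the short-range order (g = 0 below the exclusion
distance, peak just above it) the structure-factor tests need, without
claiming any particular liquid-state theory. Field extents are not
stated in the source material; they were fixed once from finite-size
noise analysis (see below) at 3000–12000 Å, giving packing fractions
of ~0.1 (nanoparticles) and ~0.3 of the RSA exclusion disks (fibrils).

The fixtures emulate *segmentations*, not micrographs: no imaging
noise, PSF, or segmentation error beyond rasterization. A green
pipeline test therefore establishes correctness of the computation
downstream of segmentation, not robustness to segmentation quality.

## Numerical and statistical choices

* q grids are log-spaced, default [10⁻³, 1] Å⁻¹ with 200 points;
  q = 0 is excluded and the q → 0 limits are handled analytically.
* P and S must share a grid; a mismatch raises rather than silently
  interpolating.
* The Debye sum on a single finite configuration carries low-q speckle
  noise of amplitude ≈ 1/√(qL): it is the ring average of a speckled
  2-D spectrum with ≈ qL/2π independent modes. Oracle-equivalence
  tests therefore average ~16 seeded configurations; the residual
  transform-vs-Debye deviation is ≤ 0.07 (J₀) and ≤ 0.05 (sinc).
* For the sinc-kernel comparison the slab depth is set to D = 2·r_max:
  the transform's truncated-background term −4πρ∫₀^{r_max} r² sinc dr
  then equals the expected far-pair (r > r_max) contribution of the
  plain Debye sum, 2πρ_A cos(q r_max)/q², so the two estimators are
  windowed identically. With any other D the comparison includes an
  O(0.2) windowing artifact that belongs to neither estimator.
* The variance of the transform-based S estimate scales as
  ρ² δr r_max⁴/(n_origins ρ_A) for the sinc route, so the monolayer
  pipeline validation uses r_max = 250 Å rather than the min(W,H)/4
  default; for Poisson fixtures no correlation information is lost.
* Border-touching particles are kept (with a warning listing their
  labels): no exclusion rule is defined for them, and dropping them
  would bias the density. Their truncated areas bias r low, so
  rasterization-fidelity tests measure interior disks.
* Centroids use 0-based pixel indices with no half-pixel offset;
  constant offsets cancel in all pairwise distances.

## Limitations

* Only the two stated geometries; no ellipsoids, core–shell particles,
  finite-length cylinders, or orientational averaging beyond them.
* S(q) comes from coordinates only — no analytic structure-factor
  models (e.g. hard-sphere Percus–Yevick).
* Equivalent radii assume compact, roughly circular cross-sections;
  elongated or ramified particles violate r = √(A/π).
* 2-D cross-sections of general 3-D samples (spheres sliced at random
  heights) are out of scope: neither true sizes nor 3-D arrangement
  can be inferred from such images.
* Absolute intensity calibration, model fitting to experimental data,
  and segmentation itself are out of scope.
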