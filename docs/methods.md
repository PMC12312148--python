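# Methods

This note records the models, estimators, numerical choices and known
limitations of the package, in the order of the analysis chain.

## Composite SANS model

The scattered intensity of a fusogenic-liposome dispersion is modelled as
a linear superposition of three structural populations plus a flat
incoherent background. The scale factors are free amplitudes — each is
proportional to, but not equal to, the volume fraction of its phase — and
absolute calibration is out of scope. Internal units are Å for lengths,
Å⁻¹ for q, Å⁻² for scattering length densities (SLDs).

### BCC paracrystal of small vesicles

The small-vesicle population sits on a body-centred-cubic lattice with
Gaussian positional disorder. For one crystal orientation the lattice
factor factorizes along the three primitive vectors
a⃗₁ = (a/2)(−1,1,1), a⃗₂ = (a/2)(1,−1,1), a⃗₃ = (a/2)(1,1,−1):

    Z(q⃗) = ∏ₖ (1 − |Fₖ|²) / (1 − 2|Fₖ| cos(a⃗ₖ·q⃗) + |Fₖ|²),
    |Fₖ| = exp(−Δa² q² / 2).

The disorder amplitude is parameterized by the distortion factor
g = Δa/d_nn with d_nn = (√3/2)·a the nearest-neighbour distance; `a` is
the primitive parameter exposed to users (a stated nearest-neighbour
distance converts as a = 2·d_nn/√3). Isotropic, axis-identical Δa is
assumed.

**Powder average.** The factorized product is *not* invariant under
single sign flips of a Cartesian axis — only under axis permutations and
inversion — so averaging over one octant of orientations silently
underestimates/overestimates Z by tens of percent. The average is
therefore taken over a hemisphere (valid by inversion symmetry):
Gauss–Legendre nodes in u = cosθ ∈ [0,1] crossed with a uniform periodic
grid in φ ∈ [0,2π), n × 4n nodes with n = 150 by default. A uniform grid
is spectrally accurate in the periodic coordinate. The default grid
matches a 2×10⁶-sample Monte-Carlo average to ≤0.2% across the
measurement window and is invariant to ~10⁻⁸ under node doubling.

**Adaptive refinement.** At small q·Δa the crystal is nearly perfect and
Z(q̂) concentrates on near-singular orientation ridges of relative width
≈ (1−|F|)/(q·|a⃗ₖ|). The node count per q point is raised proportionally
to the inverse ridge width (capped at 1200 in u, i.e. ~5.8M
orientations); below the cap the extreme low-q/low-g corner (roughly
q < 0.005 Å⁻¹ at g ≤ 0.05) remains approximate. Repeated evaluations at
identical (q grid, a, g) are memoized, which makes replicate studies and
fits with frozen lattice parameters cheap.

### Large vesicles

Thin-shell core–shell sphere with solvent core; the two amplitude terms
carry opposite contrast signs so the q→0 limit is
I(0) = scale·ϕ·V_shell·Δρ², as a hollow shell requires. First-order
sphere amplitudes use a series below |x| = 0.02 to avoid sin/cos
cancellation.

### Lamellar stacks

Flat-sheet bilayer factor (sin(qt)/qt)² times the closed-form
one-dimensional paracrystal interference Z_N(q) with Gaussian spacing
disorder w = exp(−σ_D²q²/2), divided by q² (the 2πΔρ²Γ_m prefactor is
absorbed into the scale). The closed form carries the five-term stack
coefficient

    a_N = 4w² − 2(w³+w)cos(qD) − 4w^{N+2}cos(NqD)
        + 2w^{N+3}cos[(N−1)qD] + 2w^{N+1}cos[(N+1)qD],

which equals the direct pairwise lattice sum
Z_N = (1/N)·Σⱼₖ w^{|j−k|}cos((j−k)qD) to ~10⁻¹² (verified against that
oracle for all N ≤ 10). Non-integer mean stack size N mixes the two
neighbouring integer sizes with weight x_N = 1 − frac(N) on ⌊N⌋. Where
the denominator vanishes (σ_D = 0 at a Bragg point) the direct sum is
used element-wise; near-Bragg points with w → 1 the closed form loses up
to ~8 significant digits to float cancellation, which bounds the
practically attainable oracle agreement in wide parameter sweeps.

For small N the finite-stack terms produce low-q side fringes that are
formally local maxima of Z_N; the physically meaningful interference
peak is the global (Bragg-like) maximum near 2π/D, and that is the
quantity reported as "the lamellar peak".

### Fitting

`fit_composite` performs weighted least squares (weights 1/σ, unit if no
uncertainties) with lmfit's trust-region-reflective backend. Any named
parameter can be frozen; the four SLDs are frozen by default (D₂O
6.36×10⁻⁶ Å⁻², phospholipid 1×10⁻⁶ Å⁻²). Bounds: lengths [0.1×, 10×] of
their start value, amplitudes and background [0, ∞), distortion and
volume fraction [0, 1], stack size [1, 100]. Non-convergence is flagged
on the result, not raised. Component curves are cached within a fit so
frozen populations cost one forward evaluation. χ²_red uses
n_points − n_free degrees of freedom.

Default starting values reflect the microscopy-derived geometry the fits
assume: bilayer 30 Å, BCC vesicle diameter 250 Å (form-factor radius
125 Å), nearest-neighbour distance 450 Å, large-vesicle radius 5000 Å.
The default amplitudes are set so each population dominates part of the
window, the way measured composite curves look: scale_lam ≈ 5×10⁻⁹
(the physical 2πΔρ²Γ_m prefactor it absorbs, at lipid/D₂O contrast with
Γ_m ≈ 30 Å), a large-vesicle amplitude producing the characteristic
low-q shoulder, and a background small enough to dominate only the
high-q tail.

**Resolution smearing** (Δλ/λ ≈ 10% instruments) is available as an
optional Gaussian q-smearing helper and is off everywhere by default.

## FRAP

Traces are normalized by the mean pre-bleach intensity. I₀ is the first
post-bleach sample, I∞ literally the last sample (no asymptote fit —
a documented limitation for short traces), and t_1/2 is the time from
the I₀ sample to the post-bleach sample whose intensity is nearest to
(I₀+I∞)/2, ties resolving to the earlier sample; no interpolation.
Then D = 0.224·r²/t_1/2 and R = (I∞−I₀)/(I_pre−I₀). Arbitrary non-uniform
time grids are accepted.

Estimator error budget: nearest-sample quantization contributes up to
dt/2 (exactly 5% of t_1/2 at dt = t_1/2/10), and reading I∞ at a finite
observation time T biases t_1/2 by ≈ 0.57·τ_D/T (τ_D = r²/4D), because
the uniform-disk recovery approaches its plateau like 1/t. Recovery
tests therefore sample at dt = t_1/2/16 for T = 200·t_1/2, where both
terms sit below the 5% accuracy band; at the instrument-typical 40 ms
increment, half-times below ~2 samples (fast diffusion in small ROIs)
are unresolvable, which is the main caveat when interpreting per-ROI D
values at that sampling.

The synthetic generator uses the closed-form uniform-disk recovery
f(t) = e^(−2τ_D/t)[I₀(2τ_D/t)+I₁(2τ_D/t)] with τ_D = r²/(4D) — the model
from which the 0.224 constant derives — so the estimator applied to
generated data is self-consistent by construction (f = 1/2 at
t = 0.224·r²/D). Noise is additive Gaussian. Group comparison reports
arithmetic means, sample SDs, the outside/inside ratio of means, and,
for per-vesicle pairs, the count with strictly slower diffusion inside.

## GUV membrane profiling

Pipeline defaults: Gaussian smoothing σ = 1 px; Canny edges (σ = 2) into
a circular Hough transform over a user radius range, strongest
accumulator peak, centre refined by the 5×5 accumulator-mass centroid and
radius refined against the angle-averaged radial intensity profile with
parabolic sub-sample interpolation (Canny edges sit on the ring's slopes,
so the raw accumulator radius can lock onto an edge instead of the
crest); radial maximum search along 360 rays (1° steps, configurable)
through the centre, total ray length 5× radius, bilinear sampling at
0.25 px steps, maximum taken within ±10 px of the perimeter radius,
rays leaving the image skipped; rasterized maxima dilated with a 2 px
disk, holes under 50 px² filled, skeletonized to a 1-px curve (closure
checked via the Euler characteristic); per-skeleton-pixel gray value
(from the smoothed image) vs angle, counterclockwise from +x with y up,
duplicate angles averaged.

Domains are contiguous circular angular runs of at least 5° whose
intensity reaches a fold threshold (default 2×) over the median profile
level; wrap-around through 0° is handled. The 2× default encodes the
observation that bright membrane domains carry about twice the dye
intensity of the surrounding membrane. Dilation radius and hole size are
the smallest values that reliably close 1-px sampling gaps at 1° steps.
No quality filter is applied to the ray maxima before mask building.

The synthetic image generator renders a radial Gaussian ring with
hard-edged angular fold modulation plus additive Gaussian noise (clipped
at zero). It emulates a single in-focus equatorial section with uniform
background; it does not emulate out-of-focus light, multiple vesicles,
adhesion footprints or detector shot-noise statistics, so passing tests
demonstrate the geometry/estimator chain, not robustness to those
real-data features.

## ³¹P powder lineshapes

Uniaxial CSA: δ(θ) = δ⊥ + (δ∥−δ⊥)cos²θ with isotropic orientation
statistics gives the frequency density
p(δ) = 1/(2√((δ−δ⊥)(δ∥−δ⊥))) between the edges. The implementation
integrates the exact CDF √u over each grid cell — handling the δ⊥
singularity analytically — then convolves with a Gaussian of standard
deviation `broadening_sigma` and renormalizes to unit area. The
isotropic phase is a pure Gaussian.

Defaults: lamellar δ⊥ = −20, δ∥ = +45 ppm (peak at −20, shoulder toward
+50); hexagonal δ⊥ = +5, δ∥ = −27.5 ppm (opposite-sign, half-magnitude
anisotropy — the extra motional averaging around the H_II cylinders —
peak near +5); isotropic centred at 0 ppm; σ = 1 ppm. The broadening
default matters: convolving the one-sided edge singularity with a
Gaussian shifts the apparent maximum inward by ≈0.78σ, so σ = 2 ppm
would already displace the −20 ppm landmark by ~1.5 ppm. δ∥ of the
lamellar phase is a free parameter (the +50 ppm shoulder end is a bound,
not a fitted value). Grids are uniform, stored ascending; readers accept
either order.

Decomposition is nonnegative least squares of the spectrum against the
unit-area basis lineshapes (rank-checked), returning weights on the
input's area scale and the relative L2 residual. This is a deliberately
minimal quantitative counterpart to what is usually a visual spectral
comparison; it assumes the three basis shapes span the spectrum and
shares all limitations of that assumption (e.g. intermediate-exchange
lineshapes are not modelled).

## Synthetic-data layer and test scale

Every generator is a pure function of its spec including the integer
seed (numpy `default_rng`), so outputs are bit-reproducible. Noise
models: additive Gaussian for images and traces, multiplicative
(relative) Gaussian for scattering curves with σ-column = relative
noise × true intensity.

Problem sizes used by the test suite and analysis drivers: 120-point
log-spaced scattering curves at 5% noise with 50 fit replicates; 256²
GUV images over 20 seeds at SNR 5; FRAP cohorts of 40 paired vesicles;
2048-point spectra over ±120 ppm with 20 noisy replicates. The
quadrature base for fitting work is n_orient = 48 (adaptively boosted at
low q), matching generation and fit so closed-loop comparisons are
exact; production-quality single evaluations default to n_orient = 150.

## Known limitations

- The BCC powder average below the adaptive node cap (extreme low-q,
  g ≲ 0.05 corner) is approximate; peak positions are unaffected.
- No instrument resolution smearing is applied by default; the optional
  Gaussian model ignores wavelength-spread asymmetry.
- FRAP analysis fits no bleach profile and no photofading correction;
  I∞ = last sample biases D upward for short observations (quantified
  above). No substrate-adhesion correction is applied to D.
- The GUV pipeline assumes one dominant ring per image.
- ³¹P simulation covers static uniaxial patterns only — no pulse-sequence
  effects, no magic-angle spinning, no exchange broadening.
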