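# lipidphase

Analysis toolkit for the coexisting lipid phases of fusogenic liposomes —
the quantitative chain behind a membrane-biophysics phase study combining
small-angle neutron scattering (SANS), fluorescence recovery after
photobleaching (FRAP), giant-unilamellar-vesicle (GUV) imaging, and static
³¹P solid-state NMR.

Fusogenic lipid mixtures (DOPE/DOTAP plus an aromatic amphiphile) do not
stay purely lamellar: part of the lipid reorganizes into small vesicles
ordered on a body-centred-cubic (BCC) lattice, while large vesicles and
bilayer stacks persist alongside. This package implements the forward
models and estimators needed to quantify that coexistence, plus seeded
synthetic-data generators that emulate each measurement so every pipeline
can be validated closed-loop.

## What is implemented

**Composite SANS model** (`lipidphase.sans`). The measured intensity is a
linear superposition

```
I(q) = scale_bcc·I_BCC(q) + scale_ves·I_ves(q) + scale_lam·I_lam(q) + I_B
```

- `I_BCC` — sphere form factor `P(q) = [3j₁(qR)/(qR)]²` times the
  powder-averaged paracrystalline structure factor of a BCC lattice,
  `Z(q⃗) = ∏ₖ (1−|Fₖ|²)/(1−2|Fₖ|cos(a⃗ₖ·q⃗)+|Fₖ|²)` with
  `|Fₖ| = exp(−Δa²q²/2)` and distortion `g = Δa/d_nn`, `d_nn = (√3/2)a`.
  The orientation average uses Gauss–Legendre × periodic-uniform
  quadrature over a hemisphere with adaptive node boosting at small q·Δa.
- `I_ves` — thin-shell core–shell vesicle,
  `I = scale·(ϕ/V_shell)·[V_core(ρ_s−ρ_sh)·3j₁(qR_c)/(qR_c) +
  V_tot(ρ_sh−ρ_s)·3j₁(qR_t)/(qR_t)]²`.
- `I_lam` — flat bilayer `(sin(qt)/qt)²` times the closed-form
  paracrystalline stack interference `Z_N(q)` (Gaussian spacing disorder
  `w = exp(−σ_D²q²/2)`, non-integer N mixes adjacent integer stack sizes),
  divided by `q²`.
- `fit_composite` — bounded trust-region weighted least squares (lmfit)
  with per-parameter freezing; SLDs fixed by default at 6.36×10⁻⁶ Å⁻²
  (D₂O) and 1×10⁻⁶ Å⁻² (lipid). `bragg_peaks` indexes the allowed
  (h+k+l even) BCC reflections `q_hkl = (2π/a)√(h²+k²+l²)`.

**FRAP** (`lipidphase.frap`). Pre-bleach normalization, nearest-sample
half-time estimation, the uniform-disk relation `D = 0.224·r²/t_1/2`,
mobile fraction `R = (I∞−I₀)/(I_pre−I₀)`, and inside/outside-domain group
comparison with paired sign counts.

**GUV imaging** (`lipidphase.guv`). Gaussian smoothing → circular Hough
detection with sub-pixel refinement → radial maximum search within ±10 px
of the perimeter → dilate/fill/skeletonize to a closed 1-px membrane
curve → per-pixel gray value vs angle → bright-domain flagging at a fold
threshold over the median profile (default 2×).

**³¹P lineshapes** (`lipidphase.nmr`). Uniaxial CSA powder patterns
(`δ(θ) = δ⊥ + (δ∥−δ⊥)cos²θ`, exact cell-integrated orientation density,
Gaussian broadening) for lamellar (peak −20 ppm, shoulder to ~+50 ppm),
inverted-hexagonal (opposite-sign, half-magnitude anisotropy, peak near
+5 ppm) and isotropic (0 ppm) phases; nonnegative least-squares
decomposition of a spectrum into phase weights.

**Synthetic data** (`lipidphase.synthetic`). Bit-reproducible seeded
generators for GUV ring images (64 nm/px) with angular domains, uniform-
disk FRAP recoveries (Soumpasis kernel, so the 0.224 constant is exact by
construction), SANS curves with relative counting noise over
q = 0.002–0.221 Å⁻¹, and ³¹P phase mixtures — each returning ground truth
for closed-loop tests.

## Worked example

```python
from dataclasses import replace
from lipidphase.sans import (PARAM_NAMES, bragg_peaks, fit_composite,
                             params_to_flat, table_start_params)
from lipidphase.synthetic import SansCurveSpec, gen_sans_curve

truth = table_start_params()                     # the study conditions
curve, _ = gen_sans_curve(SansCurveSpec(relative_noise=0.05, seed=1))

start = replace(truth, bcc=replace(truth.bcc, scale_bcc=0.5),
                vesicle=replace(truth.vesicle, scale_ves=40.0),
                lamellar=replace(truth.lamellar, scale_lam=1e-8),
                background_IB=5e-6)
frozen = set(PARAM_NAMES) - {"bcc_scale", "ves_scale", "lam_scale", "background"}
res = fit_composite(curve, start=start, frozen=frozen, n_orient=48)
print(res.chi2_reduced)                          # 0.736
print(params_to_flat(res.params)["bcc_scale"])   # 0.9953  (truth: 1.0)
print(bragg_peaks(460.0)[:2])
# [((1, 1, 0), 0.019317), ((2, 0, 0), 0.027318)]
```

With a 46 nm BCC lattice constant the first two allowed reflections fall
at 0.0193 and 0.0273 Å⁻¹ — the two peaks flanking the lamellar maximum at
2π/250 Å ≈ 0.025 Å⁻¹; all three population amplitudes come back within 1%
of the generating truth at 5% noise.

The numbered drivers under `analysis/` run the same chain per modality
and write tables under `results/`:

```bash
python analysis/01_sans_composite_fit.py    # amplitude recovery + Bragg table
python analysis/02_frap_diffusion.py        # D 1.83±0.31 vs 3.31±0.56 µm²/s,
                                            # slower inside in 38/40 vesicles
python analysis/03_guv_domain_profiling.py  # 20/20 domain centers within 5°
python analysis/04_nmr_phase_fractions.py   # phase weights within 0.003
```

A `lipidphase` CLI exposes the same steps on files
(`simulate`, `fit-sans`, `bragg`, `frap`, `guv-profile`, `nmr`).

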