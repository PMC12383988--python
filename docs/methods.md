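# Methods

## Model

`save-hsi` estimates a reflectance spectrum per pixel from encoded RGB in
four chained stages, all fitted on a 24-patch ColorChecker:

1. **sRGB → XYZ.** The piecewise IEC 61966-2-1 transfer function and matrix,
   scaled to the reflective 0–100 convention. Tristimulus integration of
   reference spectra uses the trapezoidal rule on a uniform grid over
   400–700 nm with the normalisation k = 100/∫S·ȳ, so Y = 100 for a perfect
   reflector regardless of illuminant.
2. **Variable-matrix correction.** A 3×20 matrix C maps the full third-order
   monomial expansion of camera XYZ onto reference XYZ,
   C = XYZ_ref·pinv(V). The expansion is capped at order 3: with only 24
   training patches, higher orders over-correct. The constant term doubles
   as the dark-current offset of the regression.
3. **Spectral basis.** Mean-centred PCA (SVD) of the patch spectra; six
   components are kept. Component signs are fixed so the
   largest-magnitude coefficient of each component is positive, making
   fitted models reproducible across runs and platforms.
4. **Transformation matrix.** M = Score·pinv(V_color), where V_color is the
   expansion of the *corrected* XYZ — the two regressions are chained, the
   second operating on the output of the first. A pixel's spectrum is
   mean + basisᵀ(M·V), clipped to [0, 1]; the clipped fraction is recorded
   on the result, never silently discarded.

Assumptions: scene reflectances live close to the low-dimensional smooth
subspace spanned by the chart spectra; illumination matches the calibration
illuminant (D65 by default — which illuminant the spectrometer side assumes
is configurable, as reference data rarely state it); the camera applies an
sRGB-like encoding. Spatially varying effects (vignetting, Bayer
demosaicing) are out of scope.

### Narrow-band synthesis

Band responses are Lorentzian-window weighted means of the cube around each
band centre. Defaults follow the classic haemoglobin rationale — 415 nm
(superficial capillaries) feeding blue+green, 540 nm (submucosal vessels)
feeding green+red, plus low-weight 600/700/780 nm red contributions that
reproduce the brown tones of real narrow-band composites. The mapping of
band to output channel is a pseudo-colour convention, not physics, and is
fully configurable.

Residual mismatch against a reference modality is modelled as a gain
g(λ) = 1 + Σ aᵢ·f(λ; x₀ᵢ, γᵢ) with Cauchy–Lorentz profiles f
(multiplicative by default; an additive variant is exposed). Amplitudes are
tuned by **fast simulated annealing**: Cauchy-distributed step proposals
scaled by visiting_scale·T_k with the fast schedule T_k = T₀/(1+k) and
Metropolis acceptance; the best-visited point is tracked and returned, so
reported cost is monotone non-increasing and never exceeds the initial
cost. The seed is a required schedule field — there is no hidden global
randomness. With the default schedule (T₀ = 1, 2000 iterations) the
optimizer reaches the minimum of a smooth 2-parameter objective to ~1e-3.
Since real narrow-band reference frames are proprietary, the calibration
loop is validated by self-recovery: a target synthesized with known
amplitudes is matched to well under 0.5 ΔE00.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| master grid | 380–780, step 5 | nm | covers the 400–700 nm analysis range plus the 780 nm band |
| expansion order | 3 (20 terms) | – | full trivariate cubic; order > 3 rejected |
| PCA components | 6 | – | ≥ 99.6% of chart spectral variance |
| pinv cutoff | 1e-10 (relative) | – | numerical robustness of 24-sample fits |
| feature scale | XYZ/100 | – | keeps cubic monomials O(1) for conditioning |
| dark current | 0 | encoded RGB | fixtures are noise-free; subtracted pre-decode when set |
| band HWHM γ | 15 (main), 10 (red) | nm | ~30 nm narrow-band width |
| FSA schedule | T₀=1, scale=1, 2000 iter | – | reaches 1e-3 on smooth low-dim objectives |
| SSIM window | 11, Gaussian σ1.5 | px | standard windowed SSIM; data range from bit depth |
| entropy | 256 bins over data range | bits/px | percentage-style entropy figures are ambiguous, so the absolute bits/pixel and a relative-difference percentage are both reported, labelled |

## Fixtures: what they emulate, and what they do not

* **Chart** (`colorchecker_synthetic.csv`): a synthetic parametric stand-in
  for a measured ColorChecker — 24 smooth spectra from a fixed 6-atom
  dictionary (flat baseline, red/yellow edges, green/blue bands, far-red
  rise) with small per-patch bumps, classic patch names, six flat neutrals
  at realistic levels (0.90 down to 0.031). The 6-atom construction mirrors
  the real chart's documented low effective spectral dimensionality. It is
  *not* a measured chart: absolute chromaticities are plausible rather than
  certified.
* **Camera**: Gaussian channel sensitivities peaking at 600/550/450 nm,
  white-normalised, optional sRGB encoding and seeded Gaussian noise. Its
  metameric mismatch with the CIE observer is real (uncorrected mean ΔE00
  ≈ 5 on the chart) — that mismatch is what the correction stage has to
  remove — but it has no spatial non-uniformity, stray light, or
  demosaicing artefacts.
* **Phantom**: sinuous vessel curves of a haemoglobin-like absorber
  (Lorentzian absorption dips at 415/540 nm) over a bright mucosa-like
  background; purely absorptive, no scattering, depth or texture.

Consequently, passing closed-loop tests shows the pipeline is
self-consistent and recovers spectra in the regime the chart spans; it does
not certify accuracy on real endoscopic scenes, whose reflectances and
illumination lie outside the fixture family.

## Numerical choices and degenerate inputs

* Pseudo-inverse fits agree with independent least-squares solves to 1e-8
  on full-rank data (asserted in tests); rank-deficient patch sets warn and
  fall back to the minimum-norm solution.
* Resampling is linear interpolation with constant extension outside the
  source support; disjoint grids are an error.
* Identical patch spectra make PCA degenerate: the basis is returned with
  zero variance ratios and zero scores rather than dividing 0/0.
* Identical images give infinite PSNR, reported as a flag rather than a
  number. A zero illuminant (k undefined) is an error.
* All-zero adjustment amplitudes return the cube values unchanged
  (bit-for-bit), so the adjustment path is exactly optional.

## Problem sizes

The closed-loop experiments use the full 24-patch chart; phantom tests use
64×64 (contrast) and 12×12 (annealing self-recovery, 300 iterations)
frames — small sizes chosen because the quantities checked (Weber contrast
ordering, recovery ΔE00) are scale-free. The whole suite runs in a few
seconds on one CPU.

## Known limitations

* The spectrometer-side illuminant assumption (D65) is a convention; a
  mismatched capture illuminant biases reconstruction and no chromatic
  adaptation transform is applied.
* Reconstruction quality is bounded by the 6-component basis: reflectances
  far outside the chart's spectral subspace (narrow emission-like spectra)
  cannot be represented.
* The narrow-band composite is a pseudo-colour simulation; no claim of
  optical equivalence with any proprietary hardware implementation is made,
  and its channel mapping is a documented convention.
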