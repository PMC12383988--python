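# save-hsi — Spectrum Aided Vision Enhancer

Conventional white-light endoscopy (WLI) has limited contrast for the subtle
mucosal and vascular changes that mark early gastrointestinal disease.
Narrow-band imaging (NBI) fixes this optically — illuminating near the
haemoglobin absorption peaks at 415 nm and 540 nm darkens vessels against
mucosa — but requires dedicated hardware. `save-hsi` implements the
software-only alternative: it reconstructs a per-pixel reflectance spectrum
(a hyperspectral cube) from an ordinary RGB frame using ColorChecker-based
calibration, and then synthesizes a simulated narrow-band composite from the
cube. It is aimed at researchers in biomedical image analysis who want
spectral estimates and NBI-style contrast from standard endoscopic (or
capsule) video without new optics.

## Method

Calibration uses the 24-patch Macbeth ColorChecker. With reference patch
spectra R(λ) and the CIE 1931 2° observer, reference tristimulus values are

    X = k ∫ S(λ) R(λ) x̄(λ) dλ   (400–700 nm; likewise Y, Z)
    k = 100 / ∫ S(λ) ȳ(λ) dλ

so a perfect reflector has Y = 100. Camera sRGB is decoded to XYZ, and a
**variable-matrix correction** C is fitted over a third-order monomial
expansion V of the camera colour (20 terms: constant "dark" term, 3 linear
colour terms, 16 non-linear terms):

    C = XYZ_spectrum · pinv(V),    XYZ_correct = C · V

A mean-centred PCA of the 24 patch spectra yields a 6-component spectral
basis (six components explain ≥ 99.6% of ColorChecker spectral variance),
and a **transformation matrix** M maps expanded corrected-XYZ features onto
the PCA scores:

    M = Score · pinv(V_color),    R̂(λ) = mean(λ) + Σᵢ (M·V)ᵢ · PCᵢ(λ)

Narrow-band synthesis extracts Cauchy–Lorentz windowed band responses at
415/540 nm (plus low-weight 600/700/780 nm red contributions) and mixes them
into an RGB composite; residual spectral mismatch is modelled as a
multiplicative Lorentzian gain, f(x; x₀, γ) = γ/π · 1/((x−x₀)² + γ²), whose
amplitudes are tuned by fast simulated annealing (Cauchy visiting
distribution, T_k = T₀/(1+k)). Evaluation metrics — spectral RMSE, CIEDE2000,
SSIM, PSNR and Shannon entropy — are built in.

Everything is self-contained: the package ships CIE tables, a synthetic
24-patch chart, a simulated camera and a vascular phantom generator, so the
whole pipeline runs offline (see `docs/methods.md` for what the fixtures do
and do not emulate).

## Worked example

```python
from save_hsi import (SpectralCalibration, load_colorchecker,
                      simulate_camera, generate_phantom, PhantomSpec,
                      synthesize_nbi)

patches = load_colorchecker()                     # packaged 24-patch chart
rgb = simulate_camera(patches, seed=0)            # noise-free camera, D65
result = SpectralCalibration(patches.with_camera_rgb(rgb)).fit()
print(result.summary())
```

```
Spectral calibration summary
================================================================
patches: 24   expansion terms: 20 (order 3)
PCA components: 6   cumulative explained variance: 100.00%
mean dE00 raw -> corrected: 5.025 -> 0.038
mean spectral RMSE: 0.0078   mean dE00 (reconstruction): 0.038
...
```

The camera's uncorrected colour error (mean ΔE00 ≈ 5.0 — a clearly visible
difference) drops to ≈ 0.04 after the polynomial correction, and the
reconstructed patch spectra deviate from the reference spectra by a mean
RMSE of 0.008 reflectance units. On the vascular phantom, the simulated
narrow-band composite raises vessel-vs-background Weber contrast from 0.148
(white light) to 0.426:

```python
cube, wli, mask = generate_phantom(PhantomSpec(seed=7))
nbi = synthesize_nbi(cube)        # 415/540 nm composite, darkened vessels
```

The same flow is available from the shell:

```sh
save fixtures --phantom --seed 3 -o phantom
save calibrate -o model.json
save reconstruct phantom.png --model model.json -o cube
save nbi cube -o nbi.png
save evaluate --pair phantom.png nbi.png -o report.json
```

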