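# Methods

## Forward model

The simulator is scalar and paraxial. A quasi-monochromatic point source
at transverse position δ and distance `u` in front of the mask illuminates
it with the quadratic-phase wave `exp(ik((x−δx)² + (y−δy)²)/2u)/u`; the
binary mask transmits it through the pinholes; the field propagates the
mask–sensor distance `v`; the sensor records `|field|²`. Extended objects
are collections of mutually incoherent point emitters, so object frames
are intensity sums over emitters and wavelengths. Within this model a
lateral source shift δ shifts the sensor pattern rigidly by −(v/u)δ, which
is why a planar scene reduces exactly to the convolution `I_O = O ⊗ I_PSF`
(the convolution fast path projects the bitmap through the geometry by
bilinear point-splatting, and simulates the PSF on a window enlarged by
the projected object radius so content shifted in across the sensor edge
is kept; it matches emitter-by-emitter summation to ≲0.1% when image
points fall on grid samples).

Propagation uses the Fresnel transfer-function kernel
`exp(−iπλz(fx²+fy²))` whenever `|z| ≤ N·pitch²/λ` (unit-modulus kernel:
pitch-preserving and energy-conserving to round-off) and the
single-transform impulse-response form beyond that limit (output pitch
`λ|z|/(N·pitch)`); requesting the transfer-function form past its limit
raises an error naming the maximum valid distance. The simulation grid is
the sensor grid × `grid_oversample`, zero-padded at least 2× and enlarged
when needed to (a) hold the mask plus a diffraction margin and (b) keep
the transfer-function kernel alias-free over the distance `v`
(`N ≥ λv/pitch²`), rounded to an FFT-friendly length. Coordinates are
centered on the `n//2` pixel (the optical axis); distances are meters
internally, with mm/nm/µm at every file and CLI interface.

## Default geometry (and why it is scaled)

All defaults: `u = v = 10 cm`, mask 2 mm × 2 mm with 100 pinholes of
80 µm (fill ≈ 12.6%), sensor 256² at 8 µm pitch, λ ∈ {488, 530, 617} nm.
This is a scaled version of the experimental bench (8 mm mask, ~2000
pinholes, 1024×768 at 4.65 µm). The paraxial physics is scale-free, and
the scaled numbers are chosen so every sampling criterion holds honestly:
the finest fringe from the widest pinhole pair has period
`λv/D ≈ 18.7 µm > 2 × 8 µm`, the source wave's quadratic phase is
Nyquist-sampled over the mask, and one PSF simulation is a sub-second
~1024² FFT. At the experimental mask size those fringes (≈6.6 µm) would
alias on any grid small enough to be practical here. The fabricated-scale
mask parameters remain available (`fixtures.paper_mask_params()`), and
mask *generation* at that scale is tested. Tests and the acceptance script
state their problem sizes explicitly; the reciprocity scans use 64²
frames and a 4 mm/400-pinhole mask, because the scan's (u, λ)
discrimination scale must be finer than the 5 mm/5 nm scan steps —
mirroring the role of the experiment's 8 mm aperture.

## Reconstruction

All correlations remove each pattern's mean first (emulating bipolar
functions; intensity patterns are non-negative, and correlating raw
positive functions leaves a large pedestal). The nonlinear filter is

```
C = | IFT{ |F_PSF|^α e^{−i·arg F_PSF} · |F_O|^β e^{+i·arg F_O} } |
```

with α on the PSF spectrum and β on the object spectrum — so (1, 1) is the
matched filter, (0, 1) the phase-only filter, and the published operating
point (0, 0.6) makes the PSF term pure phase while compressing the object
magnitudes. Zero-magnitude bins pass zero for any exponent. Transforms are
pre-padded 2× (wrap-free linear correlation) and cropped back, zero lag at
the `n//2` pixel; `pad=False` gives the circular convention for exact
shift-equivariance checks.

The (α, β) operating point is selected by minimizing the Shannon entropy
`−Σ φ log φ` of the normalized reconstruction over a window (default
32×32, centered on the global peak; the window size is this package's
choice) — a delta-like output has low entropy. The default search grid is
α ∈ {0}, β ∈ {0.2 … 1.0 step 0.1}, bracketing the published point; ties
break to the smallest α then β. The full pipeline is
low-pass → spectrum-domain weighting → nonlinear correlation → median,
each stage disabled at its neutral value (cutoff 1, strength 0, kernel 1).
The circular low-pass at cutoff 1 would clip spectrum corners, so
cutoff ≥ 1 is the exact identity by definition.

**Spectrum-domain filter.** The published recipe names a "correlation in
spectrum domain" without a main-text definition; here it is the local
cosine similarity of the two spectral magnitudes,
`w = S(|F_O||F_PSF|) / √(S(|F_O|²)·S(|F_PSF|²))` with a Gaussian `S`
(σ = 2 bins), applied to the object spectrum as `w^strength`. Identical
patterns give `w ≡ 1`; bands carrying energy the PSF cannot explain are
suppressed. On noise-contaminated point frames this raises peak SNR
(tested); on pure-noise frames it leaves the background essentially
unchanged — a known limitation of this stand-in definition.

**Peak SNR** is `(peak − background mean)/background σ` outside an
exclusion disc (default radius 10 px) — also the mask-optimization
objective, evaluated on the nonlinear reconstruction of an on-axis point.

## Response curves and the whitened metric

Axial/spectral response curves and the reciprocity scans measure
correlation peaks between *whitened* (phase-only-both-sides) spectra,
normalized to 1 at the reference. Rationale: the smooth single-pinhole
diffraction envelope is nearly independent of depth and wavelength and
leaves a ~0.5 floor under a linear normalized cross-correlation, masking
the decay that actually governs channel separation; the reconstruction
filter itself operates on whitened spectra. With this metric the measured
widths sit inside the expected factor-2 of the direct-imaging limits:
lateral Λ FWHM ≈ 0.9 × `1.22λu/D` and axial FWHM ≈ 1.4 × `8λ(u/D)²` at
the default geometry (D = the mask extent's max chord).

## Mask design

Layer 1 draws `n_candidates` random arrays — two independent child streams
of the master seed supply x and y coordinates; candidate *i* is always
seeded by (seed, i) so a larger budget extends the same stream — and keeps
the SNR argmax. Layer 2 visits pinholes in index order trying +x, −x, +y,
−y moves of one fixed step, accepting only strict SNR increases that
preserve the non-overlap (center distance ≥ diameter) and extent
constraints; each SNR evaluation counts one iteration and the search stops
at the budget or after a pass with no accepted move. Ties keep the
incumbent, so the trace is deterministic and non-decreasing. One full pass
over ~2000 pinholes × 4 moves ≈ 8000 evaluations, matching the published
~10 000-iteration budget at fabricated scale; tests and the acceptance
script use 15–50 candidates and ≤ 150 evaluations on a 64²/16 µm
configuration.

## Library, γ synthesis, reciprocity

Library entries are indexed on a (z, λ) grid with nearest-key lookup
within half a grid step. PSFs at nearby depths/wavelengths differ mainly
by an isotropic magnification γ about the optical axis; `estimate_gamma`
maximizes the correlation peak of the rescaled pattern over a coarse grid
plus golden-section refinement to 1e-4 (bilinear resampling about the
grid-center pixel; flat landscapes raise an error). γ is modeled linear
in the coordinate (the printed linear fit): measured between the two
axial boundary recordings at each spectral corner and vice versa, then
interpolated bilinearly, with each interior entry synthesized by rescaling
its nearest corner (γ ≡ 1 there) and tagged with provenance and a quality
score (correlation against its source corner). Four boundary shots thus
populate any interior grid. At the default geometry the simulated
γ(Δu: −5 → +5 mm) ≈ 0.96 (the bench measured 0.975), and the synthesized
mid-depth PSF correlates ≈ 0.8 with the directly simulated one.

Reciprocity: the paraxial pattern depends on the products λu and λv only,
so `(u′, v′) = (λ_from/λ_to)(u, v)` reproduces a pattern at a different
wavelength exactly — "colour from depth and depth from colour". Scanning
(u = v, λ) jointly against a fixed reference yields a comb of maxima on
λu = const; holding v fixed leaves a single maximum at the reference,
because the sensor-side phases no longer rescale consistently. The scan
grids contain the reference exactly (an off-grid reference smears the
single maximum over shoulder samples).

## Wide field of view

The partial-sensor experiment keeps only the central third of the sensor
active. Both windowed frames have the intensity pedestal (the window
mean) removed inside the window before correlating — the raw boxcar step
otherwise creates spurious whitened-correlation peaks at shifts 0 and
± window width. A displaced point is "resolved" when the correlation peak
falls at its geometric position (±2 px) with SNR ≥ 5. The two windows
share content only while the image shift is under the full window width,
i.e. 2× the direct-imaging half-window limit is the theoretical supremum
of the indirect field of view; zero-overlap displacements are marked
unresolved on principle, and the demonstrated ratio is the largest
contiguous resolved prefix of the sweep (≈1.6–1.8× at the default
geometry, approaching the 2× bound).

## Synthetic data: what it does and does not emulate

The fixtures module generates resolution-chart style 3-bar targets
(line-pairs/mm exact), crosshairs, point grids, multi-plane multispectral
scenes, seeded Poisson/Gaussian/quantization noise, and the central-crop
sensor mask. It does not emulate: LED spectral width as a continuum
(polychromatic sources are a finite set of weighted lines), sensor
read-noise correlations, pixel cross-talk or saturation, mask-fabrication
edge roughness, or textured biological samples. Passing tests therefore
demonstrate the method's correctness under the stated incoherent,
paraxial, single-scattering model — not robustness to every experimental
nuisance; the noise models bound the first-order sensitivity only.

## Numerical choices and limitations

- Rasterization is binary (pixel center inside the pinhole), accurate to
  ~3% in open area at ≥4 samples per diameter (enforced).
- Intensities are kept in physical units; file writers rescale to 16-bit
  with the factor recorded in the JSON sidecar (reversible); integral
  arrays round-trip losslessly. Library frames are stored as float TIFF,
  so library round-trips are bit-exact.
- `curve_fwhm` interpolates half-max crossings linearly and assumes a
  single-peaked curve; sweeps should bracket the half-max on both sides.
- Bilinear rescaling (γ) is accurate on smooth content; on speckle a
  scale–rescale round trip loses fine grain (the γ *estimate* is still
  recovered to ±2e-3 because the correlation peak, not the residual, is
  the objective).
- The depth–wavelength reciprocity and the convolution model hold only in
  the paraxial, single-scattering regime; nothing here models imaging
  through scatterers, non-scalar polarization effects, or partial spatial
  coherence beyond the incoherent point-source sum.
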