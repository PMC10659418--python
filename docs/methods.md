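# Methods

## Wavefront model

Aberrations are expressed at the pupil (back focal plane) as a phase
φ(r, θ) = Σ_m c_m Z_m(r, θ) over the unit disk, with the Zernike basis in
ANSI single-index order (j = (n(n+2) + m_az)/2). The polynomials are
**orthonormal** (RMS-normalized: √(n+1) for m_az = 0, √(2(n+1))
otherwise), so the RMS wavefront distortion over the pupil equals the
Euclidean norm of the coefficients and the bookkeeping rule
RMS_c = √(Σ_{m≥3} c_m²) is exact rather than approximate. The source
material never states a normalization; orthonormality is the only choice
under which that identity holds, which is why it is adopted. Piston and
tilt (j = 0, 1, 2) shift but do not blur the image and are pinned to zero
everywhere.

Coefficients are sampled **uniformly** on [−T_m, T_m]; only bounds, not a
distribution, are documented upstream, and uniform is the minimal
assumption. Presets:

| preset        | heavy modes (1.5 rad) | others | default M |
|---------------|-----------------------|--------|-----------|
| experimental  | 4, 12                 | 0.5 rad| 14        |
| simulation    | 3, 4, 5, 12           | 0.5 rad| 14        |
| defocus_only  | 4                     | 0      | 14        |

M follows the order map M = (order+1)(order+2)/2 − 1 (9, 14, 20, 27, 35
for orders 3–7). Two rescaling rules post-process a draw: *max-RMS*
multiplies by Ω/RMS_T (RMS_T = bound-vector RMS), capping every draw at Ω;
*fixed-RMS* multiplies by Υ/RMS_c, pinning the draw exactly at Υ. Named
single-mode aberrations place Υ on one index (defocus c₄, spherical c₁₂)
or split it over a two-mode pair in quadrature,
(c_a, c_b) = Υ(cos, sin)(π·split/2); the split defaults to 0 and can be
drawn uniformly, since only the quadrature sum is constrained.

## PSF and degradation operator

The PSF is scalar Fourier-optics pupil propagation: a circular pupil of
radius 2πNA/λ in transverse frequency, per-plane defocus phasor
exp(i·z·√((2πn/λ)² − k⊥²)), intensity = |IFT₂(pupil·phasor)|². Aberrations
multiply the pupil by exp(iφ). For the light-sheet modality the 3D PSF is
multiplied by a Gaussian axial excitation profile whose stated thickness
(2 µm default) is interpreted as FWHM (the thickness convention is not
documented upstream). Defaults mirror a 1.1 NA water-dipping detection arm
at 0.532 µm on a 0.13 µm isotropic grid. PSFs are unit-sum; a zero
coefficient vector reproduces the ideal PSF bit for bit. Vectorial/high-NA
polarization effects and spatially varying (anisoplanatic) aberrations are
out of scope; the aberration is constant across the volume.

Degradation uses the modified OTF,
mOTF = H_a·conj(H_i) / (|H_i|² + ε·max|H_i|²), ε = 10⁻³ by default: a
Wiener-regularized ratio of aberrated to ideal OTFs (the unregularized
ratio is numerically untenable where the ideal OTF vanishes). Frequencies
outside the ideal OTF support are zeroed. Applying mOTF to an ideally
blurred volume re-blurs it as if acquired with the aberrated PSF; on 64³
interior-supported phantoms the result matches direct aberrated-PSF
convolution to <1.5 % relative L2 (the 5 % contract in the tests leaves
margin for draw-to-draw variation). A strictly zero aberration is treated
as the identity degradation rather than sent through the regularized
ratio, which would otherwise damp band-edge frequencies by O(ε).
Negative intensities after the inverse FFT are clipped to zero *before*
noise injection (photon counts are nonnegative).

Poisson noise: the volume is rescaled so that S — the mean of voxels above
1 % of the maximum — equals SNR², then each voxel is Poisson-sampled. The
upstream definition renders as "SNR = S", but the companion usage
("SNR ≈ 16" for visibly shot-noise-limited images) and Poisson statistics
(mean/σ = √mean) imply SNR = √S, which is what is implemented.

## Phantoms and training pairs

Phantoms hold five structure classes in a 256³ volume at 0.13 µm voxels by
default: dots (radius 1–2 vx), lines (thickness 1–2 vx, length 20–120 vx),
circles/rings (radius 8–20 vx), spheres (radius 5–15 vx) and spherical
shells (radius 8–20 vx, thickness 1–2 vx), randomly positioned and
oriented, intensities uniform in [0.5, 1], counts (30, 20, 15, 15, 10).
No primitive dimensions are documented upstream; these are chosen to span
sub-diffraction to multi-micron features and are fully configurable.
Ground truth is the phantom convolved with the ideal PSF using a centered,
zero-padded FFT convolution (the PSF peak stays on its voxel; no
wrap-around).

Training pairs degrade each ground truth `augment` times (default 10, so
50 sources → 500 pairs) with independently sampled aberrations plus
noise. A master seed fans out via `numpy.random.SeedSequence.spawn` to one
child seed per pair, recorded in the manifest, so any pair is reproducible
in isolation. The restoration backend is a two-function contract
(train → handle, apply → volume); the shipped baseline stores the mean
sampled aberrated PSF and restores by 20-iteration Richardson–Lucy. It is
deliberately *not* a learned model — it exists so every pipeline stage is
exercisable on one CPU and so external deep networks can be slotted in
behind the same interface. Training manifests record the conventional
deep-learning hyper-parameters (200 epochs, 400 steps, 64³ patches) for
downstream backends even though the baseline does not consume them.

## Deconvolution

Richardson–Lucy uses the standard multiplicative update with a division
guard of 10⁻¹²·max(image). Convolutions run in Fourier space; the default
boundary handling zero-pads by the PSF's effective support (the centered
box holding 1 − 10⁻⁵ of its energy) to avoid wrap-around, and a
`periodic` mode skips the padding — the benchmark harness uses it, since
at 128³ the padded transforms dominate runtime and randomly placed phantom
content makes wrap-around effects negligible and identical across arms.
Flux is conserved to ≪10⁻³ and a delta PSF is an exact fixed point. The
implementation matches scikit-image's independent Richardson–Lucy to
10⁻¹² relative on compact PSFs (for PSFs whose tails fill their grid the
two differ by box-truncation convention, not algorithm).

Blind deconvolution alternates one RL update of the PSF (given the image
estimate) with one RL update of the image (given the refreshed PSF),
renormalizing the PSF to unit sum each cycle and constraining its support
to the central third of the grid to keep the joint problem well-posed.
Default 10 iterations.

## Benchmark

Each replicate draws a fresh phantom and a fresh aberration, degrades,
adds noise, restores with each arm (raw, RL with ideal PSF, RL with the
matching aberrated PSF, blind, baseline backend) and scores 3D SSIM
(Gaussian window, σ = 1.5, K₁ = 0.01, K₂ = 0.03) and PSNR. The full
protocol is 10 phantoms × 10 aberrations = 100 simulations; the test
suite runs 3 × 3 at 128³ to stay within a desktop CPU budget.

Scoring reference: by default arms are scored **against the phantom
object** (after matching total flux). Scored against the ideally blurred
volume instead, every deconvolution arm is *penalized for sharpening
beyond the diffraction limit* and the raw aberrated volume wins — the
orderings invert. Against the object, the expected ordering
RL(aberrated PSF) > RL(ideal PSF) > raw holds (measured at 128³, Ω = 2,
SNR 16: SSIM 0.87 / 0.84 / 0.76). Both references are selectable
(`reference="phantom" | "ideal-blur"`); the ideal-blur reference remains
the training target of the restoration pairs.

## Preprocessing

All preprocessing is pure (input untouched) and appended to the volume's
provenance log. Depth attenuation compensation multiplies plane z by
e^{αz} with z the **plane index** counted from the shallow
(objective-near) side — the depth unit is not documented upstream, and
plane indexing matches how the correction is applied in practice; α
defaults to 0.01 per plane. Axial rescaling multiplies the axial voxel
size metadata (1.45 being the focal-shift factor for air-objective imaging
into aqueous clearing media), with optional linear-interpolation
resampling to an isotropic grid. Dark-frame averaging is out of scope; the
background subtractor takes a precomputed scalar or plane.

## Fiber orientation and directional variance

Fibers are segmented by six-level multi-Otsu thresholding (five
thresholds; the lowest class is background, the union of the upper five is
fiber). For each fiber voxel, candidate vectors run from the center to
every fiber voxel in the n³ window whose discretized connecting segment
lies entirely inside the mask; each is weighted by segment length ×
1/(1 + CV), CV the coefficient of variation of intensities along the
segment. The upstream description weights "by length and intensity
variations" without a formula; 1/(1+CV) is the package's choice
(monotone, dimensionless, 1 for uniform intensity) and the weighting is
exposed for replacement. Vectors are flipped into the x ≥ 0 hemisphere
(ties broken by y, then z) before summation — fibers are axial, so a sign
is not physical. Window size n should be 2–3× the fiber thickness; voxels
with no candidate vectors are flagged invalid.

Angles: θ = azimuth of the xy-projection from +x; β = zx-projection angle
from +x; γ = yz-projection angle from −y; φ = polar angle from +z; all in
[0°, 180°). These satisfy tan²φ = 1/tan²β + 1/tan²γ at every nondegenerate
voxel (verified to 10⁻⁶ by property test).

Directional variance over k voxels:
D̄₃D = 1 − √(C̄² + S̄² + Z̄²) with
C̄ = (1/k)Σ (f_j/√(1+f_j²))·cos 2θ_j, S̄ analogous with sine,
Z̄ = (1/k)Σ SI_j/√(1+f_j²), f_j = √(1/tan²2β_j + 1/tan²2γ_j) and
SI_j = −sign(φ_j − 90°). The source renders these formulas without
radicals; the implemented normalization f/√(1+f²), 1/√(1+f²) is the only
reading under which each voxel contributes a *unit* vector, making a
perfectly parallel field give exactly D̄₃D = 0 — a stated property of the
statistic. Numerical guards: degenerate tangents are taken by limit
(f → ∞ ⇒ planar weight 1, axial weight 0; clamped at 10¹²); SI at exactly
φ = 90° is set to +1, harmless because its coefficient vanishes in the
same limit; the final value is clipped to [0, 1] against 10⁻¹⁶-scale
roundoff. With 10⁵ uniformly random 3D orientations D̄₃D ≈ 0.996.

The θ-histogram spans [0°, 180°) at a configurable bin width; the modal
peak's FWHM is measured by linear interpolation of the half-maximum
crossings between bin centers (a single occupied bin reports the bin
width).

## What the synthetic data does and does not show

The generator reproduces the *protocol* of the published simulations —
structure classes, volume and voxel geometry, aberration bounds and
rescalings, SNR model — with self-chosen primitive dimensions. It does not
emulate real tissue: no spatially varying aberration, no scattering or
depth-dependent SNR loss, no anisotropic noise, no sample motion.
Passing tests therefore validate the forward model, the estimators and
their contracts, not restoration performance on real microscope data; the
published deep-learning results on experimental volumes require externally
trained networks (pluggable here as restoration backends) and are outside
the scope of this package's benchmarks.

## Problem sizes and runtime

Defaults in the test suite are chosen for a single CPU: PSF/OTF tests at
32³–64³, the pair-assembly check at 50 × 10 pairs on 64³ grids, the
benchmark ordering check at 3 phantoms × 3 aberrations on 128³, bound and
rescaling compliance at 10⁴ draws, and directional-variance limits at 10⁵
orientations. The acceptance script runs the same library paths at the
same sizes and completes in seconds.
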