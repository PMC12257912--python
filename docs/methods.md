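# Methods

## Problem and model

Fan-beam CT reconstructs a 2-D attenuation map from line integrals
(a sinogram, N views x D detector cells).  Classical filtered
back-projection (FBP) computes

    y = A^T C W_cos p ,

where `W_cos` is flat-detector cosine weighting `SDD / sqrt(SDD^2 + u^2)`,
`C` is per-view ramp filtering, and `A^T` is back-projection: for every
output pixel `x_q` and view i the filtered sinogram `z` is sampled at the
projected detector coordinate `x_iq` with cross-weighted linear
interpolation and the fan-beam magnification weight `1 / L_iq^2`
(`L_iq` = source-to-pixel distance),

    y(x_q) = sum_i (1 / L_iq^2) (1 / l_i) [ l_i0 z_i1 + l_i1 z_i0 ] .

Linear interpolation is the resolution bottleneck: the detector pitch (made
worse by detector binning, which averages s adjacent cells to trade
resolution for noise) limits what any output grid can resolve.  This
package replaces the interpolation with a *continuous* local model.  A
small CNN encoder `E` extracts features from the sinogram; a 1x1
convolution `A_gamma` maps them to 2n+1 coefficients `z*` per sinogram
sample; and decoding is the inner product of `z*` with a positional
encoding of the sub-cell offset,

    PE(x) = [1, sqrt(2) cos(pi x), sqrt(2) sin(pi x), ..., sqrt(2) sin(n pi x)],

orthonormal under `(1/2) * integral_{-1}^{1}`.  The augmented
back-projection adds the decoded corrections to the interpolated values:

    y(x_q) = sum_i (1/L_iq^2)(1/l_i) [ l_i0 (z_i1 + z*_i1 . PE(D1))
                                     + l_i1 (z_i0 + z*_i0 . PE(D0)) ] ,

with offsets normalized by the (binned) detector pitch, so
`D0 = x_iq - x_i0 in [0, 1]` and `D1 = x_iq - x_i1 in [-1, 0]` always lie in
the orthogonality domain.  The decoder itself has no parameters; with
`z* = 0` the formula reduces to plain FBP *exactly*, which is the module's
primary numerical contract.  Because the map `(z, z*) -> y` is linear, its
adjoint with respect to `z*` is an exact scatter of the back-projection
weights; training needs no autodiff framework.

## Sinogram squeezing and unfolding

Only a narrow view-dependent band of the sinogram contributes to a given
ROI.  Per view, the detector index of the ray through the ROI center is
found in closed form; the detector axis is zero-padded by `pad` and the
window of width `d` centered on the *rounded* index is copied out, giving a
rectangular N x d array.  Values are copied, never resampled, and the
integer window start per view is retained, so mapping a ray coordinate into
the window is an exact affine shift that preserves the fractional offset —
ROI FBP through the window is bit-for-bit-comparable (< 1e-9) with ROI FBP
from the full sinogram whenever every ray stays inside the window.

Rounding uses half-away-from-zero; the residual travels with the map, so no
information is lost (the rounding rule is an internal convention).  The
window is `d` cells total, centered (a "minimum d" estimator that projects
the patch corners in every view is provided to check a requested ROI).
The protocol defaults are `d = 64/s`, `pad = 256/s` at binning scale s;
with the default geometry below these guarantee containment for a 128x128
ground-truth patch at 0.7 mm pixels.

Squeezing can separate sinogram neighbors that a convolutional encoder
would otherwise see together, so the 3x3 neighborhood of every sample can
be stacked as 9 channels *before* squeezing ("unfolding", zero-filled
borders); the encoder then starts with a 1x1, nine-input-channel layer.
Contracting the channels with a 1x1 kernel is equivalent to a 3x3
convolution on the unsqueezed sinogram (verified on the interior; borders
differ by the zero-fill convention).

## Geometry and numerical choices

* Flat equidistant detector; world frame with isocenter origin, x right /
  y up; view angle = source azimuth CCW from +y; detector samples at
  `u_k = (k - (D-1)/2) * pitch`.
* Default scanner: SID 800 mm, SDD 1200 mm, 128 cells x 3.6 mm pitch
  (2.4 mm at isocenter), full 2*pi scan.  The pitch is chosen so the
  squeeze-protocol containment guarantee above holds with margin; all
  values are constructor arguments.
* Ramp filter: discrete Ram-Lak (`h[0] = 1/(4 Delta^2)`,
  `h[k] = -1/(pi k Delta)^2` odd k) at the isocenter-scaled pitch,
  FFT-evaluated with zero padding to the next power of two >= 2D; optional
  Hann apodization.  Ram-Lak is the default window.
* Back-projection scale: `0.5 * (2 pi / N) * SID^2 / L^2`.  The 1/2
  compensates the double coverage of a full scan (every line is measured
  twice); `SID^2` makes the `1/L^2` magnification weight dimensionless and
  unity at the isocenter.  With the `1/L^2` weight (rather than
  the inverse squared distance *along the central ray*) the absolute scale
  carries a `cos^2`-shaped shading of a few percent at the fan angles used
  here; PSNR/SSIM comparisons are unaffected and absolute calibration is
  not a contract (the Shepp-Logan center reconstructs within ~3 HU).
* Forward projector: ray-driven, fixed step of 1/4 pixel, bilinear
  sampling, rays clipped to the grid's circumscribed circle; checkable
  against closed-form ellipse chords (`project_ellipses_analytic`), which
  also serve as the exact projector for ellipse phantoms.
* Accumulation in float64 everywhere; the squeeze/decode path shares the
  per-view ray transform with plain FBP so the zero-feature reduction and
  squeeze equivalence hold to float64 rounding, not just approximately.
* Degenerate inputs: rays outside the physical detector contribute zero and
  are counted per pixel; rays outside the squeeze window are flagged per
  pixel (`meta['outside_window']`); Poisson zero counts clip to one photon
  before the log (recorded in metadata); HU below -1000 clip to vacuum in
  `hu_to_mu`.

## Synthetic data

Phantoms are additive ellipse sets in Hounsfield units on an air (-1000 HU)
background: the published Shepp-Logan table (gray level scaled to 2000 HU
per unit, i.e. air to bone) or seeded random body-plus-structures phantoms
(water-equivalent body, 3-8 internal ellipses at -300..+500 HU).  Lesions
are additive Gaussian bumps, sigma 0.75 ground-truth pixels and peak 100 HU
by default, truncated at 6 sigma (sigma is interpreted in image-pixel units
of the ground-truth grid, since lesions are defined on image patches).
Attenuation is `mu = mu_water (HU/1000 + 1)` with `mu_water = 0.02 /mm`.
Noise follows the quantum model: counts `~ Poisson(I0 exp(-p))` at
`I0 = 1e6` incident photons per ray by default; detector binning averages s
adjacent cells (arithmetic mean, so line-integral magnitudes are
scale-invariant and binning composes).

What the generator does *not* emulate: anatomical texture, scatter, beam
hardening, detector cross-talk, polychromatic spectra.  Passing tests
therefore demonstrate the correctness of the operators and the learnability
of the binning/noise degradation on piecewise-smooth objects, not clinical
image quality.

## Training

Step 1 trains the encoder (four-layer residual CNN, 32 channels, no
downsampling — a deliberately small, CPU-trainable feature extractor; the
interface accepts any `(C, N, d) -> (F, N, d)` map) and the channel-matching
1x1 convolution jointly: per sample a (phantom, ROI center, binning scale)
triple is drawn with s in {1, 2, 4}, the noisy binned sinogram is filtered,
unfolded, and squeezed, the ROI patch is reconstructed through the
augmented back-projection, and the L1 error against the ground-truth HU
patch is minimized with Adam.  `A_gamma` is zero-initialized, so the
iteration-0 loss equals the FBP error exactly and training can only move
away from FBP by reducing the loss.  The learning rate halves at 0.2 / 0.4
/ 0.6 / 0.8 of the configured epochs; the default initial rate is 1e-3 for
the small encoder.
ROI centers are sampled uniformly over the phantom interior excluding air.
Data augmentation is a no-op hook (the reference augmentation procedure is
not public; inventing one here would change the study conditions).

Step 2 optionally trains a six-layer residual restorator (zero-initialized
last layer, hence the identity until trained) on (step-1 output, ground
truth) patch pairs with step-1 frozen.  It is plug-and-play: stored
separately, applied on request, and leaving step-1 outputs untouched when
disabled.

Basis size defaults to n = 5 (11 coefficients).  Larger n adds
high-frequency capacity but, past the band limit implied by the detector
sampling, no further fidelity — the basis-saturation test demonstrates the
effect directly on band-limited profiles.

## Desk-scale study sizes

The bundled study (test fixture and `run_experiment` defaults) uses 12
training / 10 held-out random-ellipse phantoms on 96x96 grids (0.7 mm),
120 views, scales {1, 2, 4} for training and {2, 4, 8} for evaluation,
32x32 ROI patches, 5 epochs x 30 iterations at batch 2.  These sizes are
the package's chosen toy-study conditions; they are large enough that the
trained model consistently outperforms FBP by several dB at the trained
scales and by >1 dB at the unseen s = 8, while a full run stays in the
minutes range on one CPU.  PSNR uses a 2000 HU data range by default
(configurable); SSIM is the standard 7x7 uniform-window form.

## Known limitations

* 2-D fan-beam only; no curved detectors, no cone-beam/FDK, no iterative
  reconstruction.
* The `1/L^2` weight's absolute-calibration shading (above) would matter
  for quantitative HU work at wide fan angles.
* Squeezed windows that overhang the physical detector read zero-padded
  values where full-sinogram FBP would drop the ray; the equivalence
  contract applies to ROIs whose rays stay on the detector.
* The tiny encoder is not meant to match large super-resolution encoders;
  absolute PSNR of the toy study is not comparable to clinical-data
  results.
* Training is single-threaded numpy; wall time grows quickly with views,
  window width, and patch size.
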