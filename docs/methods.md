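# Methods

## The imaging model

One axial slice of the sample is described by its attenuation map
`u(x, y)` (units: inverse field-of-view half-widths; the field of view is
`[-1, 1]²`).  A parallel-beam scan measures line integrals

    p(θ, s) = ∫ u dℓ   along the ray  x cosθ + y sinθ = s,

collected into a sinogram of `n_angles × n_cols` entries with angles
`θ_k = k · 180° / n_angles` and detector offsets
`s_j = (j + 0.5 − n_cols/2) · pixel_size`.  One infinitesimally thin ray is
traced per detector column: the aperture that defines a beamlet is one
detector pixel wide, so the beamlet is well approximated by a line.

The sample is a foam: a cylinder of one material from which non-overlapping
spheres have been removed.  For this geometry the line integral has a
closed form (cylinder chord minus the chords through intersected voids),
which serves as the exact forward model; an independent discrete Radon
transform of a rasterized slice is used in the tests to validate it.

**Counting noise.**  Each detector pixel records
`counts ~ Poisson(I0 · e^{−p})` with `I0` incident photons per pixel
(default 1000); the noisy line integral is `−ln(max(counts, 0.5)/I0)`.
The 0.5-count floor keeps fully absorbed rays finite while preserving the
scale of the maximal measurable attenuation.  The bulk attenuation `μ` is
not chosen directly: it is calibrated by a monotone root-find so the sample
absorbs a target fraction of photons on average (default 50%), which ties
the phantom's contrast to the photon budget the way a real exposure would.

## The foam phantom generator

Voids are drawn largest-first and placed by rejection sampling, uniform in
cylinder volume.  Radii follow
`r = r_min · (r_max/r_min)^(u^q)`, `u ~ U(0,1)` with exponent `q = 3`:
many small voids, few large ones, spanning the decades of scale that make
foams hard for purely local or purely global reconstruction priors.  The
distribution is a package choice (only "varying sizes" is inherent to the
benchmark); any distribution obeying the non-overlap and containment
invariants may be substituted.  Ground-truth slices are rasterized by
super-sampled area fractions (default 4×4 subsamples per pixel), so a pixel
value is `μ ×` (area fraction of material in the pixel).

## Acquisition sampling and dose

A mask of period `p` pixels and aperture `w` pixels passes `w` of every `p`
detector columns per frame.  Scan modes are expressed as boolean masks over
the sinogram grid:

- *dithered*: the sample is stepped laterally `p/w` times per angle —
  complete rows, `n_angles · p/w` frames (the 100%-dose reference);
- *cycloidal*: one frame per angle, the sampled column residue advancing by
  `shift_per_angle` (default 3) each projection:
  `mask[k, j] = (j − offset − k·shift) mod p < w`.  With `gcd(shift, p)=1`
  any `p` consecutive angles jointly cover all column residues;
- *rotation-only*: cycloidal with zero shift (every angle samples the same
  columns) — the unfavourable pattern the lateral translation avoids;
- *angular subsampling*: complete rows, every `k`-th angle kept;
- *low exposure*: complete sampling at a reduced photon count per frame.

`n_train` *training projections*, spread evenly over the angular range
(indices `round(i · n_angles / n_train)`), are acquired with full dithering
and provide the in-scan training targets.

**Dose accounting** is frame- and exposure-weighted relative to the
complete dithered scan.  An interleaved training dithering is counted as a
wholly additional `p/w` frames at its angle, i.e. no credit is taken for
the cycloidal frame already acquired there; this convention makes the dose
of a scan with training data exactly `base + n_train·(p/w) / (n_angles·p/w)`
and is the one the reported percentages (12.5 / 15.7 / 3.2 at full scale)
follow.

## Bicubic completion

Missing entries are filled by piecewise-cubic C¹ interpolation
(Clough–Tocher) over the scattered acquired points in (angle-index,
column-index) coordinates, with nearest-acquired-value filling outside the
convex hull of the data (a thin border near the first/last angles and the
detector edges).  The interpolant is exact at acquired entries and
reproduces linear sinograms exactly inside the hull.  One scattered-data
route is used for every mask shape rather than a special-cased separable
spline on the pure cycloidal lattice: interleaved training rows break the
sheared lattice in every practical scan, and a single code path keeps the
baseline identical across sampling modes.

## The MS-D network

The Mixed-Scale Dense network uses dilated 3×3 convolutions exclusively
(no down/up-sampling) and dense connectivity: layer `i` (one channel)
computes

    z_i = ReLU( b_i + Σ_{c ∈ {x, z_1..z_{i−1}}} C_{d_i}(z_c) ),

where `C_d` is a 3×3 convolution with dilation `d` and the dilations cycle
through 1…10.  The output is an affine map over all images:
`y = b_out + Σ_c w_c z_c`.  Parameter count for depth `L` is
`Σ_{i=1..L}(9i + 1) + (L + 1) + 1` — 45,652 at depth 100 — orders of
magnitude below encoder–decoder architectures, which is what makes training
on a handful of in-scan projections feasible.

Numerical choices:

- **Padding**: zero padding, so every intermediate image keeps the input
  shape and a brute-force oracle is unambiguous.  (Reflective padding is a
  common alternative; the choice is recorded in the checkpoint.)
- **Initialization**: convolution weights zero-mean normal with variance
  `2 / (9 · n_channels_in)` (fan-in scaled); biases and the final map start
  at zero, so the initial network output is identically zero and early
  training is dominated by the convex final-map direction.
- **Normalization**: inputs are standardized with training-set statistics
  and targets are regressed in standardized space; the constants are stored
  in the checkpoint and applied on prediction.  This keeps ADAM's default
  step size appropriate regardless of the physical scale of `μ`.
- Forward and backward passes are direct numpy shift-and-accumulate over
  the nine kernel taps; gradients are verified against finite differences
  (1e-4 relative) in the tests.

## In-scan training

Inputs are the bicubic-completed cycloidal sinograms; targets are
"partial" sinograms that hold the dithered training projections and are
undefined elsewhere.  The loss for one pair is the sum of squared errors
over the defined pixels only; undefined pixels cannot influence the
gradient (fuzz-tested).  Optimization is ADAM at the default learning rate
1e-3, one whole sinogram per step (no patching — the dense dilated
architecture processes large images directly), shuffled each epoch.  The
sinogram stack is split 90% / 10% into training and validation sets; after
every epoch the mean per-pixel masked loss on the validation sinograms is
evaluated and the parameters with the lowest validation loss are returned.
Logged losses are per defined pixel and in raw target units, so curves are
comparable across sinograms and runs; the optimized quantity is the raw
sum.  The budget is epochs or wall-clock, whichever ends first.

## Reconstruction

**FBP**: each projection row is ramp-filtered via FFT on zero-padded rows,
with the filter built from the exact spatial-domain Ram-Lak kernel
(`h[0] = 1/(4Δs²)`, `h[odd n] = −1/(π n Δs)²`) — the naive `|ω|` ramp on a
finite window biases the DC term and produces cupping.  Back-projection
uses linear interpolation and the discretization
`f ≈ (π / n_angles) Σ_θ q_θ`.  Pixels outside the detector's lateral
coverage are zeroed (the standard reconstruction circle).  On noise-free,
fully sampled foam data this implementation reaches the ≥ 30 dB regime
against the rasterized ground truth.

**TV**: `½‖Au − b‖² + λ·TV(u)` with isotropic TV (forward differences,
Neumann boundary), minimized by the Chambolle–Pock primal–dual algorithm.
The discrete operator `A` is a sparse matrix assembled by ray marching with
bilinear interpolation (step = one image pixel), so the adjoint is exact;
`‖A‖` is estimated by 20 power iterations and steps satisfy
`στ‖K‖² ≤ 1` with `‖K‖² ≤ ‖A‖² + 8`.  The final primal objective and a
Lagrangian gap estimate are reported in the provenance.  The TV weight can
be swept over a grid and chosen to maximize PSNR or MS-SSIM against a
reference, ties broken toward weaker regularization.

## Metrics

- **PSNR** `= 10 log₁₀(peak² / MSE)` with `peak = max(reference)` — the
  peak convention is recorded because absolute values depend on it.
- **Dice** on binary segmentations; the default threshold is `μ/2`, the
  midpoint of the known two-material phantom, with Otsu and a
  Dice-maximizing sweep available.
- **MS-SSIM**: 5 dyadic scales, canonical weights
  (0.0448, 0.2856, 0.3001, 0.2363, 0.1333), 11×11 Gaussian window
  (σ = 1.5), data range = reference peak; when an image is too small for
  5 scales the count is reduced with a warning and weights renormalized
  (128² images use 4 scales).  The single-scale reduction matches
  scikit-image's SSIM to 1e-6.

Metrics are evaluated on the central slice, consistent with how the TV
weight is tuned.

## The desk-scale benchmark (`tiny` preset)

The package's default experiment is a scaled-down version of the
full-scale study (1024² detector, 1024 angles, 1024 slices, depth-100
network, ~48 h of training), chosen so the whole four-method comparison
runs in minutes on one CPU core while preserving the acquisition physics:

| quantity | full scale | tiny preset |
|---|---|---|
| detector / angles | 1024 / 1024 | 128 / 128 |
| mask period / aperture / shift | 8 / 1 / 3 px | same |
| photons per pixel, absorption | 1000, ~50% | same |
| training projections | 33 (3.2% dose overhead) | 13 |
| sinogram stack (slices) | 1024 (922/102 split) | 32 (29/3) |
| network depth / dilations | 100 / 1–10 | 30 / 1–10 |
| training budget | ~68 epochs / 48 h | 40 epochs / ≤ 7 min |

At this scale the strategy ordering of the full-scale study is reproduced:
network completion > bicubic completion > angular subsampling on PSNR and
MS-SSIM, with the network-restored reconstruction also exceeding the
complete-data FBP because the masked-loss training denoises.  Most of the
validation-loss improvement arrives in the first third of the epoch budget.

## What the synthetic data do and do not emulate

The generator reproduces the geometry (interlaced sampling, evenly spread
training angles), the photon statistics of a counting detector, and the
two-material, multi-scale structure that makes foams a demanding benchmark.
It does **not** model: polychromatic spectra or beam hardening; source or
detector blur (the mask's resolution advantage is therefore not itself
simulated — the package addresses the *sampling* problem it creates);
fan/cone-beam geometry; detector cross-talk, mask misalignment or flyscan
motion blur; phase-contrast effects.  Passing tests therefore demonstrate
the correctness of the sampling/completion/training/reconstruction chain
and the relative ranking of strategies under ideal parallel-beam counting
statistics, not performance on any particular scanner.

## Known limitations

- Training is pure numpy on one core: desk-scale networks train in
  minutes, but the full-scale configuration is out of reach here by
  design; the preset sizes above are the package's supported scale.
- The scattered-data completion is O(n log n) in acquired points per
  sinogram; at 1024² it is noticeably slower than a lattice-aware spline.
- The Chambolle–Pock gap estimate is a diagnostic, not a certified bound,
  because the dual iterate is not exactly feasible at finite iteration
  counts.
- At the desk scale the depth-30 network's receptive field (~165 px for
  30 layers with dilations 1–10) exceeds the 128-pixel sinogram, so the
  zero-padded borders make absolute angle positions partially learnable and
  the network's raw sinogram error on unsupervised rows can exceed the
  bicubic baseline's even while its reconstructions are clearly better;
  at full scale (1024² sinograms) the receptive field is a small fraction
  of the image and this effect shrinks.
- `run_comparison` pairs noise realizations across equal-exposure methods;
  low-exposure methods draw fresh counts (a physical exposure cannot be
  shared), so low-exposure rows carry slightly more run-to-run variance.
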