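# cycloct

Simulation and restoration toolkit for **cycloidal (masked-beam) computed
tomography**, where an absorbing mask structures the x-ray beam into thin
beamlets and the sample is translated laterally *while* it rotates.  The
mask raises spatial resolution beyond the source/detector blur, but each
projection samples only a fraction `w/p` of the detector columns (aperture
width `w`, mask period `p`), so the sinogram arrives incomplete on an
interlaced lattice and must be completed before reconstruction.

`cycloct` implements the full computational chain:

- a **numerical foam phantom** (non-overlapping spherical voids in a
  uniform cylinder) with closed-form parallel-beam projection and Poisson
  photon-counting noise;
- **acquisition masks** for dithered (complete), cycloidal, rotation-only,
  angularly subsampled and low-exposure scans, with exposure-weighted dose
  accounting;
- **bicubic completion** of interlaced sinograms;
- a from-scratch **Mixed-Scale Dense (MS-D) convolutional network** —
  dilated 3×3 convolutions only, every layer densely connected, one channel
  per layer — for sinogram-to-sinogram restoration;
- **in-scan training**: a few fully dithered *training projections* are
  interleaved with the cycloidal scan; the network is trained to map the
  bicubic-completed sinogram `x_i` to the measured "partial" sinogram `y_i`
  with a loss restricted to the measured pixels `D`,

  `L_cyc(f_φ(x_i), y_i) = Σ_{j ∈ D} (f_φ(x_i)^j − y_i^j)²`

  so no reference data outside the scan itself are needed;
- **FBP** (Ram-Lak) and **total-variation reconstruction**
  (Chambolle–Pock for `½‖Au − b‖² + λ·TV(u)`), plus a metric-maximizing
  TV-weight sweep;
- **benchmark metrics**: PSNR, Dice of thresholded segmentations, and
  multiscale SSIM, with dose per strategy.

## Worked example

Run the dose-reduction benchmark at the desk-scale preset (128² phantom
with 500 voids, 128 projections over 180°, mask period 8 / aperture 1 /
shift 3 pixels per angle, 1000 photons per pixel with the attenuation
calibrated so the sample absorbs half the photons, 13 interleaved training
projections, depth-30 network):

```bash
cycloct compare --seed 1 --out results/
```

which prints (also written to `results/comparison.csv`):

```
            complete  dose  100.0%  PSNR  15.05 dB  Dice 0.983  MS-SSIM 0.851
     angular_bicubic  dose   12.5%  PSNR  13.66 dB  Dice 0.959  MS-SSIM 0.782
   cycloidal_bicubic  dose   12.5%  PSNR  17.20 dB  Dice 0.981  MS-SSIM 0.828
       cycloidal_msd  dose   22.7%  PSNR  18.58 dB  Dice 0.982  MS-SSIM 0.865
```

Reading the rows: the *complete* scan uses full dithering (8 frames per
angle, 100% dose) and is limited by photon noise.  Discarding 7 of 8
projections (*angular_bicubic*) costs 1.4 dB.  Cycloidal sampling at the
same 12.5% dose (*cycloidal_bicubic*) already beats angular subsampling by
3.5 dB because the interlaced lattice retains high-resolution content at
every angle.  Training the MS-D network on the 13 interleaved dithered
projections (*cycloidal_msd*; the training overhead raises the dose to
22.7% at this scan length) adds another 1.4 dB and the best MS-SSIM of all
strategies — it exceeds even the complete-data reconstruction because the
network denoises while it completes.

The same chain is scriptable from Python:

```python
from cycloct import tiny_config, run_comparison
reports, artifacts = run_comparison(tiny_config(seed=1))
```

Individual stages are exposed as CLI verbs (`phantom`, `simulate`, `mask`,
`interp`, `train`, `apply`, `recon`, `metrics`, `compare`, `fixtures`) and
as library functions; see `docs/methods.md` for the model details and
parameter choices.

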