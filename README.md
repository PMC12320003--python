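# laminapipe

Preprocessing and hierarchical connectome analysis for high-resolution
resting-state fMRI, built for laminar-scale studies (e.g. 0.25 mm in-plane
mouse EPI) where thermal noise dominates and every avoidable interpolation
costs resolution. The package provides:

* **RMT-PCA denoising** — sliding 3×3 patches are unfolded into Casorati
  matrices (voxels × time); under pure thermal noise their singular values
  follow the Marchenko–Pastur law, and the largest noise singular value
  fluctuates on the narrow Tracy–Widom scale set by the long time axis.
  Components above a calibrated noise edge are kept and their singular
  values debiased through the spiked-model relation
  `y = (1 + ℓ)(1 + γ/ℓ)`; everything below is removed. The residual is
  returned for Gaussianity diagnostics and `denoised + residual == input`
  holds exactly.
* **Three-stage motion estimation** — per-slice phase-encode translation,
  6-DOF rigid registration, and patch-wise Fourier phase-correlation
  non-rigid estimation, each stage estimating on the residual of the
  previous one. Estimation only: no data resampling happens here.
* **Field-map distortion correction** — B0 off-resonance (Hz) converts to a
  phase-encode voxel shift via `shift = ΔB₀ · echo-spacing · n_PE`.
* **Single-interpolation warping** — all voxel-shift sources (B0, per-slice
  PE, rigid, non-rigid, grid upsampling) are composed functionally into one
  displacement field per frame and applied with exactly one interpolation,
  keeping the output FWHM below what sequential per-source resampling
  produces.
* **Nuisance cleaning** — motion + drift regression, then zero-phase
  band-pass into the infra-slow band (0.01–0.1 Hz).
* **Alignment** — bias correction, brain masking, rigid/affine registration
  (texture-rich onto texture-poor), internal demons refinement, and
  invertible transform chains (atlas → anatomical → EPI).
* **Hierarchical connectome** — seed maps, region × region Fisher-z
  matrices at any atlas depth down to single cortical layers, connectogram
  edge lists (z > 0.2), seed-size scaling, and group averaging.

Everything is validated on a built-in layered digital brain phantom
(cortical layer volumes proportional to the barrel-field laminar
thicknesses, planted correlation networks, known motion/distortion/noise),
so the full pipeline can be tested end to end with exact ground truth and
no downloads. See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import numpy as np
from laminapipe import phantom, denoise, clean, qc
from laminapipe.connectome import hierarchical_matrix, connectogram_edges
from laminapipe.images import Image3D

# layered phantom: tSNR ~ 10, planted z = atanh(0.6) = 0.69 between the
# left (10) and right (20) cortical subregions, 310 frames at TR = 1 s
truth = phantom.default_phantom((64, 40, 2), n_frames=310, seed=42,
                                with_motion=False, with_fieldmap=False)
acq = phantom.apply_acquisition(truth.clean_series, truth, truth.acq, seed=42)

den, resid, sigma_map = denoise.denoise_series(acq, window=(3, 3))
mask = truth.atlas.labels.data > 0
gain = (np.median(qc.tsnr_map(den).data[mask])
        / np.median(qc.tsnr_map(acq).data[mask]))
print(f"tSNR gain after RMT-PCA denoising: {gain:.1f}x")
print(f"estimated noise sigma: {np.median(sigma_map.data[mask]):.2f} (true 10.00)")

design = clean.build_design(None, den.n_frames, drift="cosine", tr_s=den.tr_s)
cleaned = clean.bandpass(clean.regress_nuisance(den, design), (0.01, 0.1))
mat = hierarchical_matrix(cleaned, truth.atlas, level=2)
print(mat.to_dataframe().round(2))
print(connectogram_edges(mat, threshold=0.2).round(3))
```

prints

```
tSNR gain after RMT-PCA denoising: 49.2x
estimated noise sigma: 10.03 (true 10.00)
      10    20    30    40    50    60
10   NaN  0.54 -0.03  0.03  0.21  0.08
20  0.54   NaN  0.02  0.04  0.15  0.03
30 -0.03  0.02   NaN  0.01  0.25  0.09
40  0.03  0.04  0.01   NaN  0.16  0.41
50  0.21  0.15  0.25  0.16   NaN -0.05
60  0.08  0.03  0.09  0.41 -0.05   NaN
 region_a  region_b      z
       10        20  0.542
       40        60  0.405
       30        50  0.255
       10        50  0.209
```

The planted edge (10–20) is the strongest entry; its z of 0.54 sits within
sampling error of the planted 0.69 (band-limited signals at 310 frames carry
only ≈ 56 effective samples, so the Fisher-z standard error is ≈ 0.14, and
unplanted pairs scatter on the same scale). The denoiser recovers the true
noise level to 0.3 % and boosts tSNR ≈ 49× on this motion-free phantom.

A full run (denoise → motion → one-shot warp → clean → align → connectome,
with QC and provenance) goes through the pipeline runner or the CLI:

```bash
laminapipe make-phantom ph/ --nx 64 --ny 40 --nz 2 --n-frames 310 --seed 42
laminapipe run config.yaml      # see PipelineConfig for the YAML keys
```

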