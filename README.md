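# ctnlm — locally adaptive 3D non-local-means denoising for micro-CT

Micro-CT volumes of soft tissue — in vivo scans especially — carry enough
noise to blur the anatomical boundaries that make the modality useful,
and classical non-local-means (NLM) denoising asks the user for three
numbers nobody has for a fresh scan: the noise standard deviation, a
search-window size and a patch size. `ctnlm` implements a parameter-free
variant for 3D grayscale volumes aimed at image-analysis pipelines in
small-animal imaging: the noise level is estimated per sub-block of the
volume, the smoothing bandwidth is derived from it automatically, window
sizes are fixed, and the dominant cost of NLM — the patch distance
computation — is accelerated with a sliding-window update.

## The method

Each voxel *i* is replaced by a weighted average of the voxels *j* in an
11³ search window, with weights driven by the sum of squared differences
(SSD) between the 3³ intensity patches around *i* and *j*:

    w(i, j) = exp( −( SSD(i, j) / h_i² )^p ),       NL(u)(i) = Σ_j w(i,j) u(j) / Σ_j w(i,j)

* **Local bandwidth.** The volume is partitioned into blocks (default
  16³). In each block the noise standard deviation is estimated from
  pseudo-residuals ε_i = √(6/7)·(u_i − mean of the 6 face neighbours),
  σ̂ = √(mean ε²), and the bandwidth follows the automatic rule
  h = max(h_min, √(2 β σ̂² |N|)) with |N| the patch voxel count and β a
  dimensionless scale (default 1). Voxels in noisy blocks are smoothed
  harder than voxels in quiet ones — no global noise level is assumed.
* **Gray-scale range.** The floor h_min scales with the number of
  representable intensity levels (8-bit vs 16-bit), so the same scene
  coded at different bit depths denoises identically after the stretch.
* **Kernel shape.** The exponent *p* (default 1, the Gaussian kernel for
  additive Gaussian white noise) can be adjusted for data whose noise is
  not AGWN, e.g. Poisson–Gaussian or Rician.
* **Sliding SSD.** For a fixed search offset, the patch cubes of
  adjacent centers along a scan line share all but two end slices, so
  the SSD is updated incrementally: M³ + (N−1)·2·M² difference
  operations per row of N centers instead of N·M³ (M = patch edge).
  The accelerated path is tested element-for-element against a
  brute-force oracle.

Volumes move through one container (`Volume`: data, voxel spacing in µm,
gray-level count) with readers/writers for single-frame DICOM series,
classic netCDF and multi-page grayscale TIFF. A synthetic phantom module
(spheres, boxes, lamellar stripes; Gaussian / Poisson–Gaussian / Rician
noise) and a line-profile evaluation module make the whole pipeline
testable without any scan data.

## Worked example

```
ctnlm pipeline --out report.tsv --size 32,32,32 --sigma 10 --seed 1
cat report.tsv
```

generates the standard two-intensity phantom (background 50, sphere 150,
so σ = 10 is 10 % of the dynamic range), corrupts it, denoises with
defaults, and prints:

```
metric  value
psnr_noisy_db       28.1337
psnr_denoised_db    38.4795
variability_noisy   3.79447
variability_denoised 0.0687551
```

Read: denoising gained 10.3 dB PSNR against the known clean phantom, and
the spread of a grayscale line profile about its local structure (the
standard visual check for denoising, here quantified as the standard
deviation about a moving median) dropped from ≈3.8 to ≈0.07 intensity
units.

The same steps from Python:

```python
from ctnlm import standard_phantom, add_noise, NoiseModel, denoise, psnr

clean = standard_phantom((32, 32, 32))
noisy = add_noise(clean, NoiseModel(kind="gaussian", sigma=10.0, seed=1))
result = denoise(noisy)                  # no noise level supplied
print(psnr(clean, noisy), psnr(clean, result))
```

Other subcommands: `denoise` (file to file), `estimate-noise` (per-block
σ̂ table), `phantom`, `profile`, `metrics`, `opcount`. All accept a flat
`key = value` config file via `--config`; flags override.

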