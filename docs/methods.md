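# Methods

## Model and procedure

`ctnlm` denoises a 3D grayscale volume u with non-local means: every
voxel becomes a weighted average of the voxels in a cubic search window
around it, the weight of candidate j for center i being

    w(i, j) = exp( −( SSD(i, j) / h_i² )^p )

with SSD(i, j) the sum of squared intensity differences between the
patches around i and j. The underlying assumption is self-similarity:
small anatomical neighbourhoods recur across the volume, so averaging
over patch-similar voxels suppresses noise without averaging across
structure. The base noise model is additive Gaussian white noise; the
kernel-shape exponent p is the only concession to non-Gaussian noise
(see below).

The denoised value is accumulated in difference form,
`u(i) + Σ w·(u(j) − u(i)) / Σ w`, with the self-weight set to the
maximum of the other candidates' weights (weight 1 would let the noisy
center dominate its own average). Two consequences are guaranteed and
tested: a constant volume is a fixed point *exactly* (every difference
is exactly zero in floating point), and the output is a convex
combination of input intensities. The result is additionally clipped to
the input min/max so that the convexity bound survives last-ulp rounding
of the accumulation; the clip is a no-op to numerical precision.

## Noise estimation and automatic bandwidth

The noise standard deviation is estimated from pseudo-residuals

    ε_i = sqrt(6/7) · ( u_i − mean of the 6 face neighbours of i )

mirror-padded at boundaries; under i.i.d. noise on a locally constant
field, Var(ε) is unbiased for the noise variance. The volume is
partitioned into blocks of `block_size` voxels per edge (default 16,
ceil partition with truncated edge blocks) and each block gets
σ̂ = sqrt(mean ε²) over its voxels. The per-voxel bandwidth is then

    h = max( h_min · G/256 ,  sqrt( 2 · β · σ̂² · |N| ) )

where |N| is the patch voxel count, β a dimensionless scale (default 1,
the standard automatic choice), G the volume's gray-level count, and the
σ̂ lookup is nearest-block (piecewise constant, no interpolation) — one
estimate per sub-block rather than one per volume is the method's point,
and the piecewise-constant lookup is the simplest contract that
delivers it.

**Gray-scale-range handling.** σ̂ carries intensity units, so
h = √(2βσ̂²|N|) is automatically equivariant under intensity stretch:
SSD scales with the square of the stretch and h² does too, leaving the
weights unchanged. The only absolute constant is the floor h_min, which
therefore scales linearly with the gray-level count (default 256·10⁻⁶
at 256 levels, i.e. 10⁻⁶·G). Scaling β with bit depth as well would
break the equivariance (h² would gain an extra factor of G while SSD
gains G²), so β stays dimensionless. The package's invariance test
pins this behaviour: a scene coded 16-bit with a 256× stretch denoises
to exactly the stretched 8-bit result.

**Degenerate inputs.** σ̂ = 0 blocks floor h at h_min, where NLM
averages only exactly identical patches. Axes of length 1 (single-slice
volumes) clamp the patch, search and residual extents on that axis: the
residual then uses the 2k face neighbours that exist with normalization
sqrt(k/(k+1)). The public 3D residual operation rejects such volumes;
the clamping applies only inside the denoiser's internal estimate.

## The sliding (moving-average) SSD path

For a fixed search offset d, define D(x) = (u(x) − u(x+d))². The SSD at
center i is the box sum of D over the patch cube at i. Patch cubes of
adjacent centers along x share all but two end slices, so per offset the
implementation pre-aggregates D over the patch's y/z extents
(cumulative-sum box sums) into per-x-slice cross sections and then
slides along x: full sum of M slices at each row start, then
add-arriving / subtract-departing per step. Cost per row of N centers:
M³ + (N−1)·2·M² difference operations versus N·M³ for naive
resummation (M = patch edge length — the count M³ + (N−1)·2·M² is
dimensionally consistent only with M read as an edge length, and the
implementation and its counters use that reading throughout). An
`OpCounter` tallies the element operations the path actually performs,
and tests check the measured counts against the closed-form model —
the counter measures executed slice work, it does not re-evaluate the
formula.

Re-initializing the running sum at every row start bounds floating-point
drift of the incremental subtraction; the path is exact on
integer-valued volumes (exhaustively tested against the brute-force
oracle on a 7³ fixture over all centers and offsets) and agrees to
1e-6 relative on float volumes.

Numerical tie-breaks: squared differences make SSD ≥ 0 mathematically;
after cancellation the map is floored at 0 to keep the weight ≤ 1
contract exact. The zero offset yields exactly 0 (the difference array
is identically zero before squaring).

## Defaults and units

| parameter       | default | units | why |
|-----------------|---------|-------|-----|
| `patch_radius`  | 1 (3³ patch) | voxels | standard 3D patch; larger patches blur fine trabecular/fissure detail at micro-CT scale |
| `search_radius` | 5 (11³ window) | voxels | fixed window policy; larger windows add candidates whose similarity statistics degrade, with little quality gain |
| `block_size`    | 16 | voxels | small enough to track slowly varying noise fields, large enough (4096 voxels) for a stable σ̂; a 64³ volume gets 4³ blocks |
| `beta`          | 1.0 | — | the classical automatic bandwidth h² = 2σ̂²·N |
| `shape_p`       | 1.0 | — | Gaussian kernel, the AGWN base model |
| `h_min`         | 256·10⁻⁶ at 256 levels | intensity | keeps weights defined in noise-free blocks; scales with gray-level count |
| boundary        | mirror | — | preserves local intensity statistics better than zero padding; keeps the denoiser flip-equivariant |

The denoiser is fully deterministic; all randomness lives in the phantom
module, where one integer seed feeds named generator streams so geometry
and noise draws reproduce independently of call order.

## What the phantoms emulate — and what they do not

The phantom generator produces piecewise-constant anatomy-like scenes:
spheres and boxes for compact organs, lamellar stripes for the layered
fissure-and-lobe geometry of cerebellar tissue, at 8- or 16-bit
intensity ranges, corrupted with Gaussian, Poisson–Gaussian or Rician
noise applied in image space (the post-acquisition standpoint — the
package does not simulate CT physics: no beam hardening, ring artifacts
or reconstruction streaks). Intensities are clamped to [0, G−1] only on
export so noise statistics stay exact for estimator tests. The standard
benchmark is the 32³ two-intensity phantom (background 50, sphere 150)
with noise at 5–10 % of the dynamic range; the spatially varying fixture
splits the volume into σ = 2 and σ = 10 halves.

Passing tests on these fixtures show that the estimator, bandwidth rule,
accelerated SSD and averaging behave as designed, and that local
adaptation beats a single global bandwidth when the noise field varies.
They do not show performance on real scans: real micro-CT noise is
spatially correlated by reconstruction, intensity-dependent, and real
anatomy is not piecewise constant, so measured PSNR gains on phantoms do
not transfer as absolute numbers.

## Evaluation choices

Line profiles are sampled trilinearly (the 3D analogue of the bilinear
line profile of common 2D viewers) at equally spaced points, positions
in voxel units. "Intensity spread" of a profile is quantified as the
standard deviation about a moving median (default window 9 samples):
the median tracks plateaus, ramps and edges, so structure does not count
as noise. The window is overridable; very narrow structure (under half
a window) would be absorbed into the trend and not counted. PSNR uses
peak = G−1 by default and is cross-checked in the test suite against an
independent implementation.

## Known limitations

* The pseudo-residual estimator is not robust to structural edges: a
  block containing a strong boundary reports σ̂ above the true noise
  level (mean of ε², not a robust statistic — the blockwise estimator's
  contract is stated on locally constant regions). In consequence a
  noiseless structured volume is *not* an exact fixed point: edge blocks
  get h > h_min and nearby voxels mix slightly (PSNR of the denoised
  noiseless benchmark phantom ≈ 41–48 dB rather than ∞). On noisy
  inputs the same leakage mildly oversmooths edge-dense blocks.
* Blocks are axis-aligned with a ceil partition; flip-equivariance of
  the denoiser is exact only when block boundaries map onto block
  boundaries (volume edge a multiple of block size), as in the tests.
* netCDF support is classic (netCDF-3) format; HDF5-backed netCDF-4
  files are out of scope, as are compressed DICOM transfer syntaxes
  beyond what pydicom decodes natively and RGB TIFF.
* CPU-scale only: the implementation is vectorized per search offset
  and is comfortable at desk scale (a 64³ volume with the default 11³
  window denoises in tens of seconds on one core; timings in the test
  suite use 16³–64³ fixtures). The algorithm parallelizes trivially
  over offsets and slabs, but no GPU or multi-process path is provided.
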