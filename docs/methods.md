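# Methods

## The measurement model

A cleared-tissue immunostaining experiment produces, per sample, a Z-stack
of fluorescence intensities `I(x, y, z)` with physical plane spacing (µm).
The pipeline assumes:

- one channel per file; channels ("fluorophore groups") are analyzed and
  compared separately, never against each other;
- depth is the stack's z axis; anisotropy is handled only through the plane
  spacing, no resampling is performed;
- the stack is imaged from its cut surface downward, so staining quality is
  a (noisy, mostly decreasing) function of plane index.

### Segmentation

The internal segmentation path is: (1) whole-stack percentile normalization
— the 0.1th/99.9th percentiles map to 0/1, computed over the *entire* stack
so depth attenuation is preserved (per-plane normalization would erase the
very signal being measured; the percentile window resists hot pixels);
(2) per-plane rolling-ball background subtraction, implemented as grayscale
opening with a flat disk structuring element (erosion then dilation; the
classic intensity-paraboloid rolling ball is available via
`method="paraboloid"`), clipped at zero; (3) thresholding with strict
inequality (`voxel > t`), either a fixed value (default 0.2 on the
normalized scale) or Otsu's criterion on the whole-stack 256-bin histogram.
Externally produced masks or probability maps (multipage TIFF, e.g. from a
trained pixel classifier) can be imported instead; probabilities are
binarized at 0.5 with the same strict inequality.

Background subtraction runs in 2D per plane: the background varies slowly
within a plane but steeply across depth, and a 3D element would smear the
attenuation gradient. The default ball radius is 5 px, a few times the
default feature radius, so features are removed from the background
estimate while illumination-scale structure survives.

### Depth profile and half-max depth

Per plane: stained-voxel fraction, mean in-mask intensity (signal), mean
out-of-mask intensity (noise), and their ratio. Planes with an empty mask
have *undefined* (NaN) signal and SNR — never zero, since treating them as
zero would manufacture spurious half-max crossings.

The start plane (tissue surface) is the first plane whose smoothed metric
(centered moving average, window 3, edges truncated) reaches 10 % of the
smoothed global maximum; mounting-medium planes above the tissue therefore
do not inflate depth. The half-max depth is found on the raw metric series
from the start plane on, NaN planes skipped: locate the maximum, then the
first pair of consecutive defined planes at or after it where the series
crosses half the maximum from above, and interpolate linearly. First
crossing (rather than last) is the conservative, deterministic choice for
noisy profiles. Depth is reported in µm relative to the start plane. A
profile that never falls below half its maximum yields NaN with the maximum
recorded.

Two metrics are supported and reported side by side: mean in-mask intensity
(default — appropriate when the antigen distribution varies with depth) and
stained-area fraction (appropriate for antigens with constant distribution,
e.g. cortical neuronal nuclei). `figure_of_merit` encodes this choice.

### Normalized staining-quality score and comparison

Within a fluorophore group, every per-plane value of every sample is divided
by the single group-wide maximum, so the best plane of the best condition
scores 1.0 and all heatmap cells are comparable. Samples are blinded by a
seeded random permutation of zero-padded codes before analysis and unblinded
afterwards. Per condition, replicate half-max depths give mean ± SEM
(sample SD / √n); each condition is tested against the group's baseline with
a two-tailed two-sample t-test — Student's pooled-variance by default,
Welch by flag — labeled `*`/`**`/`ns` at 0.05/0.01. No multiplicity
correction is applied by default (each condition is reported against
baseline on its own terms); a Bonferroni flag exists and is recorded when
used.

## The synthetic generator

The generator emulates what the pipeline needs to be tested against, not
microscope physics. A scene is a binary feature mask: spheres (nucleus-like,
default radius 6 µm — the scale of a neuronal nucleus), straight tubes
(vessel-like) or meandering filaments (process-like), placed at random with
overlap allowed until a target voxel density (default 5 %, a typical
stained-soma fraction in cortex) is reached; features clip at the volume
faces the way real features are cut at a section surface, which keeps the
first plane populated so the detected start plane coincides with the stack
origin. Density is best-effort within ±20 % relative; exact packing would
add complexity without improving any metric test.

Staining intensity is `amplitude · a(z) · truth + background + noise`, with
Gaussian read noise, optional signal-dependent (Poisson-like) noise, and an
optional Gaussian blur applied after the noise — a deliberately non-physical
ordering kept for simplicity; the blur is a cheap PSF stand-in, not an
optics model. Defaults: amplitude 100, background 5, read-noise SD 2
(signal-to-background ≈ 20, a comfortable confocal regime), no blur.

Attenuation `a(z)` comes in three kinds:

- **sigmoid** `1/(1 + exp((z − d_half)/w))`: a penetration front at
  `d_half` of width `w` (default 10 µm, i.e. a sharp front ≈ two plane
  spacings). Sharpness matters for interpretation: the half-max estimator
  measures where the *observed profile* halves, which coincides with
  `d_half` only when the front is sharp relative to it — with a wide front
  the surface plane is itself already attenuated and the profile's
  half-depth sits deeper than `d_half`. The default keeps the two notions
  aligned across the 50–400 µm range used in validation.
- **exponential** `2^(−z/d_half)`: halving per `d_half`, the
  constant-relative-loss limit.
- **pde**: bound antibody from a 1D reaction–diffusion model with
  irreversible binding and depletion, `∂c/∂t = D ∂²c/∂z² − k c (B − b)`,
  `∂b/∂t = k c (B − b)`, fixed bath at z = 0, zero flux at depth, explicit
  finite differences on a 100-node grid (dz default 5 µm). The diffusive
  stability bound `dt ≤ dz²/2D` is validated, never silently corrected, and
  a negative concentration (reaction overshoot) raises rather than clamps.
  Defaults (D = 20 µm²/s, k = 0.2, B/c₀ = 50, T = 2000 s) sit in the
  strong-binding regime, where mass balance predicts a sharp front at
  `z_f ≈ √(2 D c₀ t / B)` and hence √t scaling — quadrupling the incubation
  doubles the front depth, the signature of depletion-limited penetration.
  Discrete flux accounting conserves mass to machine precision.

Penetration is one-sided by default; `two_sided=True` takes the larger of
the two one-sided factors mirrored about the deepest requested plane,
approximating a free-floating section stained from both faces.

Condition sets derive all per-replicate seeds deterministically from one
master seed (`numpy` `SeedSequence` spawn keys), so regeneration is bitwise
identical. Replicates default to 3. Conditions can share scene geometry per
replicate (only attenuation and noise differ) or use independent geometry.

### What the generator does not emulate

No optics (real PSF, light-sheet stripes, refractive-index aberrations,
spherical aberration growth with depth), no photobleaching, no spectral
crosstalk, no spatially varying background, no antigen-density gradients.
Passing the validation suite therefore shows the *measurement chain* is
correct and well calibrated on stacks whose degradation is purely
depth-dependent attenuation plus stationary noise; it does not certify
performance on artifact-laden real acquisitions.

## Numerical and design choices

- Strict threshold inequality and first-crossing half-max: deterministic
  boundary behavior.
- Otsu on the whole-stack histogram; for stacks with a wide empty
  inter-mode gap the criterion is flat across the gap and the lowest
  maximizing bin is returned.
- The rolling-ball oracle equivalence (opening = exhaustive min-then-max
  over the disk) holds with edge-replicating boundaries because the disk is
  closed under component-wise offset shrinking.
- t statistic sign convention: positive when the condition mean exceeds
  baseline. Zero variance in both groups with equal means gives p = 1 by
  convention; with unequal means it is an error rather than p = 0.
- Stacks interchange as float32 in both TIFF and HDF5 so the two paths are
  bitwise identical.
- Validation problem sizes: stacks are 24–32 px laterally × 100 planes
  (full 500 µm depth at 5 µm spacing). Depth resolution — the quantity
  under test — is untouched by lateral size; 100-repetition calibration
  runs then complete in a couple of minutes.

## Known limitations

- The half-max depth conflates penetration speed and antibody depletion; a
  protocol that destroys antigenicity can paradoxically *improve* apparent
  penetration by letting antibody travel further before binding. The
  statistic ranks staining quality, it does not identify mechanism.
- Attenuation models are stand-ins: no quantitative penetration model has
  been fitted to real cleared-tissue data here, and the pde defaults are
  order-of-magnitude choices (IgG-scale diffusivity, strong binding).
- Whether real sections admit antibody from one or both faces is
  acquisition-dependent; the default is one-sided and the two-sided option
  is an approximation (max of faces, not a solved two-bath PDE).
- The t-test at N = 3 leans on approximate normality of recovered depths;
  the calibration suite checks its level and power only under the
  generator's conditions.
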