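# Methods

`pavol` implements the full loop needed to train and validate a volumetric
deep-learning enhancer for linear-array photoacoustic tomography (PAT):
synthetic vascular phantoms, an analytic acoustic forward model of a
mechanically scanned linear array, 2D-stack delay-and-sum (DAS)
reconstruction with image-domain noise, cube tiling with exponential
seam-free fusion, a NumPy/Numba 3D fully-dense U-net with its training
recipe, and the quantification metrics used for validation. This note
records the models, their assumptions, the parameters that matter, and the
design choices made where the design was genuinely open.

## Imaging geometry

Axes are `(axial, lateral, elevation)`: axial points away from the
transducer face, lateral runs along the array aperture, elevation is the
mechanical scan direction. Volumes live on a metric `VoxelGrid` with a
standoff (default 30 mm) between the transducer face and the first axial
voxel, matching a water-coupled scanning head. The full-scale training
geometry is a 30 × 86 × 50 mm³ volume at 0.1 mm voxels scanned at 0.2 mm
steps by a 128-element, 2.25 MHz array; desk-scale presets shrink every
dimension so the same code paths run in minutes on one CPU.

## Vascular phantoms

`generate_vasculature` grows seeded branching random-walk trees: each branch
steps along a direction perturbed by Gaussian tortuosity (0.35 rad/step),
tapers geometrically (0.97/step), and spawns a narrower child (ratio 0.7)
with probability 0.12 per step, to a maximum depth of 4 generations.
Segments are rasterized as capsules (cylinder + hemispherical caps, voxel
center-inside test), so joints stay smooth and the rasterized cross-section
matches the analytic disk area to within a voxel-quantization error that
falls below 5 % for diameters of five voxels and more. Tube diameters are
confined to a configured range, 0.1–4 mm at full scale — the calibre range a
2.25 MHz array resolves. The number of trees and the per-tree intensity
(uniform in [0.6, 1]) are free parameters: neither a vessel count nor an
intensity distribution is constrained by the physical system, so both are
exposed with documented defaults. What the generator emulates is the
geometry of mid-scale vasculature (branching, tapering, tortuosity); it
does not attempt anatomically realistic arterial trees, skin layers, or
fluence-dependent intensity gradients, so passing tests show the
enhancement loop works on vessel-like geometry, not that it generalizes to
every feature of in vivo data.

`generate_line_phantom` rasterizes parallel cylinders at a fixed depth — the
printed-line resolution target (0.5/1/2/3 mm lines, 50 mm depth in the
reference layout) used for FWHM-based resolution measurements.

## Acoustic forward model

The published pipeline used a full-wave solver; this package substitutes an
analytic time-of-flight model, a deliberate scope decision: the
degradations the network learns (elevation blur, limited view,
band-limiting, 1/r decay) are geometric, and an analytic model reproduces
them at a cost that allows hundreds of training volumes on one CPU. Each
A-line is

    a_e(t) = sum_v  A_v / d_ev * D_lat(theta_ev) * D_el(phi_v) * h(t - d_ev / c)

over absorbing voxels `v` inside a moving sub-region around the imaging
plane (15 mm along elevation at full scale — the sub-region travels with
the array). `d_ev` is the 3D voxel-element distance, `D_lat` and `D_el` are
cosine-squared directivities truncated at acceptance angles, and `h` is the
element impulse response. Elevation directivity is measured from a virtual
focal line at `elevation_focus_mm` (default 30 mm); the elevation
acceptance angle may be set separately from the in-plane one
(`elevation_acceptance_deg`), since in a physical probe the former is fixed
by element height and lens, the latter by element width. The element face
is integrated across its height with 3-point Simpson quadrature including
the lens delay. Not modelled: attenuation, heterogeneity, reflections,
nonlinearity, fluence (uniform illumination of hemoglobin-like absorbers is
assumed).

The impulse response is a Gaussian-modulated cosine at the center frequency
whose envelope is set so the −6 dB spectral width equals
`fractional_bandwidth × center_freq` (default 0.6 × 2.25 MHz); its residual
DC component is projected out so the wavelet is exactly zero-mean on the
sample grid, and its peak magnitude sits at t = 0, which keeps A-line peaks
on the geometric time of flight. Defaults not fixed by the physical
system: sound speed 1500 m/s, sampling 20 MHz, pitch 0.672 mm (86 mm
aperture / 128 elements), acceptance 15°, fractional bandwidth 0.6 — all
configurable.

## Reconstruction and degradation

`das_frame` back-projects one sinogram onto the (axial, lateral) plane:
each pixel sums linearly-interpolated samples at the pixel-element time of
flight over elements within the acceptance angle. Envelope detection
(analytic-signal magnitude along each axial line) is on by default so
volumes are non-negative before [0, 1] normalization — depth-encoded
display and network targets both need non-negative intensities; a flag
disables it since it is not documented whether the original pipeline
enveloped before stacking. Frames are stacked along elevation and linearly
resampled from the scan step onto the grid spacing. Because each frame
ignores out-of-plane arrivals, lateral-running structures blur along
elevation — the anisotropy the enhancer corrects.

Noise is injected in the image domain after normalization, matching where
the original pipeline applied recorded system noise. Recorded noise is not
available here, so the model is parametric and seeded: i.i.d. Gaussian
thermal noise (sigma 0.05 by default) plus an EMI surrogate — per-frame
laterally-oscillating bands (0.8 cycles/mm) with a Gaussian axial envelope,
arriving at a Poisson rate of 0.3 stripes/frame with amplitude 0.3. The
stripe shape mimics the appearance of interference bursts in linear-array
PAT frames; it is a surrogate, not recorded interference. Values are
clipped to [0, 1].

## Tiling and fusion

Volumes are split into overlapping cubes (128 per side at full scale,
overlap A = 32; desk preset 32/8) with a stride of `cube − overlap` and a
final tile flush against each boundary. After per-cube inference, overlaps
are blended with the exponential map

    M(x) = (e^{x/A} − 1) / (e − 1),  1 ≤ x ≤ A,

applied to the incoming cube while the incumbent gets `1 − M(x)`; the pair
is a partition of unity, so constants survive fusion exactly and seams
vanish. The complementary weight is not specified in the original
formulation; `1 − M` is the unique choice that preserves constants. Weights
are applied along every axis where neighbours overlap (including axial —
the partition-of-unity argument is axis-agnostic), and corner regions use
separable per-axis weights renormalized to sum to one. Flush boundary
tiles can overlap their neighbour by more than A; both tiles then carry
full weight in the excess region and normalization halves them, which is
exact for unprocessed tiles and can retain a mild seam for processed ones —
a known limitation.

## The 3D fully-dense U-net

Encoder-decoder with DenseNet-style blocks: inner layer k of a block
consumes `in + (k−1)·growth` channels and emits `growth` new maps
(Conv 3×3×3 → BatchNorm → ELU); the block output concatenates everything.
Levels connect through 2×2×2 stride-2 convolutions (learned downsampling,
no max pooling) and 2×2×2 transposed convolutions with encoder→decoder skip
concatenation; each decoder block is followed by a 1×1×1 compression back
to the skip width. Decoding ends with a 3×3×3 refinement convolution and a
1×1×1 projection. All activations are ELU; batch normalization uses
momentum 0.99 and epsilon 0.001. Dense connectivity is within-block only.

The published-scale architecture is pinned by a single figure: 6,052,025
trainable parameters. Depth, widths and growth rates are not published, so
the reference config was chosen by searching a closed-form parameter count
over depth ∈ {4, 5}, initial width, per-level growth (doubling, with the
bottom level free) and refinement width until the total matched exactly:
5 levels, 22 initial channels, growths (7, 14, 28, 56, 100), 2 layers per
dense block, 40 refinement channels. The counting convention — convolutions
followed by batch norm carry no bias; batch norm contributes scale and
shift; the final projection has a bias — is part of the architecture
definition. `DESK_CONFIG` (3 levels, 6 initial channels, growths
(5, 10, 20), 1 layer/block, ~57 k parameters) is the slim desk-scale
variant; three levels give the receptive field needed to fill band-limited
vessel interiors while keeping full-resolution layers thin.

The network, its layers (3D convolution, transposed convolution, batch
normalization, ELU), backpropagation and the Adam optimizer are implemented
directly in NumPy with Numba JIT convolution kernels (channels-first
layout, cache-resident spatial planes, SIMD inner rows). Correctness is
pinned by finite-difference gradient checks in the test suite's spirit
(symbolic parameter-count oracle, identity-task convergence) rather than by
comparison to a framework. Weight initialization is seeded
variance-scaling (He); inference uses running batch-norm moments and is
bit-deterministic. Mixed precision appears in the config as a flag for
interface completeness; correctness paths run in single precision
(float32) with float64 loss accumulation.

Training minimizes per-batch MSE with Adam (full-scale defaults: lr 1e-4,
batch 8, up to 300 epochs, early-stopping patience 10, 8:2 train/val
split); the best-validation weights are restored. `stream_batches` loads
paired cubes (`<id>_input.npy` / `<id>_target.npy`) one batch at a time
with a seeded shuffle, so memory is bounded by two batches regardless of
dataset size. Re-iterating a stream reproduces the same order — epochs are
deliberately identically shuffled under one seed, trading shuffle diversity
for exact reproducibility.

## Desk-scale study conditions

The desk preset is the scaled-down twin used by the tests and the
end-to-end demo: 32 × 64 × 64 voxel volumes at 0.2 mm (6.4 × 12.8 × 12.8
mm³), a 32-element array (pitch 0.4 mm), 64 scan positions at 0.2 mm,
6.4 mm sub-region, 3 trees of 0.2–2.5 mm vessels per volume, the noise
defaults above, 32³ cubes with overlap 8, and the slim network. 48 volumes
yield 432 paired cubes, split 8:2. The training recipe scales the
full-size defaults to the short run: learning rate 3e-3 (a slim network on
a small dataset tolerates and needs a higher rate than the full-scale
1e-4), batch 8, 11 epochs with early-stopping patience 6, and a fresh
seeded batch shuffle every epoch — epoch-wise reshuffling is standard SGD
practice and measurably improves generalization here over replaying one
fixed order. Held-out volumes (fresh seeds) are enhanced cube-wise and
scored by volume SSIM/PSNR against the clean phantom. These sizes were
chosen so the whole loop — data synthesis, training, evaluation — completes
in minutes on a single CPU while preserving every full-scale mechanism;
they are not expected to reach published-scale image quality, which
required three orders of magnitude more training data. The dominant
residual error of the desk-trained model is vessel-interior restoration:
band-limited delay-and-sum renders large vessels as double edges, and an
MSE-trained network under uncertainty predicts conditional means, so
recovered vessel cores stay dimmer than the ground truth.

The line-phantom resolution study reconstructs the four-line target at
50 mm depth in both orientations on a 24 × 36 × 36 mm³ grid at 0.25 mm,
with a 64-element array and an elevation acceptance of 6° (the in-plane
acceptance stays 15°). The tighter elevation cone keeps the four blurred
lines separable at 8 mm spacing so per-line FWHM is well defined; the
lateral/elevation resolution asymmetry it demonstrates holds for any
elevation acceptance.

## Numerical choices and degenerate inputs

- Max-normalization uses |data|; all-zero volumes pass through unchanged.
- `fwhm` interpolates half-maximum crossings linearly and rejects profiles
  that never cross on one side; argmax ties in depth maps resolve to the
  shallowest index.
- Binarization defaults to a fixed fraction (0.1) of the maximum, with Otsu
  as the alternative; the leakage index and vessel density inherit this.
- Sub-sample delays are linearly interpolated both when binning A-line
  contributions and when reading samples in DAS.
- Fusion accumulates in float64 and divides by the accumulated weight, so
  identity round trips hold to ~1e-6 in float32 volumes.
- An empty moving sub-region yields an all-zero sinogram (not an error);
  pixels whose time of flight exceeds the record contribute zero and are
  counted in a logged warning.
- Every stochastic stage draws its seed from
  `SeedSequence((global_seed, stage_tag, index))`, so any artifact is
  reproducible from one integer; derived seeds stay below 2^31.

## Known limitations

- The analytic forward model omits diffraction: resolution scales are set
  by acceptance geometry and bandwidth, not by wave physics, so absolute
  FWHM values are indicative rather than calibrated.
- Network memory scales with `channels × cube volume`; the reference config
  is practical for parameter accounting and cube-wise inference at desk
  scale, but training it at full scale is outside a single-CPU budget.
- The EMI surrogate is parametric; a model trained on it will not remove
  interference whose structure differs substantially.
- Fusion of *processed* flush tiles with overlap > A can retain a mild
  seam (see above).
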