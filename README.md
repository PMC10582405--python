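# pavol — volumetric photoacoustic imaging enhancement for linear arrays

Linear transducer arrays are the workhorse of clinical photoacoustic
tomography (PAT), but they are 2D devices: when swept mechanically to build
a 3D image (one delay-and-sum frame per scan position, stacked along the
sweep), the result suffers poor elevation resolution, limited-view dropout
of steeply oriented vessels, and electromagnetic-interference (EMI) noise.
`pavol` implements the full simulation-to-enhancement loop for this
problem: it synthesizes vascular phantoms, simulates the scanned
acquisition, reconstructs degraded 2D-stack volumes, trains a **3D
fully-dense U-net** to map them back to the clean absorption map, and
quantifies the result with the field's standard measures.

The package is aimed at researchers in photoacoustic and ultrasound image
enhancement who want a self-contained, CPU-runnable testbed of this
pipeline — every stage from phantom to metric is importable Python, seeded
and reproducible.

## The model

The enhancer f_θ maps a normalized degraded volume to the clean absorption
map by minimizing the mean squared intensity error over paired cubes,

    L(θ) = E ‖ f_θ(x) − y ‖²,   x = degraded 2D-stack cube, y = ground truth,

with Adam, early stopping on a held-out split, and streaming batch loading.
The architecture is a U-net whose blocks use DenseNet-style connectivity —
inner layer k of a block consumes `in + (k−1)·g` channels and emits `g`
new ones — with 2×2×2 stride-2 convolutions instead of max pooling,
ELU activations, batch normalization (momentum 0.99, ε = 0.001), and a
final 3×3×3 refinement convolution before the 1×1×1 projection. The
reference configuration (5 levels, growths 7–100) carries exactly
**6,052,025 trainable parameters**. The network and its backpropagation are
implemented in NumPy with Numba JIT convolution kernels — no deep-learning
framework is required.

Volumes are enhanced cube-by-cube (128³ at full scale) and re-fused with an
exponential weighting map across each overlap of width A,

    M(x) = (e^{x/A} − 1)/(e − 1),   1 ≤ x ≤ A,

applied as M / (1 − M) to the incoming/incumbent cube — a partition of
unity, so fusion is seam-free and exact on unprocessed tiles.

Validation metrics: volume SSIM/PSNR/MSE against ground truth, SNR in dB,
FWHM-based resolution measurement on printed-line phantoms, depth-encoded
maximum-amplitude projections, and the vascular indices (leakage index =
ratio of binarized voxel counts input/output; vessel density = vessel
fraction in an ROI) used in clinical case analysis.

## Worked example

`examples/02_simulate_and_reconstruct.py` runs one desk-scale volume
through phantom → scan → reconstruction → noise:

```
$ python examples/02_simulate_and_reconstruct.py
volume shape (axial, lateral, elevation): (32, 64, 64)
scan: 64 positions at 0.2 mm
SSIM(noisy 2D-stack, ground truth) = 0.040
Values well below 1 reflect elevation blur, limited view and noise;
the enhancer's job is to push this toward 1.
```

The SSIM near 0.04 is the starting point; the end-to-end demo
(`pavol demo --out-dir out/` or `examples/05_train_and_enhance.py`) trains
the slim desk network on 432 simulated cube pairs and evaluates held-out
volumes, lifting mean SSIM from 0.05 to 0.28 and mean PSNR from 14.9 to
16.9 dB in roughly a quarter-hour on one CPU. The other examples exercise phantom generation, cube fusion
(`max |fused − source| = 0`), and each metric on inputs with known
expected values.

A thin CLI mirrors the library: `pavol phantom | simulate | recon | tile |
train | enhance | eval | quant | demo` (see `pavol --help`).

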