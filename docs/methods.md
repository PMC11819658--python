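# Methods

This note records the model, the synthetic data conditions, the numerical
conventions, and the design choices that were genuinely open, in enough
detail to re-derive any number the package produces.

## Detection model

Every pixel spectrum x ∈ [0,1]⁹⁶ is scored independently. Two
discriminators — one per tissue channel — are the anomaly scorers; each is
the surviving half of a GAN trained only on clean spectra of its channel.

**Tissue channels.** A two-component 1-D Gaussian mixture is fitted by EM
(scikit-learn `GaussianMixture`, seeded) to the per-spectrum mean
reflectance of clean fillet pixels. The scalar mean is used because lean
muscle is consistently darker than fat/connective tissue across
1000–1700 nm; a single-band feature is available as an option. Components
are ordered by mean, so channel 0 is muscle. Cluster assignment is the
posterior argmax with exact ties going to component 0.

**Discriminator.** Encoder: five 1-D convolution blocks, kernel 9,
stride 2, padding 4, ReLU, channels 1→2→4→8→16→32, spectral length
96→48→24→12→6→3; head: flatten (96 values) → affine → sigmoid, one
realness probability. Decoder (training only): five transposed
convolutions mirroring the encoder, each preceded by concatenation with
the matching encoder activation (U-Net skips), ending in a per-band logit.
The inference half (encoder + head) has 6 297 parameters and 26 880
multiply-accumulates per spectrum. The deployed model this emulates prints
≈6 359 parameters and ≈36 000 MACs without publishing kernel sizes or
stride placement, so exact equality is not attainable; the counts here are
reported, never asserted against those figures. The storage criterion
(24.8 KB fp32 / 12.4 KB fp16) is computed from the printed 6 359 count.

**Generator.** Latent z ∈ ℝ¹⁶ → affine to 8×12 → ReLU → three transposed
convolutions (8→4→2→1 channels, each doubling length to 96) → sigmoid, so
generated spectra live in (0,1) like reflectance.

**Training.** Non-saturating binary cross-entropy for both players, plus
the decoder's per-band realness BCE with weight 0.5 (real→1, fake→0 for D;
fake→1 for G). Optimizer: Adam, lr 2×10⁻⁴ for both players, β=(0.9,
0.999); batch 128; 30 epochs; all randomness from one integer seed
(sub-seeds are derived additively and kept below 2³¹). These are standard
small-GAN defaults; the source system publishes no hyperparameters.
Training is bitwise reproducible for a fixed (data, seed). Losses are
checked for finiteness every step; monotone loss decrease is *not* an
invariant of adversarial training and is not asserted. With epochs = 0 the
returned weights equal the seeded initialisation.

**Inference.** FM probability = 1 − realness. Scores are per-pixel, so
scoring a batch whole or partitioned is bitwise identical (tested).
Post-processing follows the order threshold (p ≥ t, default t = 0.5) →
reshape to H×W → 3×3 median filter (majority rule on binary maps, reflect
padding) → fusion. Both threshold and kernel are unpublished upstream;
0.5 and 3×3 are the package defaults and are exposed everywhere.

**Fusion = AND by default.** In the published accuracy table the fused
precision exceeds both channels while fused recall sits below both — the
signature of an intersection rule — but the rule itself is never named;
OR is available via configuration. AND also has a mechanistic
justification here: each channel flags the other tissue as anomalous, and
the intersection cancels exactly those single-channel false alarms.

## FP16 post-training quantization (emulated)

`cast_fp16` maps every weight to its IEEE-754 binary16 value under
round-to-nearest-even, with magnitudes above the largest finite half
saturating to ±65 504 (NumPy's native conversion overflows to infinity, so
the clip is applied first; saturation matches deployed-inference
behaviour). The cast is idempotent and every cast weight is exactly
representable (re-cast equality is tested against NumPy's conversion as
the independent oracle). The emulated fp16 forward pass rounds activations
to binary16 at each layer boundary and accumulates within a layer in
float32 — an emulation contract, not a claim about any specific
accelerator's fusion behaviour. Model sizes use 1024-byte KB (which
reproduces 24.8/12.4 KB from 6 359 parameters exactly), whereas batch-size
arithmetic uses decimal bytes; the two conventions are deliberately
different because only that combination reproduces both published
arithmetic ladders, and the discrepancy is documented rather than hidden.

Affine utilities: S = (rmax−rmin)/(2ⁿ−1), Z = round(−rmin/S) clipped to
the grid, q = clip(round(x/S)+Z). The |x−x̂| ≤ S/2 reconstruction bound
holds for ranges spanning zero (Z on-grid) — the relevant regime for
post-ReLU activations and symmetric weight ranges. Granularities:
per-tensor, per-channel, and contiguous groups along a chosen axis.

## Synthetic scenes

The generator emulates the study conditions of the undeposited inspection
dataset: fillets on a blue conveyor belt, imaged clean and contaminated
with FM squares of ~2×2 mm and ~5×5 mm at 0.4 mm cross-track resolution.
Specifics:

- **Endmembers.** Fixed smooth base shapes (muscle: mid reflectance with
  water-absorption dips near 1200/1450 nm; fat-rich non-muscle: brighter
  with C–H features; belt: dark and flat; four FM families standing in
  for the ~30 real FM types: polymer-, metal-, wood- and rubber-like)
  plus a small seeded low-frequency perturbation; all clipped to [0,1].
  A configurable minimum muscle/non-muscle mean-reflectance gap
  (default 0.15) guarantees the 1-D GMM feature separates the tissues.
- **Geometry.** The fillet is an axis-aligned ellipse inscribed after a
  3 px margin (only bounding dimensions of real fillets are published);
  non-muscle blobs are grown from seeds on the fillet rim, where fat and
  connective tissue sit anatomically, to a configurable area fraction
  (default 0.12). FM squares of side round-half-up(size_mm/res_mm) px
  (5 mm at 0.4 mm/px → 13 px) are placed uniformly, fully inside the
  ellipse, non-overlapping; failure to place raises.
- **Noise.** I.i.d. Gaussian per band, sd 0.01, clipped to [0,1] —
  calibration and denoising upstream of the real data imply modest
  residual noise.
- **Labels.** 0 belt, 1 muscle, 2 non-muscle, 3 FM. Belt is kept distinct
  so either belt convention can be evaluated.

What passing tests on these scenes shows: the pipeline's machinery —
clustering, adversarial training, scoring, fusion, quantization — behaves
correctly on data with the right structure (two separable tissue modes,
off-manifold contaminants, class imbalance). What it does not show:
radiometric realism (no scattering, illumination or moisture physics, no
SWIR→NIR transformation), real spectral variability within tissue classes,
or the published accuracy values themselves, which require the original
dataset.

## Benchmark conditions

The desk-scale benchmark (`run_benchmark`, also used by the acceptance
script) uses 80×80 px scenes at 0.4 mm/px: 4 clean scenes for training,
4 contaminated scenes (four FM patches each, 2 mm and 5 mm alternating)
for evaluation; up to 5 000 training spectra per channel; 30 epochs. These
sizes keep a full train-quantize-evaluate cycle around a minute on one CPU
while leaving thousands of FM pixels in the evaluation pool. Training
spectra are taken from fillet pixels of the clean scenes using the ground
truth footprint — standing in for the (undescribed) product segmentation
any deployment performs before scoring — and evaluation defaults to the
fillet-only mask for the same reason: the belt is deliberately absent from
training, so both channels flag it, and whether belt pixels enter the
published counts is unstated. Belt-inclusive evaluation (`eval_mask="all"`)
remains available. With seed 1 the benchmark yields fused precision 0.950,
recall 0.964, F1 0.957, BACC 0.979, ACC 0.992; per-channel FM-vs-clean
ROC AUC 1.0; and zero metric change under the fp16 cast (probability drift
stays ~10⁻⁴, far from the 0.5 threshold).

## Camera simulation

Presets: `swir_320x800` (320 spatial px of a 320×256-band detector,
1000–2500 nm, 45 lines/s, 0.4/0.3 mm, 800 lines → 256 000 spectra/cube)
and `nir_640x168` (640 px of a 640×224-band detector, 900–1700 nm,
670 lines/s, 0.4/0.8 mm, 168 lines → 107 520 spectra/cube); both deliver
96 bands to the model. The configured image dimensions slightly exceed the
ceiling-derived minima for a 228.6×127 mm fillet (318×762 and 572×159);
they are taken as given since no padding rule is published. Latency:
5 warm-ups then 10 timed repetitions, population SD, single repetition SD
defined as 0; the clock is injectable so the protocol itself is tested
with a synthetic clock. Throughput reports MB = 10⁶ bytes (the published
MB/s column mixes binary and decimal conventions irreconcilably, so one
convention is fixed and no printed throughput is treated as reproducible —
they are hardware-bound regardless). The optics-only acquisition limit
(line rate / lines per cube) is reported beside the inference rate, never
folded into it. Feasibility against line speed is boundary-inclusive
(cubes/s ≥ required fillets/s).

## Numerical conventions and degenerate inputs

- Round-half-up for FM rasterisation and byte→pixel conversion (minimum
  1 pixel); ceiling for scan-geometry pixel requirements.
- 0-based row-major pixel order: pixel (r,c) ↔ batch row r·W+c.
- Dummy band replicates the last real band (avoids a reflectance step);
  a 96-band input to the padding op is an error, never a double-append.
- Calibration (raw−dark)/(white−dark) clips to [0,1.5] to tolerate
  specular pixels; white = dark anywhere is an error.
- Undefined metric ratios (no predicted positives, no actual positives)
  are NaN with a warning, never silently 0.
- Dynamic batch plans reject inputs above their configured maximum,
  mirroring an engine built with a fixed upper bound.

## Known limitations

- The GAN is a plain NumPy implementation tuned for clarity and
  determinism, not speed; it is desk-scale (thousands of spectra), far
  below the ~850 k-spectrum training regime of the deployed system.
- Scores depend on the encoder only; no ensembling, no temperature
  calibration of probabilities.
- The synthetic benchmark's near-perfect AUC reflects the generator's
  clean class structure, not expected field performance.
- INT8 execution, calibration-set search, GPU kernels and multi-GPU
  parallelism are out of scope; the affine utilities stop at the
  arithmetic.
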