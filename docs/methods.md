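# Methods

`umsrep` implements the training sequence behind unified modality-specific
representations (UMS-Rep): construct one shared backbone per imaging
modality, attach lightweight task-specific heads, fine-tune them under one
of three strategies, and derive explanation/recommendation outputs from the
trained heads. This note records the model, the conventions chosen where the
design was genuinely open, the synthetic data the package tests itself on,
and the numerical choices that make runs reproducible.

## The model

**Shared backbone (θsrc).** Two constructions are provided.

* *Denoising autoencoder (CDAE).* Encoder: four stages of 3×3 convolution
  with stride 2 (strided convolution replaces pooling), batch normalization
  and ReLU; a 64-px input reaches a 4×4 bottleneck. Decoder: four stages of
  nearest-neighbour 2× upsampling, 3×3 convolution, batch norm, ReLU,
  closed by a single-channel 3×3 convolution with a sigmoid. Trained
  unsupervised on (noisy → clean) pairs with MSE and RMSprop
  (batch 16, initial learning rate 1e-3).
* *Supervised dilated classifier.* Six 3×3 stride-1 same-padded
  convolutions with ReLU, dilation 2 in layers 4–6 (wider receptive field
  at unchanged cost), then global average pooling → FC → dropout 0.5 →
  FC(n_classes) → softmax, trained with categorical cross-entropy and Adam
  (batch 16, lr 1e-3).

The backbone records an *encoder cut point* — the deepest layer that still
produces a spatial feature map. Heads attach there and **alias** the
encoder parameters: there is exactly one copy of θsrc.

**Task heads (θ_Ti).** Classification heads are GAP → FC(width) →
dropout 0.5 → FC(n_classes) → softmax. Segmentation heads: on a CDAE
backbone the pretrained decoder is copied into the head (its final
reconstruction convolution replaced by a freshly initialized one-channel
convolution); on the stride-1 supervised backbone a symmetric stride-1
convolution stack mirrors the encoder widths down to one sigmoid channel
(no upsampling is needed because nothing was downsampled).

**Losses.** Classification: categorical cross-entropy. Segmentation: the
compound loss `w1·BCE + w2·Dice` with `w1 = w2 = 0.5`, each sample
contributing one term and the batch loss being their mean. The BCE is the
standard negative log-likelihood (non-negative, minimized at prediction =
target); probabilities are clamped to `[1e-7, 1-1e-7]` before logarithms.
Empty-vs-empty conventions: Dice loss 0 and IoU 1, so perfect agreement is
never penalized.

**Fine-tuning strategies.**

* *Independent* — θsrc frozen; each head minimizes its own loss with its own
  optimizer on its own data. The encoder runs in inference mode during
  independent fine-tuning so that even batch-norm running statistics cannot
  drift; "frozen" is bit-identical, and the test suite hashes the serialized
  state to prove it.
* *Alternating* — tasks take turns in declaration order, task *i* receiving
  `n_i` consecutive batches per cycle; each batch updates θsrc and that
  task's head. Each task keeps its own optimizer state (including state for
  θsrc); the number of cycles defaults to `epochs × max_i ceil(batches_i / n_i)`
  so every task sees roughly `epochs` passes over its data.
* *Joint* — every step draws one batch per task and minimizes
  `L = Σ_i w_i·L_i` with a single Adam step over θsrc and all heads. By
  construction the θsrc gradient is exactly the weighted sum of the
  per-task gradients (verified against a central-finite-difference oracle
  in float64 to 1e-4 relative error). Weights default to equal.

**Derivable tasks.** Gradient class-activation maps: the gradient of the
winning class's pre-softmax score with respect to the deepest convolutional
feature map is averaged per channel into weights; the weighted channel sum
is rectified (negative evidence zeroed — the text description of the method
omits this, the standard form includes it), min-max normalized to [0, 1]
(an all-constant map maps to zeros), then bilinearly upsampled to input
resolution. Normalization happens before upsampling. The recommendation
rule accepts an image iff the flow head predicts the requested flow *and*
the quality head predicts `good`; every other combination is excluded with
a reason naming the failed condition.

**Budget accounting.** Trainable parameters are counted in closed form
(conv: `(k_h·k_w·c_in + 1)·c_out`; FC: `(c_in + 1)·c_out`; batch norm:
`2·channels`, running statistics excluded as non-trainable) and
cross-checked against the engine's enumerated parameter arrays for every
shipped architecture. The published reference budgets ship as
per-component data (`umsrep.budgets`) because the exact filter widths
behind those counts are underdetermined; totals and percentage reductions
(`100·(1 − proposed/baseline)`) are always recomputed.

## The numerical engine

No deep-learning framework is a dependency: the models run on a compact
numpy engine (`umsrep.nn`) with hand-derived backward passes for
convolution (stride/dilation/TF-style same padding), batch norm, nearest
upsampling, GAP, FC, dropout, softmax and sigmoid, plus SGD/RMSprop/Adam.
Backprop is verified against central finite differences in float64 (worst
relative error below 1e-4 across layer combinations). Arithmetic is
float32 by default; weight initialization is fan-in-scaled uniform
(LeCun), seeded per run. All shuffling, noise draws and dropout masks
derive from the run seed, so identical configurations reproduce identical
histories bit for bit.

Pretraining uses plateau-driven learning-rate reduction (factor 0.5 after
3 non-improving validation epochs) and early stopping (8 non-improving
epochs) with best-weight restoration; the mechanisms are standard, the
constants are this package's defaults. Denoiser corruption is re-sampled
every epoch (a regularizer); a `fixed_noise` mode exists for deterministic
pairing. Validation corruption is fixed once per run.

## Synthetic phantoms

The package carries its own data: a seeded generator
(`umsrep.phantom_data`) with two families.

* `xray_like`: two bright ellipses ("lungs") on a dim textured background;
  their union is the segmentation mask. Abnormal classes add lesion discs
  *inside* a lung (one large disc for `abnormal`/`bacterial`, three small
  discs for `viral`); lesion placement is sampled in a margin-shrunken
  ellipse so the disc provably stays inside the mask.
* `doppler_like`: a half-period spectral envelope filled below a bright
  zero-velocity line; the filled region is the mask. TR/MV/MA differ in
  envelope peak height and width (class means 0.60/0.38/0.22 of the image
  side for peak, 0.72/0.55/0.42 for width); the default flow mix
  (TR 0.45, MV 0.35, MA 0.20) mirrors the reference corpus proportions.

Geometry is jittered uniformly within ±15% of class means — separable but
not trivial (a linear classifier on mean-intensity + bright-area features
reaches ≥95% accuracy at n = 500, which guarantees downstream tasks are
learnable at desk scale). Class and quality counts follow a deterministic
largest-remainder allocation. "Low quality" is rendered as Gaussian blur
plus multiplicative speckle — an artifact convention, since no physical
definition of low quality is available. Noise is parameterized on the
0–255 scale even for [0, 1] images (Gaussian σ in 0–255 units; Poisson
draws with mean = variance = pixel×255, i.e. the μ = σ² convention), and
values are clipped, not wrapped, after corruption.

What the phantoms do **not** emulate: anatomy, projection physics, scanner
artifacts, inter-patient variability, label noise. Passing the phantom
experiments shows the *training machinery* behaves as designed (sharing,
freezing, scheduling, gradients, metrics) — it says nothing about clinical
performance on real radiographs or echocardiograms.

## Desk-scale reference experiments

`umsrep.harness` fixes the problem sizes used by the test suite and by
`scripts/acceptance.py`; all were chosen to finish in about a minute each
on one CPU core.

* *Denoising*: 2,000 64-px X-ray phantoms, CDAE widths (16, 32, 64, 128),
  Gaussian σ = 30, ≤5 epochs. Measured: test PSNR of denoised output vs the
  raw noisy input, and the raw-input PSNR ladder over σ = 10…50 (strictly
  decreasing).
* *Supervised backbone*: 600 64-px Doppler phantoms, widths
  (8, 16, 16, 16, 32, 32), ≤8 epochs; test accuracy on the three flows.
  The reference widths (16, 32, 64, 64, 128, 128) remain the constructor
  default; the slimmer experiment widths are a deliberate desk-scale choice.
* *Heatmap localization*: a 2-class abnormality classifier (widths
  (8, 8, 16, 16, 16, 16), lesion contrast 0.6 — the level at which the
  desk-scale classifier reliably converges) on 500 phantoms; 50 freshly
  generated abnormal phantoms are probed and the fraction whose heatmap
  argmax falls inside the lesion bounding box is reported.
* *Strategy ordering* (5 seeds each): the *cooperative* suite fine-tunes
  three binary flow-discrimination heads on a briefly (4-epoch) pretrained
  supervised backbone at 32 px — independent fine-tuning is stuck with the
  partially trained frozen features while joint keeps adapting them, so
  joint's mean accuracy should be at least independent's. The
  *conflicting* suite pairs true lung segmentation with a
  classification head trained on randomly permuted labels, weighted 4× in
  the joint loss; the weight amplifies the unlearnable task's GAP-head
  gradient (intrinsically much weaker at θsrc than a dense decoder
  gradient) so that negative transfer is actually exercised — the worst
  case for sharing. Independent fine-tuning shields θsrc from that noise,
  so its mean test IoU should be at least joint's. Both orderings are
  asserted on means over the documented seeds (0–4 in the test suite).

An earlier candidate adversary — masks of *other* images as targets — turned
out to be accidentally cooperative (lung masks share a strong location
prior), which is why the conflict task uses permuted labels instead.

## Known limitations

* The engine is CPU/numpy; it is built for desk-scale reproducibility, not
  throughput, and supports only the layer types the architectures need.
* MS-SSIM uses as many dyadic scales as the image admits (≤5, weights
  renormalized); 64-px evaluations use 3 scales. Negative
  contrast-structure terms are clipped at zero before exponentiation.
* McNemar's test switches from the exact binomial to the
  continuity-corrected chi-square at 25 discordant pairs (standard
  practice; cross-checked against an independent implementation).
* Mean normalization subtracts a scalar training-split mean (per-image
  centring available behind a flag); no variance scaling.
* The bicubic resampler fixes one dialect (Catmull-Rom a = −0.5,
  half-pixel centers, clamped edges) for bit-reproducibility; other
  libraries' resizes will differ at edges.
* Wall-clock times in budget reports are measured and logged but never
  asserted — they are hardware facts.
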