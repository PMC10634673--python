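# Methods

This note documents the models and procedures implemented in `cryopicker`,
the parameters that matter, the design decisions taken where the design was
genuinely open, and the limits of what the desk-scale test regime shows.

## Denoising chain

Cryo-EM micrographs have very low signal-to-noise; the detector consumes a
preprocessed image produced by six deterministic stages, in order:

1. **Gaussian smoothing**, 9×9 kernel. The smoothing width follows the
   common kernel-size convention σ = 0.3·((k−1)/2 − 1) + 0.8 (σ = 1.7 for
   k = 9), truncated at radius 4 so the effective support is 9×9.
2. **Standardization** to zero mean, unit variance; a constant image is a
   degenerate-input error.
3. **8-bit conversion**: min→0, max→255, linear, rounded half-up. A
   constant image maps to all zeros.
4. **Fast non-local means**, patch size 7, patch search distance 10
   (a 21-px search window), strength h = 10 on the 0–255 scale. h is not a
   literature-fixed value and is exposed in `DenoiseConfig`.
5. **Adaptive Wiener filtering**, 5×5 window, noise power estimated as the
   mean local variance.
6. **CLAHE**, 16×16 tile grid. The clip limit is stored in the convention
   where 2 means "clip at twice the uniform bin height" and mapped to
   scikit-image's normalized clip limit as `value / 100`.
7. **Self-guided filtering** of the CLAHE output (radius 8 px, ε = 0.01 on
   intensities rescaled to [0, 1]): a local linear model of the image in
   itself, giving edge-preserving smoothing.

All convolutions use reflect borders so no artificial dark rim can seed
phantom detections at the edges. Every stage after the 8-bit conversion
stays within [0, 255]; the chain is deterministic and shape-preserving.

The package measures contrast recovery as
`SNR = (mean(foreground) − mean(background)) / sd(background)` over known
masks; on the seeded noisy-disk fixture the chain raises this statistic by
a factor of ≈3.7.

## Synthetic micrographs

The simulator renders soft-edged disks or ellipses (2-px sigmoid edge) at
a signed contrast offset on a smooth cosine background ramp, adds
unannotated high-contrast distractor blobs (the ice/carbon junk a picker
must reject), and finishes with additive Gaussian noise. Everything is a
pure function of `(seed, index)`.

Default conditions: 256×256 px, 5–15 particles of radius 14–20 px at
contrast −50 against a background of 128, noise σ = 25 (per-pixel SNR ≈ 2,
visibly noisy), background ramp amplitude 10, up to three distractors at
contrast −90. Particle centers stay at least one radius inside the border
and 1.2× the mean radius apart (rejection sampling, capped at 10,000
attempts).

The particle radius deserves a note: the detector downsamples by 32×, and
real micrographs (particles of 100–300 px on 4k–7k-px images) present
particles spanning one to several feature-grid cells to the backbone.
The simulation preserves that ratio. Particles much smaller than one
feature cell are nearly invisible to any /32-stride detector and do not
emulate the real geometry.

What the simulation does **not** model: projection physics (CTF, defocus),
structured noise, particle overlap and aggregation, carbon-film edges, or
orientation-dependent appearance. Passing tests on this data demonstrate
that the pipeline's machinery — labeling, matching, optimization, export,
scoring — is correct, not that the trained tiny model would transfer to
real micrographs.

## Detector

`SetPredictionDetector` follows the query-based set-prediction design:

* **Backbone**: grayscale input replicated to 3 channels, standardized per
  image over real (unpadded) pixels; output at 1/32 resolution. Full-scale
  configurations use a bottleneck residual network (50- or 152-layer
  layout, C = 2048, with per-channel affine layers in place of batch
  statistics, identity at initialization); the `tiny` backbone (five 3×3
  stride-2 conv+ReLU stages, C = 64) is the desk-scale path. Conv layers
  in front of ReLUs use fan-in (He) initialization with gain √2 — with
  plain Xavier scaling a five-deep ReLU stack attenuates the signal ~30×
  and the content drowns under the positional encodings. Inputs are padded
  bottom/right to a multiple of 32 so the /32 grid is exact; a feature
  cell is masked when all of its 32×32 pixels are padding.
* **Encoder**: 1×1 convolution from C to the hidden size d, flatten to
  H·W tokens, then post-norm transformer layers. Fixed 2-D sinusoidal
  positional encodings (half the channels for y, half for x) are added to
  the full self-attention input — queries, keys *and* values — at every
  layer, so the memory tokens carry explicit position. (Position only in
  the attention logits is not enough here: synthetic particles are
  visually identical, so token content alone cannot encode location, and
  the decoder could never regress coordinates.)
* **Queries and decoder**: each of the N slots owns a content embedding
  (initialized small, σ = 0.1) and a learned reference box in logit space,
  laid out on a jittered regular grid over the unit square with width/
  height 0.08. The decoder input is the content embeddings (never the zero
  vector — LayerNorm has a 1/√ε Jacobian at exactly zero input, which
  floods the inert first self-attention block with gradient and starves
  every other parameter through the gradient clip). The query positional
  code is the sinusoidal embedding of the slot's reference center, and
  cross-attention carries a Gaussian locality prior
  `−d²/(2σ²)`, σ = 0.06 (normalized units), centred on the reference, so
  each slot reads its own neighborhood from the first step. Content
  attention scores are gated by a zero-initialized scalar and phased in by
  gradient.
* **Heads** (shared across decoder layers): a linear + softmax class head
  over {particle, ∅} — its bias starts in favor of ∅, since most slots are
  empty in any micrograph — and a 3-layer ReLU perceptron whose output is
  added to the slot's reference box in logit space before the sigmoid, so
  boxes always lie in [0, 1] and slots specialize by region immediately.

N = 600 queries, d = 256, 6+6 layers, 8 heads and dropout 0.1 are the
full-scale defaults; the tested desk-scale profile is d = 64, 2+2 layers,
4 heads, dropout 0 (at a few hundred optimizer steps dropout noise
outweighs the faint particle signal and traps the model in an
input-independent solution), and 30–64 queries.

## Matching and loss

The matching cost and Hungarian loss are exactly the two-step formulation
stated in the README: probabilities (not logs) in the matching, −log in
the loss, ∅ terms down-weighted ×0.1, box loss λ_iou·GIoU + λ_L1·L1 with
λ_iou = 2, λ_L1 = 5. The assignment is solved exactly
(`scipy.optimize.linear_sum_assignment`); tests verify it against the
brute-force permutation minimum.

Numerical choices: probabilities are clamped at 1e-12 before the log;
degenerate zero-area box pairs define IoU = 0 and enclosing-box penalty 0
(loss 1, the continuity limit); matching ties are broken by adding the
ground-truth-to-reference-box center distance at weight 1.0 to the cost.
The tie-break matters: two slots that have both learned a particle's exact
box are interchangeable under the pure cost, the assignment then flips
between them from step to step, and — because the ∅ term is down-weighted —
both converge to confident duplicate predictions instead of one yielding.

During training the Hungarian loss is also applied to every intermediate
decoder layer's predictions through the shared heads (deep supervision).
The reported loss is always the final layer's. This is off by default at
full scale and on in the desk-scale profile, where the short gradient path
through the first decoder layer is what makes learning possible at a few
hundred steps.

## Optimization

AdamW with decoupled weight decay 1e-4 and gradient clipping. Full-scale
defaults: transformer lr 1e-4, backbone lr 1e-5, 300 epochs with a ×10 lr
drop after epoch 200, clip 0.1. The desk-scale profile
(`toy_train_config`) uses lr 1e-2 for backbone and transformer (the tiny
backbone is trained from scratch, not fine-tuned), clip 1.0, batch 4, the
drop at two-thirds of the run — and a third parameter group holding all
attention projections at lr/100. The last point is load-bearing: Adam
moves every parameter at roughly lr per step regardless of gradient
magnitude, so at lr 1e-2 the attention projections random-walk away from
their prior-dominated initialization faster than the rest of the network
can learn to use them.

Ground-truth boxes are normalized against the **padded** batch frame, so
image content and boxes stay aligned after collation; pick export maps
boxes back through the padded frame and clips centers to the original
micrograph bounds. Training is fully seeded and single-threaded;
checkpoints (a zip of parameter arrays plus the configs) reproduce
eval-mode outputs bit-identically.

## Post-processing and evaluation

Slots whose most probable class is ∅ are dropped before anything else, so
the confidence percentile is computed over plausible particles only. The
percentile filter keeps picks with score ≥ the 25th percentile of the
micrograph's scores, using the floor-rank percentile (the observed score
at the floor of the rank), which guarantees at least ⌈0.75·n⌉ survivors
and keeps ties. The filter runs per micrograph by default, with a
dataset-wide alternative behind `--percentile-scope`. No non-maximum
suppression is applied by default; an optional center-distance
de-duplication exists for models that still emit near-coincident picks.

Evaluation matches picks to truth one-to-one, minimizing summed center
distance among pairs within tolerance (default: half the candidate truth
box width — a pick inside the particle's footprint is a hit). Precision,
recall and F1 (harmonic mean; a geometric-mean variant is available
behind a flag) come from the matched counts; Dice is deliberately
different — the pixel overlap of the two box-union masks,
2|P∩G|/(|P|+|G|) — because a count-based Dice would duplicate F1.

## Desk-scale performance and known limitations

The acceptance pipeline trains the tiny detector on 64 simulated
micrographs for 30 epochs (≈480 optimizer steps) and evaluates on 16
held-out micrographs. Under the default noisy conditions it reaches
precision ≈ 0.45, recall ≈ 0.71 at one-radius tolerance, with the
percentile filter removing ≈ 22% of raw non-∅ slots. Two factors bound
this regime, both documented so the numbers are interpretable:

* **Optimization budget.** Set-prediction detectors of this family are
  notoriously slow to converge; published training runs use pretrained
  backbones and tens of thousands of optimizer steps even in their
  accelerated variants. Training everything from random initialization in
  a few hundred steps is one to two orders of magnitude below that, and
  the residual errors (median localization error ≈ 12 px against a ≈16-px
  tolerance, and imperfect duplicate suppression) are exactly the slow
  modes of this architecture.
* **Feature stride.** At 1/32 resolution, sub-cell localization must be
  decoded from learned channel structure; that is also a slow mode.

The single-micrograph overfit check — the same tiny model memorizing one
256×256 five-particle micrograph — reduces its training loss by ≈ 99%
within 200 iterations, confirming that the gradient path, matching and
loss are sound; the held-out gap is a budget limitation, not a
correctness one.

## Problem sizes used

Unit and property tests run on 48–96-px images and ≤ 12-slot models;
the overfit check uses one 256×256 micrograph (≈ 15 s); the parameter-
recovery experiment uses 64 + 16 micrographs of 256×256 at ≈ 2 minutes
per seed. The acceptance script runs the full set once (≈ 2.5 minutes).
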