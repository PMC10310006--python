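# Methods

## Survival model

Each patient *i* carries a bag of ROI images `X_i = {x_1, …, x_K}` (K may
vary), an observed time `Y_i = min(T_i, C_i)` and an event indicator
`δ_i ∈ {0,1}`. The model outputs one log-hazard `ĥ_θ(X_i)` per patient and
is fitted by minimising the Cox negative partial log-likelihood over the
event subjects, with the proportional-hazards assumption that covariates
act multiplicatively on a shared baseline hazard. Implementation choices:

* **Risk sets include ties** (`Y_j ≥ Y_i`, Breslow-style). With continuous
  simulated times ties are measure-zero, but real follow-up times are
  rounded, so the inclusive convention is the safe default.
* **Reduction.** The loss is divided by the number of events in the batch,
  so batch size does not rescale gradients; the raw sum is available via
  `reduction="sum"`.
* **Stability.** All log-sum-exp computations subtract the running maximum
  first. During bag-level training the risk sets are formed *within the
  minibatch* — standard practice for deep Cox models, since the full-cohort
  partial likelihood cannot fit in one pass.
* **All-censored input** contributes zero loss with a warning (and an error
  where silently learning nothing would be a user mistake, e.g. an
  all-censored training set).

The concordance index is computed over admissible pairs (event subject *i*,
any *j* with `Y_j > Y_i`). The strict-inequality indicator is the default,
so tied predictions score zero; `ties="half"` scores them 0.5, which is the
convention of lifelines / scikit-survival and is what the package uses when
comparing trained models (where exact ties are vanishingly rare, the two
conventions agree).

## Aggregation network

ROIs are sampled **with replacement** to a fixed bag length N = 10,
augmented and order-shuffled at training time, and embedded to 256
dimensions by a weight-shared CNN. Two Attention-LSTM blocks follow: each
is a 4-head scaled dot-product attention (head width 64) feeding a
two-stacked LSTM with hidden width 256. Block 1 uses self-attention; block
2 uses **co-attention whose query is the original CNN embedding sequence**
and whose keys/values are block 1's output — the reading of "visual
embeddings as the query" adopted here, switchable to `co_query="block1"`.
The final hidden state of the last LSTM (config: mean-pooling alternative)
passes through a 256→64→1 MLP whose last linear layer emits the log-hazard.

Further choices where the design was genuinely open:

* **Attention scaling.** Scores are divided by √d (the standard choice);
  a `scale="linear"` flag divides by d itself for the literal reading.
* **LSTM details.** Gate order (input, forget, cell, output) with
  forget-gate bias initialised to 1; hidden width 256 and the MLP widths
  are the package's own defaults.
* **Inference.** Because bags are sampled stochastically, inference
  averages the log-hazard over 8 independent draws with a fixed seed
  (`inference_draws`); one draw is used during training.
* **Gradient clipping** at global L2 norm 1.0 (package default);
  AdamW with decoupled weight decay; optional per-epoch exponential
  learning-rate decay (γ = 0.995 in the simulation profiles).

### Two-stage training

Stage 1 fine-tunes the CNN trunk with a temporary scalar Cox head on
ROI-level data, where every ROI inherits its patient's (time, event);
augmentation is applied (flips plus rotation for the digit design, flips
plus brightness/contrast for histology-style images). The head is then
discarded, the front half of the trunk's parameter tensors (in forward
order — "half of the front layers" is ambiguous for any modern backbone, so
freezing is defined over parameter groups, fraction configurable) is
frozen, and stage 2 trains the full aggregation network at bag level.
The naive baselines reuse the *same* stage-1 model and budget, so the
comparison isolates the aggregation step.

## Simulator

The generator defines the study conditions: survival is a fixed random
linear functional of pixel content,

    T_roi = exp( mean(I ⊙ M) + 0.001 ε ),   ε ~ Lognormal(0, 1),

with **one** Uniform(0,1) mask `M` drawn per cohort and shared by all ROIs
(a per-ROI-mask flag exists for ablation; with per-ROI masks the times are
pure noise with respect to image content and nothing is learnable). The
patient's true time is the mean of its ROI times; exactly ⌊n/2⌋ randomly
chosen subjects are censored at `C ~ Uniform(0, T)` (the censoring law is
unspecified upstream; uniform-below-truth is the package's documented
choice), and an 80/20 patient-level split is drawn per replicate.

The two ROI sources are synthetic stand-ins, generated programmatically so
no download is required:

* *Digit-like strokes* (28×28×1): a closed ring ("zero-like") versus a
  ring plus an upward tail ("six-like"), with randomised radius, stroke
  width, centre jitter, tail angle, amplitude and pixel noise. The tail
  gives the six-like class systematically larger ink mass, so the weighted
  intensity — and hence survival — differs between classes.
* *Textures* (H×W×3): two blurred-noise octaves around a per-image mean
  drawn `Uniform(0.5 ± 0.4·heterogeneity)`, giving heterogeneous bag
  brightness at the default heterogeneity of 1.

What these stand-ins do **not** emulate: real digit stroke topology, stain
variation, tissue morphology, spatial correlation between a patient's
lesions, or informative censoring. Passing tests therefore demonstrate that
the architecture and training recipe recover an image-determined hazard
under the stated generative law — not clinical performance on real slides.

A useful calibration bound: the *mask-aware oracle* risk, the negative mean
weighted intensity over the bag, orders an uncensored noise-0.001 cohort
almost perfectly (c-index ≥ 0.95 at n = 500). It is not exactly 1 even at
zero noise because the patient's time averages `exp(m_k)` while the oracle
averages `m_k` (Jensen's gap), and censored observation times add further
admissible-pair noise.

Note also that the *ROI-level* concordance ceiling on the two-ROI design is
only ≈ 0.75 (even for the oracle): each ROI carries half of the averaged
patient signal, and the duplicated patient records create uninformative
within-patient pairs. Strong signal appears at the patient level after
aggregation, which is what the comparison measures.

## Problem sizes and profiles

Full-scale profiles carry the full-scale training recipe: the digit simulation
profile (`sim_digit`: lr 5e-5, weight decay 1e-3, 100 epochs, batch 32,
γ = 0.995, 20 replicates) and the histology profile (`histology`: lr 1e-6,
weight decay 1e-2, batch 32, 50 epochs; stage 1: lr 1e-5, wd 1e-6, batch
64, 30 epochs) assume a pretrained ResNet-50-class backbone and full-size
data.

The package's own **desk profile** is the scaled-down configuration used by
the test suite and the acceptance script: the `small_cnn` backbone (three
3×3 conv blocks of widths 8/16/32, global average pooling, linear
projection to 256) trained *from scratch*, lr 1e-3 in both stages (a
from-scratch small CNN needs a larger step size than a pretrained
ResNet-50), 30 epochs, 5 replicates of n = 500 patients. Under these
conditions the study reproduces the qualitative full-scale result — learned
aggregation > average > min/max, with a gap over max well above 0.05 —
at a few minutes of CPU per replicate.

A `resnet50_like` backbone (bottleneck residual blocks, [3,4,6,3] layout,
batch normalisation) is implemented for the full-scale setting; weights can
be loaded from an `.npz` archive by parameter name.

## Numerical and reproducibility notes

* Everything runs on the package's own NumPy autodiff engine in float32;
  CPU runs are bit-reproducible under fixed seeds (embedding rows for
  identical inputs agree to float32 tolerance across batch positions, since
  batched BLAS may reassociate sums).
* Per-replicate seeds derive from the master seed via
  `SeedSequence(master, spawn_key=(replicate, stream))`, with separate
  streams for data generation, stage-1, stage-2 and inference; all derived
  seeds stay below 2³¹.
* Tertile ties at a cut point are resolved by stable sort order (original
  cohort position), making stratification deterministic; tertile group
  sizes differ by at most one.
* Known limitations: right censoring only (no interval censoring, no
  competing risks, no time-varying covariates); no multimodal fusion; the
  simulator's linear-functional hazard is deliberately simple.
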