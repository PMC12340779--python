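# Methods

`noduleclip` implements a semantic-guided vision-language pipeline for
one-year lung-cancer risk prediction from chest CT nodules. This note
documents the model, the preprocessing conventions, the synthetic phantom
cohort used for end-to-end validation, and the numerical and design choices
made where the design was genuinely open.

## Model

The core is a dual-encoder (image/text) architecture. Nodule imaging enters
as nine 2D sections ("2.5D"): the scan is resampled to 1 mm isotropic
spacing, a 50×50×50 mm cube is cropped around the nodule centroid (padded
with air, −1000 HU, where the cube leaves the scan), HU values are clipped to
[−1000, 500] and mapped linearly to [0, 1], and the cube is sectioned along
its nine symmetry planes through the centroid — three axis-aligned and six
diagonal. Each 50×50 section is resized to the encoder input size,
replicated to three channels, and standardized with the published image–text
pretraining pixel statistics.

Each view is encoded by a vision transformer; the nine per-view embeddings
form a bag pooled by attention-based multiple-instance learning (non-gated
tanh attention):

    a_k = softmax_k( wᵀ tanh(V h_k) ),   z = Σ_k a_k h_k .

The pooled embedding and the text embedding (a causal transformer pooled at
the end-of-text token) are projected to a shared 256-dimensional space and
aligned with a symmetric InfoNCE objective on cosine similarities divided by
a learnable temperature τ (initialized 0.03, clamped to [1e-3, 1]):

    L_img = −(1/B) Σ_i log softmax_j( sim(I_i, S_j)/τ ) at j=i
    L_sem = the same over the image index
    L_clip = (L_img + L_sem)/2 .

Two linear prediction heads — one per branch — consume the (unnormalized)
256-d embeddings and are trained with class-weighted cross-entropy on the
one-year cancer label; class weights are inverse class frequencies of the
training fold, normalized to mean 1. The total objective is
`L_clip + CE_img + CE_txt` with equal weighting. At inference only the image
branch is used, so no radiologist annotation is needed at prediction time.

### Low-rank adaptation

For fine-tuning from pretrained weights, rank-r adapters (default r=2,
scale α/r with α=1, dropout 0.25 on the adapter input) are injected into
every query/key/value projection of both transformers. The effective weight
is W₀ + (α/r)·B·A with B zero-initialized, so the adapted model is exactly
the base model until the first update. Base weights are frozen; adapters,
the two 256-d projection heads, the MIL head, the prediction heads and τ
remain trainable — 0.34% of all parameters at ViT-B/32 dimensions
(vision: patch 32, width 768, depth 12; text: width 512, depth 12, vocab
49408, context 77). Pretrained weights themselves are an optional plug-in
(checkpoint path); all tests run the randomly initialized "tiny" preset.
The MIL head pools the encoder's final projected (embedding-space) per-view
features; this keeps the bag pooling directly upstream of the 256-d
projection head and keeps the trainable budget inside the 0.4% envelope.

### Numerical substrate

No GPU tensor framework is assumed: the package ships a compact
reverse-mode autodiff engine on numpy arrays (`noduleclip.nn`) with fused
layer-norm/softmax/GELU primitives. All analytic gradients are validated
against central finite differences in the test suite. AdamW implements
decoupled weight decay. Dtypes are preserved end-to-end, so gradient checks
run in float64 while training runs in float32.

## Text side

Radiologist semantic features follow a harmonized schema: multi-label margin
(smooth / lobulated / spiculated / ill-defined), categorical consistency,
shape and margin conspicuity, and binary internal/external findings. MISSING
is distinct from "absent": an unassessed feature is skipped in text, while an
absent binary finding is rendered as an explicit negative in the findings
section only. A deterministic templater renders findings (one sentence per
non-missing feature) and an impression (salient general descriptors plus
present findings); an external generator can be plugged in via the
`text_provider` hook. Training text is drawn from findings or impression
with probability ½ and augmented by synonym substitution over a packaged
lexicon of non-clinical filler words (class vocabulary is never substituted)
and random contiguous sentence cropping.

Zero-shot prompts use the template "This nodule {feature} is {class}." for
(multi-)categorical features and "There is {feature}." / "No findings." for
binaries; class probabilities are softmaxed cosine similarities at the
learned τ.

Tokenization is a deterministic hashing whitespace tokenizer (CRC-32 into a
fixed vocabulary, SOT/EOT framing, padding/truncation at the context
length). A BPE tokenizer with the same `encode_batch` interface can be
substituted when pretrained text-encoder weights are used.

LIDC-style 1–5 ordinal medians are harmonized by fixed thresholds
(spiculation/lobulation ≥ 4 ⇒ the margin label; margin ≤ 2 ⇒ ill-defined,
otherwise smooth in the absence of irregular labels; texture 1–2/3/4–5 ⇒
pure ground glass / part-solid / solid; sphericity ≥ 4/3/≤ 2 ⇒
round/ovoid/irregular). The thresholds are an explicit, overridable
approximation — the harmonization is not published at that granularity.

## Training protocol

Splits are patient-level: 20% of patients held out as a test set, the rest
partitioned into five folds (each fold trains on 4/5 and validates on 1/5 of
the development patients). Batches of 16 are drawn with replacement,
weighted by semantic rarity: a nodule's weight is the inverse frequency of
its rarest non-missing feature value, floored at 0.5% to avoid
single-exemplar explosion, normalized to mean 1. An epoch is ⌈n/batch⌉
steps. Each fold checkpoints at the epoch with the best validation AUROC of
the image branch (early stopping patience 10, maximum 100 epochs by
default); defaults follow the fine-tuning recipe (AdamW, lr 1e-4, weight
decay 0.1, τ₀ = 0.03).

Per-fold probabilities are Beta-calibrated — μ(p) = sigmoid(c + a·ln p −
b·ln(1−p)) fitted by logistic regression of labels on (ln p, −ln(1−p)) with
non-negativity on a and b enforced by refitting without a negative-signed
feature — on that fold's validation split, the only unbiased in-training
choice. Nodule scores are max-aggregated per patient and the calibrated
per-fold scores are averaged into the ensemble. Calibration precedes
aggregation and ensembling so the calibrators stay at the nodule level where
the labels live.

## Phantom cohort

Real screening cohorts are restricted, so end-to-end behaviour is validated
on a synthetic cohort whose construction mirrors the structure the method
needs: per-nodule semantic records sampled from screening-like marginals,
volumes whose rendered morphology is a deterministic-plus-noise function of
the record, and labels drawn from a declared logistic model on the record —
never on the pixels directly, so an image-based predictor must recover the
signal through morphology.

Rendering: Gaussian background (−850 ± 40 HU); a radial implicit nodule
shape (per-direction radius modulation for irregular shape, a fourth-power
ball for polygonal, anisotropic scaling for ovoid); margin classes modulate
the surface — low-order lobes for lobulated, Poisson(8) radiating strands of
length 2–6 mm for spiculated (base-thickened cones, 2.4→0.8 mm, so the nine
section planes reliably cut them), Gaussian edge blur σ=1.5 mm for
ill-defined. Consistency sets interior attenuation (solid ≈ +30 HU, pure
ground glass ≈ −620, part-solid a ground-glass shell with a solid core,
semiconsolidation ≈ −300, peri-cystic solid with cystic spaces). Eccentric
calcification is a 1–2 mm +400 HU sphere at ≥ r/2 offset; cyst-like spaces
are −800 HU interior spheres; pleural attachment is a 3 mm soft-tissue
(0 HU) wall tangent to the nodule.

Margin labels are sampled with the coherent dependency that "smooth"
excludes every irregular descriptor (a margin with lobulation, spiculation
or blur is not smooth); pure ground-glass nodules never carry an eccentric
calcification. The label model defaults are: intercept −2.0, spiculated
+2.0, ill-defined +1.0, smooth −1.0, pure ground glass +0.5, eccentric
calcification −1.5, vascular convergence +1.0, and a size term
0.8·(r−6)/3 with r in mm; missing features contribute zero.

What the phantoms do *not* emulate: real lung anatomy (airways, vessels,
fissures), scanner/reconstruction variability, reader disagreement in the
semantic annotations, and multi-nodule patients. Passing the phantom study
therefore demonstrates that the pipeline's mechanics — alignment, pooling,
calibration, ensembling, zero-shot ranking — can recover a planted
morphology-mediated signal; it is not evidence about clinical performance.

## The end-to-end phantom study

The study generates 400 phantoms (cohort seed 7) at 32³ voxels — the
desk-hardware rendering scale; the generator default for general use is
64³ — and, per run seed: splits patients (the seed drives the whole
stochastic path), trains two folds of the tiny preset from random
initialization with the full objective, calibrates each fold on its
validation split, ensembles, and scores the held-out patients. The tiny
preset trains all parameters ("full" tuning): freezing randomly initialized
encoders and training rank-2 adapters, as the fine-tuning recipe would,
is not meaningful without pretrained weights. Because training starts from
random initialization rather than pretrained weights, the study uses
lr 1e-3 — the conventional from-scratch transformer rate — while the
`TrainConfig` default stays at the published fine-tuning rate 1e-4.
Train-time augmentation is applied at the view level as random in-plane
flips — the 2D realization of the volumetric flip augmentation, an exact
symmetry of the cubic crop (a dihedral variant adding right-angle rotations
and fresh pixel noise is available; it regularizes harder and underfits
within the 50-epoch budget). Without any view augmentation the encoder
memorizes each case's unique acquisition-noise fingerprint — identical
between training and evaluation views — and generalizes at chance.

## Numerical choices and edge cases

- Interpolation is trilinear for resampling and oblique sampling, bilinear
  for 2D resize; padding fills with air before normalization, so padded
  voxels are exactly 0 after the HU map.
- The nine-plane frames use a deterministic rule (first in-plane axis = the
  normalized projection of the lowest-index world axis not parallel to the
  normal; second completes a right-handed frame), so diagonal views crop the
  cube's corners rather than rescaling — uniform 1 mm physical scale across
  views.
- The contrast augmentation exponent is log-gamma in (−0.02, 0.02), i.e.
  intensity ↦ intensity^e^u on normalized values; a literal exponent near
  zero would flatten all contrast.
- Softmax/log-softmax are computed with a detached max shift; InfoNCE is
  exactly ln B on a uniform similarity matrix by construction.
- τ is clamped after each optimizer step, not inside the loss graph.
- Beta calibration clips probabilities to [1e-6, 1−1e-6] before the log
  features and maps the endpoints to their limits (0→0, 1→1 when a, b > 0).
- Bootstrap confidence intervals resample (score, label) rows — patients,
  when patient-level scores are supplied — and redraw resamples lacking a
  class; the interval is the 2.5/97.5 percentile over 10,000 resamples.
- Operating points at a target recall use observed-score thresholds; ties
  resolve toward higher recall, then fewer false positives (the screening
  convention).
- The Friedman/Nemenyi/Wilcoxon fold comparison treats identical systems as
  the boundary case (statistic 0, p = 1); t-based CIs use
  mean ± t₀.₉₇₅,ₙ₋₁·sd/√n.

## Known limitations

- The packaged tokenizer is a hashing toy adequate for the from-scratch
  configuration; using pretrained text weights requires plugging in the
  matching BPE tokenizer.
- The phantom study trains a tiny randomly initialized model; its absolute
  discrimination is bounded by the finite-sample Bayes ceiling of an 80-
  patient test draw and is far below what pretrained encoders reach on real
  cohorts.
- Multi-nodule patients are exercised by the aggregation API but not by the
  phantom cohort (one nodule per patient).
- DICOM reading assumes a single axis-aligned series per directory.
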