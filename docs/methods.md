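# Methods

## The model

`dermxai` implements an ontology-guided, self-explaining classifier for the
dermoscopic differential diagnosis of melanoma versus nevus. Instead of
predicting the diagnosis directly, a convolutional network predicts each
*characteristic* of a fixed 18-item catalogue (10 melanoma criteria, 8
nevus criteria, `dermxai.ontology`) with an independent sigmoid output.
The diagnosis then follows a transparent counting rule: **melanoma iff at
least two melanoma-class characteristics are detected**, nevus otherwise.
Nevus-class detections never contribute to the count.

### Guided attention

Each output class c has a class-activation map (CAM) computed from the
final convolutional stage: `A_c = relu(Σ_k w_ck F_k)`, min–max normalised
to [0, 1] per map and bilinearly upsampled to image size. During training
the CAMs are pushed toward the expert regions of interest H with a soft
Dice loss

    L_A = (1/N) Σ_i ( 1 − (1/C) Σ_c 2·Σ(A_ic ⊙ H_ic) / (Σ A_ic + Σ H_ic + ε) )

with ε = 1e-6; absent characteristics use all-zero target matrices (their
Dice term is identically zero, so they contribute a constant and no
gradient — supervision acts only on present characteristics). The combined
objective is

    L = λ_C · L_C + λ_A · L_A,    λ_C = 1, λ_A = 10 (defaults),

where L_C is the mean per-characteristic binary cross-entropy. Because
characteristics are multi-label, "cross entropy" is realised per criterion
on sigmoid outputs; the single-neuron reading applies to the *baseline*
model, which has one diagnosis output trained with plain cross-entropy and
no attention supervision.

For a backbone that ends in global average pooling followed by a linear
head, the gradient of a class logit with respect to the final feature maps
is constant (`w_c / hw`), so Grad-CAM channel weights equal the head
weights up to a positive factor and Grad-CAM coincides with the CAM after
normalisation. Training therefore uses the differentiable CAM form (no
second-order gradients needed); inference-time maps use the analytic
Grad-CAM weights, and the equality of the two routes is asserted in a test.

### Numerical choices

* The per-map max in the min–max normalisation is treated as a constant
  (stop-gradient) inside the loss — the usual stabilisation for
  guided-attention losses; the gradient implementation is verified exactly
  against central finite differences under that convention.
* An all-zero map stays all-zero under normalisation (no division by the
  ε-guard).
* The network is implemented directly on NumPy arrays: im2col convolutions
  with hand-written backward passes, ReLU, GAP, dropout, a linear head and
  an Adam optimiser (ε = 1e-8). The `tiny_cnn` backbone is four 3×3
  convolution blocks (16, 32, 64, 64 channels; strides 2, 2, 2, 1), giving
  an 8× downsampled final feature grid.
* Training keeps the checkpoint of the best validation epoch
  (`select_best`), mitigating last-epoch noise in small runs.
* Balanced sampling draws each epoch's indices with replacement, weighted
  so both diagnoses are equally likely.
* One config seed drives initialisation, sampling and augmentation.

### Calibration and explanations

Per-class temperature scaling divides each logit by a positive scalar T_c
fitted on validation data by bounded scalar minimisation of the binary NLL
(T ∈ [0.05, 20], tolerance 1e-4); classes with degenerate validation
labels keep T = 1. Calibrated scores drive three thresholds:

* detection at ≥ 0.5 (configurable; the printed rule threshold is not part
  of the catalogue, so 0.5 on calibrated scores is the package default),
* "strong evidence" wording and classifier certainty at > 0.7 (strict),
* region extraction over the top 20% of attribution values (exactly
  ⌊0.2·H·W⌋ pixels, ties broken in stable raster order; an absolute-
  threshold mode at 0.7 is available as an alternative).

When no characteristic passes 0.7, the explanation falls back to the
single most certain characteristic at the "some evidence" level, so an
explanation is never empty. Region boundaries are traced per 8-connected
component and serialised as [x, y] polygons; overlays draw only white
outlines so the lesion stays visible.

## The synthetic data generator

The generator emulates the structure of an expert-annotated dermoscopy
dataset: skin-tone background, one elliptical pigmented lesion, and one
parametric *motif* per supported criterion drawn inside the lesion. Ten of
the 18 criteria have motif renderers (six melanoma, four nevus); the
site-specific criteria and the "melanoma simulator" (an annotator
judgement, not a visual feature) are excluded from generation but remain
first-class in the ontology. Ground-truth masks are the exact renderer
footprints dilated by 2 px (a stand-in for hand-drawn ROI looseness),
clipped to the lesion. Melanoma images carry ≥ 2 melanoma motifs, nevus
images ≤ 1 melanoma and ≥ 1 nevus motif, so the labels reproduce the
diagnosis rule by construction.

Motifs are colour/shape codes chosen for visual separability (a grey
patch, a saturated-orange eccentric blob, bold white line bands, a
dark-blue grid, red dots of varying size, peripheral black dots, a light
uniform disc, mirrored olive discs, a regular pink dot lattice, dark
maroon circumferential spokes). Cosmetic fidelity to real dermoscopy is
explicitly not modelled — no hair, vasculature texture, colour gradients
within patterns, or inter-annotator mask disagreement — so a passing test
demonstrates the pipeline's mechanics and the *relative* behaviour of
guided vs unguided attention, not clinical performance.

Splits are at lesion level: a class-balanced test set is drawn first
(mirroring a balanced test design at configurable scale), the remainder is
split 82:18 into train and validation; every image of a lesion, and every
lesion of a patient, lands in exactly one split. Artefacts (edge rulers,
violet ink markings) are drawn strictly outside the lesion; with a
positive `artefact_diagnosis_bias` b the per-image artefact probability is
shifted by ±b/2 around the base rate for melanoma/nevus, producing the
spurious correlation that the guided-attention comparison exploits.

## Desk-scale study conditions

The standard experiments in `dermxai.experiments` (used by the tests and
by `scripts/acceptance.py`) run at a problem size one CPU handles in
minutes, chosen once:

* 300 lesions at 64×64 px, melanoma fraction 0.5, noise σ = 0.02,
  artefact probability 0.4 with bias 0.8;
* `tiny_cnn`, learning rate 1e-2, batch 16, dropout 0, 100 epochs (xai) /
  60 epochs (baseline), geometry-only augmentation (transpose, flips,
  shift-scale-rotate) — colour augmentations are counterproductive on
  colour-coded motifs;
* faithfulness on 100 freshly generated artefact-free images;
* bootstrap CIs with 1000 resamples inside the coverage simulation, 10000
  elsewhere (the default).

The reference configuration (`ModelConfig` defaults) keeps the full-scale
settings — 224×224 inputs, learning rate 1e-4, batch 32, dropout 0.4,
30/25 epochs, the full augmentation list including colour jitter, CLAHE
and HSV shifts, seed 42 — as documentation of the intended large-scale
regime; they are not what the desk-scale tests run.

## Evaluation

* **Balanced accuracy** (mean of per-class recalls) with seeded
  percentile-bootstrap CIs; resampling at image level; bootstrap draws
  that lose a class are dropped.
* **Attribution ratio** — mean attention inside the lesion over mean
  attention outside. For the multi-label model the attribution map of a
  diagnosis is the mean CAM over the detected characteristics (max-score
  characteristic when nothing is detected); the baseline uses its single
  CAM. Infinite ratios (zero outside attribution) are excluded from means
  and reported as a count.
* **Faithfulness** by contrastive deletion: pixels in the top t% of the
  attribution map are replaced by uniform random values per channel and
  the drop in the diagnosis-driving output score is recorded (swept over
  t = 5…95 for curves). The diagnosis-driving score is the melanoma
  probability for the baseline and the mean calibrated score over the
  originally detected characteristics for the characteristic model. A
  paired salient-vs-random-region variant quantifies whether the marked
  pixels matter more than equal-area random ones.
* **Dice overlap** on label sets (2TP/(2TP+FP+FN); two empty sets count
  as agreement 1 — configurable) and on soft masks
  ((2Σab+ε)/(Σa+Σb+ε), ε = 1 by default), plus per-image pairwise rater
  agreement.
* **Paired tests** (two-sided paired t, Wilcoxon signed-rank,
  Mann-Whitney U, Spearman) with Bonferroni adjustment min(1, m·p).

The bootstrap-coverage check fixes a known-rate classifier a priori at
sensitivity 0.65 / specificity 0.55 with n = 50 (25 per class): a
design-time simulation showed the percentile method attains 93.6–94.5%
coverage at moderate rates, whereas at more extreme rates the lattice
discreteness of recall at n = 25 per class pushes coverage below 93% — a
property of the statistic's discreteness, not of the implementation.

## Known limitations

* Only the `tiny_cnn` backbone is implemented; larger backbones are
  rejected with an informative error.
* The generator emits single-source masks; when multi-rater tables are
  read, labels merge by union (no information-loss-aware ROI merging).
* Acceptance-scale accuracies on synthetic data say nothing about real
  dermoscopy performance; they validate mechanics and relative effects.
* Polygon tracing uses sub-pixel iso-contours around the selected pixel
  set; vertices are continuous coordinates, not pixel corners.
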