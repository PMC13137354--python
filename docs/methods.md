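# Methods

`hemofuse` is a desk-scale, fully synthetic re-implementation of a
multimodal intracranial-hemorrhage (IH) analysis pipeline: image
enhancement, simulated temporal lesion progression, templated clinical
narratives, toy image/text encoders, cross-attention fusion classifiers,
and structured prognosis/therapeutic sentiment reports.  Everything runs
on one CPU in minutes and every random draw flows from a single run seed
through named substreams, so any artifact can be regenerated in
isolation.

## Synthetic data model

**Phantom.** One axial brain slice: an elliptical brain (default 64×64
px, semi-axes 26×22) with a bright skull ring (intensity 230), tissue at
a configurable mean (default 120) with Gaussian noise (default σ = 8),
and two darker elliptical ventricles (tissue − 60).  The phantom is a
geometric stand-in, not an MRI physics simulation: no bias fields, no
partial-volume effects, no anatomy beyond the three compartments.

**Lesions.** Each hemorrhage subtype gets the geometry radiologists use
to recognize it:

| subtype | geometry | default parameters |
|---|---|---|
| ICH | parenchymal disc + edema halo at 40% offset | radius 4.5–7 px |
| SDH | crescent along the inner skull | band width ≈ radius, 120° extent |
| EDH | biconvex lens straddling the inner skull | two-disc intersection |
| IVH | blood clipped to the ventricle mask | radius 3.5–5.5 px |
| SAH | thin rim along the whole brain boundary | width ≈ radius/3, 360° |

SDH and SAH share a parametric boundary-band family (width, angular
extent).  20% of SDH/SAH cases are rendered with an intermediate band
(width ~2 px, extent ~200–260°) that geometry alone cannot attribute to
either compartment — mirroring the real-world confusability of boundary
collections.  The clinical note always names the true subtype, so the
image and text modalities carry deliberately complementary information;
this property is what the fusion benchmark measures.  Lesions are
hyperdense (positive intensity offset, default +70; +55 for the subtler
SAH rim).

**Temporal progression.** A five-frame expand-then-resorb trajectory:
the lesion radius is multiplied by a growth factor per frame up to the
peak frame (index 2 of 5), then by a shrink factor; the intensity offset
decays after the peak (the hyperdense→hypodense evolution of a resolving
hematoma).  Defaults: growth 1.3, shrink 0.7, decay 0.25 per frame.  All
frames are rendered onto the *same* noisy base slice so inter-frame
differences reflect only lesion change.  A model-selection harness
regenerates candidate trajectories and scores them by mean squared error
against a reference sequence (averaged over frames and pixels), with
SSIM and PSNR reported alongside and ties broken by candidate order.

**Labels.** Four progression regimes are cycled across the cases of each
subtype — improving (growth 1.3, shrink 0.65, decay 0.3), worsening
(1.25, 1.25, 0), stable (1.15, 0.95, 0.1), indeterminate (1.2, 1.0, 0) —
so all sentiment classes appear in every split.  Prognosis sentiment is
a pure function of the mask-area trajectory: *uncertain* when shrink = 1
with no decay, *positive* when the final area is below the initial area,
*negative* when it exceeds the peak area, *neutral* otherwise.
Therapeutic sentiment tracks the resorption factor (positive < 1 <
negative; uncertain/neutral at 1).  The progression-parameter validator
therefore accepts shrink ≥ 1 (worsening and indeterminate courses), even
though the default regime is resorptive.  Dementia-risk level is a fixed
map: ICH→High, SDH→Moderate, EDH→Low, IVH→Moderate to High; SAH→Moderate
and Mixed→Moderate to High are documented extensions.

**Notes.** Four note kinds (consultation, progression, procedural,
radiology) are expanded from fixed templates: the subtype name, the
per-frame size trajectory, two prognosis-sentiment sentences and one
therapeutic sentence drawn from lexicon-bearing pools, a two-item
differential naming other subtypes, and generic filler until the
whitespace token count lands in [400, 900] (target ≈ 520).  Because the
notes are templated, their linguistic variety is far below real clinical
text; passing text benchmarks here says nothing about free-text
generalization.

**Manifest.** The packaged reference blueprint reproduces the published
per-split, per-subtype case counts (378/73/75 cases; ICH 142, SDH 91,
EDH 58, IVH 49, Mixed 38 in training) at 10 images per case; the five
stored progression frames are cycled across the ten image slots.  Mixed
cases are a random overlapping lesion pair and are excluded from subtype
classification by default.  The classification benchmark instead uses a
balanced five-subtype design (70/15/15 cases per subtype = 500 cases),
since the reference table has no subarachnoid row.

## Enhancement (entropy-adaptive CLAHE)

Tiles are half-open, row-major, 0-based (default 8×8 grid; a 2×2 mode
exists; non-divisible sizes enlarge the last tile; use ≥16×16-pixel
tiles so 256-bin histograms stay populated).  Per tile: Shannon entropy
of the histogram; a clip limit from an affine map of normalized entropy
h/8 onto [clip_min_rel, clip_max_rel] bin heights (defaults 1.5/4.0) —
the dependence of clip limit on entropy is the method's premise; the
affine form is our choice (monotone, bounded, two interpretable knobs).
Clipping redistributes excess uniformly (integer share per bin, the
remainder one count per bin from bin 0), conserving total mass exactly.
The remap LUT uses the CDF-min convention (darkest occupied level → 0);
a delta histogram falls back to the plain-CDF rule (all mass → L−1).
Pixels are blended bilinearly between the four neighboring tile LUTs by
distance to tile centers, with edge clamping.  Gamma correction follows
(fixed 1.25 by default, the empirically preferred value for brain MRI;
an entropy-adaptive mode γ = 0.5 + 2(1 − h̄/8) clamped to [0.5, 2.5] is
provided), then unsharp masking with a 3×3 box blur (strength 0.5) — the
sharpening kernel is unspecified upstream, so a standard unsharp mask
was chosen.  The comparison harness runs M-CLAHE, plain CLAHE (fixed
clip at clip_max_rel, no gamma/sharpening) and Laplacian sharpening and
tabulates PSNR, SSIM, entropy and RMS contrast before/after.  RMS
contrast is std(v/mean(v)) — a convention that makes values ≈1 on 8-bit
images — and no sign is asserted on contrast change (clip-limited
equalization can legitimately reduce it).

## Encoders

**Image.** A toy ViT: non-overlapping P×P patches (default P = 8), a
shared linear projection with per-vector standardization, a CLS token
and positional table, and two blocks of 4-head self-attention + ReLU MLP
with residuals and inter-block re-standardization.  All parameters are
frozen seeded random draws — at this scale the encoder is a
random-feature extractor and only the classifier heads are trained
(there is no deep-learning framework in the stack, and at 500 cases
random features are sufficient; this is the package's deliberate
design).  Initialization scales are 1/√fan-in for the projection and
1/√D elsewhere so attention logits vary enough for content-dependent
mixing; tiny near-zero initializations would make attention uniform and
the features spatially uninformative.

**Text.** Greedy longest-prefix WordPiece over a vocabulary built from
the packaged templates and lexicons (continuation pieces carry "##";
greedy failure maps the whole word to [UNK]), then additive token +
segment + position embeddings (all single-segment, max length 512 with
logged truncation).  The sentiment lexicons are fixed domain lists
(positive: "favorable outcome", "recovery", …; negative: "coma", "large
hematoma", …; neutral: "Glasgow Coma Scale", "midline shift", …),
extensible via JSON.  Estimated Association (EA) = 100 × complex words /
total words; "complex" defaults to the constituent words of the negative
and neutral lexicon phrases (a convention — no canonical definition
exists).

**Patch-size search.** The pufferfish optimizer minimizes a pluggable
fitness over a discrete candidate set {4, 8, 16, 32}: each population
member moves toward the best-so-far solution (exploration, β = 0.7) and
away from the worst "predator" position (evasion, α = 0.5), positions
snap to the nearest candidate, fitness values are memoized, and the
best-ever solution is kept (elitism).  The population is initialized
spread across the candidate set, so with population ≥ |candidates| every
candidate is evaluated and the search provably matches exhaustive
enumeration on small spaces.

## Fusion and classification

Per case, the feature extractor computes per-frame image features
([CLS ; mean patch embedding], quadrant-pooled patch embeddings as a
coarse spatial pyramid), a cross-attention fused vector (queries from
the note's token embeddings, keys/values from the encoded patches,
attended outputs mean-pooled over text positions), pooled token
embeddings ([mean ; max]), and a 9-dimensional clinical feature vector
(per-subtype mention counts, lexicon sentiment counts, EA/100).

Strategies:

* **early** — pooled raw patch ⊕ pooled raw token embedding, before any
  encoder;
* **late** — independent image ([CLS ; mean]) and text ([mean ; max ;
  clinical]) classifiers, probabilities averaged;
* **joint** — [CLS ; mean ; quadrants ; clinical ; cross-attention
  fused], plus a learnable class-aligned *text-evidence gate* on the
  logits: for the subtype head the evidence is −1 for subtypes the note
  does not mention (0 otherwise), for the sentiment heads the matched
  lexicon counts.  The gate weight starts at 0 and is learned jointly;
  it implements, as a rule-augmented decision layer, the Bayesian
  observation that the note's stated differential constrains the
  diagnosis.

Pooled raw text *embeddings* are deliberately excluded from the joint
representation: experiments during development showed they act as a
per-case memorization channel (each templated note is nearly unique)
that reduces test accuracy; the clinical features carry the same robust
signal in 9 dimensions.

Heads are single-hidden-layer perceptrons (hidden 64) trained with
mini-batch Adam (lr 0.01, batch 32, 100 epochs), softmax cross-entropy,
and decoupled weight decay (w ← (1 − lr·λ)w, λ = 1).  Every temporal
frame is a training sample (a natural ×5 augmentation; text features
repeat across a case's frames) and case-level predictions average
per-frame probabilities.  Each head is an ensemble of 5 seeded members;
checkpoints are selected on validation *loss* (validation accuracy
saturates on this benchmark and cannot rank checkpoints).  Three heads
share each representation: subtype (5-class), prognosis and therapeutic
sentiment (4-class each).  Class balance is generator-side (balanced
benchmark counts), so no loss re-weighting is applied.

Evaluation reports one row per (subtype, task): the subtype row carries
that class's one-vs-rest metrics; the sentiment rows carry metrics on
the subset of cases with that subtype, macro-averaged over the sentiment
classes present.  Division-by-zero metrics report 0 with a warning.

## Reports and pipeline

The structured report couples the predicted subtype and its fixed risk
level with the note's EA statistic and sentiment-keyed narrative
templates quoting the lexicon phrases actually matched in the case's
notes — an auditable, fully deterministic stand-in for LLM-generated
reports.  `run_pipeline` chains simulate → enhance → train → evaluate →
report under one output directory with a run-summary JSON referencing
every emitted file; reruns with the same seed are byte-identical.

## Problem sizes and reproducibility

Defaults were chosen so the full stack runs on one CPU: 64×64 phantoms,
500-case benchmark, 5 frames, toy encoder dims 64 (image) / 32 (text).
The acceptance harness (`scripts/acceptance.py`) re-derives the manifest
totals, oracle agreements and fusion accuracies from scratch in roughly
two minutes.  Results are bit-reproducible for a fixed seed on a fixed
platform; across platforms, floating-point differences can move
accuracies by at most one test case.

## Known limitations

* The phantom and templated notes are far simpler than clinical data;
  benchmark accuracies characterize the pipeline's mechanics, not
  clinical performance.
* Encoders are frozen random features; no representation learning
  occurs, and the adversarial/LLM generation stages of the original
  system are replaced by parametric simulation and templates.
* The progression model is geometric (scaled masks), not biophysical;
  MSE/SSIM trends across frames follow from the geometry by
  construction.
* Sentiment ground truth is defined by the generator's area rules;
  there is no inter-rater ambiguity to model.
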