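# hemofuse

Desk-scale multimodal analysis of intracranial hemorrhage (IH): synthetic
brain phantoms with subtype-specific lesions and simulated temporal
progression, entropy-adaptive contrast enhancement (M-CLAHE), templated
clinical narratives, toy vision/text encoders, cross-attention fusion
classifiers for hemorrhage subtype and prognosis/therapeutic sentiment,
and structured per-patient reports.

The package is aimed at method developers and teaching: every stage of a
radiology image+text fusion pipeline — enhancement, temporal simulation,
embedding, fusion, evaluation, reporting — is runnable end-to-end on one
CPU in minutes with **no external dataset**: the synthetic generator is a
first-class, tested component that plants complementary signal in the two
modalities (lesion geometry in the image, lexicon terms and the stated
differential in the note), so multimodal fusion has something real to
gain over either modality alone.

## The methods at the core

**Entropy-adaptive CLAHE.** The image is split into tiles; each tile's
histogram entropy H = −Σ pᵢ log₂ pᵢ sets its clip limit via an affine map
of H/log₂L onto [c_min, c_max] bin heights; clipped mass is redistributed
(total count conserved exactly); pixels are remapped through per-tile CDF
lookup tables, blended bilinearly between the four neighboring tile
centers; gamma correction v → (L−1)(v/(L−1))^γ (default γ = 1.25) and a
3×3 unsharp mask finish the pipeline.

**Temporal progression.** A lesion of radius r grows by g per frame to a
peak at the middle frame, then shrinks by s while its intensity offset
decays — the hyperdense→hypodense course of a resolving hematoma.
Candidate configurations are ranked by sequence MSE
(Σ_t Σ_xy (gen−ref)² / (T·N)) against a reference sequence.

**Fusion.** A toy ViT encodes each frame (patchify → linear projection +
standardization → CLS + positions → multi-head self-attention); WordPiece
tokens of the radiology note get additive token+segment+position
embeddings.  Cross-attention uses text queries against image patch
keys/values, softmax(QKᵀ/√d)V, pooled over text positions.  The joint
classifier combines the encoded image, low-dimensional clinical text
features (subtype mentions, sentiment lexicon counts, Estimated
Association EA = 100 × complex words / total words) and the
cross-attention vector, with a learnable class-aligned text-evidence gate
on the logits.  Early (raw-feature concatenation) and late (per-modality
probability averaging) baselines are included, along with
accuracy/precision/recall/F1, ROC/AUC, PR curves and confusion matrices.

A pufferfish optimizer (population moves toward the best solution and
away from the worst, snapped to a discrete candidate grid) selects the
ViT patch size against a pluggable fitness.

## Worked example

```python
import numpy as np
from hemofuse import (PhantomSpec, LesionSpec, ProgressionParams, generate_phantom,
                      simulate_progression, compare_methods, EnhanceParams, assign_labels)
from hemofuse.synthetic_data import progression_masks

phantom = PhantomSpec(seed=42)
lesion = LesionSpec("ICH", center=(30, 34), base_radius_px=6.0)
params = ProgressionParams()   # growth 1.3, shrink 0.7, decay 0.25
base = generate_phantom(phantom)
frames = simulate_progression(base, lesion, params, phantom)

areas = [int(m.sum()) for m in progression_masks(lesion, params, phantom)]
print("lesion area per frame:", areas)
print("labels:", assign_labels(lesion, params, phantom))
table = compare_methods(frames[0], EnhanceParams(tile_grid=(4, 4)))
print(table[["method", "psnr_db", "ssim", "entropy_after"]].round(4).to_string(index=False))
```

prints

```
lesion area per frame: [113, 185, 325, 161, 69]
labels: ('positive', 'positive', 'High')
   method  psnr_db   ssim  entropy_after
   mCLAHE  19.5947 0.7633         5.2194
    CLAHE  18.3864 0.8248         4.6545
Laplacian  17.3706 0.7084         4.6147
```

The lesion area rises to a peak at frame 2 (113 → 325 px²) and resorbs
to 69 px² — a shrinking final lesion, so the prognosis label is
*positive*, therapy response (shrink < 1) is *positive*, and an
intracerebral hemorrhage carries *High* dementia risk.  The enhancement
table compares M-CLAHE against plain CLAHE and Laplacian sharpening on
frame 0: M-CLAHE keeps the highest PSNR while raising the image's
entropy the most (5.22 bits after enhancement).

The same stages are available from the shell:

```bash
hemofuse simulate --out data/ --seed 7          # manifest + index (+ images)
hemofuse enhance slice.png --out enhanced.png --tiles 8x8 --compare table.csv
hemofuse train --out runs/ --seed 7             # fusion classifier checkpoint
hemofuse run-all --out runs/full --seed 7       # entire pipeline + reports
```

`run-all` finishes with one JSON + text report per test case, e.g.

```
Patient ID        : test-EDH-000
Hemorrhage type   : EDH
Risk of dementia  : Low
Estimated Assoc.  : 1.0%
Prognosis [positive]   : Prognosis is favorable: serial imaging shows progressive resorption of the collection and the clinical course supports recovery.
Therapeutic [positive] : Therapeutic outlook is positive: intervention achieved measurable reduction of the lesion and a curative course is plausible.
Evidence          : intraventricular hemorrhage; favorable outcome; improved survival; good outcome; recovery; stable
```

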