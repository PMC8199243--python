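# lvprop

Left-ventricle (LV) localization machinery for short-axis cardiac MRI: the
stages that come *before* a detection network. On a short-axis slice the LV
appears as a bright, roughly circular blood pool inside a darker myocardial
annulus; its area varies by over two orders of magnitude across slices, so
generic region-proposal anchors fit it poorly. `lvprop` implements three
cooperating pieces:

1. **Candidate regions by discriminative dictionary classification.** An
   image is oversegmented into ~400 SLIC superpixels; each region's
   descriptor is classified against 7 learned sub-dictionaries
   `D = [D_1 .. D_c]` of unit-norm atoms. Training minimizes

       min_{D,X}  Σ_i [ ‖Y_i − D X_i‖²_F + ‖Y_i − D_i X_i^i‖²_F
                        + Σ_{j≠i} ‖D_j X_i^j‖²_F ]
                  + ε₁‖X‖₁ + ε₂ ( tr S_W(X) − tr S_B(X) + ‖X‖²_F ),

   with ε₁ = 0.1, ε₂ = 0.001: sparse codes that reconstruct well, are
   discriminative per class (own-block reconstruction), and carry a Fisher
   penalty on within/between-class code scatter. Class 1 merges the
   myocardium and blood pool into one "LV" type; the other 6 classes come
   from k-means over non-LV regions. A test region `y` is coded on each
   sub-dictionary, `β_i = argmin ‖y − D_i β‖² + η₁‖β‖₁ + η₂‖β − m_i^i‖²`
   (η₁ = 0.1, η₂ = 0.005), and labeled by the smallest score. Same-label
   superpixels are fused into connected candidate regions.

2. **Scale-adaptive anchors.** The tight box of a candidate (the *saliency
   anchor*) spawns 9 concentric anchors: the box itself plus two squares
   (long/short side for a rectangle; diagonal/semi-diagonal for a square),
   each also scaled by s₁ and s₂ (0.8/0.9 on the dictionary path, 1.1/1.2 on
   the tracker path). Centers map onto the stride-16 feature grid of a
   region-proposal network; IOU-band labeling (RPN: >0.7 / <0.3;
   proposal layer: >0.5 / 0.1–0.5), random center perturbation for positive
   -sample augmentation, grid anchors (64/128/256 px) and NMS at 0.7 are
   included.

3. **Fast anchor generation by correlation-filter tracking.** Within one
   individual's slice sequence the dictionary runs only once: a
   DSST-style tracker follows the LV box. The box is tiled 3×3; each block
   learns a frequency-domain filter `A^l = Ḡ F^l`, `B = Σ_k F̄^k F^k`, with
   response `y = F⁻¹[Σ_l Ā^l Z^l / (B + λ)]` (λ = 0.01). Block peak
   displacements average into a prediction P₁, blended with the prior
   center as `P_t = w₁P₁ + w₂P₂` (w₁ = 0.2, w₂ = 0.8); a 1-D filter over 33
   geometric scales `1.02ⁿ, n ∈ [−16, 16]` re-estimates the size; numerator
   and denominator update by exponential moving average (θ = 0.025). Each
   tracked box emits the same 9 scale-adaptive anchors.

Evaluation follows detection practice: P = TP/(TP+FP), R = TP/(TP+FN),
F1 = 2PR/(P+R) with a 0.7 confidence gate, AP50/AP75 from the score-ranked
precision–recall curve, and mAP as the mean AP over individuals.

## Worked example

Everything below runs on seeded synthetic phantoms from `lvprop.phantoms`
(no external data needed):

```python
import numpy as np
from lvprop import (PhantomSpec, MotionSpec, make_phantom, make_sequence,
                    make_training_set, DictionaryProposalModel, RunConfig,
                    run_propose_dict, run_propose_track, iou)

# -- dictionary path: train on clean phantoms, propose on a new image
pairs = make_training_set(6, (800, 9000), seed=0, noise_sd=0.0)
images, masks = [p[0] for p in pairs], [p[1] for p in pairs]
model = DictionaryProposalModel(RunConfig(dict_max_iter=10, seed=0)).fit(images, masks)

spec = PhantomSpec(lv_center=(120.0, 140.0), blood_pool_radius=25.0,
                   myocardium_thickness=9.0, noise_sd=0.0, n_distractors=2, seed=7)
image, lv_mask, gt_box = make_phantom(spec)
proposals, anchors = run_propose_dict(image, model)
top = proposals[0][0]
print(f"candidates: {len(proposals)}")
print(f"top candidate box: {top.bounding_box}, area {top.area} px")
print(f"IOU vs ground-truth box {gt_box}: {iou(top.bounding_box, gt_box):.3f}")
print(f"anchors emitted: {len(anchors)}")

# -- tracker path: follow the LV through a drifting, zooming sequence
seq = make_sequence(PhantomSpec(lv_center=(80.0, 70.0), blood_pool_radius=22.0,
                                myocardium_thickness=8.0, noise_sd=0.02,
                                n_distractors=3, seed=5),
                    MotionSpec(n_frames=20, translation=(3.0, 0.0), scale=1.02))
frames = [f for f, _ in seq]
boxes, anchor_df = run_propose_track(frames, tuple(map(float, seq[0][1])))
ious = [iou(b.box, g) for b, (_, g) in zip(boxes[1:], seq[1:])]
print(f"tracked frames: {len(boxes)}, mean box IOU: {np.mean(ious):.3f}")
```

Output:

```
candidates: 2
top candidate box: (116, 87, 174, 154), area 2693 px
IOU vs ground-truth box (107, 87, 174, 154): 0.866
anchors emitted: 18
tracked frames: 20, mean box IOU: 0.944
```

The top fused candidate covers the LV (IOU 0.87 against the rasterized
ground-truth box; the second, smaller candidate is a distractor blob that
downstream IOU labeling discards). Each candidate contributes 9 anchors —
hence 18 rows in the anchor table. The tracker holds a mean box IOU of 0.94
over a 20-frame sequence with 3 px/frame drift and 2 %/frame growth.

A `lvprop` command-line tool mirrors the library:
`lvprop fixtures | train-dict | propose-dict | propose-track |
label-anchors | evaluate` (see `lvprop --help`).

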